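"""File formats: TSV genotype/count/truth/map tables, minimal VCF, YAML
run configuration.

All tables are tab-separated with a header row.  Genotype matrices use
cells in {AA, AB, BB, NA} with a metadata sidecar
(individual, population, phenotype, doubled_haploid).  Coordinates are
1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CODE_TO_STR, STR_TO_CODE, AA, AB, BB, MISSING,
    GenotypeMatrix, InputError, ReadCountMatrix,
)
from .genotyping import GenotypeThresholds
from .outliers import OutlierConfig
from .qcfilter import FilterConfig
from .simdata import SimConfig
from .stats import WindowConfig
from .genomescan import SmoothConfig

GT_MAP = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# genotype matrix TSV + metadata sidecar

def write_genotype_table(matrix: GenotypeMatrix, path, meta_path=None) -> None:
    frame = matrix.to_frame()
    frame.index.name = "locus"
    frame.to_csv(path, sep="\t")
    if meta_path is not None:
        write_metadata(matrix.metadata, meta_path)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "individual"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="individual")
    meta["doubled_haploid"] = meta["doubled_haploid"].astype(bool)
    return meta


def read_genotype_table(path, meta_path) -> GenotypeMatrix:
    """Read a genotype TSV plus its metadata sidecar.

    Round-trips byte-identically with :func:`write_genotype_table`.
    Unknown cell symbols and duplicate locus ids raise
    :class:`~radpopgen.core.InputError` naming the offending line.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise InputError(f"empty_input: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False)
    if frame.empty and len(frame.columns) == 0:
        raise InputError(f"empty_input: {path}")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        line = int(np.flatnonzero(frame.index == dup)[-1]) + 2
        raise InputError(f"duplicate locus id {dup!r} at line {line} of {path}")
    calls = np.empty(frame.shape, dtype=np.int8)
    values = frame.to_numpy()
    for (i, j), cell in np.ndenumerate(values):
        code = STR_TO_CODE.get(cell)
        if code is None:
            raise InputError(
                f"unknown genotype symbol {cell!r} at line {i + 2}, "
                f"column {frame.columns[j]!r} of {path}"
            )
        calls[i, j] = code
    metadata = read_metadata(meta_path)
    absent = [c for c in frame.columns if c not in metadata.index]
    if absent:
        raise InputError(f"metadata mismatch: individuals {absent[:5]} "
                         f"not described in {meta_path}")
    return GenotypeMatrix(
        loci=frame.index, individuals=frame.columns, calls=calls,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# read counts, truth, map

def write_read_counts(counts: ReadCountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_read_counts(path) -> ReadCountMatrix:
    frame = pd.read_csv(path, sep="\t")
    loci = pd.Index(frame["locus"].unique())
    individuals = pd.Index(frame["individual"].unique())
    a = frame.pivot(index="locus", columns="individual", values="count_a")
    b = frame.pivot(index="locus", columns="individual", values="count_b")
    a = a.loc[loci, individuals]
    b = b.loc[loci, individuals]
    return ReadCountMatrix(
        loci=loci, individuals=individuals,
        counts_a=a.to_numpy(dtype=np.int64), counts_b=b.to_numpy(dtype=np.int64),
    )


def write_linkage_map(linkage_map: pd.DataFrame, path) -> None:
    linkage_map.to_csv(path, sep="\t", index=False)


def read_linkage_map(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"marker", "chromosome", "position_cm"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"linkage map missing columns: {sorted(missing)}")
    if (frame["position_cm"] < 0).any():
        raise InputError("negative map positions")
    if frame["marker"].duplicated().any():
        raise InputError("a marker may sit on only one chromosome/position")
    return frame


# ---------------------------------------------------------------------------
# VCF

def write_vcf(matrix: GenotypeMatrix, path, linkage_map: pd.DataFrame | None = None,
              pos_scale: int = 10_000) -> None:
    """Minimal VCF 4.2, GT only.

    Mapped loci get CHROM from the map and POS = round(cM * 10^4) + 1 (an
    integer projection of the genetic position, documented here); unmapped
    loci go to contig "unplaced" with POS = running index.
    """
    map_idx = {}
    contigs = ["unplaced"]
    if linkage_map is not None:
        map_idx = {
            r.marker: (r.chromosome, int(round(r.position_cm * pos_scale)) + 1)
            for r in linkage_map.itertuples()
        }
        contigs = sorted({c for c, _ in map_idx.values()}) + ["unplaced"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radpopgen\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individuals) + "\n")
        rows = []
        unplaced_pos = 0
        for i, locus in enumerate(matrix.loci):
            if locus in map_idx:
                chrom, pos = map_idx[locus]
            else:
                unplaced_pos += 1
                chrom, pos = "unplaced", unplaced_pos
            gts = "\t".join(GT_MAP[int(c)] for c in matrix.calls[i])
            rows.append((contigs.index(chrom), pos,
                         f"{chrom}\t{pos}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"))
        for _, _, line in sorted(rows):
            fh.write(line)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Pipeline configuration: one section per stage plus global settings."""

    seed: int = 0
    outdir: str = "radpopgen_out"
    log_level: str = "INFO"
    n_discovery_individuals: int = 20
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: GenotypeThresholds = field(default_factory=GenotypeThresholds)
    filters: FilterConfig = field(default_factory=FilterConfig)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    smoothing: SmoothConfig = field(default_factory=SmoothConfig)


_SECTIONS = {
    "sim": SimConfig,
    "thresholds": GenotypeThresholds,
    "filters": FilterConfig,
    "outliers": OutlierConfig,
    "windows": WindowConfig,
    "smoothing": SmoothConfig,
}


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys fall back to defaults.

    The top-level ``seed`` propagates into the simulation and outlier
    sections unless those set their own.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("seed", "outdir", "log_level", "n_discovery_individuals"):
        if key in raw:
            kwargs[key] = raw[key]
    seed = int(kwargs.get("seed", 0))
    for name, cls in _SECTIONS.items():
        section = dict(raw.get(name) or {})
        for tuple_key in ("ancestral_freq", "pop_names", "neutral_band",
                          "sample_sizes"):
            if tuple_key in section and isinstance(section[tuple_key], list):
                section[tuple_key] = tuple(section[tuple_key])
        if cls in (SimConfig, OutlierConfig) and "seed" not in section:
            section["seed"] = seed
        kwargs[name] = cls(**section)
    return RunConfig(**kwargs)


def dump_run_config(config: RunConfig, path) -> None:
    raw = {
        "seed": config.seed,
        "outdir": config.outdir,
        "log_level": config.log_level,
        "n_discovery_individuals": config.n_discovery_individuals,
    }
    for name in _SECTIONS:
        section = dict(vars(getattr(config, name)))
        raw[name] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in section.items()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
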