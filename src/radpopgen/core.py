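"""Core containers shared across the pipeline.

Genotypes are stored as int8 codes in a loci x individuals array:
``AA=0, AB=1, BB=2, MISSING=-1``.  Individual metadata (population,
phenotype, doubled-haploid flag) rides along on every
:class:`GenotypeMatrix` so that downstream filters and statistics can
select analysis groups without extra plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
AA = 0
AB = 1
BB = 2

#: text representation used in TSV files
CODE_TO_STR = {MISSING: "NA", AA: "AA", AB: "AB", BB: "BB"}
STR_TO_CODE = {v: k for k, v in CODE_TO_STR.items()}

#: population label given to doubled-haploid reference individuals
REFERENCE_POP = "reference"

META_COLUMNS = ("population", "phenotype", "doubled_haploid")


class InputError(ValueError):
    """Malformed input data (wrong length, unknown symbol, mismatch...)."""


class ParameterError(ValueError):
    """Invalid configuration parameter."""


def _check_metadata(metadata: pd.DataFrame, individuals) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in metadata.columns]
    if missing:
        raise InputError(f"metadata missing columns: {missing}")
    absent = [i for i in individuals if i not in metadata.index]
    if absent:
        raise InputError(f"individuals absent from metadata: {absent[:5]}")
    return metadata.loc[list(individuals), list(META_COLUMNS)].copy()


@dataclass
class ReadCountMatrix:
    """Per-locus, per-individual read counts for alleles A and B."""

    loci: pd.Index
    individuals: pd.Index
    counts_a: np.ndarray  # (n_loci, n_ind) int
    counts_b: np.ndarray

    def __post_init__(self) -> None:
        self.loci = pd.Index(self.loci)
        self.individuals = pd.Index(self.individuals)
        self.counts_a = np.asarray(self.counts_a)
        self.counts_b = np.asarray(self.counts_b)
        shape = (len(self.loci), len(self.individuals))
        if self.counts_a.shape != shape or self.counts_b.shape != shape:
            raise InputError("count arrays do not match loci x individuals")
        if (self.counts_a < 0).any() or (self.counts_b < 0).any():
            raise InputError("negative read counts")

    @property
    def total(self) -> np.ndarray:
        return self.counts_a + self.counts_b

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: locus, individual, count_a, count_b."""
        li, ii = np.meshgrid(
            np.arange(len(self.loci)), np.arange(len(self.individuals)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "locus": self.loci[li.ravel()],
                "individual": self.individuals[ii.ravel()],
                "count_a": self.counts_a.ravel(),
                "count_b": self.counts_b.ravel(),
            }
        )


@dataclass
class GenotypeMatrix:
    """Called genotypes plus individual metadata.

    Parameters
    ----------
    loci, individuals
        Row / column labels.
    calls
        int8 array of genotype codes (see module constants).
    metadata
        DataFrame indexed by individual id with columns
        ``population``, ``phenotype``, ``doubled_haploid``.
    reasons
        Optional int8 array of call reasons (see :mod:`radpopgen.genotyping`).
    """

    loci: pd.Index
    individuals: pd.Index
    calls: np.ndarray
    metadata: pd.DataFrame
    reasons: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.loci = pd.Index(self.loci)
        self.individuals = pd.Index(self.individuals)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.individuals)):
            raise InputError("calls array does not match loci x individuals")
        if self.loci.has_duplicates:
            dup = self.loci[self.loci.duplicated()][0]
            raise InputError(f"duplicate locus id: {dup}")
        self.metadata = _check_metadata(self.metadata, self.individuals)

    # -- selection helpers -------------------------------------------------
    def individual_mask(self, population: str | None = None,
                        doubled_haploid: bool | None = None) -> np.ndarray:
        mask = np.ones(len(self.individuals), dtype=bool)
        if population is not None:
            mask &= (self.metadata["population"].to_numpy() == population)
        if doubled_haploid is not None:
            mask &= (
                self.metadata["doubled_haploid"].to_numpy().astype(bool)
                == doubled_haploid
            )
        return mask

    def analysis_mask(self) -> np.ndarray:
        """Non-reference, non-doubled-haploid individuals."""
        dh = self.metadata["doubled_haploid"].to_numpy().astype(bool)
        return ~dh

    @property
    def populations(self) -> list[str]:
        pops = self.metadata.loc[self.analysis_mask(), "population"]
        return sorted(pops.unique())

    def subset_loci(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.loci.get_indexer(keep)
        return GenotypeMatrix(
            loci=self.loci[idx],
            individuals=self.individuals,
            calls=self.calls[idx],
            metadata=self.metadata,
            reasons=None if self.reasons is None else self.reasons[idx],
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = self.individuals.get_indexer(mask)
        return GenotypeMatrix(
            loci=self.loci,
            individuals=self.individuals[idx],
            calls=self.calls[:, idx],
            metadata=self.metadata.iloc[idx],
            reasons=None if self.reasons is None else self.reasons[:, idx],
        )

    # -- summaries ---------------------------------------------------------
    def counts(self, mask: np.ndarray | None = None):
        """Per-locus genotype counts (n_AA, n_AB, n_BB, n_missing)."""
        calls = self.calls if mask is None else self.calls[:, mask]
        return (
            (calls == AA).sum(axis=1),
            (calls == AB).sum(axis=1),
            (calls == BB).sum(axis=1),
            (calls == MISSING).sum(axis=1),
        )

    def allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele A among non-missing calls (NaN if none)."""
        n_aa, n_ab, n_bb, _ = self.counts(mask)
        called = n_aa + n_ab + n_bb
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, (2 * n_aa + n_ab) / (2.0 * called), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.vectorize(CODE_TO_STR.get)(self.calls),
            index=self.loci,
            columns=self.individuals,
        )
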