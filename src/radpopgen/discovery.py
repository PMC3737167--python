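"""De novo RAD locus construction from stacked identical 89-bp reads.

Reads sharing an identical sequence form a *stack*; stacks within a small
Hamming distance of one another are paired into candidate biallelic SNP
loci subject to depth thresholds.  Candidate partners are found with a
pigeonhole index (four exact chunks of the tag: two sequences differing at
at most three positions must agree on at least one chunk), which makes
pairing near-linear without changing its semantics.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .core import InputError, ParameterError
from .simdata import TAG_LENGTH

MIN_STACK_DEPTH = 5     # stacks with fewer reads are discarded
MAX_STACK_DEPTH = 200   # stacks with more reads are discarded
MIN_ALLELE_DEPTH = 5    # both alleles of a candidate locus need this depth
MAX_SNPS_PER_TAG = 3

_N_CHUNKS = MAX_SNPS_PER_TAG + 1


@dataclass
class TagStack:
    sequence: str
    depth: int
    individuals: set = field(default_factory=set)


@dataclass(frozen=True)
class CandidateLocus:
    """A biallelic candidate SNP locus: two near-identical tag sequences."""

    locus_id: str
    allele_a: str
    allele_b: str
    offsets: tuple  # 1-based SNP positions within the tag
    depth_a: int
    depth_b: int


def default_individual_from_id(read_id: str) -> str:
    """Read ids follow ``individual:...``; the prefix names the individual."""
    return read_id.split(":", 1)[0]


def stack_reads(reads, min_depth: int = MIN_STACK_DEPTH,
                max_depth: int = MAX_STACK_DEPTH,
                individual_from_id=default_individual_from_id) -> list[TagStack]:
    """Group identical reads into stacks; drop under/over-covered stacks.

    Parameters
    ----------
    reads
        Iterable of ``(read_id, sequence)`` pairs; every sequence must be
        exactly 89 bp.
    min_depth, max_depth
        Inclusive retention bounds on stack depth ([5, 200] by default:
        stacks with fewer than five or more than 200 reads are discarded).
    """
    depths: dict[str, int] = defaultdict(int)
    members: dict[str, set] = defaultdict(set)
    for read_id, seq in reads:
        if len(seq) != TAG_LENGTH:
            raise InputError(
                f"read {read_id!r} has length {len(seq)}, expected {TAG_LENGTH}"
            )
        depths[seq] += 1
        members[seq].add(individual_from_id(read_id))
    return [
        TagStack(seq, d, members[seq])
        for seq, d in depths.items()
        if min_depth <= d <= max_depth
    ]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mismatch_offsets(a: str, b: str) -> tuple:
    return tuple(i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y)


def _candidate_pairs(stacks: list[TagStack]):
    """Yield index pairs (i < j) at Hamming distance 1..MAX_SNPS_PER_TAG."""
    bounds = [round(k * TAG_LENGTH / _N_CHUNKS) for k in range(_N_CHUNKS + 1)]
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, st in enumerate(stacks):
        for c in range(_N_CHUNKS):
            buckets[(c, st.sequence[bounds[c]:bounds[c + 1]])].append(i)
    seen = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i, j in itertools.combinations(members, 2):
            if (i, j) in seen:
                continue
            seen.add((i, j))
            d = hamming(stacks[i].sequence, stacks[j].sequence)
            if 1 <= d <= MAX_SNPS_PER_TAG:
                yield i, j


def pair_alleles(stacks: list[TagStack],
                 min_allele_depth: int = MIN_ALLELE_DEPTH) -> list[CandidateLocus]:
    """Pair stacks differing at 1-3 positions into candidate biallelic loci.

    Connected groups of stacks in which any tag position shows more than
    two distinct bases are discarded outright (biallelic constraint).
    Within a group, each stack pairs with its highest-depth available
    partner (ties broken toward the lexicographically smaller sequence);
    both alleles must reach ``min_allele_depth``.
    """
    n = len(stacks)
    adj: dict[int, set] = defaultdict(set)
    for i, j in _candidate_pairs(stacks):
        adj[i].add(j)
        adj[j].add(i)

    # connected components over the pairing graph
    comp_of = {}
    components: list[list[int]] = []
    for start in adj:
        if start in comp_of:
            continue
        comp = []
        stack_ = [start]
        while stack_:
            u = stack_.pop()
            if u in comp_of:
                continue
            comp_of[u] = len(components)
            comp.append(u)
            stack_.extend(adj[u] - comp_of.keys())
        components.append(comp)

    loci: list[CandidateLocus] = []
    for comp in components:
        if len(comp) > 2:
            cols = defaultdict(set)
            for idx in comp:
                for pos, base in enumerate(stacks[idx].sequence):
                    cols[pos].add(base)
            if any(len(b) > 2 for b in cols.values()):
                continue  # >2 alleles at some offset: not biallelic
        # greedy pairing by partner depth
        order = sorted(
            comp, key=lambda i: (-stacks[i].depth, stacks[i].sequence)
        )
        paired: set[int] = set()
        for i in order:
            if i in paired:
                continue
            partners = [j for j in adj[i] if j not in paired and j != i]
            if not partners:
                continue
            j = min(partners, key=lambda j: (-stacks[j].depth, stacks[j].sequence))
            if stacks[i].depth < min_allele_depth or stacks[j].depth < min_allele_depth:
                continue
            paired.update((i, j))
            a, b = sorted((stacks[i], stacks[j]), key=lambda s: s.sequence)
            loci.append(
                CandidateLocus(
                    locus_id="",  # assigned when the database is built
                    allele_a=a.sequence,
                    allele_b=b.sequence,
                    offsets=_mismatch_offsets(a.sequence, b.sequence),
                    depth_a=a.depth,
                    depth_b=b.depth,
                )
            )
    return loci


def discover(reads, individual_from_id=default_individual_from_id,
             individuals: set | None = None) -> list[CandidateLocus]:
    """Stack reads (optionally restricted to a subset of individuals) and
    pair alleles."""
    if individuals is not None:
        reads = (
            (rid, seq) for rid, seq in reads
            if individual_from_id(rid) in individuals
        )
    return pair_alleles(stack_reads(reads, individual_from_id=individual_from_id))


def build_snp_database(candidate_sets: list[list[CandidateLocus]]) -> pd.DataFrame:
    """Merge candidate loci found in separate individual-subset comparisons.

    Loci with identical allele-sequence pairs are deduplicated (depths from
    the first occurrence are kept); ids are stable: sorted by allele-A then
    allele-B sequence, numbered ``T000001``...  The result is therefore
    independent of subset processing order.
    """
    if not candidate_sets:
        raise ParameterError("at least one candidate set is required")
    for k, cs in enumerate(candidate_sets):
        if cs is None:
            raise ParameterError(f"candidate set {k} is empty")
    merged: dict[tuple, CandidateLocus] = {}
    for cs in candidate_sets:
        for loc in cs:
            merged.setdefault((loc.allele_a, loc.allele_b), loc)
    rows = []
    for i, key in enumerate(sorted(merged), start=1):
        loc = merged[key]
        rows.append(
            {
                "locus": f"T{i:06d}",
                "allele_a": loc.allele_a,
                "allele_b": loc.allele_b,
                "offsets": ",".join(map(str, loc.offsets)),
                "depth_a": loc.depth_a,
                "depth_b": loc.depth_b,
            }
        )
    return pd.DataFrame(
        rows, columns=["locus", "allele_a", "allele_b", "offsets", "depth_a", "depth_b"]
    ).set_index("locus")


def count_snps_from_multiplicities(tag_counts: dict[int, int]) -> int:
    """Total SNP count implied by a per-tag SNP-multiplicity tally.

    ``tag_counts`` maps SNPs-per-tag to the number of tags in that class;
    the implied SNP total is the multiplicity-weighted sum.
    """
    if any(k < 0 or v < 0 for k, v in tag_counts.items()):
        raise ParameterError("multiplicities and tag counts must be non-negative")
    return sum(k * v for k, v in tag_counts.items())
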