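"""Haploid RAD-locus genotyping.

Aligned reads are grouped into RAD loci keyed by (chromosome, strand,
5'-anchor of the read on the reference). Within each locus stack the
*leading haplotype* -- the unique sequence with the strictly highest read
count -- is the individual's haploid genotype, provided it occurs in at
least ``min_copies`` reads. Stacks whose total depth exceeds
``depth_factor`` times the individual's genome-wide expected depth
(total reads / total loci) are discarded as likely collapsed repeats.
Only loci called in every individual enter the SNP matrix, so the final
data set carries no missing genotypes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pysam

DEFAULT_MIN_COPIES = 2
DEFAULT_DEPTH_FACTOR = 4.5


class LocusKey(NamedTuple):
    """Identity of a RAD locus: reference name, 5' anchor (1-based), strand.

    Field order gives the deterministic total ordering (chrom, anchor, strand)
    used for locus iteration everywhere downstream. Forward- and reverse-strand
    stacks at the same cut site are distinct loci.
    """

    chrom: str
    anchor: int
    strand: str


@dataclass
class AlignedRead:
    """A reference-aligned read as consumed from SAM/BAM."""

    read_id: str
    individual_id: str
    chrom: str
    pos: int  # 1-based leftmost reference coordinate
    strand: str
    bases: str

    @property
    def locus_key(self) -> LocusKey:
        return LocusKey(self.chrom, self.pos, self.strand)


@dataclass
class LocusStack:
    """All reads of one individual at one locus, tallied by unique sequence."""

    key: LocusKey
    individual_id: str
    seq_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.seq_counts.values())


@dataclass
class HaploidCall:
    """One individual's haploid genotype (or exclusion reason) at one locus."""

    individual_id: str
    key: LocusKey
    haplotype: str | None
    support: int
    status: str  # called | tie | insufficient_copies | excess_depth
    depth: int = 0

    def __post_init__(self) -> None:
        if self.status == "called" and self.haplotype is None:
            raise ValueError("called status requires a haplotype")
        if self.status != "called" and self.haplotype is not None:
            raise ValueError(f"status {self.status} must not carry a haplotype")


@dataclass
class GenotypeTable:
    """Individuals x shared loci matrix of haplotypes with zero missing cells."""

    individuals: list[str]
    loci: list[LocusKey]
    cells: dict[tuple[str, LocusKey], str] = field(repr=False)

    def __post_init__(self) -> None:
        for ind in self.individuals:
            for key in self.loci:
                if (ind, key) not in self.cells:
                    raise ValueError(f"missing genotype for {ind} at {key}")

    def haplotype(self, individual: str, key: LocusKey) -> str:
        return self.cells[(individual, key)]

    def column(self, key: LocusKey) -> dict[str, str]:
        return {ind: self.cells[(ind, key)] for ind in self.individuals}


def read_alignments(
    path: str | Path,
    individual_id: str,
    trim_len: int = 70,
) -> tuple[list[AlignedRead], dict]:
    """Load aligned reads for one individual from SAM/BAM.

    Uses only read name, flag (strand / unmapped), reference name, leftmost
    position and sequence. The locus anchor is the read's 5' end on the
    reference: the post-clipping alignment start for forward reads, the
    alignment end for reverse reads. Unmapped reads and reads whose stored
    sequence is not ``trim_len`` long are skipped and counted.
    """
    reads: list[AlignedRead] = []
    skipped = {"unmapped": 0, "bad_length": 0, "no_position": 0}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.reference_start is None or rec.reference_name is None:
                skipped["no_position"] += 1
                continue
            seq = rec.query_sequence
            if seq is None or len(seq) != trim_len:
                skipped["bad_length"] += 1
                continue
            if rec.is_reverse:
                strand = "-"
                anchor = rec.reference_end  # 1-based inclusive 5' end of a reverse read
            else:
                strand = "+"
                anchor = rec.reference_start + 1
            reads.append(
                AlignedRead(rec.query_name, individual_id, rec.reference_name, anchor, strand, seq)
            )
    return reads, skipped


def stack_reads(aligned: Iterable[AlignedRead], individual: str) -> list[LocusStack]:
    """Group one individual's aligned reads into per-locus stacks.

    Returns stacks sorted by LocusKey. Reads whose sequence length is not 70
    are rejected (by read_id) -- they should have been filtered upstream.
    """
    counters: dict[LocusKey, Counter] = {}
    for read in aligned:
        if len(read.bases) != 70:
            raise ValueError(f"read {read.read_id!r} has length {len(read.bases)}, expected 70")
        counters.setdefault(read.locus_key, Counter())[read.bases] += 1
    return [
        LocusStack(key, individual, dict(counts))
        for key, counts in sorted(counters.items())
    ]


def call_leading_haplotype(stack: LocusStack, min_copies: int = DEFAULT_MIN_COPIES) -> HaploidCall:
    """Call the unique highest-count sequence of a stack as the haploid genotype.

    A shared top count is a tie (locus excluded for this individual); a unique
    top count below ``min_copies`` is insufficient support.
    """
    if not stack.seq_counts:
        raise ValueError("empty stack")
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    top = max(stack.seq_counts.values())
    leaders = [s for s, c in stack.seq_counts.items() if c == top]
    depth = stack.depth
    if len(leaders) > 1:
        return HaploidCall(stack.individual_id, stack.key, None, top, "tie", depth)
    if top < min_copies:
        return HaploidCall(stack.individual_id, stack.key, None, top, "insufficient_copies", depth)
    return HaploidCall(stack.individual_id, stack.key, leaders[0], top, "called", depth)


def compute_expected_depth(total_reads: int, total_loci: int) -> float:
    """Genome-wide expected read depth: total reads divided by total RAD loci."""
    if total_loci < 1:
        raise ValueError("no loci stacked: expected depth undefined")
    if total_reads < 0:
        raise ValueError("total_reads must be non-negative")
    return total_reads / total_loci


def filter_excess_depth(
    calls: Sequence[HaploidCall],
    expected_depth: float,
    factor: float = DEFAULT_DEPTH_FACTOR,
) -> list[HaploidCall]:
    """Mark calls whose stack depth is strictly beyond factor x expected depth.

    Depth equal to the cutoff is retained ("beyond" read strictly). The depth
    compared is the stack total across all sequences, not the leading
    haplotype's support, because collapsed repeats inflate the total.
    """
    if expected_depth <= 0:
        raise ValueError("expected_depth must be positive")
    cutoff = factor * expected_depth
    out = []
    for call in calls:
        if call.depth > cutoff:
            out.append(
                HaploidCall(call.individual_id, call.key, None, call.support, "excess_depth", call.depth)
            )
        else:
            out.append(call)
    return out


def genotype_individual(
    stacks: Sequence[LocusStack],
    min_copies: int = DEFAULT_MIN_COPIES,
    depth_factor: float = DEFAULT_DEPTH_FACTOR,
) -> tuple[list[HaploidCall], dict]:
    """Run the per-individual genotyping chain: call, then excess-depth filter.

    Expected depth is computed from ALL stacked loci of the individual before
    any exclusion, matching the genome-wide definition.
    """
    if not stacks:
        return [], {"loci_stacked": 0}
    total_reads = sum(s.depth for s in stacks)
    expected = compute_expected_depth(total_reads, len(stacks))
    calls = [call_leading_haplotype(s, min_copies) for s in stacks]
    calls = filter_excess_depth(calls, expected, depth_factor)
    summary = {
        "loci_stacked": len(stacks),
        "total_reads": total_reads,
        "expected_depth": expected,
        "loci_called": sum(c.status == "called" for c in calls),
        "loci_tie": sum(c.status == "tie" for c in calls),
        "loci_insufficient_copies": sum(c.status == "insufficient_copies" for c in calls),
        "loci_excess_depth": sum(c.status == "excess_depth" for c in calls),
    }
    return calls, summary


def intersect_shared_loci(
    per_individual_calls: Mapping[str, Sequence[HaploidCall]],
) -> GenotypeTable:
    """Build the zero-missing genotype table from loci called in every individual.

    Individual order follows the mapping's order (the sample sheet); locus
    order is the LocusKey total ordering. An empty intersection raises an
    error naming, for each locus surviving up to the fatal individual, the
    individual that eliminated it.
    """
    individuals = list(per_individual_calls)
    if len(individuals) < 2:
        raise ValueError("need at least two individuals to intersect loci")
    called: dict[str, dict[LocusKey, str]] = {
        ind: {c.key: c.haplotype for c in calls if c.status == "called"}
        for ind, calls in per_individual_calls.items()
    }
    shared = set(called[individuals[0]])
    for ind in individuals[1:]:
        survivors = shared & set(called[ind])
        if not survivors:
            lost = sorted(shared)[:10]
            raise ValueError(
                f"no RAD locus is genotyped in every individual: individual {ind!r} "
                f"eliminated the last surviving loci {lost}"
            )
        shared = survivors
    if not shared:
        raise ValueError(
            f"no RAD locus is genotyped in every individual: individual "
            f"{individuals[0]!r} has no called loci"
        )
    loci = sorted(shared)
    cells = {(ind, key): called[ind][key] for ind in individuals for key in loci}
    return GenotypeTable(individuals, loci, cells)


def write_genotype_tsv(calls: Sequence[HaploidCall], path: str | Path) -> None:
    """Per-individual genotype TSV: chrom, anchor, strand, haplotype, support, depth, status."""
    with open(path, "w") as fh:
        fh.write("chrom\tanchor\tstrand\thaplotype\tsupport\tdepth\tstatus\n")
        for c in sorted(calls, key=lambda c: c.key):
            hap = c.haplotype if c.haplotype is not None else "."
            fh.write(
                f"{c.key.chrom}\t{c.key.anchor}\t{c.key.strand}\t{hap}\t"
                f"{c.support}\t{c.depth}\t{c.status}\n"
            )
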