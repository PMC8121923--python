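"""SNP detection and the concatenated supermatrix.

Within each shared RAD locus, a column is polymorphic when at least two
distinct non-N nucleotides occur across individuals; columns where any
individual carries N are ignored. To avoid pseudo-SNPs caused by
indel-induced misalignment, a SNP is accepted only if it lies at least
``min_spacing`` bases from the immediately preceding polymorphic position
(accepted or not). Accepted alleles are concatenated per individual into
one string and written as a single FASTA alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from radhap.genotype import GenotypeTable, LocusKey

DEFAULT_MIN_SPACING = 8
NUCLEOTIDES = frozenset("ACGT")


@dataclass
class SnpSite:
    """One accepted SNP: locus, 0-based offset within the locus, per-individual alleles."""

    key: LocusKey
    offset: int
    alleles: dict[str, str]


@dataclass
class SnpAlignment:
    """Concatenated SNP strings per individual with per-column provenance."""

    individuals: list[str]
    sequences: dict[str, str]
    sites: list[SnpSite]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.sites and lengths and lengths != {len(self.sites)}:
            raise ValueError("sequence length does not match number of sites")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def detect_polymorphic_offsets(table: GenotypeTable, key: LocusKey) -> list[int]:
    """Offsets (ascending) with >=2 distinct non-N nucleotides; N columns skipped."""
    haps = [table.haplotype(ind, key) for ind in table.individuals]
    length = len(haps[0])
    offsets = []
    for i in range(length):
        column = {h[i] for h in haps}
        if not column <= NUCLEOTIDES:  # any N (or other ambiguity) voids the column
            continue
        if len(column) >= 2:
            offsets.append(i)
    return offsets


def apply_spacing_filter(offsets: list[int], min_spacing: int = DEFAULT_MIN_SPACING) -> list[int]:
    """Left-to-right scan keeping offsets >= min_spacing from the previous polymorphic offset.

    The first polymorphic offset is always accepted; every later offset is
    measured against its immediate predecessor in the input list, whether or
    not that predecessor was itself accepted (a rejected position still
    evidences an indel cluster).
    """
    if any(b <= a for a, b in zip(offsets, offsets[1:])):
        raise ValueError("offsets must be strictly ascending")
    accepted = []
    for i, off in enumerate(offsets):
        if i == 0 or off - offsets[i - 1] >= min_spacing:
            accepted.append(off)
    return accepted


def build_alignment(table: GenotypeTable, min_spacing: int = DEFAULT_MIN_SPACING) -> SnpAlignment:
    """Detect, space-filter and concatenate SNPs over all loci of the table."""
    sites: list[SnpSite] = []
    parts: dict[str, list[str]] = {ind: [] for ind in table.individuals}
    for key in table.loci:
        offsets = apply_spacing_filter(detect_polymorphic_offsets(table, key), min_spacing)
        for off in offsets:
            alleles = {ind: table.haplotype(ind, key)[off] for ind in table.individuals}
            sites.append(SnpSite(key, off, alleles))
            for ind in table.individuals:
                parts[ind].append(alleles[ind])
    if not sites:
        raise ValueError("no SNP accepted: alignment would be empty")
    sequences = {ind: "".join(parts[ind]) for ind in table.individuals}
    return SnpAlignment(list(table.individuals), sequences, sites)


def write_fasta(aln: SnpAlignment, path: str | Path) -> None:
    """One FASTA record per individual, header = individual_id."""
    if aln.n_sites == 0:
        raise ValueError("refusing to write an empty alignment")
    if len(set(aln.individuals)) != len(aln.individuals):
        raise ValueError("duplicate individual_id in alignment")
    with open(path, "w") as fh:
        for ind in aln.individuals:
            fh.write(f">{ind}\n{aln.sequences[ind]}\n")


def read_fasta(path: str | Path) -> SnpAlignment:
    """Read an alignment back (sequences only; site provenance is not stored in FASTA)."""
    individuals: list[str] = []
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate individual_id {rec.id!r} in {path}")
        individuals.append(rec.id)
        sequences[rec.id] = str(rec.seq).upper()
    if not individuals:
        raise ValueError(f"no FASTA records in {path}")
    if len({len(s) for s in sequences.values()}) != 1:
        raise ValueError(f"records of unequal length in {path}")
    return SnpAlignment(individuals, sequences, sites=[])


def write_sites_tsv(aln: SnpAlignment, path: str | Path) -> None:
    """Site provenance: column index, chrom, anchor, strand, offset, alleles observed."""
    with open(path, "w") as fh:
        fh.write("column\tchrom\tanchor\tstrand\toffset\talleles\n")
        for i, site in enumerate(aln.sites):
            observed = "".join(sorted(set(site.alleles.values())))
            fh.write(
                f"{i}\t{site.key.chrom}\t{site.key.anchor}\t{site.key.strand}\t"
                f"{site.offset}\t{observed}\n"
            )
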