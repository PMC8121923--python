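"""Ground-truthed RAD-seq simulator.

Generates what the genotyping pipeline consumes -- per-individual FASTQ
reads and their SAM alignments -- from a known Yule tree, known per-locus
haplotypes evolved under a GTR-family model, and a known read-depth /
error process, so every downstream stage can be scored against truth.

Emulated features of real single-end RAD data: 70-bp loci starting with the
SbfI restriction residual, diploid individuals with optional heterozygous
loci, negative-binomially overdispersed per-locus read depth, rare
repeat-like loci with doubled expected depth (the targets of the 4.5x
excess-depth filter), and independent per-base miscalls. Residual bases are
exempt from both mutation and sequencing error so that read QC pass rates
are controlled by design. Reads are emitted pre-aligned at their true locus
anchors: the pipeline treats alignment as an external step, and the
simulator bypasses it by writing truth coordinates directly.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pysam

from radhap.genotype import LocusKey
from radhap.models import STATES, SubstitutionModel
from radhap.tree import Tree

CHROM = "chrSim"
LOCUS_SPACING = 1000


@dataclass
class SimulationConfig:
    """Knobs of the generative process; defaults mirror a realistic RAD study.

    Depths and error rates correspond to a well-behaved Illumina RAD library:
    ~20x mean locus coverage with moderate overdispersion, 0.2% per-base
    miscall, low per-locus heterozygosity typical of inbred freshwater
    stickleback populations, and ~1% repeat-like loci.
    """

    n_taxa: int = 12
    individuals_per_taxon: int = 1
    n_loci: int = 800
    locus_len: int = 70
    residual: str = "TGCAGG"
    birth_rate: float = 1.0
    tree_depth_scale: float = 0.05  # mean root-to-tip, substitutions/site
    subst_model: SubstitutionModel = field(default_factory=SubstitutionModel.jc)
    heterozygosity: float = 0.01  # per (individual, locus) probability
    depth_mean: float = 20.0  # expected reads per locus
    depth_dispersion: float = 5.0  # negative-binomial size parameter
    error_rate: float = 0.002  # per-base miscall probability
    repeat_locus_rate: float = 0.01  # probability a locus has doubled depth
    emit_sam: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heterozygosity", "error_rate", "repeat_locus_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.locus_len <= len(self.residual):
            raise ValueError("locus_len must exceed the residual length")


@dataclass
class TruthSet:
    """Simulation ground truth for scoring the pipeline."""

    true_tree: Tree
    individuals: list[str]
    taxon_of: dict[str, str]
    true_haplotypes: dict[tuple[str, int], tuple[str, ...]]  # 1 or 2 alleles
    true_polymorphic_sites: list[tuple[int, int]]  # (locus index, offset)
    locus_keys: list[LocusKey]
    repeat_loci: set[int]
    config: SimulationConfig


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    depth_scale: float = 0.05,
) -> Tree:
    """Yule tree with mean root-to-tip path rescaled to ``depth_scale``."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_random.Random(int(seed)),
    )
    width = max(2, len(str(n_taxa)))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1:0{width}d}"
    tree = Tree.from_newick(dtree.as_string(schema="newick").strip())
    # The generator stops at the instant of the final split, leaving a
    # zero-length cherry; complete the Yule process by extending every
    # pending lineage by the waiting time to the next (uncut) speciation.
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    extra = rng.exponential(1.0 / (n_taxa * birth_rate))
    for leaf in tree.leaves():
        leaf.length += extra
    depths = []

    def walk(node, acc):
        if node.is_leaf:
            depths.append(acc + node.length)
        for child in node.children:
            walk(child, acc + (node.length if node.parent is not None else 0.0))

    walk(tree.root, 0.0)
    mean_depth = float(np.mean(depths))
    if mean_depth > 0 and depth_scale >= 0:
        factor = depth_scale / mean_depth if mean_depth else 0.0
        for node in tree.postorder():
            node.length *= factor
    return tree


def _evolve_site_states(
    tree: Tree, root_states: np.ndarray, rates: np.ndarray,
    site_class: np.ndarray, model: SubstitutionModel, rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve integer site states down the tree; returns leaf-name -> states."""
    eigvals, right, left = model._eigen()
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            if node.is_leaf:
                out[node.name] = root_states
            continue
        parent_states = states[id(node.parent)]
        child_states = parent_states.copy()
        for k, r in enumerate(np.unique(rates[site_class])):
            P = (right * np.exp(eigvals * node.length * r)[None, :]) @ left
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            mask = rates[site_class] == r
            for s in range(4):
                sel = mask & (parent_states == s)
                n_sel = int(sel.sum())
                if n_sel:
                    child_states[sel] = rng.choice(4, size=n_sel, p=P[s])
        states[id(node)] = child_states
        if node.is_leaf:
            out[node.name] = child_states
    return out


def evolve_loci(tree: Tree, config: SimulationConfig) -> TruthSet:
    """Evolve per-locus haplotypes along the tree; record truth.

    Residual bases are held invariant. Each individual inherits its taxon's
    leaf haplotype; with probability ``heterozygosity`` it gains a second
    allele differing at one random non-residual position.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    model = config.subst_model
    pi = np.asarray(model.base_freqs)
    rates, weights = model.category_rates()
    res_len = len(config.residual)
    var_len = config.locus_len - res_len

    individuals: list[str] = []
    taxon_of: dict[str, str] = {}
    for taxon in tree.leaf_names():
        if config.individuals_per_taxon == 1:
            individuals.append(taxon)
            taxon_of[taxon] = taxon
        else:
            for j in range(config.individuals_per_taxon):
                ind = f"{taxon}_{j + 1}"
                individuals.append(ind)
                taxon_of[ind] = taxon

    haplotypes: dict[tuple[str, int], tuple[str, ...]] = {}
    polymorphic: list[tuple[int, int]] = []
    keys = [
        LocusKey(CHROM, 1 + i * LOCUS_SPACING, "+") for i in range(config.n_loci)
    ]
    for locus in range(config.n_loci):
        root_states = rng.choice(4, size=var_len, p=pi)
        site_class = rng.choice(len(rates), size=var_len, p=weights)
        leaf_states = _evolve_site_states(tree, root_states, rates, site_class, model, rng)
        alleles_at: dict[int, set[str]] = {}
        for ind in individuals:
            states = leaf_states[taxon_of[ind]]
            hap = config.residual + "".join(STATES[s] for s in states)
            alleles = (hap,)
            if config.heterozygosity and rng.random() < config.heterozygosity:
                pos = int(rng.integers(res_len, config.locus_len))
                old = hap[pos]
                new = STATES[(STATES.index(old) + 1 + int(rng.integers(3))) % 4]
                alleles = (hap, hap[:pos] + new + hap[pos + 1:])
            haplotypes[(ind, locus)] = alleles
            for allele in alleles:
                for off in range(res_len, config.locus_len):
                    alleles_at.setdefault(off, set()).add(allele[off])
        for off in sorted(alleles_at):
            if len(alleles_at[off]) >= 2:
                polymorphic.append((locus, off))
    n_repeat = rng.binomial(config.n_loci, config.repeat_locus_rate)
    repeat_loci = set(map(int, rng.choice(config.n_loci, size=n_repeat, replace=False))) \
        if n_repeat else set()
    return TruthSet(tree, individuals, taxon_of, haplotypes, polymorphic, keys,
                    repeat_loci, config)


def simulate_reads(truth: TruthSet, out_dir: str | Path) -> dict[str, dict[str, str]]:
    """Emit per-individual FASTQ (and SAM) files; returns paths per individual.

    Depth per (individual, locus) is negative-binomial with mean
    ``depth_mean`` (doubled at repeat loci) and size ``depth_dispersion``;
    heterozygous loci split reads binomially between alleles; each non-residual
    base miscalls independently at ``error_rate``. FASTQ and SAM agree
    read-for-read; byte-identical output for a fixed seed.
    """
    config = truth.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res_len = len(config.residual)
    L = config.locus_len
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": CHROM, "LN": config.n_loci * LOCUS_SPACING + L}],
    }
    paths: dict[str, dict[str, str]] = {}
    qual = "I" * L
    for ind in truth.individuals:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2, truth.individuals.index(ind)])
        )
        fastq_path = out_dir / f"{ind}.fastq"
        sam_path = out_dir / f"{ind}.sam"
        records: list[tuple[str, str, int]] = []  # (read_id, bases, anchor)
        for locus in range(config.n_loci):
            mean = config.depth_mean * (2.0 if locus in truth.repeat_loci else 1.0)
            k = config.depth_dispersion
            depth = int(rng.negative_binomial(k, k / (k + mean)))
            if depth == 0:
                continue
            alleles = truth.true_haplotypes[(ind, locus)]
            if len(alleles) == 2:
                n_first = int(rng.binomial(depth, 0.5))
                origins = [alleles[0]] * n_first + [alleles[1]] * (depth - n_first)
            else:
                origins = [alleles[0]] * depth
            anchor = truth.locus_keys[locus].anchor
            for r, origin in enumerate(origins):
                bases = np.frombuffer(origin.encode(), dtype=np.uint8).copy()
                err = rng.random(L - res_len) < config.error_rate
                if err.any():
                    idx = res_len + np.nonzero(err)[0]
                    for pos in idx:
                        cur = chr(bases[pos])
                        shift = 1 + int(rng.integers(3))
                        bases[pos] = ord(STATES[(STATES.index(cur) + shift) % 4])
                records.append((f"{ind}_L{locus}_{r}", bases.tobytes().decode(), anchor))
        with open(fastq_path, "w") as fq:
            for read_id, bases, _ in records:
                fq.write(f"@{read_id}\n{bases}\n+\n{qual}\n")
        paths[ind] = {"fastq": str(fastq_path)}
        if config.emit_sam:
            with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
                for read_id, bases, anchor in records:
                    a = pysam.AlignedSegment(sam.header)
                    a.query_name = read_id
                    a.query_sequence = bases
                    a.flag = 0
                    a.reference_id = 0
                    a.reference_start = anchor - 1
                    a.mapping_quality = 60
                    a.cigarstring = f"{L}M"
                    a.query_qualities = pysam.qualitystring_to_array(qual)
                    sam.write(a)
            paths[ind]["sam"] = str(sam_path)
    return paths


def write_truth(truth: TruthSet, out_dir: str | Path) -> dict[str, str]:
    """Write the truth tree (Newick) and haplotype/SNP TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree_path = out_dir / "true_tree.nwk"
    tree_path.write_text(truth.true_tree.to_newick(include_supports=False) + "\n")
    hap_path = out_dir / "true_haplotypes.tsv"
    with open(hap_path, "w") as fh:
        fh.write("individual\tlocus\tanchor\talleles\n")
        for (ind, locus), alleles in sorted(truth.true_haplotypes.items()):
            fh.write(f"{ind}\t{locus}\t{truth.locus_keys[locus].anchor}\t{','.join(alleles)}\n")
    snp_path = out_dir / "true_polymorphic_sites.tsv"
    with open(snp_path, "w") as fh:
        fh.write("locus\toffset\n")
        for locus, off in truth.true_polymorphic_sites:
            fh.write(f"{locus}\t{off}\n")
    return {"tree": str(tree_path), "haplotypes": str(hap_path), "sites": str(snp_path)}


def write_sample_sheet(
    truth: TruthSet,
    paths: dict[str, dict[str, str]],
    path: str | Path,
    outgroup: set[str] | None = None,
) -> None:
    """Sample sheet TSV: individual_id, population, outgroup flag, file paths.

    By default the first taxon's individuals are flagged as the outgroup.
    """
    if outgroup is None:
        first = truth.true_tree.leaf_names()[0]
        outgroup = {i for i in truth.individuals if truth.taxon_of[i] == first}
    with open(path, "w") as fh:
        fh.write("individual_id\tpopulation\toutgroup\tfastq_path\tsam_path\n")
        for ind in truth.individuals:
            flag = 1 if ind in outgroup else 0
            fastq = paths.get(ind, {}).get("fastq", ".")
            sam = paths.get(ind, {}).get("sam", ".")
            fh.write(f"{ind}\t{truth.taxon_of[ind]}\t{flag}\t{fastq}\t{sam}\n")


def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> TruthSet:
    """Full generator: tree, truth, reads, truth files and sample sheet."""
    out_dir = Path(out_dir)
    tree = simulate_tree(config.n_taxa, config.birth_rate, config.seed,
                         config.tree_depth_scale)
    truth = evolve_loci(tree, config)
    paths = simulate_reads(truth, out_dir / "reads")
    write_truth(truth, out_dir / "truth")
    write_sample_sheet(truth, paths, out_dir / "samples.tsv")
    return truth
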