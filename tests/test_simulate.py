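import math

import numpy as np
import pytest
from scipy.stats import binom

from radhap.genotype import read_alignments, stack_reads
from radhap.qc import filter_and_trim_reads, read_fastq
from radhap.simulate import (
    SimulationConfig,
    evolve_loci,
    simulate_dataset,
    simulate_reads,
    simulate_tree,
)
from radhap.tree import robinson_foulds


class TestSimulateTree:
    def test_three_taxa_shape(self):
        tree = simulate_tree(3, seed=1)
        assert len(tree.leaves()) == 3
        n_branches = sum(1 for n in tree.postorder() if n.parent is not None)
        assert n_branches == 4  # rooted 3-leaf tree

    def test_deterministic_given_seed(self):
        t1 = simulate_tree(8, seed=5)
        t2 = simulate_tree(8, seed=5)
        assert t1.to_newick() == t2.to_newick()
        assert t1.to_newick() != simulate_tree(8, seed=6).to_newick()

    def test_mean_root_to_tip_depth_matches_scale(self):
        tree = simulate_tree(10, seed=2, depth_scale=0.07)
        depths = []

        def walk(node, acc):
            if node.is_leaf:
                depths.append(acc + node.length)
            for c in node.children:
                walk(c, acc + (node.length if node.parent is not None else 0))

        walk(tree.root, 0.0)
        assert abs(np.mean(depths) - 0.07) < 1e-9

    def test_terminal_branches_never_zero(self):
        for seed in range(20):
            tree = simulate_tree(6, seed=seed)
            assert all(l.length > 0 for l in tree.leaves())

    def test_both_four_taxon_shapes_appear(self):
        # Yule: balanced vs pectinate rooted shapes both have positive probability
        shapes = set()
        for seed in range(60):
            tree = simulate_tree(4, seed=seed, depth_scale=1.0)
            child_sizes = tuple(sorted(
                len([l for l in _subtree_leaves(c)]) for c in tree.root.children
            ))
            shapes.add(child_sizes)
            if len(shapes) == 2:
                break
        assert shapes == {(1, 3), (2, 2)}


def _subtree_leaves(node):
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_subtree_leaves(c))
    return out


class TestEvolveLoci:
    def test_zero_depth_scale_gives_identical_haplotypes(self):
        tree = simulate_tree(4, seed=1, depth_scale=0.0)
        config = SimulationConfig(n_taxa=4, n_loci=20, heterozygosity=0.0, seed=1)
        truth = evolve_loci(tree, config)
        assert truth.true_polymorphic_sites == []
        for locus in range(20):
            haps = {truth.true_haplotypes[(i, locus)][0] for i in truth.individuals}
            assert len(haps) == 1

    def test_all_homozygous_when_heterozygosity_zero(self):
        tree = simulate_tree(4, seed=2, depth_scale=0.05)
        config = SimulationConfig(n_taxa=4, n_loci=30, heterozygosity=0.0, seed=2)
        truth = evolve_loci(tree, config)
        assert all(len(a) == 1 for a in truth.true_haplotypes.values())

    def test_heterozygotes_have_two_distinct_alleles(self):
        tree = simulate_tree(4, seed=3, depth_scale=0.05)
        config = SimulationConfig(n_taxa=4, n_loci=50, heterozygosity=1.0, seed=3)
        truth = evolve_loci(tree, config)
        for alleles in truth.true_haplotypes.values():
            assert len(alleles) == 2 and alleles[0] != alleles[1]

    def test_every_haplotype_starts_with_residual(self):
        tree = simulate_tree(5, seed=4, depth_scale=0.1)
        config = SimulationConfig(n_taxa=5, n_loci=40, heterozygosity=0.3, seed=4)
        truth = evolve_loci(tree, config)
        for alleles in truth.true_haplotypes.values():
            for hap in alleles:
                assert hap.startswith(config.residual) and len(hap) == config.locus_len

    def test_high_divergence_makes_every_locus_polymorphic(self):
        tree = simulate_tree(6, seed=5, depth_scale=0.5)
        config = SimulationConfig(n_taxa=6, n_loci=50, tree_depth_scale=0.5, seed=5)
        truth = evolve_loci(tree, config)
        assert len({l for l, _ in truth.true_polymorphic_sites}) == 50
        assert len(truth.true_polymorphic_sites) >= 50


class TestSimulateReads:
    def test_noise_free_stacks_match_truth(self, tmp_path):
        tree = simulate_tree(3, seed=6, depth_scale=0.05)
        config = SimulationConfig(n_taxa=3, n_loci=40, error_rate=0.0,
                                  heterozygosity=0.0, depth_mean=20.0, seed=6)
        truth = evolve_loci(tree, config)
        paths = simulate_reads(truth, tmp_path)
        for ind in truth.individuals:
            aligned, _ = read_alignments(paths[ind]["sam"], ind)
            for stack in stack_reads(aligned, ind):
                locus = (stack.key.anchor - 1) // 1000
                assert set(stack.seq_counts) == {truth.true_haplotypes[(ind, locus)][0]}

    def test_same_seed_byte_identical_output(self, tmp_path):
        tree = simulate_tree(3, seed=7, depth_scale=0.05)
        config = SimulationConfig(n_taxa=3, n_loci=15, seed=7)
        truth = evolve_loci(tree, config)
        p1 = simulate_reads(truth, tmp_path / "a")
        p2 = simulate_reads(truth, tmp_path / "b")
        for ind in truth.individuals:
            for kind in ("fastq", "sam"):
                b1 = open(p1[ind][kind], "rb").read()
                b2 = open(p2[ind][kind], "rb").read()
                assert b1 == b2

    def test_fastq_and_sam_agree_read_for_read(self, tmp_path):
        tree = simulate_tree(3, seed=8, depth_scale=0.05)
        config = SimulationConfig(n_taxa=3, n_loci=10, seed=8)
        truth = evolve_loci(tree, config)
        paths = simulate_reads(truth, tmp_path)
        ind = truth.individuals[0]
        fq = {r.read_id: r.bases for r in read_fastq(paths[ind]["fastq"])}
        aligned, _ = read_alignments(paths[ind]["sam"], ind)
        sam = {r.read_id: r.bases for r in aligned}
        assert fq == sam

    def test_all_reads_pass_qc(self, tmp_path):
        tree = simulate_tree(4, seed=9, depth_scale=0.05)
        config = SimulationConfig(n_taxa=4, n_loci=30, error_rate=0.01,
                                  heterozygosity=0.2, seed=9)
        truth = evolve_loci(tree, config)
        paths = simulate_reads(truth, tmp_path)
        for ind in truth.individuals:
            reads = list(read_fastq(paths[ind]["fastq"]))
            kept = list(filter_and_trim_reads(reads, config.residual, config.locus_len))
            assert len(kept) == len(reads) > 0

    def test_repeat_loci_have_roughly_doubled_depth(self, tmp_path):
        tree = simulate_tree(3, seed=10, depth_scale=0.02)
        config = SimulationConfig(n_taxa=3, n_loci=200, repeat_locus_rate=0.2,
                                  depth_mean=30.0, depth_dispersion=50.0, seed=10)
        truth = evolve_loci(tree, config)
        paths = simulate_reads(truth, tmp_path)
        assert truth.repeat_loci
        ind = truth.individuals[0]
        aligned, _ = read_alignments(paths[ind]["sam"], ind)
        depth = {(s.key.anchor - 1) // 1000: s.depth for s in stack_reads(aligned, ind)}
        rep = np.mean([depth[l] for l in truth.repeat_loci if l in depth])
        normal = np.mean([d for l, d in depth.items() if l not in truth.repeat_loci])
        assert 1.5 < rep / normal < 2.5

    def test_fastq_only_mode(self, tmp_path):
        tree = simulate_tree(3, seed=11, depth_scale=0.05)
        config = SimulationConfig(n_taxa=3, n_loci=5, emit_sam=False, seed=11)
        truth = evolve_loci(tree, config)
        paths = simulate_reads(truth, tmp_path)
        assert all("sam" not in p for p in paths.values())


class TestGenotypingRecovery:
    def test_sensitivity_monotone_in_depth(self, tmp_path):
        """Fraction of truth haplotypes recovered rises with mean depth."""
        fractions = []
        for depth in (5.0, 10.0, 20.0):
            recovered = total = 0
            for seed in (21, 22):
                tree = simulate_tree(3, seed=seed, depth_scale=0.05)
                config = SimulationConfig(n_taxa=3, n_loci=120, depth_mean=depth,
                                          error_rate=0.002, heterozygosity=0.0,
                                          seed=seed)
                truth = evolve_loci(tree, config)
                paths = simulate_reads(truth, tmp_path / f"d{depth}_{seed}")
                from radhap.genotype import genotype_individual

                for ind in truth.individuals:
                    aligned, _ = read_alignments(paths[ind]["sam"], ind)
                    calls, _ = genotype_individual(stack_reads(aligned, ind))
                    by_locus = {(c.key.anchor - 1) // 1000: c for c in calls
                                if c.status == "called"}
                    total += config.n_loci
                    recovered += sum(
                        1 for l, c in by_locus.items()
                        if c.haplotype == truth.true_haplotypes[(ind, l)][0]
                    )
            fractions.append(recovered / total)
        assert fractions[0] < fractions[1] < fractions[2]
        assert fractions[2] > 0.95

    def test_balanced_heterozygote_ties_match_binomial(self, tmp_path):
        """Tie-exclusion frequency equals the depth-conditional binomial rate."""
        tree = simulate_tree(3, seed=31, depth_scale=0.03)
        config = SimulationConfig(n_taxa=3, n_loci=700, heterozygosity=1.0,
                                  error_rate=0.0, depth_mean=12.0, seed=31)
        truth = evolve_loci(tree, config)
        paths = simulate_reads(truth, tmp_path)
        from radhap.genotype import call_leading_haplotype

        observed = expected = variance = 0.0
        for ind in truth.individuals:
            aligned, _ = read_alignments(paths[ind]["sam"], ind)
            for stack in stack_reads(aligned, ind):
                d = stack.depth
                p_tie = binom.pmf(d // 2, d, 0.5) if d % 2 == 0 else 0.0
                expected += p_tie
                variance += p_tie * (1 - p_tie)
                call = call_leading_haplotype(stack)
                locus = (stack.key.anchor - 1) // 1000
                alleles = truth.true_haplotypes[(ind, locus)]
                if call.status == "tie":
                    observed += 1
                elif call.status == "called" and len(alleles) == 2:
                    # leading haplotype is the majority allele
                    counts = stack.seq_counts
                    assert counts[call.haplotype] == max(counts.values())
        assert abs(observed - expected) <= 3 * math.sqrt(variance)


def test_simulate_dataset_writes_consistent_truth(tmp_path):
    config = SimulationConfig(n_taxa=4, n_loci=25, seed=12)
    truth = simulate_dataset(config, tmp_path)
    assert (tmp_path / "samples.tsv").exists()
    from radhap.tree import Tree

    stored = Tree.from_newick((tmp_path / "truth" / "true_tree.nwk").read_text())
    assert robinson_foulds(stored, truth.true_tree) == 0
    sheet = (tmp_path / "samples.tsv").read_text().strip().splitlines()
    assert len(sheet) == 1 + len(truth.individuals)
    assert sum(line.split("\t")[2] == "1" for line in sheet[1:]) >= 1
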