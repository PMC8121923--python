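"""End-to-end orchestration: QC -> genotyping -> SNP matrix -> tree -> PCoA.

Two presets mirror the published protocol: the default run accepts leading
haplotypes with >=2 copies and SNPs >=8 bp from the previous polymorphic
position; the stringent robustness run uses >=5 copies and >=12 bp. Stage
outputs are materialized under the run directory and a machine-readable
report collects the per-stage counts (reads kept, loci stacked/called/
excluded, shared loci, polymorphic positions, accepted SNPs, model, lnL).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import radhap
from radhap import qc as qc_mod
from radhap.genotype import (
    genotype_individual,
    intersect_shared_loci,
    read_alignments,
    stack_reads,
    write_genotype_tsv,
)
from radhap.likelihood import encode_alignment
from radhap.ordination import p_distance, pcoa, write_coordinates
from radhap.search import bootstrap_support, fit_model, ml_tree, select_model
from radhap.snp import build_alignment, detect_polymorphic_offsets, write_fasta, write_sites_tsv
from radhap.tree import root_on_outgroup

PRESETS = {"default": (2, 8), "stringent": (5, 12)}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, report: dict | None = None) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.report = report or {}


@dataclass
class SampleSheet:
    individuals: list[str]
    population: dict[str, str]
    outgroup: set[str]
    fastq_path: dict[str, str]
    sam_path: dict[str, str]

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        individuals, population, outgroup = [], {}, set()
        fastq_path, sam_path = {}, {}
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"individual_id", "population", "outgroup", "fastq_path", "sam_path"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"sample sheet {path} must have columns {sorted(required)}")
            for row in reader:
                ind = row["individual_id"]
                individuals.append(ind)
                population[ind] = row["population"]
                if row["outgroup"].strip() in {"1", "true", "True"}:
                    outgroup.add(ind)
                fastq_path[ind] = row["fastq_path"]
                sam_path[ind] = row["sam_path"]
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual_id in sample sheet")
        return cls(individuals, population, outgroup, fastq_path, sam_path)


@dataclass
class RunConfig:
    sample_sheet: str
    out_dir: str
    residual: str = "TGCAGG"
    trim_len: int = 70
    min_copies: int = 2
    depth_factor: float = 4.5
    min_spacing: int = 8
    model: str = "auto"  # auto | JC | HKY | GTR with optional +G / +I
    bootstrap_n: int = 500  # 0 disables the bootstrap
    support_threshold: int = 50
    representatives_per_population: int = 2
    exclude_outgroup_in_pcoa: bool = True
    pcoa_axes: int = 2
    seed: int = 0

    @classmethod
    def preset(cls, name: str, **kwargs) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        min_copies, min_spacing = PRESETS[name]
        kwargs.setdefault("min_copies", min_copies)
        kwargs.setdefault("min_spacing", min_spacing)
        return cls(**kwargs)


def select_representatives(
    depth_by_individual: dict[str, int],
    population_map: dict[str, str],
    k: int = 2,
) -> set[str]:
    """Keep the k deepest-sequenced individuals per population.

    All individuals are kept where a population has <= k; ties break by
    individual_id ascending.
    """
    missing = set(depth_by_individual) - set(population_map)
    if missing:
        raise ValueError(f"individuals without a population: {sorted(missing)}")
    by_pop: dict[str, list[str]] = {}
    for ind in depth_by_individual:
        by_pop.setdefault(population_map[ind], []).append(ind)
    keep: set[str] = set()
    for members in by_pop.values():
        members.sort(key=lambda i: (-depth_by_individual[i], i))
        keep.update(members[:k])
    return keep


def run_full(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "radhap", "version": radhap.__version__},
        "config": asdict(config),
        "seed": config.seed,
        "per_individual": {},
        "outputs": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc, report) from exc
        return deco

    sheet = stage("sample_sheet")(lambda: SampleSheet.read(config.sample_sheet))

    # ----------------------------------------------------------------- QC
    def do_qc():
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        counts = {}
        for ind in sheet.individuals:
            stats = qc_mod.qc_fastq(
                sheet.fastq_path[ind], qc_dir / f"{ind}.fastq",
                config.residual, config.trim_len,
            )
            report["per_individual"][ind] = {"qc": stats}
            counts[ind] = stats["reads_kept"]
        return counts

    reads_kept = stage("qc")(do_qc)

    # ------------------------------------------------- representative selection
    def do_select():
        keep = select_representatives(
            reads_kept, sheet.population, config.representatives_per_population
        )
        return [i for i in sheet.individuals if i in keep]

    retained = stage("select_representatives")(do_select)
    report["individuals_retained"] = retained

    # ----------------------------------------------------------- genotyping
    def do_genotype():
        geno_dir = out / "genotypes"
        geno_dir.mkdir(exist_ok=True)
        per_ind_calls = {}
        for ind in retained:
            aligned, skipped = read_alignments(sheet.sam_path[ind], ind, config.trim_len)
            stacks = stack_reads(aligned, ind)
            calls, summary = genotype_individual(stacks, config.min_copies, config.depth_factor)
            summary["alignment_skipped"] = skipped
            report["per_individual"][ind]["genotyping"] = summary
            write_genotype_tsv(calls, geno_dir / f"{ind}.tsv")
            per_ind_calls[ind] = calls
        return per_ind_calls

    per_ind_calls = stage("genotype")(do_genotype)
    table = stage("intersect")(lambda: intersect_shared_loci(per_ind_calls))
    report["shared_loci"] = len(table.loci)

    # ------------------------------------------------------------ SNP matrix
    def do_matrix():
        aln = build_alignment(table, config.min_spacing)
        report["polymorphic_positions_found"] = sum(
            len(detect_polymorphic_offsets(table, key)) for key in table.loci
        )
        report["snps_accepted"] = len(aln.sites)
        report["loci_with_snps"] = len({s.key for s in aln.sites})
        fasta = out / "snp_alignment.fasta"
        write_fasta(aln, fasta)
        write_sites_tsv(aln, out / "snp_sites.tsv")
        report["outputs"]["fasta"] = str(fasta)
        return aln

    aln = stage("snp_matrix")(do_matrix)

    # ----------------------------------------------------------------- phylo
    def do_tree():
        data = encode_alignment(aln)
        if config.model == "auto":
            selection = select_model(data)
            model = selection.best
            report["model_selection"] = [
                {k: (round(v, 4) if isinstance(v, float) else v) for k, v in row.items()}
                for row in selection.table
            ]
        else:
            model, _, _ = fit_model(data, config.model)
        tree = ml_tree(data, model, seed=config.seed)
        from radhap.likelihood import log_likelihood

        report["model"] = {
            "label": model.label,
            "exchangeabilities": list(model.exchangeabilities),
            "base_freqs": list(model.base_freqs),
            "gamma_shape": model.gamma_shape,
            "p_invariant": model.p_invariant,
            "lnL": log_likelihood(tree, data, model),
        }
        if config.bootstrap_n > 0:
            bootstrap_support(data, tree, model, n=config.bootstrap_n, seed=config.seed)
        if sheet.outgroup and set(retained) & sheet.outgroup:
            rooted = root_on_outgroup(tree, set(retained) & sheet.outgroup)
        else:
            rooted = tree
        nwk = out / "tree.nwk"
        nwk.write_text(rooted.to_newick() + "\n")
        display = out / "tree_display.nwk"
        display.write_text(
            rooted.to_newick(support_threshold=config.support_threshold) + "\n"
        )
        report["outputs"]["newick"] = str(nwk)
        report["outputs"]["newick_display"] = str(display)
        return tree

    stage("phylo")(do_tree)

    # ------------------------------------------------------------------ PCoA
    def do_pcoa():
        exclude = sheet.outgroup if config.exclude_outgroup_in_pcoa else set()
        dist = p_distance(aln, exclude=frozenset(exclude))
        result = pcoa(dist, n_axes=config.pcoa_axes)
        coords = out / "pcoa_coordinates.tsv"
        write_coordinates(result, coords)
        report["outputs"]["pcoa"] = str(coords)
        report["pcoa_eigenvalues"] = [float(v) for v in result.eigenvalues[: config.pcoa_axes]]

    stage("pcoa")(do_pcoa)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report["outputs"]["report"] = str(report_path)
    return report
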