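"""Tree inference: NJ starting trees, NNI maximum-likelihood search,
model selection by AIC, and nonparametric bootstrap support.

The search is hill-climbing: starting from a neighbor-joining tree on
p-distances, branch lengths are optimized coordinate-wise and
nearest-neighbor-interchange rearrangements are accepted whenever they
increase the log-likelihood, until a full sweep improves the score by less
than ``SWEEP_TOL`` log units. One integer seed drives the NNI sweep order
and the bootstrap resampling through independently derived streams.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from radhap.likelihood import (
    PatternData,
    PruningEngine,
    encode_alignment,
    pattern_p_distances,
    resample_columns,
)
from radhap.models import SubstitutionModel, empirical_base_freqs
from radhap.snp import SnpAlignment
from radhap.tree import Node, Tree

SWEEP_TOL = 1e-4
BL_TOL = 1e-6
MAX_SWEEPS = 20


class ModelFitError(RuntimeError):
    """Raised when parameter optimization fails for a named candidate model."""


# --------------------------------------------------------------------------- NJ
def nj_tree(dist: np.ndarray, labels: list[str]) -> Tree:
    """Neighbor-joining tree; negative estimated branch lengths clamped to 0."""
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    tree = Tree.from_newick(str(skbio_nj(SkbioDM(dist, ids=labels))))
    for node in tree.postorder():
        if node.length < 0:
            node.length = 0.0
    return tree


# ------------------------------------------------------------------- NNI moves
def _nni_candidates(tree: Tree) -> list[tuple[Node, Node, Node]]:
    """All NNI moves as (focal_child_node v, child_of_v, partner_subtree).

    Swapping a child of v with a subtree on the parent side of the edge
    (parent(v), v) realizes one of the two NNIs across that internal edge.
    """
    moves = []
    for v in tree.postorder():
        if v.is_leaf or v.parent is None:
            continue
        u = v.parent
        if u is tree.root and len(u.children) >= 3:
            partners = [c for c in u.children if c is not v][:2]
            a = v.children[0]
            for p in partners:
                moves.append((v, a, p))
        else:
            siblings = [c for c in u.children if c is not v]
            if len(siblings) != 1:
                continue
            s = siblings[0]
            for a in v.children[:2]:
                moves.append((v, a, s))
    return moves


def _swap(a: Node, b: Node) -> None:
    """Exchange two subtrees between their (distinct) parents."""
    pa, pb = a.parent, b.parent
    pa.children[pa.children.index(a)] = b
    pb.children[pb.children.index(b)] = a
    a.parent, b.parent = pb, pa


# --------------------------------------------------------------------- ML search
def _ml_search(
    data: PatternData,
    model: SubstitutionModel,
    rng: np.random.Generator,
    start: Tree | None = None,
) -> tuple[Tree, float]:
    if start is None:
        start = nj_tree(pattern_p_distances(data), data.taxa)
    tree = start.copy()
    engine = PruningEngine(tree, data, model)
    best = engine.optimize_branch_lengths(tol=BL_TOL, improvement_tol=SWEEP_TOL)
    if len(data.taxa) < 4:
        return tree, best
    for _ in range(MAX_SWEEPS):
        sweep_start = best
        moves = _nni_candidates(tree)
        rng.shuffle(moves)
        for v, a, p in moves:
            if a.parent is not v or p.parent is not v.parent:
                continue  # a previous accepted move rearranged this neighborhood
            saved_len = v.length
            _swap(a, p)
            engine.refresh()
            lnl = engine.optimize_edge(v, tol=BL_TOL)
            if lnl > best + 1e-9:
                best = lnl
            else:
                _swap(a, p)
                v.length = saved_len
        best = engine.optimize_branch_lengths(tol=BL_TOL, improvement_tol=SWEEP_TOL)
        if best - sweep_start < SWEEP_TOL:
            break
    else:
        raise RuntimeError(f"NNI search did not converge in {MAX_SWEEPS} sweeps")
    return tree, best


def ml_tree(
    aln: SnpAlignment | PatternData,
    model: SubstitutionModel,
    seed: int = 0,
) -> Tree:
    """Maximum-likelihood tree by NJ start + NNI hill climbing (unrooted)."""
    data = aln if isinstance(aln, PatternData) else encode_alignment(aln)
    if len(data.taxa) < 3:
        raise ValueError("ML tree search needs at least 3 individuals")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    tree, _ = _ml_search(data, model, rng)
    return tree


# ----------------------------------------------------------------- model fitting
_LABELS = [
    f"{base}{g}{i}"
    for base, g, i in itertools.product(("JC", "HKY", "GTR"), ("", "+G"), ("", "+I"))
]


def _initial_model(label: str, data: PatternData) -> SubstitutionModel:
    gamma = 1.0 if "+G" in label else None
    pinv = 0.1 if "+I" in label else None
    base = label.split("+")[0]
    if base == "JC":
        return SubstitutionModel.jc(gamma, pinv)
    freqs = empirical_base_freqs(
        {t: "".join("ACGTN"[c] for c in data.codes[i]) for i, t in enumerate(data.taxa)}
    )
    if base == "HKY":
        return SubstitutionModel.hky(2.0, freqs, gamma, pinv)
    if base == "GTR":
        return SubstitutionModel.gtr((1.0,) * 6, freqs, gamma, pinv)
    raise ValueError(f"unknown model label {label!r}")


def _pack(model: SubstitutionModel, base: str) -> np.ndarray:
    x = []
    if base == "HKY":
        x.append(np.log(model.exchangeabilities[1]))
    elif base == "GTR":
        x.extend(np.log(np.asarray(model.exchangeabilities[:5])))
    if model.gamma_shape is not None:
        x.append(np.log(model.gamma_shape))
    if model.p_invariant is not None:
        p = min(max(model.p_invariant, 1e-6), 1 - 1e-6)
        x.append(np.log(p / (1 - p)))
    return np.array(x)


def _unpack(x: np.ndarray, template: SubstitutionModel, base: str) -> SubstitutionModel:
    i = 0
    ex = template.exchangeabilities
    if base == "HKY":
        kappa = float(np.exp(np.clip(x[i], -10, 10)))
        ex = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        i += 1
    elif base == "GTR":
        vals = np.exp(np.clip(x[i:i + 5], -10, 10))
        ex = (*map(float, vals), 1.0)
        i += 5
    gamma = template.gamma_shape
    if gamma is not None:
        gamma = float(np.exp(np.clip(x[i], -5, 7)))
        i += 1
    pinv = template.p_invariant
    if pinv is not None:
        pinv = float(1.0 / (1.0 + np.exp(-np.clip(x[i], -30, 30))))
        i += 1
    return template.with_params(
        exchangeabilities=ex, gamma_shape=gamma, p_invariant=pinv
    )


def fit_model(
    data: PatternData,
    label: str,
    topology: Tree | None = None,
    n_cycles: int = 2,
) -> tuple[SubstitutionModel, float, Tree]:
    """Fit one model's free parameters + branch lengths on a fixed topology.

    Base frequencies stay at their empirical (count-based) estimates.
    Returns (fitted model, log-likelihood, tree with optimized lengths).
    """
    if topology is None:
        topology = nj_tree(pattern_p_distances(data), data.taxa)
    tree = topology.copy()
    base = label.split("+")[0]
    model = _initial_model(label, data)
    lnl = -np.inf
    try:
        for _ in range(n_cycles):
            engine = PruningEngine(tree, data, model)
            lnl = engine.optimize_branch_lengths(tol=BL_TOL, improvement_tol=SWEEP_TOL)
            x0 = _pack(model, base)
            if x0.size:
                def neg(x: np.ndarray) -> float:
                    m = _unpack(x, model, base)
                    val = PruningEngine(tree, data, m).log_likelihood()
                    return np.inf if not np.isfinite(val) else -val

                res = minimize(neg, x0, method="Nelder-Mead",
                               options={"xatol": 1e-4, "fatol": 1e-4, "maxiter": 400})
                if not np.isfinite(res.fun):
                    raise ModelFitError(f"optimizer failed for candidate {label}")
                model = _unpack(res.x, model, base)
        engine = PruningEngine(tree, data, model)
        lnl = engine.optimize_branch_lengths(tol=BL_TOL, improvement_tol=SWEEP_TOL)
    except ModelFitError:
        raise
    except Exception as exc:
        raise ModelFitError(f"optimizer failed for candidate {label}: {exc}") from exc
    if not np.isfinite(lnl):
        raise ModelFitError(f"optimizer did not converge for candidate {label}")
    return model, float(lnl), tree


@dataclass
class ModelSelection:
    """AIC comparison of candidate models on a fixed NJ topology."""

    best: SubstitutionModel
    table: list[dict] = field(default_factory=list)  # label, lnL, k, AIC per candidate


def select_model(
    aln: SnpAlignment | PatternData,
    candidates: list[str] | None = None,
) -> ModelSelection:
    """Pick the AIC-minimizing model among JC/HKY/GTR x {+G} x {+I}.

    All candidates are scored on the same NJ topology with branch lengths
    re-optimized per candidate; k counts free model parameters plus branch
    lengths. Ties break toward fewer parameters.
    """
    data = aln if isinstance(aln, PatternData) else encode_alignment(aln)
    labels = candidates if candidates is not None else _LABELS
    topology = nj_tree(pattern_p_distances(data), data.taxa)
    n_branches = sum(1 for n in topology.postorder()) - 1
    rows = []
    for label in labels:
        model, lnl, _ = fit_model(data, label, topology)
        k = model.n_free_parameters + n_branches
        rows.append({"label": label, "lnL": lnl, "k": k, "AIC": 2 * k - 2 * lnl,
                     "model": model})
    rows.sort(key=lambda r: (round(r["AIC"], 6), r["k"]))
    table = [{k: v for k, v in r.items() if k != "model"} for r in rows]
    return ModelSelection(best=rows[0]["model"], table=table)


# -------------------------------------------------------------------- bootstrap
@dataclass
class BootstrapResult:
    """Bipartition support percentages from column-resampled replicates."""

    n_replicates: int
    support: dict[frozenset, float]
    seed: int


def bootstrap_support(
    aln: SnpAlignment | PatternData,
    ml: Tree,
    model: SubstitutionModel,
    n: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Support of each internal bipartition of ``ml`` over ``n`` replicates.

    Each replicate resamples alignment columns with replacement (same total
    length), then re-runs the ML search with model parameters fixed at the
    full-data estimates. Supports are attached to ``ml``'s internal nodes as
    integer percentages. Bit-for-bit reproducible given (seed, n).
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    data = aln if isinstance(aln, PatternData) else encode_alignment(aln)
    splits = ml.bipartitions()
    counts = {split: 0 for split in splits}
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, i]))
        rep = resample_columns(data, rng)
        rep_tree, _ = _ml_search(rep, model, rng)
        rep_splits = set(rep_tree.bipartitions())
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    support = {split: 100.0 * c / n for split, c in counts.items()}
    for split, node in splits.items():
        node.support = int(round(support[split]))
    return BootstrapResult(n_replicates=n, support=support, seed=seed)
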