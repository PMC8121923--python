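"""Felsenstein pruning likelihood for GTR-family models on SNP alignments.

Alignments are compressed to unique site patterns with multiplicities. The
conditional likelihood of each node is a (patterns x 4) array propagated
from the leaves to the root, mixed over the model's rate classes (discrete
gamma categories and, under +I, a zero-rate invariant class). The
log-likelihood is invariant to root placement for these reversible models.

Branch-length optimization uses the two-direction decomposition: with
conditional likelihoods both below and above an edge cached, the likelihood
as a function of that one branch length costs a single 4x4 mixing step per
rate class, so coordinate-wise Brent optimization is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from radhap.models import STATES, SubstitutionModel
from radhap.snp import SnpAlignment
from radhap.tree import Node, Tree

_CODE = {c: i for i, c in enumerate(STATES)}
MISSING = 4

BL_MIN = 1e-9
BL_MAX = 10.0


@dataclass
class PatternData:
    """Pattern-compressed alignment: taxa, (n_taxa x n_patterns) codes, weights."""

    taxa: list[str]
    codes: np.ndarray
    weights: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]


def encode_alignment(aln: SnpAlignment | dict[str, str]) -> PatternData:
    """Encode sequences as integer codes and collapse identical columns."""
    sequences = aln.sequences if isinstance(aln, SnpAlignment) else aln
    taxa = list(aln.individuals) if isinstance(aln, SnpAlignment) else list(sequences)
    mat = np.array(
        [[_CODE.get(c, MISSING) for c in sequences[t].upper()] for t in taxa],
        dtype=np.int8,
    )
    if mat.size == 0:
        raise ValueError("empty alignment")
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return PatternData(taxa, patterns, counts.astype(float))


def resample_columns(data: PatternData, rng: np.random.Generator) -> PatternData:
    """Bootstrap resample: draw n_sites pattern columns with replacement."""
    probs = data.weights / data.weights.sum()
    counts = rng.multinomial(data.n_sites, probs)
    keep = counts > 0
    return PatternData(data.taxa, data.codes[:, keep], counts[keep].astype(float))


def pattern_p_distances(data: PatternData) -> np.ndarray:
    """Pairwise proportion of differing (both-unambiguous) sites between taxa."""
    n = len(data.taxa)
    d = np.zeros((n, n))
    codes, w = data.codes, data.weights
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] != MISSING) & (codes[j] != MISSING)
            tot = w[ok].sum()
            diff = w[ok & (codes[i] != codes[j])].sum()
            d[i, j] = d[j, i] = diff / tot if tot > 0 else 0.0
    return d


class PruningEngine:
    """Cached pruning machinery for one (tree, data, model) triple.

    The tree is held by reference: callers may change branch lengths or
    topology, then call :meth:`refresh` to rebuild the cached conditionals.
    """

    def __init__(self, tree: Tree, data: PatternData, model: SubstitutionModel) -> None:
        leaf_names = set(tree.leaf_names())
        if leaf_names != set(data.taxa):
            raise ValueError(
                "tree leaves and alignment individuals differ: "
                f"{sorted(leaf_names ^ set(data.taxa))}"
            )
        self.tree = tree
        self.data = data
        self.model = model
        self.pi = np.asarray(model.base_freqs)
        self.rates, self.rate_weights = model.category_rates()
        self.eigvals, self.right, self.left = model._eigen()
        eye = np.vstack([np.eye(4), np.ones(4)])  # code 4 = missing
        self._leaf_part = {t: eye[data.codes[i]] for i, t in enumerate(data.taxa)}
        self._down: dict[int, np.ndarray] = {}
        self._up: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------------ matrices
    def pmat(self, t: float) -> np.ndarray:
        """Transition matrices for all rate classes: (n_classes, 4, 4)."""
        out = np.empty((len(self.rates), 4, 4))
        for k, r in enumerate(self.rates):
            P = (self.right * np.exp(self.eigvals * t * r)[None, :]) @ self.left
            np.clip(P, 0.0, None, out=P)
            out[k] = P
        return out

    # ---------------------------------------------------------------- conditionals
    def _compute_down(self) -> None:
        """down[v][k] = P(data below v | state at v), per rate class k."""
        self._down.clear()
        npat, ncls = self.data.n_patterns, len(self.rates)
        for node in self.tree.postorder():
            if node.is_leaf:
                part = np.broadcast_to(
                    self._leaf_part[node.name], (ncls, npat, 4)
                ).copy()
            else:
                part = np.ones((ncls, npat, 4))
                for child in node.children:
                    P = self.pmat(child.length)
                    down_c = self._down[id(child)]
                    for k in range(ncls):
                        part[k] *= down_c[k] @ P[k].T
            self._down[id(node)] = part

    def _compute_up(self) -> None:
        """up[v][k] = P(data outside subtree(v) | state at parent(v)), pi folded at root."""
        self._up.clear()
        npat, ncls = self.data.n_patterns, len(self.rates)
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            parent = node.parent
            if parent is self.tree.root:
                base = np.broadcast_to(self.pi, (ncls, npat, 4)).copy()
            else:
                up_p = self._up[id(parent)]
                P = self.pmat(parent.length)
                base = np.empty((ncls, npat, 4))
                for k in range(ncls):
                    base[k] = up_p[k] @ P[k]
            for sib in parent.children:
                if sib is node:
                    continue
                P = self.pmat(sib.length)
                down_s = self._down[id(sib)]
                for k in range(ncls):
                    base[k] *= down_s[k] @ P[k].T
            self._up[id(node)] = base

    def refresh(self) -> None:
        self._compute_down()
        self._compute_up()

    # ------------------------------------------------------------------ likelihood
    def site_likelihoods(self) -> np.ndarray:
        self._compute_down()
        root = self._down[id(self.tree.root)]
        total = np.zeros(self.data.n_patterns)
        for k, w in enumerate(self.rate_weights):
            total += w * (root[k] @ self.pi)
        return total

    def log_likelihood(self) -> float:
        lik = self.site_likelihoods()
        if np.any(lik <= 0):
            return -np.inf
        return float(np.dot(self.data.weights, np.log(lik)))

    def edge_log_likelihood(self, node: Node, t: float) -> float:
        """Log-likelihood as a function of the length of the edge above ``node``.

        Requires :meth:`refresh` to have been called with the current tree.
        """
        down = self._down[id(node)]
        up = self._up[id(node)]
        P = self.pmat(t)
        total = np.zeros(self.data.n_patterns)
        for k, w in enumerate(self.rate_weights):
            total += w * np.einsum("px,xy,py->p", up[k], P[k], down[k])
        if np.any(total <= 0):
            return -np.inf
        return float(np.dot(self.data.weights, np.log(total)))

    def optimize_edge(self, node: Node, tol: float = 1e-6) -> float:
        """Optimize one branch length (edge above ``node``) using cached conditionals."""
        res = minimize_scalar(
            lambda t: -self.edge_log_likelihood(node, t),
            bounds=(BL_MIN, BL_MAX), method="bounded", options={"xatol": tol},
        )
        node.length = float(res.x)
        return -float(res.fun)

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_rounds: int = 20, improvement_tol: float = 1e-4
    ) -> float:
        """Sweep all branches until the gain per sweep drops below tolerance."""
        current = -np.inf
        for _ in range(max_rounds):
            new = current
            for node in self.tree.postorder():
                if node is self.tree.root:
                    continue
                self.refresh()
                new = self.optimize_edge(node, tol=tol)
            if new - current < improvement_tol:
                current = max(new, current)
                break
            current = new
        return current


def site_likelihoods(tree: Tree, data: PatternData, model: SubstitutionModel) -> np.ndarray:
    """Per-pattern likelihoods, mixed over rate classes."""
    return PruningEngine(tree, data, model).site_likelihoods()


def log_likelihood(tree: Tree, data: PatternData | SnpAlignment, model: SubstitutionModel) -> float:
    """Sum over sites of log P(site | tree, model)."""
    if isinstance(data, SnpAlignment):
        data = encode_alignment(data)
    return PruningEngine(tree, data, model).log_likelihood()


def optimize_branch_lengths(
    tree: Tree,
    data: PatternData,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 20,
    improvement_tol: float = 1e-4,
) -> float:
    """Coordinate-wise branch-length optimization in place; returns final lnL."""
    engine = PruningEngine(tree, data, model)
    return engine.optimize_branch_lengths(tol, max_rounds, improvement_tol)
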