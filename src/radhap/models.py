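"""Time-reversible nucleotide substitution models (JC through GTR+G+I).

State order is A, C, G, T. The rate matrix Q is built from six
exchangeabilities (AC, AG, AT, CG, CT, GT; GT is the reference and fixed to
1 in fitting) and the stationary base frequencies, and is normalized so the
variable-rate part of the mixture has mean rate 1: branch lengths are
expected substitutions per site averaged over all rate classes, including
the invariant class when present. Rate heterogeneity uses the discrete
gamma approximation with equal-probability categories represented by their
category means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

STATES = "ACGT"
# exchangeability order
PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability categories of a mean-1 gamma distribution."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    q = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], q, [np.inf]])
    # partial expectation of a mean-1 gamma: E[X; X<=x] = I(shape+1, shape*x)
    upper = gammainc(shape + 1.0, shape * bounds[1:])
    lower = gammainc(shape + 1.0, shape * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()  # exact mean 1 despite discretization


@dataclass(frozen=True)
class SubstitutionModel:
    """A GTR-family model, optionally with +G rate heterogeneity and +I sites."""

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    p_invariant: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(x < 0 for x in self.exchangeabilities):
            raise ValueError("need 6 non-negative exchangeabilities")
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if self.p_invariant is not None and not (0.0 <= self.p_invariant < 1.0):
            raise ValueError("p_invariant must lie in [0, 1)")

    # ------------------------------------------------------------------ naming
    @property
    def label(self) -> str:
        ex = self.exchangeabilities
        uniform_freqs = np.allclose(self.base_freqs, 0.25)
        if all(x == ex[0] for x in ex) and uniform_freqs:
            base = "JC"
        elif ex[0] == ex[2] == ex[3] == ex[5] and ex[1] == ex[4]:
            base = "HKY"
        else:
            base = "GTR"
        if self.gamma_shape is not None:
            base += "+G"
        if self.p_invariant is not None:
            base += "+I"
        return base

    # ------------------------------------------------------------ constructors
    @classmethod
    def jc(cls, gamma_shape: float | None = None, p_invariant: float | None = None,
           n_rate_categories: int = 4) -> "SubstitutionModel":
        return cls((1.0,) * 6, (0.25,) * 4, gamma_shape, p_invariant, n_rate_categories)

    @classmethod
    def hky(cls, kappa: float, base_freqs, gamma_shape: float | None = None,
            p_invariant: float | None = None, n_rate_categories: int = 4) -> "SubstitutionModel":
        # transitions (AG, CT) scaled by kappa relative to transversions
        ex = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        return cls(ex, tuple(base_freqs), gamma_shape, p_invariant, n_rate_categories)

    @classmethod
    def gtr(cls, exchangeabilities, base_freqs, gamma_shape: float | None = None,
            p_invariant: float | None = None, n_rate_categories: int = 4) -> "SubstitutionModel":
        return cls(tuple(exchangeabilities), tuple(base_freqs), gamma_shape,
                   p_invariant, n_rate_categories)

    def with_params(self, **kwargs) -> "SubstitutionModel":
        return replace(self, **kwargs)

    # -------------------------------------------------------------- rate maths
    def rate_matrix(self) -> np.ndarray:
        """Q normalized to mean rate 1 at stationarity (variable classes)."""
        pi = np.asarray(self.base_freqs)
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.exchangeabilities, PAIRS):
            Q[i, j] = r * pi[j]
            Q[j, i] = r * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition via symmetrization (reversibility)."""
        pi = np.asarray(self.base_freqs)
        Q = self.rate_matrix()
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        eigvals, U = np.linalg.eigh((B + B.T) / 2.0)
        left = U.T * sqrt_pi[None, :]
        right = U / sqrt_pi[:, None]
        return eigvals, right, left

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the rate mixture, invariant class included.

        Variable-class rates are inflated by 1/(1-p_inv) so the overall mean
        rate stays 1 and branch lengths keep their substitutions-per-site
        meaning under +I.
        """
        if self.gamma_shape is not None:
            rates = discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)
            weights = np.full(self.n_rate_categories, 1.0 / self.n_rate_categories)
        else:
            rates = np.array([1.0])
            weights = np.array([1.0])
        if self.p_invariant:
            p = self.p_invariant
            rates = np.concatenate([[0.0], rates / (1.0 - p)])
            weights = np.concatenate([[p], weights * (1.0 - p)])
        return rates, weights

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t*r) for each rate class r: array (n_classes, 4, 4)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        eigvals, right, left = self._eigen()
        rates, _ = self.category_rates()
        out = np.empty((len(rates), 4, 4))
        for k, r in enumerate(rates):
            P = (right * np.exp(eigvals * t * r)[None, :]) @ left
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            out[k] = P
        return out

    @property
    def n_free_parameters(self) -> int:
        """Free model parameters for AIC: exchangeabilities + freqs + shape + p_inv."""
        ex = self.exchangeabilities
        if all(x == ex[0] for x in ex) and np.allclose(self.base_freqs, 0.25):
            k = 0  # JC
        elif ex[0] == ex[2] == ex[3] == ex[5] and ex[1] == ex[4]:
            k = 1 + 3  # HKY: kappa + 3 free frequencies
        else:
            k = 5 + 3  # GTR: 5 free exchangeabilities + 3 free frequencies
        if self.gamma_shape is not None:
            k += 1
        if self.p_invariant is not None:
            k += 1
        return k


def empirical_base_freqs(sequences: dict[str, str]) -> tuple[float, float, float, float]:
    """Base frequencies counted over all sequences (N ignored), floored away from 0."""
    counts = np.zeros(4)
    for seq in sequences.values():
        for i, s in enumerate(STATES):
            counts[i] += seq.count(s)
    if counts.sum() == 0:
        raise ValueError("no unambiguous nucleotides in alignment")
    freqs = np.maximum(counts / counts.sum(), 1e-6)
    freqs = freqs / freqs.sum()
    return tuple(freqs)
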