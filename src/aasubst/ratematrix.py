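"""Continuous-time Markov chain machinery for reversible substitution models.

A rate model ``(M, f)`` defines the instantaneous generator

    Q[i, j] = M[i, j] * f[j]      (i != j),

with the diagonal set so rows sum to zero.  By default ``Q`` is rescaled so
that the expected substitution rate at stationarity, ``-sum_i f[i] *
Q[i, i]``, equals 1 — branch lengths then measure expected substitutions per
site, the convention of every mainstream phylogenetics framework.

Transition probabilities ``P(t) = expm(Q t)`` are computed through the
symmetric eigendecomposition of ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which
is symmetric exactly when the chain is reversible, guaranteeing a real
spectrum and an orthogonal eigenbasis.  The decomposition is cached on the
generator, so repeated evaluation at many branch lengths (the common case in
pruning and simulation) costs one small matrix product each.

Among-site rate heterogeneity follows the standard discrete-gamma (+G) and
invariant-sites (+I) constructions, normalized so the expected rate over all
sites is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

from .models import RateModel


class DegenerateModelError(ValueError):
    """The model cannot yield a usable generator (e.g. all rates zero)."""


@dataclass
class GeneratorMatrix:
    """Normalized instantaneous-rate matrix with its stationary distribution."""

    Q: np.ndarray
    pi: np.ndarray
    alphabet: tuple[str, ...]
    scaled: bool = True
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.alphabet)

    def eigensystem(self):
        """Cached ``(eigenvalues, U, sqrt_pi)`` of the pi-symmetrized generator."""
        if self._eig is None:
            sqrt_pi = np.sqrt(self.pi)
            B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            B = 0.5 * (B + B.T)  # kill round-off asymmetry before eigh
            w, U = np.linalg.eigh(B)
            self._eig = (w, U, sqrt_pi)
        return self._eig

    def expected_rate(self) -> float:
        """Expected substitutions per site per unit time at stationarity."""
        return float(-np.dot(self.pi, np.diag(self.Q)))


@dataclass
class TransitionMatrix:
    """Substitution probabilities over a branch of length ``t``."""

    P: np.ndarray
    t: float
    alphabet: tuple[str, ...]


def build_generator(model: RateModel, scale: bool = True) -> GeneratorMatrix:
    """Assemble the generator ``Q[i, j] = M[i, j] * f[j]`` from a rate model.

    Symbols with zero equilibrium frequency are unreachable at stationarity;
    they are dropped from the state space with a warning rather than
    regularized, which would silently change the model.
    """
    keep = model.f > 0.0
    if not np.all(keep):
        dropped = [s for s, k in zip(model.alphabet, keep) if not k]
        warnings.warn(
            f"dropping zero-frequency symbols {dropped} from the state space",
            stacklevel=2,
        )
    alphabet = tuple(s for s, k in zip(model.alphabet, keep) if k)
    M = model.M[np.ix_(keep, keep)]
    f = model.f[keep]
    f = f / f.sum()
    if not np.any(M > 0.0):
        raise DegenerateModelError("all relative rates are zero")

    Q = M * f[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -np.dot(f, np.diag(Q))
        if mean_rate <= 0.0:
            raise DegenerateModelError("zero expected substitution rate")
        Q = Q / mean_rate
    return GeneratorMatrix(Q=Q, pi=f, alphabet=alphabet, scaled=scale)


def transition_probabilities(gen: GeneratorMatrix, t: float) -> np.ndarray:
    """``P(t) = expm(Q t)`` as a bare array (fast path for inner loops)."""
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    w, U, sqrt_pi = gen.eigensystem()
    inner = (U * np.exp(w * t)) @ U.T
    P = inner / sqrt_pi[:, None] * sqrt_pi[None, :]
    # Round-off can push entries a hair outside [0, 1]; clip only near the boundary.
    P[(P < 0.0) & (P > -1e-12)] = 0.0
    P[(P > 1.0) & (P < 1.0 + 1e-12)] = 1.0
    return P


def transition_matrix(gen: GeneratorMatrix, t: float) -> TransitionMatrix:
    """Transition probability matrix over branch length ``t`` (in expected
    substitutions per site when the generator is scaled)."""
    return TransitionMatrix(P=transition_probabilities(gen, t), t=float(t),
                            alphabet=gen.alphabet)


@dataclass
class RateHeterogeneity:
    """Discrete among-site rate distribution (+G categories, optional +I class).

    ``category_rates`` and ``category_probs`` describe the full mixture,
    including the rate-0 invariant class when ``p_inv > 0``.  The mixture is
    normalized so the expected rate over all sites is 1, keeping branch
    lengths interpretable as expected substitutions per site.
    """

    p_inv: float = 0.0
    alpha: float | None = None
    k: int = 1
    category_rates: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    category_probs: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self) -> None:
        self.category_rates = np.asarray(self.category_rates, dtype=float)
        self.category_probs = np.asarray(self.category_probs, dtype=float)
        if self.category_rates.shape != self.category_probs.shape:
            raise ValueError("category rates and probabilities must align")
        if np.any(self.category_rates < 0) or np.any(self.category_probs < 0):
            raise ValueError("negative category rate or probability")
        if abs(self.category_probs.sum() - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")

    @property
    def mean_rate(self) -> float:
        return float(np.dot(self.category_probs, self.category_rates))

    @property
    def is_homogeneous(self) -> bool:
        return self.alpha is None and self.p_inv == 0.0

    @classmethod
    def homogeneous(cls) -> "RateHeterogeneity":
        return cls()


def discrete_gamma(alpha: float, k: int = 4) -> RateHeterogeneity:
    """Discretize Gamma(alpha, alpha) into ``k`` equal-probability categories.

    Each category rate is the *mean* of the distribution within its
    inter-quantile slice (the convention of the model-selection tools this
    mirrors), so the mixture mean is exactly 1.  With the rate parameter
    equal to the shape, the slice mean between quantile bounds ``a < b`` at
    probabilities ``p_a < p_b`` is ``k * (I(alpha+1, alpha*b) - I(alpha+1,
    alpha*a))`` where ``I`` is the regularized lower incomplete gamma.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    probs = np.arange(k + 1) / k
    bounds = np.empty(k + 1)
    bounds[0] = 0.0
    bounds[-1] = np.inf
    bounds[1:-1] = gammaincinv(alpha, probs[1:-1]) / alpha
    upper = gammainc(alpha + 1, alpha * bounds[1:])
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = k * (upper - lower)
    rates = rates / np.dot(np.full(k, 1.0 / k), rates)  # exact unit mean
    return RateHeterogeneity(
        p_inv=0.0, alpha=float(alpha), k=k,
        category_rates=rates, category_probs=np.full(k, 1.0 / k),
    )


def apply_invariant(het: RateHeterogeneity, p_inv: float) -> RateHeterogeneity:
    """Add a rate-0 invariant-sites class of weight ``p_inv``.

    The remaining category rates are rescaled by ``1 / (1 - p_inv)`` so the
    overall expected rate stays 1.  ``p_inv = 1`` (all sites frozen) is
    allowed as a degenerate case for simulation tests.
    """
    if not 0.0 <= p_inv <= 1.0:
        raise ValueError(f"p_inv must lie in [0, 1], got {p_inv}")
    if het.p_inv != 0.0:
        raise ValueError("heterogeneity already carries an invariant class")
    if p_inv == 0.0:
        return RateHeterogeneity(
            p_inv=0.0, alpha=het.alpha, k=het.k,
            category_rates=het.category_rates.copy(),
            category_probs=het.category_probs.copy(),
        )
    if p_inv == 1.0:
        return RateHeterogeneity(
            p_inv=1.0, alpha=het.alpha, k=het.k,
            category_rates=np.array([0.0]), category_probs=np.array([1.0]),
        )
    rates = np.concatenate([[0.0], het.category_rates / (1.0 - p_inv)])
    probs = np.concatenate([[p_inv], het.category_probs * (1.0 - p_inv)])
    return RateHeterogeneity(
        p_inv=float(p_inv), alpha=het.alpha, k=het.k,
        category_rates=rates, category_probs=probs,
    )
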