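"""Phylogenetic likelihood by Felsenstein pruning and BIC model selection.

The alignment likelihood on a fixed tree is computed by post-order
accumulation of partial likelihoods over unique site patterns, with
per-node rescaling against underflow, mixed over discrete rate categories:

    lnL = sum_patterns  mult * log sum_c  prob_c * L_pattern(rate_c)

The rate-0 invariant class needs no special casing: pruning at rate 0 turns
leaf indicators into the indicator of a constant (or gap-compatible) column,
so the class contributes ``f[x]`` exactly for constant-site patterns.

Model selection scores each candidate (an empirical matrix, optionally +G
and/or +I, fitted by bounded derivative-free search) with

    BIC = -2 lnL + k ln(n_sites),

where the empirical matrix itself contributes no free parameters, +G and +I
one each, and the tree is a fixed input whose branch lengths are not
counted.  Lower BIC wins; ties break toward fewer parameters, then by name.
The sample-size convention (n = alignment length in sites) follows the
mainstream model-selection tools; it matters, because changing it can
reorder candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .models import RateModel
from .ratematrix import (
    RateHeterogeneity,
    apply_invariant,
    build_generator,
    discrete_gamma,
    transition_probabilities,
)
from .simulate import GAP_SYMBOLS, Alignment
from .trees import Phylogeny

MISSING = -1

ALPHA_BOUNDS = (0.02, 100.0)
PINV_BOUNDS = (0.0, 0.99)
SCALE_BOUNDS = (0.02, 50.0)


def encode_alignment(alignment: Alignment, alphabet: tuple[str, ...]) -> np.ndarray:
    """Map to an (n_taxa, n_sites) int array; gaps/ambiguity become MISSING."""
    index = {s: i for i, s in enumerate(alphabet)}
    rows = []
    for taxon, seq in alignment.sequences.items():
        rows.append([index.get(ch, MISSING) for ch in seq])
    return np.array(rows, dtype=np.int64)


def site_pattern_compress(alignment: Alignment,
                          alphabet: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Collapse identical columns.

    Returns ``(patterns, counts, taxa)`` where ``patterns`` is
    (n_patterns, n_taxa) in first-occurrence order and ``counts`` sums to the
    alignment length.
    """
    coded = encode_alignment(alignment, alphabet)
    seen: dict[tuple, int] = {}
    counts: list[int] = []
    order: list[tuple] = []
    for col in coded.T:
        key = tuple(col)
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(order)
            order.append(key)
            counts.append(1)
    return np.array(order, dtype=np.int64), np.array(counts, dtype=np.int64), alignment.taxa


def _pattern_log_likelihoods(patterns: np.ndarray, taxa: list[str], tree: Phylogeny,
                             gen, het: RateHeterogeneity,
                             branch_scale: float = 1.0) -> np.ndarray:
    """Per-pattern log-likelihood, mixed over rate categories."""
    n_states = gen.n
    n_pat = patterns.shape[0]
    taxon_row = {name: i for i, name in enumerate(taxa)}

    # Leaf partials are category-independent: one-hot, all-ones for missing.
    leaf_partials: dict[str, np.ndarray] = {}
    eye = np.eye(n_states)
    ones = np.ones(n_states)
    for name, col in taxon_row.items():
        states = patterns[:, col]
        L = np.where(states[:, None] == MISSING, ones[None, :], eye[states.clip(min=0)])
        leaf_partials[name] = L

    cat_loglik = np.empty((len(het.category_rates), n_pat))
    for c, rate in enumerate(het.category_rates):
        partials: dict[int, np.ndarray] = {}
        scales: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf():
                partials[id(node)] = leaf_partials[node.taxon.label]
                scales[id(node)] = np.zeros(n_pat)
                continue
            L = np.ones((n_pat, n_states))
            logscale = np.zeros(n_pat)
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * branch_scale * rate
                P = transition_probabilities(gen, t)
                L = L * (partials[id(child)] @ P.T)
                logscale += scales[id(child)]
            peak = L.max(axis=1)
            safe = peak > 0
            L[safe] /= peak[safe, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(safe, np.log(peak, where=safe,
                                                  out=np.zeros_like(peak)), -np.inf)
            partials[id(node)] = L
            scales[id(node)] = logscale
        root = tree.tree.seed_node
        site = partials[id(root)] @ gen.pi
        with np.errstate(divide="ignore"):
            cat_loglik[c] = np.log(site) + scales[id(root)]

    with np.errstate(divide="ignore"):
        log_probs = np.log(het.category_probs)
    return logsumexp(cat_loglik + log_probs[:, None], axis=0)


def log_likelihood(alignment: Alignment, tree: Phylogeny, model: RateModel,
                   het: RateHeterogeneity | None = None,
                   branch_scale: float = 1.0) -> float:
    """Alignment log-likelihood on a fixed tree under ``model`` (+ heterogeneity)."""
    het = het or RateHeterogeneity.homogeneous()
    tree_names = set(tree.leaf_names())
    aln_names = set(alignment.taxa)
    if tree_names != aln_names:
        raise ValueError(
            f"taxa mismatch: only in tree {sorted(tree_names - aln_names)}, "
            f"only in alignment {sorted(aln_names - tree_names)}"
        )
    gen = build_generator(model, scale=True)
    patterns, counts, taxa = site_pattern_compress(alignment, gen.alphabet)
    per_pattern = _pattern_log_likelihoods(patterns, taxa, tree, gen, het, branch_scale)
    return float(np.dot(counts, per_pattern))


@dataclass
class CandidateSpec:
    """One entry of a model-selection candidate list (matrix [+I][+G])."""

    model: RateModel
    use_gamma: bool = False
    use_inv: bool = False
    k: int = 4
    fit_branch_scale: bool = False

    def __post_init__(self) -> None:
        if self.use_gamma and self.k < 1:
            raise ValueError("gamma discretization needs k >= 1")

    @property
    def name(self) -> str:
        suffix = ("+I" if self.use_inv else "") + ("+G" if self.use_gamma else "")
        return self.model.name + suffix

    @property
    def kpar(self) -> int:
        return int(self.use_gamma) + int(self.use_inv) + int(self.fit_branch_scale)


@dataclass
class CandidateFit:
    """Fitted parameters and scores for one candidate."""

    name: str
    model_name: str
    lnL: float
    alpha: float | None
    p_inv: float | None
    branch_scale: float
    kpar: int
    bic: float
    converged: bool
    rank: int = 0


@dataclass
class SelectionResult:
    """All candidate fits, ranked ascending by BIC."""

    fits: list[CandidateFit]
    n_sites: int

    @property
    def best(self) -> CandidateFit:
        return self.fits[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(rank=f.rank, candidate=f.name, lnL=f.lnL, alpha=f.alpha,
                     p_inv=f.p_inv, branch_scale=f.branch_scale, kpar=f.kpar, BIC=f.bic)
                for f in self.fits
            ]
        )

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False, float_format="%.6f")


def _build_het(cand: CandidateSpec, alpha: float, p_inv: float) -> RateHeterogeneity:
    het = discrete_gamma(alpha, cand.k) if cand.use_gamma else RateHeterogeneity.homogeneous()
    if cand.use_inv:
        het = apply_invariant(het, p_inv)
    return het


def fit_heterogeneity(alignment: Alignment, tree: Phylogeny, candidate: CandidateSpec,
                      tol: float = 1e-6, max_cycles: int = 6) -> CandidateFit:
    """Maximize lnL over the candidate's free parameters.

    Bounded derivative-free search (golden-section style via Brent on a
    bounded interval), one axis at a time, cycling until the cycle improves
    lnL by less than ``tol``.  Alpha and the optional branch-scale factor are
    searched in log space, where the likelihood surface is far closer to
    quadratic.  Non-convergence within ``max_cycles`` returns the best point,
    flagged.
    """
    gen = build_generator(candidate.model, scale=True)
    patterns, counts, taxa = site_pattern_compress(alignment, gen.alphabet)

    def neg_lnl(alpha: float, p_inv: float, scale: float) -> float:
        het = _build_het(candidate, alpha, p_inv)
        per = _pattern_log_likelihoods(patterns, taxa, tree, gen, het, scale)
        return -float(np.dot(counts, per))

    alpha, p_inv, scale = 1.0, 0.05, 1.0
    axes = []
    if candidate.use_gamma:
        axes.append("alpha")
    if candidate.use_inv:
        axes.append("p_inv")
    if candidate.fit_branch_scale:
        axes.append("scale")

    current = neg_lnl(alpha if candidate.use_gamma else 1.0,
                      p_inv if candidate.use_inv else 0.0, scale)
    converged = True
    if axes:
        converged = False
        for _ in range(max_cycles):
            before = current
            for axis in axes:
                if axis == "alpha":
                    res = minimize_scalar(
                        lambda la: neg_lnl(np.exp(la), p_inv if candidate.use_inv else 0.0, scale),
                        bounds=np.log(ALPHA_BOUNDS), method="bounded",
                        options={"xatol": 5e-3},
                    )
                    alpha = float(np.exp(res.x))
                elif axis == "p_inv":
                    res = minimize_scalar(
                        lambda p: neg_lnl(alpha if candidate.use_gamma else 1.0, p, scale),
                        bounds=PINV_BOUNDS, method="bounded",
                        options={"xatol": 2e-3},
                    )
                    p_inv = float(res.x)
                else:
                    res = minimize_scalar(
                        lambda ls: neg_lnl(alpha if candidate.use_gamma else 1.0,
                                           p_inv if candidate.use_inv else 0.0, np.exp(ls)),
                        bounds=np.log(SCALE_BOUNDS), method="bounded",
                        options={"xatol": 5e-3},
                    )
                    scale = float(np.exp(res.x))
                current = min(current, float(res.fun))
            if before - current < tol:
                converged = True
                break

    lnl = -current
    return CandidateFit(
        name=candidate.name,
        model_name=candidate.model.name,
        lnL=lnl,
        alpha=alpha if candidate.use_gamma else None,
        p_inv=p_inv if candidate.use_inv else None,
        branch_scale=scale,
        kpar=candidate.kpar,
        bic=float("nan"),  # filled by select_model
        converged=converged,
    )


def select_model(alignment: Alignment, tree: Phylogeny,
                 candidates: list[CandidateSpec]) -> SelectionResult:
    """Fit every candidate and rank by BIC (n = alignment length in sites)."""
    if len(candidates) < 2:
        raise ValueError("model selection needs at least 2 candidates")
    n_sites = alignment.n_sites
    fits = []
    for cand in candidates:
        fit = fit_heterogeneity(alignment, tree, cand)
        fit.bic = -2.0 * fit.lnL + fit.kpar * np.log(n_sites)
        fits.append(fit)
    fits.sort(key=lambda f: (f.bic, f.kpar, f.name))
    for rank, fit in enumerate(fits, start=1):
        fit.rank = rank
    return SelectionResult(fits=fits, n_sites=n_sites)
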