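# Methods

This note documents the models, conventions, and numerical choices behind
`aasubst`. It is written for users who want to know exactly what the code
computes and what its validation does — and does not — demonstrate.

## The substitution model

An empirical amino-acid substitution model is a pair `(M, f)`: a symmetric
matrix `M` of relative rates of change between residue pairs, estimated
once from a large protein database, and a vector `f` of equilibrium residue
frequencies. The instantaneous generator of the continuous-time Markov
chain is

    Q_ij = M_ij f_j   (i ≠ j),      Q_ii = -Σ_{j≠i} Q_ij,

which is time-reversible by construction: `f_i Q_ij = f_j Q_ji` because `M`
is symmetric. Transition probabilities over a branch of length `t` are
`P(t) = exp(Qt)`.

A note on vocabulary: some authors call `Q` itself the "exchangeability
matrix"; the more common usage, which this package follows, reserves
*exchangeabilities* for `M` and calls `Q` the generator. Both conventions
describe the same arithmetic, `Q_ij = M_ij f_j`.

**Branch-length scaling.** By default `Q` is divided by `-Σ_i f_i Q_ii` so
the expected substitution rate at stationarity is 1 and branch lengths are
expected substitutions per site. Every mainstream phylogenetics framework
assumes this normalization; `build_generator(..., scale=False)` disables it.

**Matrix exponential.** `P(t)` is obtained from the eigendecomposition of
the symmetrized matrix `diag(√f) Q diag(1/√f)`, which is symmetric exactly
when the chain is reversible — the spectrum is guaranteed real and the
eigenbasis orthogonal, so the computation is stable for any `t`. The
decomposition is cached per generator, making repeated evaluation at many
branch lengths (pruning, simulation) one small matrix product each. Entries
that round-off pushes outside `[0, 1]` are clipped only within 1e-12 of the
boundary; anything worse would indicate a real defect and is left visible.
Non-reversible inputs are rejected rather than silently routed to a generic
exponential. Symbols with zero equilibrium frequency are dropped from the
state space (with a warning) instead of being regularized, which would
silently alter the model.

## The PAML text dialect

The parser accepts exactly: `n−1` rows of the strict lower triangle (row
`k` holds `k` whitespace-separated entries, no diagonal), then `n`
frequencies on the following non-blank line(s); blank lines, `#` comments,
and anything after the frequencies are ignored. Files carrying the diagonal
are rejected with a diagnostic rather than guessed at. Frequencies whose
sum deviates from 1 by at most 1e-3 (published rounding) are renormalized
with a warning; larger deviations are treated as corruption. A missing
frequency block yields uniform frequencies and a `frequency_free` flag so
such models can be excluded from frequency-sensitive analyses. The writer
emits shortest-round-trip decimal strings, so write∘parse is exact at the
bit level. The amino-acid order is fixed to `ARNDCQEGHILKMFPSTWYV` (the
PAML convention) and recorded as a header comment; the alphabet is generic
(`n ≥ 2`) so small toy alphabets can exercise every algorithm.

## Distances between models and clustering

Rate scales differ across published matrices, so each `M` is first
normalized by its largest entry. Distances are mean absolute differences:

* **rates** — over the `n(n−1)/2` unordered off-diagonal pairs of the
  normalized `M` (the structurally zero diagonal is excluded so it cannot
  dilute the distance);
* **freqs** — over the `n` equilibrium frequencies;
* **combined** — the arithmetic mean of the two, giving rates and
  frequencies equal contribution despite their different entry counts.

The distances are computed on `M`, not on the product `M·f`: relative
rates and frequencies are distinct ingredients of the model, and the
combined mode is where frequency information enters. All three are
L1-type pseudometrics (symmetry, zero self-distance, triangle inequality),
property-tested on random model triples.

Clustering uses Saitou–Nei neighbor joining, implemented in-package so
that two behaviors are contractual: ties in the joining criterion break
toward the lexicographically smallest pair of clade representatives
(determinism), and negative branch lengths are clamped to zero with the
deficit moved to the sister branch (topology never changes). On additive
distances NJ recovers the generating topology exactly; tests verify this
against patristic distances of random trees and cross-check against an
independent NJ implementation.

## Sequence simulation

Evolution runs from the root to the tips. The root sequence is either
fixed (e.g. the sequence of a representative protein structure) or drawn
i.i.d. from `f`. Per-site rate multipliers are drawn once at the root and
inherited down the whole tree — the standard +G/+I semantics; redrawing
per branch would average the heterogeneity away. Each branch then draws
every site's child state from the row of `P(r·t)` by inverse CDF; only
endpoint states are needed, so this is exact and no event-by-event
simulation is performed. Indels are not modeled.

Replicate `r` of a run with master seed `s` uses
`numpy.random.default_rng([s, r])` (SeedSequence spawning over PCG64).
This scheme is part of the interface: the same spec reproduces the same
alignments bit-for-bit across platforms, and replicates are independent
streams that redraw site rates and (when applicable) the equilibrium root.

## Rate heterogeneity

+G discretizes Gamma(α, α) (mean 1) into `k` equal-probability categories,
`k = 4` by default, each category rate being the *mean* of the distribution
within its inter-quantile slice — the dominant convention of model-selection
tools. Slice means are computed from regularized incomplete-gamma
differences, then normalized so the mixture mean is exactly 1. +I prepends
a rate-0 class with weight `p_inv` and rescales the remaining rates by
`1/(1−p_inv)`, keeping the expected rate 1 so branch lengths retain their
meaning. `p_inv = 1` is allowed only as a degenerate simulation case.

## Likelihood and model selection

Site patterns are collapsed (first-occurrence order) and the likelihood is
computed by Felsenstein pruning per rate category, with per-node rescaling
of partial likelihoods so 200-taxon × 1000-site problems stay finite. Gaps
and ambiguity codes are missing data (all-ones partial likelihood). The
invariant class falls out of the generic machinery at rate 0: pruning with
`P(0) = I` contributes `f[x]` exactly for constant-compatible patterns and
0 otherwise; categories are combined by log-sum-exp.

Candidates are an empirical matrix optionally extended with +G and/or +I.
Free parameters are fitted by bounded derivative-free search (Brent on a
bounded interval, one axis at a time, cyclic for two parameters,
terminating when a full cycle improves lnL by < 1e-6 or after 6 cycles,
in which case the best point is returned flagged as unconverged). α and
the optional global branch-scale factor are searched in log space
(α ∈ [0.02, 100], scale ∈ [0.02, 50]), `p_inv ∈ [0, 0.99]` directly; the
log transform makes the surface near-quadratic and the bounded search
robust to the flatness near the large-α boundary.

Scoring uses `BIC = −2 lnL + k ln(n)` with **n = number of sites** — the
convention of the mainstream selection tools; this choice can reorder
candidates and is therefore stated prominently. The empirical matrix
contributes 0 parameters (its entries are not estimated from the data),
+G and +I one each, and the tree with its branch lengths is a fixed input
(no branch-length optimization; an optional single branch-scale factor,
off by default, adds one parameter when enabled). Frequencies always come
from the model file and are never re-estimated (+F is out of scope). Ties
in BIC break toward fewer parameters, then by candidate name.

## Synthetic data: what it emulates and what it does not

The generator produces random reversible models (exchangeabilities i.i.d.
log-normal with median 1 and σ = 1 — a heavy right tail like the rate
spread of empirical matrices; frequencies from a symmetric Dirichlet with
concentration 5, which for 20 residues gives compositions roughly in the
0.01–0.12 range, comparable to real proteomes), *families* of models (a
base model plus members perturbed multiplicatively by `exp(ε·z)` on the
normalized rates and by Dirichlet resampling with concentration `1/ε` on
the frequency simplex — multiplicative so positivity survives without
clipping), random rooted binary trees by sequential random attachment with
exponential branch lengths (mean 0.1 substitutions/site by default), and
complete on-disk fixture sets (PAML catalog + metadata TSV + Newick +
FASTA + seed manifest) that regenerate byte-identically.

The default family layout — 4 families × 4 members at ε = 0.05 — mimics a
catalog in which models derived from related proteins are more similar to
each other than to models from other groups. What passing the clustering
and selection analyses on such data shows is that the *pipeline* detects
structure of that size and kind; it does not show that any particular
published matrix clusters with any other, nor does the generator attempt to
mimic the numerical content of named models. Likewise the simulator draws
no gap structure, no site-specific (structural) constraints, and no
compositional drift — real alignments carry all three.

## Validation problem sizes

The validation suite runs at desk scale, chosen so the full analysis is
reproducible on a single CPU in minutes: the likelihood oracle compares
pruning against exhaustive enumeration on ≤5-taxon, ≤4-state instances;
CTMC identities are checked on 100 random 20-state models; simulator
calibration uses 20,000–50,000 sites on one branch (transition counts
checked against exact binomial bands at 3σ coverage — for small-expectation
cells the normal ±3σ approximation is badly skewed, so exact quantiles are
used); clustering recovery runs 20 seeded catalogs of 16 models; and model
selection runs 20 seeded replicates of 1000 sites on 16 taxa under a known
model with α = 0.5, checking both the BIC ranking and the recovered α.

## Known limitations

* Only reversible, site-homogeneous empirical models: no structurally
  constrained, codon, nucleotide, or non-reversible models.
* No tree search or branch-length optimization; trees are inputs.
* No +F (data-derived frequencies), no AIC/AICc, no partitioned models.
* Score matrices are parsed, validated, stored, and written, but not used
  for alignment; no distances are defined between score matrices.
* NJ dendrograms carry no bootstrap support values.
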