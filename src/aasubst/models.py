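"""Core model containers: rate models, score models, and catalog records.

A *rate model* is the classic empirical amino-acid replacement model: a
symmetric matrix ``M`` of relative substitution rates between residue pairs
plus a vector ``f`` of equilibrium residue frequencies.  ``M`` and ``f`` are
combined downstream into a time-reversible generator ``Q[i, j] = M[i, j] *
f[j]``.  A *score model* is a symmetric matrix of alignment substitution
scores (log-odds style); it never enters likelihood computations here.

The residue alphabet is generic (any ``n >= 2`` symbols) so that small toy
alphabets can exercise every algorithm; the default is the 20 amino acids in
PAML ordering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

#: The 20 amino acids in the canonical PAML ordering.
AMINO_ACIDS: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

FREQ_SUM_TOL = 1e-3


class ModelValidationError(ValueError):
    """A model violates its structural invariants."""


def _as_alphabet(alphabet) -> tuple[str, ...]:
    symbols = tuple(str(s) for s in alphabet)
    if len(symbols) < 2:
        raise ModelValidationError("alphabet needs at least 2 symbols")
    if len(set(symbols)) != len(symbols):
        raise ModelValidationError("alphabet symbols must be unique")
    return symbols


@dataclass
class RateModel:
    """A reversible substitution model: relative rates plus equilibrium frequencies.

    Parameters
    ----------
    alphabet
        Ordered residue symbols; defaults to the 20 amino acids in PAML order.
    M
        Symmetric ``n x n`` matrix of nonnegative relative rates, zero diagonal.
    f
        Equilibrium frequencies, one per symbol, summing to 1.
    name
        Identifier used in catalogs, distance matrices, and reports.
    frequency_free
        True when the source file carried no frequency line and ``f`` was
        defaulted to uniform; such models can then be excluded from analyses
        that depend on frequencies.
    """

    alphabet: tuple[str, ...]
    M: np.ndarray
    f: np.ndarray
    name: str = "unnamed"
    frequency_free: bool = False

    def __post_init__(self) -> None:
        self.alphabet = _as_alphabet(self.alphabet)
        self.M = np.asarray(self.M, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.alphabet)

    def validate(self) -> None:
        n = self.n
        if self.M.shape != (n, n):
            raise ModelValidationError(
                f"rate matrix shape {self.M.shape} does not match alphabet size {n}"
            )
        if self.f.shape != (n,):
            raise ModelValidationError(
                f"frequency vector length {self.f.shape} does not match alphabet size {n}"
            )
        if not np.allclose(self.M, self.M.T, atol=1e-12, rtol=0.0):
            raise ModelValidationError("rate matrix must be symmetric")
        if np.any(np.diag(self.M) != 0.0):
            raise ModelValidationError("rate matrix diagonal must be zero")
        if np.any(self.M < 0.0):
            raise ModelValidationError("relative rates must be nonnegative")
        if np.any(self.f < 0.0):
            raise ModelValidationError("frequencies must be nonnegative")
        if abs(self.f.sum() - 1.0) > 1e-6:
            raise ModelValidationError(
                f"frequencies sum to {self.f.sum():.8f}, expected 1 within 1e-6"
            )
        if not np.any(self.M > 0.0):
            raise ModelValidationError("rate matrix has no positive entry")

    def copy(self, **changes) -> "RateModel":
        kwargs = dict(M=self.M.copy(), f=self.f.copy())
        kwargs.update(changes)
        return replace(self, **kwargs)

    def triangle(self) -> np.ndarray:
        """Lower-triangle entries of ``M`` (row-major, without diagonal)."""
        idx = np.tril_indices(self.n, k=-1)
        return self.M[idx]

    @classmethod
    def equal_rates(cls, alphabet=AMINO_ACIDS, name: str = "equal-rates") -> "RateModel":
        """All off-diagonal rates 1, uniform frequencies (Jukes-Cantor analog)."""
        alphabet = _as_alphabet(alphabet)
        n = len(alphabet)
        M = np.ones((n, n)) - np.eye(n)
        f = np.full(n, 1.0 / n)
        return cls(alphabet=alphabet, M=M, f=f, name=name)


@dataclass
class ScoreModel:
    """A symmetric matrix of alignment substitution scores.

    Scores may be negative and the diagonal is typically nonzero; unlike
    :class:`RateModel` there are no frequencies and no positivity constraint.
    """

    alphabet: tuple[str, ...]
    S: np.ndarray
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.alphabet = _as_alphabet(self.alphabet)
        self.S = np.asarray(self.S, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.alphabet)

    def validate(self) -> None:
        n = self.n
        if self.S.shape != (n, n):
            raise ModelValidationError(
                f"score matrix shape {self.S.shape} does not match alphabet size {n}"
            )
        if not np.array_equal(self.S, self.S.T):
            i, j = np.argwhere(self.S != self.S.T)[0]
            raise ModelValidationError(
                f"score matrix is asymmetric at ({self.alphabet[i]}, {self.alphabet[j]})"
            )


class MatrixKind(str, enum.Enum):
    RATE = "rate"
    SCORE = "score"


class TaxonomicGroup(str, enum.Enum):
    NUCLEAR_GENERAL = "nuclear_general"
    NUCLEAR_TAXON_SPECIFIC = "nuclear_taxon_specific"
    MITOCHONDRIAL = "mitochondrial"
    CHLOROPLAST = "chloroplast"
    VIRAL = "viral"
    OTHER = "other"


@dataclass
class ModelRecord:
    """A model plus its catalog metadata (provenance, taxonomy, reference)."""

    model: RateModel | ScoreModel
    kind: MatrixKind
    taxonomic_group: TaxonomicGroup
    year: int
    authors: str = ""
    reference: str = ""
    comments: str = ""

    def __post_init__(self) -> None:
        self.kind = MatrixKind(self.kind)
        self.taxonomic_group = TaxonomicGroup(self.taxonomic_group)
        expected = MatrixKind.RATE if isinstance(self.model, RateModel) else MatrixKind.SCORE
        if self.kind is not expected:
            raise ModelValidationError(
                f"record kind {self.kind.value!r} inconsistent with payload "
                f"{type(self.model).__name__}"
            )
        if self.year <= 1960:
            raise ModelValidationError(f"year {self.year} not plausible (must be > 1960)")

    @property
    def name(self) -> str:
        return self.model.name
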