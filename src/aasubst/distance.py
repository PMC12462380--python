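"""Pairwise distances between substitution models.

Rate-matrix scales vary across published models, so before comparison each
relative-rate matrix is normalized by its largest entry.  The distance
between two models is then the mean absolute difference over corresponding
entries — over the ``n(n-1)/2`` unordered off-diagonal rate pairs for the
rate distance, over the ``n`` frequencies for the frequency distance, and
the arithmetic mean of the two for the combined distance ("equal
contribution" of rates and frequencies).  All three are L1-type
pseudometrics on the normalized representation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import RateModel
from .ratematrix import DegenerateModelError


class DistanceMode(str, enum.Enum):
    RATES = "rates"
    FREQS = "freqs"
    COMBINED = "combined"


def normalize_rates(model: RateModel) -> RateModel:
    """Divide every relative rate by the matrix maximum (idempotent)."""
    peak = model.M.max()
    if peak <= 0.0:
        raise DegenerateModelError("cannot normalize an all-zero rate matrix")
    return model.copy(M=model.M / peak)


def _check_alphabets(a: RateModel, b: RateModel) -> None:
    if a.alphabet != b.alphabet:
        raise ValueError(
            f"alphabet mismatch between {a.name!r} and {b.name!r}"
        )


def rate_distance(a: RateModel, b: RateModel) -> float:
    """Mean absolute difference of max-normalized relative rates."""
    _check_alphabets(a, b)
    return float(np.mean(np.abs(normalize_rates(a).triangle() - normalize_rates(b).triangle())))


def freq_distance(a: RateModel, b: RateModel) -> float:
    """Mean absolute difference of equilibrium frequencies."""
    _check_alphabets(a, b)
    return float(np.mean(np.abs(a.f - b.f)))


def combined_distance(a: RateModel, b: RateModel) -> float:
    """Equal-contribution average of rate and frequency distances."""
    return 0.5 * (rate_distance(a, b) + freq_distance(a, b))


_DISTANCE_FN = {
    DistanceMode.RATES: rate_distance,
    DistanceMode.FREQS: freq_distance,
    DistanceMode.COMBINED: combined_distance,
}


@dataclass
class DistanceMatrix:
    """Symmetric model-by-model distance matrix with labels."""

    labels: tuple[str, ...]
    D: np.ndarray
    mode: DistanceMode

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.D = np.asarray(self.D, dtype=float)
        self.mode = DistanceMode(self.mode)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")

    def to_phylip(self) -> str:
        """PHYLIP square distance format."""
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.D):
            lines.append(label + "  " + " ".join(format(x, ".10g") for x in row))
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        lines = ["\t".join(("",) + self.labels)]
        for label, row in zip(self.labels, self.D):
            lines.append("\t".join([label] + [format(x, ".10g") for x in row]))
        return "\n".join(lines) + "\n"


def distance_matrix(models: Sequence[RateModel],
                    mode: DistanceMode | str = DistanceMode.COMBINED) -> DistanceMatrix:
    """All-pairs distances between models under the chosen mode."""
    if len(models) < 2:
        raise ValueError("need at least 2 models for a distance matrix")
    mode = DistanceMode(mode)
    fn = _DISTANCE_FN[mode]
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(models[i], models[j])
    return DistanceMatrix(labels=tuple(m.name for m in models), D=D, mode=mode)
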