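"""Readers and writers for PAML-style substitution matrix text files.

The PAML rate-matrix dialect is fixed here as: ``n - 1`` rows of the strict
lower triangle (row ``k`` has ``k`` whitespace-separated entries, no
diagonal), followed by ``n`` equilibrium frequencies on the next non-blank
line(s).  Anything after the frequencies is ignored, as are blank lines and
``#`` comment lines.  Files that carry the diagonal (``n`` rows) are rejected
rather than guessed at.

Score matrices are read either as a labeled square matrix (header row of
symbols, one labeled row per symbol — the BLOSUM/PAM layout) or as a lower
triangle *with* diagonal.
"""

from __future__ import annotations

import io
import warnings

import numpy as np

from .models import AMINO_ACIDS, FREQ_SUM_TOL, ModelValidationError, RateModel, ScoreModel


class PamlFormatError(ValueError):
    """The text does not conform to the expected matrix layout."""


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the double exactly."""
    return repr(float(x))


def _content_lines(text: str) -> list[str]:
    lines = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            lines.append(line)
    return lines


def _parse_floats(tokens: list[str], where: str) -> np.ndarray:
    try:
        return np.array([float(t) for t in tokens], dtype=float)
    except ValueError as exc:
        raise PamlFormatError(f"non-numeric entry in {where}: {exc}") from None


def parse_paml(text: str | io.TextIOBase, alphabet=AMINO_ACIDS, name: str = "unnamed") -> RateModel:
    """Parse a PAML rate-matrix file into a :class:`RateModel`.

    Parameters
    ----------
    text
        File content or an open text stream.
    alphabet
        Ordered symbols defining the matrix dimension; default 20 amino acids.
    name
        Name to attach to the parsed model.

    If the frequency line is missing, frequencies default to uniform and the
    model is flagged ``frequency_free``.  Frequencies whose sum deviates from
    1 by at most 1e-3 are renormalized with a warning; larger deviations are
    rejected.
    """
    if hasattr(text, "read"):
        text = text.read()
    alphabet = tuple(alphabet)
    n = len(alphabet)
    lines = _content_lines(text)
    if len(lines) < n - 1:
        raise PamlFormatError(
            f"expected {n - 1} triangular rows for a {n}-state model, found {len(lines)} lines"
        )

    M = np.zeros((n, n))
    for k in range(1, n):
        tokens = lines[k - 1].split()
        if len(tokens) != k:
            if len(tokens) == k + 1:
                raise PamlFormatError(
                    f"row {k} has {len(tokens)} entries, expected {k}: this looks like a "
                    "lower triangle with diagonal, which is not the supported dialect"
                )
            raise PamlFormatError(f"row {k} has {len(tokens)} entries, expected {k}")
        row = _parse_floats(tokens, f"row {k}")
        if np.any(row < 0):
            raise ModelValidationError(f"negative rate in row {k}")
        M[k, :k] = row
    M = M + M.T

    # Frequencies may wrap across lines; collect tokens until n are seen.
    freq_tokens: list[str] = []
    for line in lines[n - 1:]:
        freq_tokens.extend(line.split())
        if len(freq_tokens) >= n:
            break
    if not freq_tokens:
        return RateModel(alphabet=alphabet, M=M, f=np.full(n, 1.0 / n), name=name,
                         frequency_free=True)
    if len(freq_tokens) < n:
        raise PamlFormatError(
            f"found {len(freq_tokens)} frequency values, expected {n}"
        )
    f = _parse_floats(freq_tokens[:n], "frequency line")
    if np.any(f < 0):
        raise ModelValidationError("negative equilibrium frequency")
    total = f.sum()
    if abs(total - 1.0) > FREQ_SUM_TOL:
        raise ModelValidationError(
            f"frequencies sum to {total:.6f}, outside [1-{FREQ_SUM_TOL}, 1+{FREQ_SUM_TOL}]"
        )
    if abs(total - 1.0) > 1e-12:
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"frequencies sum to {total:.6f}; renormalizing", stacklevel=2
            )
        f = f / total
    return RateModel(alphabet=alphabet, M=M, f=f, name=name)


def write_paml(model: RateModel) -> str:
    """Serialize a :class:`RateModel` to PAML text at full double precision.

    The output reparses to the original model bit-for-bit.  A header comment
    records the symbol ordering.
    """
    out = [f"# alphabet order: {' '.join(model.alphabet)}"]
    for k in range(1, model.n):
        out.append(" ".join(_fmt(x) for x in model.M[k, :k]))
    out.append("")
    out.append(" ".join(_fmt(x) for x in model.f))
    return "\n".join(out) + "\n"


def parse_score(text: str | io.TextIOBase, alphabet=None, name: str = "unnamed") -> ScoreModel:
    """Parse a score matrix (labeled square or lower triangle with diagonal).

    A labeled square layout is detected by a header line of bare symbols.
    Asymmetric square input is rejected — scores are exchangeable by
    construction, so asymmetry signals a corrupt file.
    """
    if hasattr(text, "read"):
        text = text.read()
    lines = _content_lines(text)
    if not lines:
        raise PamlFormatError("empty score matrix")

    header = lines[0].split()
    is_labeled = all(not _is_number(tok) for tok in header)
    if is_labeled:
        symbols = tuple(header)
        n = len(symbols)
        if len(lines) < n + 1:
            raise PamlFormatError(f"expected {n} labeled rows, found {len(lines) - 1}")
        S = np.zeros((n, n))
        seen = []
        for i in range(n):
            tokens = lines[1 + i].split()
            if len(tokens) != n + 1:
                raise PamlFormatError(
                    f"labeled row {i + 1} has {len(tokens) - 1} values, expected {n}"
                )
            seen.append(tokens[0])
            S[i] = _parse_floats(tokens[1:], f"row {tokens[0]}")
        if tuple(seen) != symbols:
            missing = set(symbols) - set(seen)
            raise PamlFormatError(
                f"row labels {seen} do not match header symbols; missing {sorted(missing)}"
            )
        if not np.array_equal(S, S.T):
            i, j = np.argwhere(S != S.T)[0]
            raise ModelValidationError(
                f"asymmetric score matrix: S[{symbols[i]},{symbols[j]}] != "
                f"S[{symbols[j]},{symbols[i]}]"
            )
        return ScoreModel(alphabet=symbols, S=S, name=name)

    # Lower triangle with diagonal: row k has k entries, k = 1..n.
    n = len(lines[-1].split())
    if alphabet is None:
        if n == 20:
            alphabet = AMINO_ACIDS
        else:
            raise PamlFormatError(
                "triangular score matrix without header needs an explicit alphabet"
            )
    symbols = tuple(alphabet)
    if len(symbols) != n or len(lines) < n:
        raise PamlFormatError(
            f"triangular score matrix has {len(lines)} rows of up to {n} entries, "
            f"which does not fit alphabet size {len(symbols)}"
        )
    S = np.zeros((n, n))
    for k in range(n):
        tokens = lines[k].split()
        if len(tokens) != k + 1:
            raise PamlFormatError(f"row {k + 1} has {len(tokens)} entries, expected {k + 1}")
        S[k, : k + 1] = _parse_floats(tokens, f"row {k + 1}")
    S = S + np.tril(S, k=-1).T
    return ScoreModel(alphabet=symbols, S=S, name=name)


def write_score(model: ScoreModel) -> str:
    """Serialize a :class:`ScoreModel` as a labeled square matrix."""
    out = [" ".join(model.alphabet)]
    for i, sym in enumerate(model.alphabet):
        out.append(sym + " " + " ".join(_fmt(x) for x in model.S[i]))
    return "\n".join(out) + "\n"


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
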