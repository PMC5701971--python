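"""Permutation entropy of a univariate time series.

Permutation entropy (PE) quantifies the temporal irregularity of a signal by
looking only at the *ordinal patterns* — the rank orderings — of overlapping
embedding windows, never at the amplitudes themselves.  A window of ``m``
samples taken every ``l`` steps is mapped to the permutation that sorts it
ascending; PE is the Shannon entropy (in nats) of the empirical distribution
of those permutations, and the normalized value divides by ``ln(m!)`` so that
0 means a single repeated pattern (perfectly regular signal) and 1 means all
``m!`` patterns are equally frequent (e.g., white noise).

Ties are broken by original position: if two window values are equal, the
earlier sample is ranked first.  Because only ranks matter, PE is invariant
under any strictly increasing transform of the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PEParams",
    "EntropyValue",
    "PatternDistribution",
    "extract_ordinal_pattern",
    "pattern_distribution",
    "permutation_entropy",
    "entropy_from_distribution",
    "validate_params",
    "pe_norm_rows",
]


@dataclass(frozen=True)
class PEParams:
    """Embedding parameters: dimension ``m`` (window length) and delay ``l``.

    Defaults ``m=4, l=1`` suit short BOLD series (~130 volumes); ``m`` in
    [3, 7] is the commonly recommended range.
    """

    m: int = 4
    l: int = 1

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 2:
            raise ValueError(f"embedding dimension m must be an integer >= 2, got {self.m}")
        if int(self.l) != self.l or self.l < 1:
            raise ValueError(f"delay l must be an integer >= 1, got {self.l}")

    @property
    def span(self) -> int:
        """Number of raw samples covered by one embedding window."""
        return (self.m - 1) * self.l + 1


@dataclass(frozen=True)
class EntropyValue:
    """Shannon entropy of the ordinal-pattern distribution.

    ``pe`` is in nats; ``pe_norm = pe / ln(m!)`` lies in [0, 1].
    """

    pe: float
    pe_norm: float


@dataclass(frozen=True)
class PatternDistribution:
    """Empirical distribution of ordinal patterns of one series.

    ``probs`` maps each observed pattern — the 1-based ascending-order index
    sequence (j1..jm) — to its relative frequency.  ``n_windows`` is the
    number of embedding windows, ``N - (m-1)*l``.
    """

    probs: dict[tuple[int, ...], float]
    m: int
    n_windows: int

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pattern probabilities must sum to 1, got {total!r}")
        if len(self.probs) > math.factorial(self.m):
            raise ValueError("more patterns than m! — inconsistent distribution")

    @classmethod
    def uniform(cls, m: int) -> "PatternDistribution":
        """The maximum-entropy distribution: every one of the m! patterns equally likely."""
        import itertools

        pats = list(itertools.permutations(range(1, m + 1)))
        p = 1.0 / len(pats)
        return cls(probs={pat: p for pat in pats}, m=m, n_windows=len(pats))


@dataclass(frozen=True)
class ValidationResult:
    """Verdict of the (N, m, l) parameter check, with a diagnostic message."""

    valid: bool
    message: str

    def __bool__(self) -> bool:  # pragma: no cover - trivial
        return self.valid


def validate_params(n: int, params: PEParams) -> ValidationResult:
    """Check that a series of length ``n`` supports the embedding (m, l).

    Two conditions must hold: every possible pattern must be able to occur,
    ``m! <= n - (m-1)*l``, and to avoid undersampling the series must satisfy
    ``n >= (m+1)!``.  Returns a verdict rather than raising so that callers
    may log and proceed for exploratory parameter choices.
    """
    m, l = params.m, params.l
    if n < 1:
        return ValidationResult(False, f"series length must be positive, got {n}")
    problems = []
    if math.factorial(m) > n - (m - 1) * l:
        problems.append(
            f"m! = {math.factorial(m)} exceeds the number of windows "
            f"n - (m-1)*l = {n - (m - 1) * l}; not every pattern can occur"
        )
    if n < math.factorial(m + 1):
        problems.append(
            f"n = {n} < (m+1)! = {math.factorial(m + 1)}; series too short for m = {m} (undersampling)"
        )
    if problems:
        return ValidationResult(False, "; ".join(problems))
    return ValidationResult(True, f"(n={n}, m={m}, l={l}) satisfies the embedding constraints")


def _as_series(values: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"time series must be 1-D, got shape {x.shape}")
    if x.size < 2:
        raise ValueError("time series must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains NaN or infinite values")
    return x


def extract_ordinal_pattern(window: Sequence[float], params: PEParams) -> tuple[int, ...]:
    """Map one embedding window to its ordinal pattern.

    The pattern is the 1-based index sequence (j1..jm) such that
    ``window[j1-1] <= window[j2-1] <= ... <= window[jm-1]``; equal values are
    ordered by original position (stable sort).
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size != params.m:
        raise ValueError(f"window must contain exactly m = {params.m} values, got shape {w.shape}")
    return tuple(int(j) + 1 for j in np.argsort(w, kind="stable"))


def _ordinal_codes(rows: np.ndarray, m: int, l: int) -> np.ndarray:
    """Encode every embedding window of every row as an integer in [0, m**m).

    ``rows`` has shape (R, N).  Returns integer codes of shape
    (R, N - (m-1)*l); the code is the base-m digit expansion of the stable
    argsort, injective over permutations.
    """
    span = (m - 1) * l + 1
    if rows.shape[1] < span:
        raise ValueError(
            f"series of length {rows.shape[1]} is shorter than one embedding window (span {span})"
        )
    win = np.lib.stride_tricks.sliding_window_view(rows, span, axis=1)[..., ::l]
    order = np.argsort(win, axis=-1, kind="stable")
    weights = m ** np.arange(m, dtype=np.int64)
    return order.astype(np.int64) @ weights


def _decode(code: int, m: int) -> tuple[int, ...]:
    digits = []
    for _ in range(m):
        digits.append(int(code % m) + 1)
        code //= m
    return tuple(digits)


def pattern_distribution(series: Sequence[float], params: PEParams) -> PatternDistribution:
    """Slide the embedding window over the series and tally ordinal patterns.

    Produces ``N - (m-1)*l`` windows (step 1); probabilities are pattern
    counts divided by the number of windows.
    """
    x = _as_series(series)
    codes = _ordinal_codes(x[None, :], params.m, params.l)[0]
    uniq, counts = np.unique(codes, return_counts=True)
    n_windows = codes.size
    probs = {_decode(c, params.m): int(k) / n_windows for c, k in zip(uniq, counts)}
    return PatternDistribution(probs=probs, m=params.m, n_windows=n_windows)


def entropy_from_distribution(dist: PatternDistribution) -> EntropyValue:
    """Shannon entropy (nats) of a pattern distribution, with ln(m!) normalization.

    The convention 0*ln(0) = 0 applies; a single-pattern distribution has
    entropy 0 and the uniform distribution over all m! patterns has
    normalized entropy exactly 1.
    """
    p = np.array([v for v in dist.probs.values() if v > 0.0])
    pe = float(-np.sum(p * np.log(p))) + 0.0  # avoid -0.0
    norm = math.log(math.factorial(dist.m))
    return EntropyValue(pe=pe, pe_norm=pe / norm)


def permutation_entropy(
    series: Sequence[float],
    params: PEParams = PEParams(),
    *,
    check: bool = True,
) -> EntropyValue:
    """Permutation entropy of a series.

    With ``check=True`` (default) the (N, m, l) validity constraints are
    enforced; pass ``check=False`` to compute anyway (exploratory use).
    """
    x = _as_series(series)
    if check:
        verdict = validate_params(x.size, params)
        if not verdict.valid:
            raise ValueError(f"invalid PE parameters: {verdict.message}")
    return entropy_from_distribution(pattern_distribution(x, params))


def pe_norm_rows(rows: np.ndarray, params: PEParams = PEParams()) -> np.ndarray:
    """Normalized permutation entropy of many series at once.

    ``rows`` has shape (R, N): one series per row.  Vectorized over rows; the
    per-row result equals ``permutation_entropy(row).pe_norm`` exactly.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError(f"expected a (n_series, n_timepoints) array, got shape {rows.shape}")
    m, l = params.m, params.l
    codes = _ordinal_codes(rows, m, l)
    n_rows, n_win = codes.shape
    norm = math.log(math.factorial(m))
    n_codes = m**m
    if n_rows * n_codes <= 50_000_000:
        flat = codes + (np.arange(n_rows, dtype=np.int64)[:, None] * n_codes)
        counts = np.bincount(flat.ravel(), minlength=n_rows * n_codes).reshape(n_rows, n_codes)
        p = counts / n_win
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return terms.sum(axis=1) / norm
    out = np.empty(n_rows)
    for i in range(n_rows):  # large m fallback: per-row tally
        _, counts = np.unique(codes[i], return_counts=True)
        p = counts / n_win
        out[i] = float(-(p * np.log(p)).sum()) / norm
    return out
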