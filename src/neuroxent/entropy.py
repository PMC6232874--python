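"""Cross-Approximate and Cross-Sample Entropy between paired series.

Both metrics quantify statistical dissimilarity between two equal-length
series ``u`` and ``v``: templates of ``m`` consecutive points from one series
are matched against all templates of the other under the Chebyshev
(maximum-coordinate) distance with tolerance ``r``, and the entropy measures
how poorly length-m matches persist at length m + 1.  Higher values mean less
shared temporal structure, i.e. weaker coupling.

Conventions fixed here (and relied on throughout the package):

* both series are z-normalized first, so ``r`` is in units of standard
  deviations; the standard deviation uses the population (divide-by-N) form;
* a template pair matches when its distance is less than **or equal to** r;
* Cross-SampEn pools matches over templates ``i, j = 1 .. N - m`` at both
  lengths and applies a single outer ``-ln`` to the ratio of pooled match
  probabilities (the Richman & Moorman form).  A ``variant="literal"`` is
  provided for audit: it averages the per-template log-probabilities at each
  length and takes ``-ln`` of the ratio of those averages;
* Cross-ApEn uses templates ``i = 1 .. N - m + 1`` at length m and
  ``i = 1 .. N - m`` (denominator ``N - m``) at length m + 1 — only that many
  length-(m + 1) templates exist — and is direction dependent:
  ``cross_apen(u, v)`` computes ApEn(v‖u) with reference templates from u.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import cumulative_counts, match_counts

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateSeriesError",
    "SeriesTooShortError",
    "EntropyParams",
    "SeriesPair",
    "MatchCounts",
    "znormalize",
    "chebyshev_distance",
    "template_match_counts",
    "cross_sampen",
    "cross_apen",
    "cross_entropy",
]

METRICS = ("cross_apen", "cross_sampen")
CORRECTIONS = ("bias_max", "bias_zero", "none")
VARIANTS = ("canonical", "literal")


class DegenerateSeriesError(ValueError):
    """Raised for constant (zero-variance) or non-finite input series."""


class SeriesTooShortError(ValueError):
    """Raised when N < m + 2, i.e. no length-(m + 1) comparison is possible."""


@dataclass(frozen=True)
class EntropyParams:
    """Configuration of a cross-entropy metric.

    Parameters
    ----------
    metric : {"cross_apen", "cross_sampen"}
    m : int
        Run (template) length; the screening grid uses m in {1, 2}.
    r : float
        Tolerance as a fraction of the (unit) standard deviation, 0 < r < 1.
    correction : {"bias_max", "bias_zero", "none"}
        Zero-match handling for Cross-ApEn.
    variant : {"canonical", "literal"}
        Cross-SampEn formulation (see module docstring).
    self_match_exclusion : bool
        Exclude the j = i template comparison in Cross-SampEn counting.
    on_no_matches : {"surrogate", "inf"}
        Cross-SampEn behaviour when no length-(m + 1) match exists anywhere.
    """

    metric: str = "cross_sampen"
    m: int = 1
    r: float = 0.2
    correction: str = "bias_max"
    variant: str = "canonical"
    self_match_exclusion: bool = False
    on_no_matches: str = "surrogate"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError("run length m must be a positive integer")
        if not 0.0 < self.r < 1.0:
            raise ValueError("tolerance r must satisfy 0 < r < 1")
        if self.correction not in CORRECTIONS:
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.on_no_matches not in ("surrogate", "inf"):
            raise ValueError("on_no_matches must be 'surrogate' or 'inf'")


@dataclass(frozen=True)
class SeriesPair:
    """A validated pair of equal-length series."""

    u: np.ndarray
    v: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=np.float64)
        v = np.asarray(self.v, dtype=np.float64)
        if u.ndim != 1 or v.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if u.shape[0] != v.shape[0]:
            raise ValueError("series must have equal length")
        for s in (u, v):
            if not np.all(np.isfinite(s)):
                raise DegenerateSeriesError("series contains non-finite values")
            if s.shape[0] >= 2 and np.std(s) == 0.0:
                raise DegenerateSeriesError("degenerate series: zero variance")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "n", int(u.shape[0]))


@dataclass(frozen=True)
class MatchCounts:
    """Per-template match counts underlying one metric evaluation.

    ``short`` are the length-m counts, ``long`` the length-(m + 1) counts;
    ``short_denom``/``long_denom`` are the normalizing template counts.
    For every template i, ``long[i] <= short[i]`` (an (m + 1)-match is in
    particular an m-match over the same comparison range).
    """

    short: np.ndarray
    long: np.ndarray
    short_denom: int
    long_denom: int

    def __post_init__(self) -> None:
        n_long = self.long.shape[0]
        if np.any(self.long > self.short[:n_long]):
            raise AssertionError("count subset property violated")


def znormalize(series: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the population standard deviation.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (zero variance) or non-finite.
    """
    s = np.asarray(series, dtype=np.float64)
    if s.ndim != 1 or s.shape[0] < 2:
        raise ValueError("series must be one-dimensional with length >= 2")
    if not np.all(np.isfinite(s)):
        raise DegenerateSeriesError("series contains non-finite values")
    sd = s.std()
    if sd == 0.0:
        raise DegenerateSeriesError("degenerate series: zero variance")
    return (s - s.mean()) / sd


def chebyshev_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum absolute difference between two equal-length templates."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("template length mismatch")
    return float(np.max(np.abs(x - y)))


def _validate(u: np.ndarray, v: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    pair = u if isinstance(u, SeriesPair) else SeriesPair(u, v)
    if pair.n < m + 2:
        raise SeriesTooShortError(f"series too short: N={pair.n} needs N >= m + 2 = {m + 2}")
    return pair.u, pair.v


def _kernel_counts(us: np.ndarray, vs: np.ndarray, m: int, r: float):
    rs = np.array([float(r)], dtype=np.float64)
    full, full_t, last, diag = match_counts(us, vs, m + 1, rs)
    return (
        cumulative_counts(full)[:, 0, :],
        cumulative_counts(full_t)[:, 0, :],
        cumulative_counts(last)[:, 0, :],
        cumulative_counts(diag)[:, 0, :],
    )


def sampen_counts(full, last, diag, m: int, n: int, exclude_self: bool) -> MatchCounts:
    """Slice kernel counts into the Cross-SampEn B (length m) and A (m + 1) arrays.

    Both lengths use templates i, j = 1 .. N - m: at length m the final
    (j = N - m + 1) template is excluded via ``last``; at length m + 1 the full
    range is already j = 1 .. N - m.
    """
    b = full[m - 1, : n - m] - last[m - 1, : n - m]
    a = full[m, : n - m].copy()
    if exclude_self:
        b = b - diag[m - 1, : n - m]
        a = a - diag[m, : n - m]
    return MatchCounts(short=b, long=a, short_denom=n - m, long_denom=n - m)


def apen_counts(full, m: int, n: int) -> MatchCounts:
    """Slice kernel counts into the Cross-ApEn C^m and C^(m+1) count arrays."""
    return MatchCounts(
        short=full[m - 1, : n - m + 1].copy(),
        long=full[m, : n - m].copy(),
        short_denom=n - m + 1,
        long_denom=n - m,
    )


def template_match_counts(
    u: np.ndarray,
    v: np.ndarray,
    params: EntropyParams,
    *,
    prenormalized: bool = False,
) -> MatchCounts:
    """Match counts for a pair under ``params`` (inspection/testing helper)."""
    us, vs = _validate(u, v, params.m)
    if not prenormalized:
        us, vs = znormalize(us), znormalize(vs)
    full, full_t, last, diag = _kernel_counts(us, vs, params.m, params.r)
    if params.metric == "cross_sampen":
        return sampen_counts(full, last, diag, params.m, us.shape[0], params.self_match_exclusion)
    return apen_counts(full, params.m, us.shape[0])


def sampen_value(
    counts: MatchCounts,
    *,
    variant: str = "canonical",
    on_no_matches: str = "surrogate",
) -> float:
    """Cross-SampEn from B/A match counts."""
    n_t = counts.short_denom  # = N - m templates per series
    if variant == "literal":
        b_i = np.maximum(counts.short, 1)  # floor zero counts to keep logs defined
        a_i = np.maximum(counts.long, 1)
        if np.any(counts.short == 0) or np.any(counts.long == 0):
            logger.warning("literal variant: zero per-template counts floored to 1")
        b_bar = float(np.mean(np.log(b_i / n_t)))
        a_bar = float(np.mean(np.log(a_i / n_t)))
        if b_bar == 0.0 or a_bar == 0.0:
            warnings.warn("literal Cross-SampEn undefined (all templates match)", RuntimeWarning)
            return float("nan")
        return float(-np.log(a_bar / b_bar))
    b_total = int(counts.short.sum())
    a_total = int(counts.long.sum())
    denom = float(n_t) * float(n_t)
    if b_total == 0:
        if on_no_matches == "inf":
            return float("inf")
        logger.warning("Cross-SampEn: no length-m matches; returning resolution bound 2 ln(N - m)")
        return float(2.0 * np.log(n_t))
    b_prob = b_total / denom
    if a_total == 0:
        if on_no_matches == "inf":
            return float("inf")
        logger.warning(
            "Cross-SampEn: no length-(m + 1) matches; returning surrogate upper bound"
        )
        return float(-np.log((1.0 / denom) / b_prob))
    return float(-np.log((a_total / denom) / b_prob))


def apen_phi_difference(counts: MatchCounts, correction: str = "bias_max") -> float:
    """Cross-ApEn phi^m - phi^(m+1) from C^m / C^(m+1) counts."""
    c_m = counts.short / counts.short_denom
    c_m1 = counts.long / counts.long_denom
    if correction == "bias_max":
        sub = 1.0 / counts.short_denom  # (N - m + 1)^-1, the bias-max floor
        c_m1 = np.where(c_m1 == 0.0, sub, c_m1)
        # C^m zeros take the corrected C^(m+1) of the same template; the final
        # length-m template has no length-(m+1) counterpart and takes the floor.
        c_m1_ext = np.concatenate([c_m1, np.full(c_m.shape[0] - c_m1.shape[0], sub)])
        c_m = np.where(c_m == 0.0, c_m1_ext, c_m)
        phi_m = float(np.mean(np.log(c_m)))
        phi_m1 = float(np.mean(np.log(c_m1)))
    elif correction == "bias_zero":
        # zero-probability templates contribute lim x->0 x ln x = 0
        phi_m = float(np.sum(np.log(np.where(c_m == 0.0, 1.0, c_m))) / c_m.shape[0])
        phi_m1 = float(np.sum(np.log(np.where(c_m1 == 0.0, 1.0, c_m1))) / c_m1.shape[0])
    else:  # "none"
        if np.any(c_m == 0.0) or np.any(c_m1 == 0.0):
            warnings.warn("Cross-ApEn undefined without correction (zero counts)", RuntimeWarning)
            return float("nan")
        phi_m = float(np.mean(np.log(c_m)))
        phi_m1 = float(np.mean(np.log(c_m1)))
    return phi_m - phi_m1


def cross_sampen(
    u: np.ndarray,
    v: np.ndarray,
    m: int = 1,
    r: float = 0.2,
    *,
    variant: str = "canonical",
    self_match_exclusion: bool = False,
    on_no_matches: str = "surrogate",
) -> float:
    """Cross-Sample Entropy between ``u`` and ``v`` (symmetric, >= 0)."""
    params = EntropyParams(
        metric="cross_sampen",
        m=m,
        r=r,
        variant=variant,
        self_match_exclusion=self_match_exclusion,
        on_no_matches=on_no_matches,
    )
    counts = template_match_counts(u, v, params)
    return sampen_value(counts, variant=variant, on_no_matches=on_no_matches)


def cross_apen(
    u: np.ndarray,
    v: np.ndarray,
    m: int = 1,
    r: float = 0.2,
    *,
    correction: str = "bias_max",
) -> float:
    """Cross-Approximate Entropy ApEn(v‖u): reference templates from ``u``.

    Direction dependent: ``cross_apen(u, v)`` and ``cross_apen(v, u)`` differ
    for generic inputs.
    """
    params = EntropyParams(metric="cross_apen", m=m, r=r, correction=correction)
    counts = template_match_counts(u, v, params)
    return apen_phi_difference(counts, correction=correction)


def cross_entropy(u: np.ndarray, v: np.ndarray, params: EntropyParams) -> float:
    """Dispatch on ``params.metric``."""
    if params.metric == "cross_sampen":
        return cross_sampen(
            u,
            v,
            params.m,
            params.r,
            variant=params.variant,
            self_match_exclusion=params.self_match_exclusion,
            on_no_matches=params.on_no_matches,
        )
    return cross_apen(u, v, params.m, params.r, correction=params.correction)
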