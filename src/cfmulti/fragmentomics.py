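"""Fragment-length features.

Implements the fragmentation read-outs used for ctDNA detection: inclusive
range proportions (notably P163-169 for urine), the 10 bp-oscillation score
on the sub-150 bp profile (sum of local-maximum heights minus sum of
local-minimum depths), in-silico size selection, and Kolmogorov-Smirnov
comparison of cumulative fragment-length distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .datatypes import (
    LENGTH_GRID,
    LENGTH_GRID_HI,
    LENGTH_GRID_LO,
    FragmentProfile,
    ValidationError,
)


@dataclass
class OscillationResult:
    maxima: list[tuple[int, float]]  # (length bp, height = rel_freq)
    minima: list[tuple[int, float]]  # (length bp, depth = rel_freq)
    score: float  # sum of heights - sum of depths
    analysis_range: tuple[int, int]
    smooth: int | None


@dataclass
class RangeFeature:
    name: str
    lo: int
    hi: int
    value: float


def _check_range(lo: int, hi: int) -> None:
    if not (LENGTH_GRID_LO <= lo <= hi <= LENGTH_GRID_HI):
        raise ValueError(
            f"range [{lo}, {hi}] must lie within {LENGTH_GRID_LO}-{LENGTH_GRID_HI} bp"
        )


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width % 2 != 1 or width < 1:
        raise ValueError("smoothing width must be a positive odd integer")
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def local_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima/minima by strict neighbor comparison.

    Returns (maxima indices, minima indices) into ``values``; endpoints are
    never extrema, and plateaus (ties) break no extremum.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    interior = np.arange(1, v.size - 1)
    is_max = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    is_min = (v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])
    return interior[is_max], interior[is_min]


def oscillation_score(
    profile: FragmentProfile,
    analysis_range: tuple[int, int] = (30, 150),
    smooth: int | None = None,
    detrend: bool = False,
) -> OscillationResult:
    """10 bp-oscillation score on the (optionally smoothed) profile.

    Heights and depths are the relative frequencies at the extrema
    (``detrend=False``, the default) or their deviations from a linear trend
    through the analysis range (``detrend=True``). A profile with no
    interior extrema scores 0.
    """
    lo, hi = analysis_range
    _check_range(lo, hi)
    sel = (LENGTH_GRID >= lo) & (LENGTH_GRID <= hi)
    y = profile.rel_freq[sel]
    lengths = LENGTH_GRID[sel]
    if smooth is not None:
        y = _moving_average(y, smooth)
    if detrend:
        coef = np.polyfit(lengths, y, 1)
        ref = y - np.polyval(coef, lengths)
    else:
        ref = y
    imax, imin = local_extrema(y)
    maxima = [(int(lengths[i]), float(ref[i])) for i in imax]
    minima = [(int(lengths[i]), float(ref[i])) for i in imin]
    score = float(sum(h for _, h in maxima) - sum(d for _, d in minima))
    return OscillationResult(
        maxima=maxima, minima=minima, score=score, analysis_range=(lo, hi), smooth=smooth
    )


def range_proportion(profile: FragmentProfile, lo: int, hi: int) -> float:
    """Proportion of fragments with length in the inclusive band [lo, hi]."""
    _check_range(lo, hi)
    sel = (LENGTH_GRID >= lo) & (LENGTH_GRID <= hi)
    return float(profile.rel_freq[sel].sum())


def p163_169(profile: FragmentProfile) -> float:
    """Proportion of 163-169 bp fragments among all 30-700 bp fragments."""
    return range_proportion(profile, 163, 169)


def range_ratio(profile: FragmentProfile, num: tuple[int, int], den: tuple[int, int]) -> float:
    """Ratio of fragment mass between two inclusive length bands."""
    d = range_proportion(profile, *den)
    if d == 0:
        raise ValidationError("denominator range carries no mass")
    return range_proportion(profile, *num) / d


def size_select(profile: FragmentProfile, lo: int = 90, hi: int = 150) -> FragmentProfile:
    """Restrict a profile to [lo, hi] bp and renormalize (in-silico size selection)."""
    if lo >= hi:
        raise ValueError("size-selection band requires lo < hi")
    _check_range(lo, hi)
    sel = (LENGTH_GRID >= lo) & (LENGTH_GRID <= hi)
    kept = profile.rel_freq * sel
    mass = kept.sum()
    if mass <= 0:
        raise ValidationError(
            f"sample {profile.sample_id}: no fragments in the {lo}-{hi} bp selection band"
        )
    return FragmentProfile(
        sample_id=profile.sample_id,
        rel_freq=kept / mass,
        n_fragments=int(round(profile.n_fragments * mass)),
    )


def ecdf(profile: FragmentProfile) -> np.ndarray:
    """Cumulative fragment-length distribution on the 30-700 bp grid."""
    return np.cumsum(profile.rel_freq)


def ks_compare(profile_a: FragmentProfile, profile_b: FragmentProfile) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of fragment-length ECDFs.

    D is the maximum absolute ECDF difference over the length grid; the
    p-value is the asymptotic two-sample approximation using the fragment
    counts as sample sizes.
    """
    d = float(np.max(np.abs(ecdf(profile_a) - ecdf(profile_b))))
    n, m = profile_a.n_fragments, profile_b.n_fragments
    if n == 0 or m == 0:
        return d, float("nan")
    en = np.sqrt(n * m / (n + m))
    p = float(np.clip(special.kolmogorov((en + 0.12 + 0.11 / en) * d), 0.0, 1.0))
    return d, p


def fragment_features(
    profile: FragmentProfile,
    fluid: str,
    extra_ranges: list[tuple[str, int, int]] | None = None,
) -> dict[str, float]:
    """Standard per-sample fragmentation features.

    Plasma: 10 bp-oscillation score (30-150 bp). Urine: P163-169. Extra
    inclusive ranges may be supplied as (name, lo, hi) triples.
    """
    out: dict[str, float] = {}
    if fluid == "plasma":
        out["oscillation_score"] = oscillation_score(profile).score
    elif fluid == "urine":
        out["p163_169"] = p163_169(profile)
    for name, lo, hi in extra_ranges or []:
        out[name] = range_proportion(profile, lo, hi)
    return out
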