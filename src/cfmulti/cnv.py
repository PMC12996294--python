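"""Copy-number analysis and chromosomal instability from bin-level counts.

A transparent, testable re-implementation of the standard low-coverage WGS
workflow for cfDNA: GC/mappability normalization of 1000 kb bin counts,
comparison to a panel of normals (PoN), hidden-Markov segmentation over
integer copy states {0..4} with tumor-fraction-dependent Gaussian emission
means, grid-search tumor-fraction (TFx) estimation, and a synoptic
chromosomal-instability (CIA) score summarizing control-standardized
deviation mass beyond a z cutoff.

The emission model matches the ichorCNA family: a bin in copy state c at
tumor fraction t has expected log2 depth ratio
``mu_c(t) = log2((t*c + 2*(1-t)) / 2)`` relative to the diploid reference,
so state 2 is ratio-neutral at every t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import BinCountTrack, ValidationError

COPY_STATES = np.arange(5)  # {0, 1, 2, 3, 4}


@dataclass
class PanelOfNormals:
    """Per-bin mean/SD of normalized log2 depth across control samples."""

    bins: pd.DataFrame  # chrom, start, end
    mean: np.ndarray
    sd: np.ndarray
    member_ids: list[str]

    def __post_init__(self):
        if len(self.member_ids) < 2:
            raise ValidationError("a panel of normals requires >= 2 control samples")
        # zero-SD or non-finite bins are masked for scoring
        bad = ~np.isfinite(self.mean) | ~np.isfinite(self.sd) | (self.sd <= 0)
        self.mask = ~bad

    def leave_one_out(self, sample_id: str, tracks: dict[str, "np.ndarray"]) -> "PanelOfNormals":
        """PoN over all member profiles except ``sample_id``."""
        others = [m for m in self.member_ids if m != sample_id]
        return _pon_from_stack(self.bins, np.vstack([tracks[m] for m in others]), others)


@dataclass
class CopyNumberResult:
    sample_id: str
    bins: pd.DataFrame  # chrom, start, end of retained bins
    log2_ratio: np.ndarray
    states: np.ndarray  # Viterbi copy states per retained bin
    segments: pd.DataFrame  # chrom, start, end, state
    tfx_hat: float
    log_likelihood: float
    size_selected: bool = False

    @property
    def altered_fraction(self) -> float:
        return float(np.mean(self.states != 2)) if self.states.size else 0.0


@dataclass
class CIAResult:
    sample_id: str
    z: np.ndarray
    z_cut: float
    cia_score: float


def normalize_bins(
    track: BinCountTrack,
    mappability_min: float = 0.75,
    lowess_frac: float = 0.3,
    min_bins: int = 100,
) -> pd.DataFrame:
    """GC/mappability-normalized, median-centered log2 depth per bin.

    Bins below the mappability threshold or with zero counts are masked
    (NaN). The GC effect is removed by a LOESS-style local regression of log
    depth on GC fraction, then values are median-centered.

    Returns the bin table with an added ``log2_norm`` column.
    """
    df = track.bins.copy()
    counts = df["raw_count"].to_numpy(float)
    mapp = df["mappability"].to_numpy(float)
    keep = (mapp >= mappability_min) & (counts > 0)
    if keep.sum() < min_bins:
        raise ValidationError(
            f"sample {track.sample_id}: only {int(keep.sum())} usable bins "
            f"(need >= {min_bins})"
        )
    log_depth = np.full(len(df), np.nan)
    log_depth[keep] = np.log2(counts[keep] / mapp[keep])
    gc = df["gc"].to_numpy(float)
    fit = lowess(log_depth[keep], gc[keep], frac=lowess_frac, return_sorted=False)
    resid = np.full(len(df), np.nan)
    resid[keep] = log_depth[keep] - fit
    resid -= np.nanmedian(resid)
    df["log2_norm"] = resid
    return df


def build_pon(
    control_tracks: list[BinCountTrack],
    mappability_min: float = 0.75,
    lowess_frac: float = 0.3,
) -> tuple[PanelOfNormals, dict[str, np.ndarray]]:
    """Panel of normals from control tracks.

    Returns the PoN and the per-control normalized profiles (needed for the
    leave-one-out variant used when scoring a control against the remaining
    controls).
    """
    if len(control_tracks) < 2:
        raise ValidationError("a panel of normals requires >= 2 control samples")
    profiles: dict[str, np.ndarray] = {}
    ref_bins = control_tracks[0].bins[["chrom", "start", "end"]]
    for t in control_tracks:
        if not t.bins[["chrom", "start", "end"]].equals(ref_bins):
            raise ValidationError("control tracks have inconsistent bin definitions")
        profiles[t.sample_id] = normalize_bins(
            t, mappability_min=mappability_min, lowess_frac=lowess_frac
        )["log2_norm"].to_numpy()
    stack = np.vstack(list(profiles.values()))
    pon = _pon_from_stack(ref_bins.copy(), stack, [t.sample_id for t in control_tracks])
    return pon, profiles


def _pon_from_stack(bins: pd.DataFrame, stack: np.ndarray, ids: list[str]) -> PanelOfNormals:
    # bins masked in every member yield all-NaN slices; they stay masked
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return PanelOfNormals(
            bins=bins,
            mean=np.nanmean(stack, axis=0),
            sd=np.nanstd(stack, axis=0, ddof=1),
            member_ids=ids,
        )


def state_means(t: float, ratio_floor: float = 0.05) -> np.ndarray:
    """Expected log2 ratios per copy state at tumor fraction t.

    The homozygous-deletion ratio is floored to avoid -inf.
    """
    ratio = (t * COPY_STATES + 2.0 * (1.0 - t)) / 2.0
    return np.log2(np.maximum(ratio, ratio_floor))


def _transition_matrix(n_states: int, p_self: float) -> np.ndarray:
    off = (1.0 - p_self) / (n_states - 1)
    m = np.full((n_states, n_states), off)
    np.fill_diagonal(m, p_self)
    return m


def viterbi(
    log2_ratio: np.ndarray,
    means: np.ndarray,
    sigma: float,
    p_self: float = 1 - 1e-6,
    state_prior_bonus: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Most likely state path under Gaussian emissions and sticky transitions.

    ``state_prior_bonus`` adds tiny per-state log weights to the initial
    distribution; the default prefers the diploid state so flat genomes with
    degenerate (equal-mean) states decode to copy state 2.
    """
    paths, ll = viterbi_batch(log2_ratio, means[None, :], sigma, p_self, state_prior_bonus)
    return paths[0], float(ll[0])


def viterbi_batch(
    log2_ratio: np.ndarray,
    means: np.ndarray,  # (n_t, n_states)
    sigma: float,
    p_self: float = 1 - 1e-6,
    state_prior_bonus: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Viterbi decoding for a batch of emission-mean vectors at once.

    Used by the tumor-fraction grid search: each row of ``means`` is the
    state-mean vector at one candidate tumor fraction.
    """
    y = np.asarray(log2_ratio, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite ratios must be masked before decoding")
    n_t, n_states = means.shape
    n = y.size
    log_trans = np.log(_transition_matrix(n_states, p_self))
    if state_prior_bonus is None:
        # break exact ties toward the diploid state
        state_prior_bonus = -1e-9 * np.abs(COPY_STATES[:n_states] - 2).astype(float)
    log_init = -np.log(n_states) + state_prior_bonus

    const = -0.5 * np.log(2 * np.pi * sigma**2)

    def emission(i: int) -> np.ndarray:  # (n_t, n_states)
        return const - 0.5 * ((y[i] - means) / sigma) ** 2

    dp = log_init[None, :] + emission(0)
    back = np.empty((n, n_t, n_states), dtype=np.int8)
    back[0] = 0
    for i in range(1, n):
        cand = dp[:, :, None] + log_trans[None, :, :]  # (n_t, from, to)
        best_from = np.argmax(cand, axis=1)  # (n_t, to)
        dp = np.take_along_axis(cand, best_from[:, None, :], axis=1)[:, 0, :] + emission(i)
        back[i] = best_from
    last = np.argmax(dp, axis=1)
    ll = np.take_along_axis(dp, last[:, None], axis=1)[:, 0]
    paths = np.empty((n_t, n), dtype=np.int8)
    paths[:, -1] = last
    rows = np.arange(n_t)
    for i in range(n - 1, 0, -1):
        paths[:, i - 1] = back[i, rows, paths[:, i]]
    return paths, ll


def segment_hmm(
    log2_ratio: np.ndarray,
    t: float,
    sigma: float | None = None,
    p_self: float = 1 - 1e-6,
    ratio_floor: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Copy-state segmentation at a candidate tumor fraction t.

    Emissions are Gaussian around the state means ``mu_c(t)`` with a shared
    standard deviation estimated robustly from bin-to-bin differences unless
    supplied.
    """
    if not 0.0 <= t <= 0.95:
        raise ValueError("candidate tumor fraction must lie in [0, 0.95]")
    y = np.asarray(log2_ratio, dtype=float)
    if sigma is None:
        sigma = estimate_sigma(y)
    return viterbi(y, state_means(t, ratio_floor), sigma, p_self=p_self)


def estimate_sigma(log2_ratio: np.ndarray, floor: float = 0.02) -> float:
    """Robust emission SD from first differences (insensitive to segments)."""
    d = np.diff(log2_ratio)
    if d.size == 0:
        return floor
    return float(max(1.4826 * np.median(np.abs(d)) / np.sqrt(2), floor))


def _segments_table(bins: pd.DataFrame, states: np.ndarray) -> pd.DataFrame:
    rows = []
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    i = 0
    n = len(bins)
    while i < n:
        j = i
        while j + 1 < n and states[j + 1] == states[i] and chroms[j + 1] == chroms[i]:
            j += 1
        rows.append({"chrom": chroms[i], "start": int(starts[i]), "end": int(ends[j]),
                     "state": int(states[i])})
        i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def estimate_tfx(
    track: BinCountTrack,
    pon: PanelOfNormals,
    size_selected: bool = False,
    t_grid: np.ndarray | None = None,
    min_altered_fraction: float = 0.01,
    p_self: float = 1 - 1e-6,
    ratio_floor: float = 0.05,
    mappability_min: float = 0.75,
    lowess_frac: float = 0.3,
    min_bins: int = 100,
) -> CopyNumberResult:
    """Grid-search tumor-fraction estimate with HMM segmentation.

    For each candidate t in {0, 0.01, ..., 0.95} the Viterbi likelihood of
    the PoN-referenced log2 ratios is computed; the estimate is the
    likelihood argmax, preferring smaller t on ties, and is set to 0 when
    the decoded path alters less than ``min_altered_fraction`` of bins
    (flat genomes must not hallucinate tumor fraction).
    """
    norm = normalize_bins(track, mappability_min=mappability_min,
                          lowess_frac=lowess_frac, min_bins=min_bins)
    ratio = norm["log2_norm"].to_numpy() - pon.mean
    keep = np.isfinite(ratio) & pon.mask
    if keep.sum() < min_bins:
        raise ValidationError(
            f"sample {track.sample_id}: only {int(keep.sum())} bins usable against the PoN"
        )
    y = ratio[keep]
    bins = norm.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
    sigma = estimate_sigma(y)
    if t_grid is None:
        t_grid = np.arange(0, 0.951, 0.01)
    means = np.vstack([state_means(t, ratio_floor) for t in t_grid])
    paths, ll = viterbi_batch(y, means, sigma, p_self=p_self)
    # argmax preferring smaller t: strict improvement required to move up
    best = 0
    for i in range(1, len(t_grid)):
        if ll[i] > ll[best] + 1e-9:
            best = i
    states = paths[best].astype(int)
    tfx_hat = float(t_grid[best])
    if np.mean(states != 2) < min_altered_fraction:
        tfx_hat = 0.0
    return CopyNumberResult(
        sample_id=track.sample_id,
        bins=bins,
        log2_ratio=y,
        states=states,
        segments=_segments_table(bins, states),
        tfx_hat=tfx_hat,
        log_likelihood=float(ll[best]),
        size_selected=size_selected,
    )


def cia_score(
    track: BinCountTrack,
    pon: PanelOfNormals,
    z_cut: float = 3.0,
    mappability_min: float = 0.75,
    lowess_frac: float = 0.3,
    min_bins: int = 100,
) -> CIAResult:
    """Chromosomal-instability score: mean thresholded excess of |z|.

    z per bin standardizes the normalized log2 depth against the PoN;
    score = sum over |z|>z_cut of (|z| - z_cut), divided by the number of
    retained bins. Zero when no bin deviates beyond the cutoff.
    """
    norm = normalize_bins(track, mappability_min=mappability_min,
                          lowess_frac=lowess_frac, min_bins=min_bins)
    val = norm["log2_norm"].to_numpy()
    keep = np.isfinite(val) & pon.mask
    z = (val[keep] - pon.mean[keep]) / pon.sd[keep]
    excess = np.maximum(np.abs(z) - z_cut, 0.0)
    return CIAResult(sample_id=track.sample_id, z=z, z_cut=z_cut,
                     cia_score=float(excess.sum() / z.size))


class CopyNumberEstimator(BaseEstimator):
    """Panel-of-normals copy-number/tumor-fraction estimator.

    scikit-learn-style surface: ``fit`` builds the panel of normals from
    control tracks; ``predict`` returns a :class:`CopyNumberResult` per
    track (controls in the panel are scored against a leave-one-out panel);
    ``score_instability`` returns CIA scores.

    Parameters
    ----------
    z_cut : positive z threshold of the CIA score.
    min_altered_fraction : minimum fraction of non-diploid bins for a
        nonzero tumor-fraction call.
    p_self : HMM self-transition probability (sticky segmentation).
    """

    def __init__(self, z_cut: float = 3.0, min_altered_fraction: float = 0.01,
                 p_self: float = 1 - 1e-6, ratio_floor: float = 0.05,
                 mappability_min: float = 0.75, lowess_frac: float = 0.3,
                 min_bins: int = 100, t_step: float = 0.01):
        self.z_cut = z_cut
        self.min_altered_fraction = min_altered_fraction
        self.p_self = p_self
        self.ratio_floor = ratio_floor
        self.mappability_min = mappability_min
        self.lowess_frac = lowess_frac
        self.min_bins = min_bins
        self.t_step = t_step

    def fit(self, control_tracks: list[BinCountTrack], y=None) -> "CopyNumberEstimator":
        self.pon_, self.control_profiles_ = build_pon(
            control_tracks, mappability_min=self.mappability_min,
            lowess_frac=self.lowess_frac,
        )
        return self

    def _pon_for(self, sample_id: str) -> PanelOfNormals:
        if sample_id in self.pon_.member_ids:
            return self.pon_.leave_one_out(sample_id, self.control_profiles_)
        return self.pon_

    def predict(self, track: BinCountTrack, size_selected: bool = False) -> CopyNumberResult:
        return estimate_tfx(
            track, self._pon_for(track.sample_id), size_selected=size_selected,
            t_grid=np.arange(0, 0.951, self.t_step),
            min_altered_fraction=self.min_altered_fraction, p_self=self.p_self,
            ratio_floor=self.ratio_floor, mappability_min=self.mappability_min,
            lowess_frac=self.lowess_frac, min_bins=self.min_bins,
        )

    def score_instability(self, track: BinCountTrack) -> CIAResult:
        return cia_score(
            track, self._pon_for(track.sample_id), z_cut=self.z_cut,
            mappability_min=self.mappability_min, lowess_frac=self.lowess_frac,
            min_bins=self.min_bins,
        )
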