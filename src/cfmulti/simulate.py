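"""Synthetic cohort generator.

Emulates the data layers of a plasma/urine cfDNA study of prostate cancer:

* plasma fragment-length densities with a dominant mono-nucleosomal peak at
  167 bp, a di-nucleosomal peak at 334 bp, a sub-150 bp component carrying a
  10 bp-periodic oscillation, and tumor-fraction-dependent short-fragment
  enrichment with damped oscillation;
* broad urinary densities (most mass within 30-400 bp) with a variable
  nucleosomal peak whose 163-169 bp mass grows with tumor fraction;
* bin-level read counts over a segment-structured copy-number profile with
  GC bias and negative-binomial overdispersion;
* window-level methylation beta-values mixing a background with a tumor
  level in a planted marker-window set;
* cohort structure (controls / localized / advanced disease) with group-wise
  tumor-fraction and PSA distributions.

Every quantity is a deterministic function of (config, seed), and the
generated ground truth (true tumor fractions, planted segments, planted
markers) is returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    LENGTH_GRID,
    BinCountTrack,
    Cohort,
    CohortTruth,
    Fluid,
    Metastasis,
    FragmentProfile,
    MethylWindowMatrix,
    RegionSet,
    SampleRecord,
    SyntheticCohort,
    ValidationError,
)

# approximate relative chromosome lengths, used only to spread bins over
# plausible chromosome labels
_CHROM_WEIGHTS = np.array(
    [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
     115, 107, 103, 90, 81, 78, 59, 63, 48, 51], dtype=float
)


@dataclass(frozen=True)
class FragmentMixture:
    """One component population's fragment-length mixture."""

    w_short: float
    w_mono: float
    w_di: float
    short_mu: float
    short_sd: float
    osc_amplitude: float


@dataclass(frozen=True)
class UrineMixture:
    w_broad: float
    w_peak: float
    broad_mu: float
    broad_sd: float
    peak_mu: float
    peak_sd: float
    osc_amplitude: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the qualitative structure of a newly-diagnosed
    prostate-cancer cohort: 36 cancer-free controls, 55 localized (lPCa) and
    18 advanced (aPCa) patients; tumor fractions are zero in controls, small
    (mean ~2%) in localized disease and heavy-tailed (reaching >30%) in
    advanced disease; PSA is log-normal with medians ordered
    control < lPCa < aPCa (~2, ~8, ~19 ng/mL).
    """

    n_controls: int = 36
    n_lpca: int = 55
    n_apca: int = 18
    n_missing_urine: int = 5  # patients without a urine sample (drawn from lPCa)

    # tumor-fraction distributions per cohort
    lpca_tfx_beta: tuple[float, float] = (0.8, 39.2)  # mean 0.02
    apca_tfx_beta: tuple[float, float] = (2.0, 18.0)  # mean 0.10
    apca_tail_prob: float = 0.35
    apca_tail_range: tuple[float, float] = (0.30, 0.60)

    # plasma fragment model: nucleosomal peaks shared by all components
    mono_mu: float = 167.0
    mono_sd: float = 10.0
    di_mu: float = 334.0
    di_sd: float = 20.0
    osc_period: float = 10.0
    osc_phase: float = 0.0  # cosine maxima at multiples of the period
    plasma_normal: FragmentMixture = FragmentMixture(
        w_short=0.15, w_mono=0.60, w_di=0.25, short_mu=118.0, short_sd=28.0,
        osc_amplitude=0.25,
    )
    plasma_tumor: FragmentMixture = FragmentMixture(
        w_short=0.45, w_mono=0.42, w_di=0.13, short_mu=134.0, short_sd=22.0,
        osc_amplitude=0.06,
    )
    plasma_osc_range: tuple[int, int] = (30, 150)

    # urine fragment model
    urine_normal: UrineMixture = UrineMixture(
        w_broad=0.88, w_peak=0.12, broad_mu=170.0, broad_sd=85.0,
        peak_mu=166.0, peak_sd=6.0, osc_amplitude=0.12,
    )
    urine_tumor: UrineMixture = UrineMixture(
        w_broad=0.62, w_peak=0.38, broad_mu=150.0, broad_sd=70.0,
        peak_mu=166.0, peak_sd=4.0, osc_amplitude=0.04,
    )
    urine_osc_range: tuple[int, int] = (30, 300)
    urine_peak_weight_concentration: float = 40.0  # per-sample Beta concentration

    n_fragments: int = 1_000_000

    # genome / copy-number model
    n_bins: int = 2500
    bin_size: int = 1_000_000
    # ~2.8x coverage with 100 bp reads -> ~18k reads per 1000 kb bin; the
    # negative-binomial size parameter adds ~2% extra-Poisson noise
    depth_per_bin: float = 18000.0
    nb_dispersion: float = 2000.0
    gc_beta: tuple[float, float] = (1.2, -8.0)  # log-linear + quadratic GC bias
    low_mappability_frac: float = 0.02
    cnv_loss_frac: float = 0.18  # fraction of genome at copy state 1
    cnv_gain_frac: float = 0.10  # fraction at state 3
    cnv_amp_frac: float = 0.02  # fraction at state 4
    cnv_segment_bins: int = 80  # typical planted segment length in bins
    size_select_band: tuple[int, int] = (90, 150)

    # methylation model
    n_windows: int = 5000
    window_width: int = 300
    n_marker_windows: int = 67
    beta_background: tuple[float, float] = (1.6, 8.0)  # Beta params, mean ~0.17
    beta_tumor: float = 0.85
    beta_noise_sd: float = 0.05
    methyl_ref_signal: float = 1.0  # median adjusted nrpkm anchoring beta=0.5

    # PSA model per cohort: (log-median, sd of log)
    psa_control: tuple[float, float] = (np.log(1.95), 0.6)
    psa_lpca: tuple[float, float] = (np.log(7.7), 0.5)
    psa_apca: tuple[float, float] = (np.log(18.8), 0.8)

    seed: int = 0

    def __post_init__(self):
        for mix in (self.plasma_normal, self.plasma_tumor):
            if abs(mix.w_short + mix.w_mono + mix.w_di - 1.0) > 1e-9:
                raise ValidationError("plasma mixture weights must sum to 1")
            if mix.osc_amplitude < 0:
                raise ValidationError("oscillation amplitude must be nonnegative")
        for mix in (self.urine_normal, self.urine_tumor):
            if abs(mix.w_broad + mix.w_peak - 1.0) > 1e-9:
                raise ValidationError("urine mixture weights must sum to 1")
        if self.n_marker_windows > self.n_windows:
            raise ValidationError("n_marker_windows must be <= n_windows")


def _truncnorm_pdf(x: np.ndarray, mu: float, sd: float, lo: float, hi: float) -> np.ndarray:
    pdf = sps.norm.pdf(x, mu, sd)
    pdf = np.where((x >= lo) & (x <= hi), pdf, 0.0)
    z = sps.norm.cdf(hi, mu, sd) - sps.norm.cdf(lo, mu, sd)
    return pdf / z


def _check_tfx(tfx: float) -> float:
    if not 0.0 <= tfx <= 1.0:
        raise ValueError(f"tumor fraction must lie in [0, 1], got {tfx}")
    return float(tfx)


def _oscillation(lengths: np.ndarray, amplitude: float, period: float, phase: float,
                 lo: int, hi: int) -> np.ndarray:
    mod = 1.0 + amplitude * np.cos(2 * np.pi * (lengths - phase) / period)
    mod = np.clip(mod, 0.0, None)
    return np.where((lengths >= lo) & (lengths <= hi), mod, 1.0)


def _plasma_component_density(mix: FragmentMixture, config: GeneratorConfig) -> np.ndarray:
    l = LENGTH_GRID.astype(float)
    lo, hi = config.plasma_osc_range
    short = _truncnorm_pdf(l, mix.short_mu, mix.short_sd, lo, hi)
    short *= _oscillation(l, mix.osc_amplitude, config.osc_period, config.osc_phase, lo, hi)
    dens = (
        mix.w_short * short
        + mix.w_mono * sps.norm.pdf(l, config.mono_mu, config.mono_sd)
        + mix.w_di * sps.norm.pdf(l, config.di_mu, config.di_sd)
    )
    return dens / dens.sum()


def _urine_component_density(mix: UrineMixture, config: GeneratorConfig) -> np.ndarray:
    l = LENGTH_GRID.astype(float)
    lo, hi = config.urine_osc_range
    broad = _truncnorm_pdf(l, mix.broad_mu, mix.broad_sd, LENGTH_GRID[0], LENGTH_GRID[-1])
    broad *= _oscillation(l, mix.osc_amplitude, config.osc_period, config.osc_phase, lo, hi)
    dens = mix.w_broad * broad + mix.w_peak * sps.norm.pdf(l, mix.peak_mu, mix.peak_sd)
    return dens / dens.sum()


def plasma_fragment_density(tfx: float, config: GeneratorConfig | None = None) -> np.ndarray:
    """Expected plasma fragment-length density on the 30-700 bp grid.

    The density is a two-population mixture: a fraction ``tfx`` of fragments
    is tumor-derived (more sub-150 bp mass, damped oscillation), the rest
    follows the healthy nucleosomal profile. Hence short-fragment mass is
    non-decreasing and oscillation amplitude non-increasing in ``tfx``.
    """
    config = config or GeneratorConfig()
    tfx = _check_tfx(tfx)
    dens = (1 - tfx) * _plasma_component_density(config.plasma_normal, config) + (
        tfx
    ) * _plasma_component_density(config.plasma_tumor, config)
    return dens / dens.sum()


def urine_fragment_density(tfx: float, config: GeneratorConfig | None = None,
                           mix_normal: UrineMixture | None = None) -> np.ndarray:
    """Expected urinary fragment-length density on the 30-700 bp grid.

    Broad 30-400 bp profile with a variable nucleosomal peak; the 163-169 bp
    mass is non-decreasing in ``tfx``. ``mix_normal`` overrides the healthy
    component (used for per-sample heterogeneity in the cohort generator).
    """
    config = config or GeneratorConfig()
    tfx = _check_tfx(tfx)
    normal = mix_normal or config.urine_normal
    dens = (1 - tfx) * _urine_component_density(normal, config) + tfx * _urine_component_density(
        config.urine_tumor, config
    )
    return dens / dens.sum()


def sample_fragments(density: np.ndarray, n_fragments: int, seed: int | np.random.Generator,
                     sample_id: str = "sample") -> FragmentProfile:
    """Multinomial draw of a fragment-length histogram from a density."""
    if n_fragments <= 0:
        raise ValidationError("n_fragments must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    density = np.asarray(density, dtype=float)
    counts = rng.multinomial(n_fragments, density / density.sum())
    return FragmentProfile(
        sample_id=sample_id, rel_freq=counts / n_fragments, n_fragments=n_fragments
    )


def mass_in_band(density: np.ndarray, lo: int, hi: int) -> float:
    """Total density mass on the inclusive length band [lo, hi]."""
    sel = (LENGTH_GRID >= lo) & (LENGTH_GRID <= hi)
    return float(np.asarray(density)[sel].sum())


def size_selection_enrichment(tfx: float, config: GeneratorConfig) -> tuple[float, float]:
    """Effective tumor fraction and retained mass after in-silico size selection.

    Tumor-derived fragments are shorter, so restricting to the selection band
    (default 90-150 bp) enriches the tumor fraction:
    tfx' = tfx*rho_t / (tfx*rho_t + (1-tfx)*rho_n) with rho the band mass of
    each component density.
    """
    lo, hi = config.size_select_band
    rho_t = mass_in_band(_plasma_component_density(config.plasma_tumor, config), lo, hi)
    rho_n = mass_in_band(_plasma_component_density(config.plasma_normal, config), lo, hi)
    retained = tfx * rho_t + (1 - tfx) * rho_n
    eff = tfx * rho_t / retained if retained > 0 else 0.0
    return eff, retained


# ---------------------------------------------------------------------------
# genome model


def make_genome_bins(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Bin scaffold: chromosome labels, coordinates, GC and mappability."""
    counts = np.maximum(1, np.round(_CHROM_WEIGHTS / _CHROM_WEIGHTS.sum() * config.n_bins)).astype(int)
    while counts.sum() > config.n_bins:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < config.n_bins:
        counts[np.argmin(counts)] += 1
    chroms = np.concatenate([
        np.repeat(f"chr{i + 1}", c) for i, c in enumerate(counts)
    ])
    starts = np.concatenate([np.arange(c) * config.bin_size for c in counts])
    gc = 0.30 + 0.30 * rng.beta(5, 5, size=config.n_bins)
    mapp = rng.beta(60, 2, size=config.n_bins)
    n_low = int(round(config.low_mappability_frac * config.n_bins))
    if n_low:
        low = rng.choice(config.n_bins, size=n_low, replace=False)
        mapp[low] = rng.uniform(0.2, 0.7, size=n_low)
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + config.bin_size,
         "gc": gc, "mappability": mapp}
    )
    # canonical (lexicographic chrom, start) order so bin indices line up
    # with BinCountTrack rows everywhere downstream
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def plant_cnv_segments(bins: pd.DataFrame, config: GeneratorConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Assign integer copy states per bin; contiguous altered segments."""
    n = len(bins)
    states = np.full(n, 2, dtype=int)
    targets = [
        (1, int(round(config.cnv_loss_frac * n))),
        (3, int(round(config.cnv_gain_frac * n))),
        (4, int(round(config.cnv_amp_frac * n))),
    ]
    order = rng.permutation(len(targets))
    for idx in order:
        state, n_target = targets[idx]
        placed = 0
        attempts = 0
        while placed < n_target and attempts < 200:
            attempts += 1
            seg_len = max(5, int(rng.poisson(config.cnv_segment_bins)))
            seg_len = min(seg_len, n_target - placed + 5)
            start = int(rng.integers(0, n - seg_len))
            sl = slice(start, start + seg_len)
            if np.all(states[sl] == 2) and np.all(
                bins["chrom"].values[sl] == bins["chrom"].values[start]
            ):
                states[sl] = state
                placed += seg_len
    return states


def segments_from_states(bins: pd.DataFrame, states: np.ndarray,
                         name: str = "planted_cnv") -> RegionSet:
    """Collapse per-bin states into a RegionSet of non-diploid segments."""
    rows = []
    n = len(bins)
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and states[j + 1] == states[i]
            and bins["chrom"].iat[j + 1] == bins["chrom"].iat[i]
        ):
            j += 1
        if states[i] != 2:
            rows.append(
                {"chrom": bins["chrom"].iat[i], "start": int(bins["start"].iat[i]),
                 "end": int(bins["end"].iat[j]), "copy_state": int(states[i])}
            )
        i = j + 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_state"])
    return RegionSet(name=name, regions=df)


def gen_bin_counts(bins: pd.DataFrame, states: np.ndarray, tfx: float, config: GeneratorConfig,
                   rng: np.random.Generator, sample_id: str = "sample",
                   depth: float | None = None) -> BinCountTrack:
    """Negative-binomial bin counts for a copy-state profile at tumor fraction tfx.

    The expected normalized depth ratio of a state-c segment is
    (tfx*c + 2*(1-tfx)) / 2 relative to diploid, modulated by a smooth GC
    bias and mappability.
    """
    tfx = _check_tfx(tfx)
    if np.any((states < 0) | (states > 4)):
        raise ValidationError("copy states must lie in {0..4}")
    depth = config.depth_per_bin if depth is None else depth
    ratio = (tfx * states + 2.0 * (1.0 - tfx)) / 2.0
    b1, b2 = config.gc_beta
    gc_centered = bins["gc"].to_numpy() - 0.45
    gc_factor = np.exp(b1 * gc_centered + b2 * gc_centered**2)
    mean = depth * ratio * gc_factor * bins["mappability"].to_numpy()
    size = config.nb_dispersion
    p = size / (size + np.maximum(mean, 1e-9))
    counts = rng.negative_binomial(size, p)
    df = bins.copy()
    df["raw_count"] = counts
    return BinCountTrack(sample_id=sample_id,
                         bins=df[["chrom", "start", "end", "raw_count", "gc", "mappability"]],
                         bin_size=config.bin_size)


# ---------------------------------------------------------------------------
# methylation model


def make_methyl_windows(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Window scaffold on chr1 with per-window CpG counts (CpG-dense markers)."""
    starts = np.arange(config.n_windows) * config.window_width
    cpg = rng.poisson(8, size=config.n_windows) + 1
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + config.window_width,
         "cpg_count": cpg}
    )


def gen_methyl_matrix(
    windows: pd.DataFrame,
    marker_idx: np.ndarray,
    tfx_by_sample: dict[str, float],
    config: GeneratorConfig,
    rng: np.random.Generator,
    tumor_beta: float | None = None,
    base_beta: np.ndarray | None = None,
) -> MethylWindowMatrix:
    """Beta-value matrix: markers mix background with the tumor level by tfx.

    observed beta = (1-tfx)*beta_background + tfx*beta_tumor in marker
    windows, beta_background elsewhere, plus truncated Gaussian noise. The
    nrpkm signal is the saturating inverse of the beta transform
    (s = m * beta/(1-beta), CpG-scaled), so beta is a monotone transform of
    signal within each sample.
    """
    n_win = len(windows)
    tumor_beta = config.beta_tumor if tumor_beta is None else tumor_beta
    if base_beta is None:
        a, b = config.beta_background
        base_beta = rng.beta(a, b, size=n_win)
    marker_mask = np.zeros(n_win, dtype=bool)
    marker_mask[marker_idx] = True

    betas = {}
    for sid, tfx in tfx_by_sample.items():
        tfx = _check_tfx(tfx)
        mix = np.where(marker_mask, (1 - tfx) * base_beta + tfx * tumor_beta, base_beta)
        if config.beta_noise_sd > 0:
            mix = mix + rng.normal(0.0, config.beta_noise_sd, size=n_win)
        betas[sid] = np.clip(mix, 1e-6, 1 - 1e-6)
    beta_df = pd.DataFrame(betas).T
    cpg = windows["cpg_count"].to_numpy(float)
    cpg_scale = cpg / np.median(cpg)
    signal = beta_df / (1 - beta_df) * config.methyl_ref_signal * cpg_scale[None, :]
    return MethylWindowMatrix(windows=windows, signal=signal, beta=beta_df)


# ---------------------------------------------------------------------------
# full cohort


def _draw_tfx(cohort: Cohort, config: GeneratorConfig, rng: np.random.Generator) -> float:
    if cohort == Cohort.CONTROL:
        return 0.0
    if cohort == Cohort.LPCA:
        return float(rng.beta(*config.lpca_tfx_beta))
    if rng.random() < config.apca_tail_prob:
        return float(rng.uniform(*config.apca_tail_range))
    return float(rng.beta(*config.apca_tfx_beta))


def _draw_psa(cohort: Cohort, config: GeneratorConfig, rng: np.random.Generator) -> float:
    mu, sd = {
        Cohort.CONTROL: config.psa_control,
        Cohort.LPCA: config.psa_lpca,
        Cohort.APCA: config.psa_apca,
    }[cohort]
    return float(np.exp(rng.normal(mu, sd)))


def gen_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Per patient: a plasma sample always; a urine sample unless the patient is
    among the ``n_missing_urine`` designated missing-urine patients (drawn
    from the localized group, mirroring real-world missingness).
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    bins = make_genome_bins(config, rng)
    states = plant_cnv_segments(bins, config, rng)
    windows = make_methyl_windows(config, rng)
    marker_idx = np.sort(rng.choice(config.n_windows, size=config.n_marker_windows, replace=False))
    base_beta = rng.beta(*config.beta_background, size=config.n_windows)

    cohorts = (
        [Cohort.CONTROL] * config.n_controls
        + [Cohort.LPCA] * config.n_lpca
        + [Cohort.APCA] * config.n_apca
    )
    n_lpca_start = config.n_controls
    missing_urine = set()
    if config.n_missing_urine and config.n_lpca:
        chosen = rng.choice(config.n_lpca, size=min(config.n_missing_urine, config.n_lpca),
                            replace=False)
        missing_urine = {n_lpca_start + int(i) for i in chosen}

    samples: list[SampleRecord] = []
    profiles = {}
    tracks = {}
    tracks_sel = {}
    true_tfx: dict[str, float] = {}
    tfx_by_sample: dict[str, float] = {}

    for i, cohort in enumerate(cohorts):
        pid = f"P{i:03d}"
        patient_tfx = _draw_tfx(cohort, config, rng)
        psa = _draw_psa(cohort, config, rng)
        met = None
        if cohort == Cohort.APCA:
            met = rng.choice(["N1M0", "M1"])
        fluids = [Fluid.PLASMA] if i in missing_urine else [Fluid.PLASMA, Fluid.URINE]
        for fluid in fluids:
            sid = f"{pid}_{fluid.value}"
            # biofluid-specific tumor fractions share the patient's level but
            # are not identical (shedding differs between compartments)
            tfx = patient_tfx
            if cohort != Cohort.CONTROL:
                tfx = float(np.clip(patient_tfx * rng.lognormal(0.0, 0.25), 0.0, 0.95))
            samples.append(
                SampleRecord(sample_id=sid, patient_id=pid, fluid=fluid, cohort=cohort,
                             psa=psa, metastasis=Metastasis(met) if met else None)
            )
            true_tfx[sid] = tfx
            tfx_by_sample[sid] = tfx

            if fluid == Fluid.PLASMA:
                dens = plasma_fragment_density(tfx, config)
            else:
                w_peak = float(rng.beta(
                    config.urine_normal.w_peak * config.urine_peak_weight_concentration,
                    (1 - config.urine_normal.w_peak) * config.urine_peak_weight_concentration,
                ))
                mix = replace(config.urine_normal, w_peak=w_peak, w_broad=1 - w_peak)
                dens = urine_fragment_density(tfx, config, mix_normal=mix)
            profiles[sid] = sample_fragments(dens, config.n_fragments, rng, sample_id=sid)

            sample_states = states if cohort != Cohort.CONTROL else np.full(len(bins), 2)
            tracks[sid] = gen_bin_counts(bins, sample_states, tfx, config, rng, sample_id=sid)
            if fluid == Fluid.PLASMA:
                eff, retained = size_selection_enrichment(tfx, config)
                tracks_sel[sid] = gen_bin_counts(
                    bins, sample_states, eff, config, rng, sample_id=sid,
                    depth=config.depth_per_bin * retained,
                )

    methylation = gen_methyl_matrix(windows, marker_idx, tfx_by_sample, config, rng,
                                    base_beta=base_beta)
    marker_regions = RegionSet(
        name="planted_markers",
        regions=windows.iloc[marker_idx][["chrom", "start", "end"]].reset_index(drop=True),
    )
    truth = CohortTruth(
        true_tfx=true_tfx,
        cnv_segments=segments_from_states(bins, states),
        marker_windows=marker_regions,
        seed=config.seed,
    )
    return SyntheticCohort(
        samples=samples,
        fragment_profiles=profiles,
        bin_tracks=tracks,
        bin_tracks_size_selected=tracks_sel,
        methylation=methylation,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# tissue-vs-buffy marker experiment


@dataclass
class TissueExperiment:
    """Matched tumor-tissue / buffy-coat methylation matrices with truth."""

    matrix: MethylWindowMatrix
    tissue_ids: list[str]
    buffy_ids: list[str]
    planted_idx: np.ndarray
    external_top: RegionSet  # emulated published top-ranked DMR list (500 bp windows)


def gen_tissue_experiment(config: GeneratorConfig | None = None, seed: int = 0,
                          n_pairs: int = 8, n_external: int = 100) -> TissueExperiment:
    """Simulate the tissue marker-derivation experiment.

    ``n_pairs`` tumor tissues and matched buffy coats; the planted marker
    windows are strongly hypermethylated in tissue. The emulated external
    list contains 500 bp windows overlapping every planted window plus decoy
    windows placed over unplanted genome, so the marker-selection overlap
    should recover exactly the planted set.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    windows = make_methyl_windows(config, rng)
    planted_idx = np.sort(rng.choice(config.n_windows, size=config.n_marker_windows, replace=False))
    base_beta = rng.beta(*config.beta_background, size=config.n_windows)

    tissue_ids = [f"T{i}" for i in range(n_pairs)]
    buffy_ids = [f"B{i}" for i in range(n_pairs)]
    tfx_by_sample = {sid: 1.0 for sid in tissue_ids}
    tfx_by_sample.update({sid: 0.0 for sid in buffy_ids})
    matrix = gen_methyl_matrix(windows, planted_idx, tfx_by_sample, config, rng,
                               base_beta=base_beta)

    # external top list: 500 bp windows centered on planted windows (coordinate
    # grids differ, as for a published list) plus unplanted decoys
    planted = windows.iloc[planted_idx]
    centers = ((planted["start"] + planted["end"]) // 2).to_numpy()
    rows = [
        {"chrom": c, "start": max(0, int(m - 250)), "end": int(m + 250)}
        for c, m in zip(planted["chrom"], centers)
    ]
    n_decoy = max(0, n_external - len(rows))
    unplanted = np.setdiff1d(np.arange(config.n_windows), planted_idx)
    decoys = rng.choice(unplanted, size=n_decoy, replace=False)
    for i in decoys:
        w = windows.iloc[int(i)]
        rows.append({"chrom": w["chrom"], "start": int(w["start"]) - 100,
                     "end": int(w["start"]) + 400})
    ext = pd.DataFrame(rows).drop_duplicates(subset=["chrom", "start", "end"])
    external = RegionSet(name="external_top100", regions=ext)
    return TissueExperiment(matrix=matrix, tissue_ids=tissue_ids, buffy_ids=buffy_ids,
                            planted_idx=planted_idx, external_top=external)
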