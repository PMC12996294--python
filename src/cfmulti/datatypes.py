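"""Core domain types for multimodal cfDNA analysis.

All genomic coordinates are 0-based, half-open (BED convention). Any 1-based
source must be converted at the reader boundary and only there.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LENGTH_GRID_LO = 30
LENGTH_GRID_HI = 700  # inclusive
LENGTH_GRID = np.arange(LENGTH_GRID_LO, LENGTH_GRID_HI + 1)


class Fluid(str, enum.Enum):
    PLASMA = "plasma"
    URINE = "urine"
    TISSUE = "tissue"
    BUFFY = "buffy"


class Cohort(str, enum.Enum):
    CONTROL = "control"
    LPCA = "lPCa"
    APCA = "aPCa"


class Metastasis(str, enum.Enum):
    N0M0 = "N0M0"
    N1M0 = "N1M0"
    M1 = "M1"


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """One biofluid sample of one patient."""

    sample_id: str
    patient_id: str
    fluid: Fluid
    cohort: Cohort
    psa: float | None = None  # ng/mL
    stage_t: str | None = None
    gleason: str | None = None
    metastasis: Metastasis | None = None

    def __post_init__(self):
        if self.psa is not None and not np.isnan(self.psa) and self.psa < 0:
            raise ValidationError(
                f"sample {self.sample_id}: PSA must be nonnegative, got {self.psa}"
            )


def validate_sample_sheet(records: list[SampleRecord]) -> list[SampleRecord]:
    """Enforce sheet-level invariants: unique sample ids, one sample per
    (patient, fluid)."""
    seen_ids: dict[str, int] = {}
    for r in records:
        seen_ids[r.sample_id] = seen_ids.get(r.sample_id, 0) + 1
    dups = sorted(k for k, v in seen_ids.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate sample_id(s): {', '.join(dups)}")
    seen_pf: dict[tuple[str, Fluid], str] = {}
    for r in records:
        key = (r.patient_id, r.fluid)
        if key in seen_pf:
            raise ValidationError(
                f"patient {r.patient_id} has more than one {r.fluid.value} sample "
                f"({seen_pf[key]}, {r.sample_id})"
            )
        seen_pf[key] = r.sample_id
    return records


@dataclass
class FragmentProfile:
    """Normalized fragment-length frequency vector on the 30-700 bp grid."""

    sample_id: str
    rel_freq: np.ndarray  # aligned to LENGTH_GRID
    n_fragments: int

    def __post_init__(self):
        self.rel_freq = np.asarray(self.rel_freq, dtype=float)
        if self.rel_freq.shape != LENGTH_GRID.shape:
            raise ValidationError(
                f"rel_freq must cover the {LENGTH_GRID_LO}-{LENGTH_GRID_HI} bp grid "
                f"({LENGTH_GRID.size} points), got {self.rel_freq.shape}"
            )
        if np.any(self.rel_freq < 0):
            raise ValidationError("rel_freq must be nonnegative")
        if self.n_fragments > 0:
            total = self.rel_freq.sum()
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"rel_freq must sum to 1, got {total!r}")

    @property
    def lengths(self) -> np.ndarray:
        return LENGTH_GRID

    def freq_at(self, length: int) -> float:
        return float(self.rel_freq[length - LENGTH_GRID_LO])


_BIN_COLUMNS = ["chrom", "start", "end", "raw_count", "gc", "mappability"]


@dataclass
class BinCountTrack:
    """Per-bin read counts with GC/mappability covariates (default 1000 kb bins)."""

    sample_id: str
    bins: pd.DataFrame  # columns: chrom, start, end, raw_count, gc, mappability
    bin_size: int = 1_000_000

    def __post_init__(self):
        missing = [c for c in _BIN_COLUMNS if c not in self.bins.columns]
        if missing:
            raise ValidationError(f"bin table missing columns: {missing}")
        df = self.bins.reset_index(drop=True)
        if (df["raw_count"] < 0).any():
            bad = df.index[df["raw_count"] < 0][0]
            raise ValidationError(f"negative raw_count at bin index {bad}")
        for col in ("gc", "mappability"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValidationError(f"{col} must lie in [0, 1]")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        _check_non_overlapping(df, what="bins")
        self.bins = df

    def __len__(self) -> int:
        return len(self.bins)


def _check_non_overlapping(df: pd.DataFrame, what: str) -> None:
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{what}: start must be < end")
    same = df["chrom"].values[1:] == df["chrom"].values[:-1]
    overlap = same & (df["start"].values[1:] < df["end"].values[:-1])
    if overlap.any():
        i = int(np.flatnonzero(overlap)[0])
        a, b = df.iloc[i], df.iloc[i + 1]
        raise ValidationError(
            f"overlapping {what}: {a.chrom}:{a.start}-{a.end} and "
            f"{b.chrom}:{b.start}-{b.end}"
        )


@dataclass
class RegionSet:
    """Named set of sorted, non-overlapping-by-duplicate genomic intervals."""

    name: str
    regions: pd.DataFrame  # columns: chrom, start, end [, label]

    def __post_init__(self):
        df = self.regions.reset_index(drop=True)
        for c in ("chrom", "start", "end"):
            if c not in df.columns:
                raise ValidationError(f"region set {self.name!r} missing column {c!r}")
        if (df["start"] >= df["end"]).any():
            raise ValidationError(f"region set {self.name!r}: start must be < end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(subset=["chrom", "start", "end"]).any():
            raise ValidationError(f"region set {self.name!r}: duplicate regions")
        self.regions = df

    def __len__(self) -> int:
        return len(self.regions)

    def keys(self) -> pd.Index:
        r = self.regions
        return pd.Index(
            r["chrom"].astype(str) + ":" + r["start"].astype(str) + "-" + r["end"].astype(str)
        )


@dataclass
class MethylWindowMatrix:
    """Fixed-width methylation windows with per-sample enrichment signal (nrpkm)
    and derived beta-values.

    ``signal`` and ``beta`` are sample x window DataFrames sharing the same
    column order as ``windows`` rows.
    """

    windows: pd.DataFrame  # columns: chrom, start, end, cpg_count
    signal: pd.DataFrame  # samples x windows, nrpkm
    beta: pd.DataFrame | None = None

    def __post_init__(self):
        w = self.windows.reset_index(drop=True)
        for c in ("chrom", "start", "end", "cpg_count"):
            if c not in w.columns:
                raise ValidationError(f"window table missing column {c!r}")
        w = w.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        _check_non_overlapping(w, what="windows")
        widths = w["end"] - w["start"]
        if widths.nunique() > 1:
            raise ValidationError("windows must share a fixed width")
        self.windows = w
        if (self.signal.values < 0).any():
            raise ValidationError("signal (nrpkm) must be nonnegative")
        if self.beta is not None:
            b = self.beta.values
            if np.nanmin(b) < -1e-12 or np.nanmax(b) > 1 + 1e-12:
                raise ValidationError("beta values must lie in [0, 1]")

    @property
    def window_keys(self) -> pd.Index:
        w = self.windows
        return pd.Index(
            w["chrom"].astype(str) + ":" + w["start"].astype(str) + "-" + w["end"].astype(str)
        )

    def region_set(self, name: str = "windows") -> RegionSet:
        return RegionSet(name=name, regions=self.windows[["chrom", "start", "end"]].copy())


#: canonical per-(patient, fluid) scalar features
FEATURES = [
    "tfx",
    "tfx_size_selected",
    "cia_score",
    "methylation_score",
    "oscillation_score",
    "p163_169",
]


@dataclass
class FeatureTable:
    """Per-(patient, fluid) scalar features with optional z-scores and calls.

    ``df`` is indexed by (patient_id, fluid) with feature columns; z-scored
    columns carry a ``_z`` suffix and positivity flags a ``_positive`` suffix.
    """

    df: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.df.index, pd.MultiIndex) or self.df.index.names != [
            "patient_id",
            "fluid",
        ]:
            raise ValidationError("FeatureTable must be indexed by (patient_id, fluid)")
        for col in ("tfx", "tfx_size_selected", "methylation_score"):
            if col in self.df.columns:
                v = self.df[col].dropna()
                if ((v < 0) | (v > 1)).any():
                    raise ValidationError(f"{col} must lie in [0, 1]")

    def fluid_slice(self, fluid: str) -> pd.DataFrame:
        return self.df.xs(fluid, level="fluid")


@dataclass
class CohortTruth:
    """Generator ground truth for parameter-recovery tests."""

    true_tfx: dict[str, float]  # sample_id -> tumor fraction
    cnv_segments: RegionSet  # planted segments with integer 'copy_state' label
    marker_windows: RegionSet  # planted hypermethylated marker windows
    seed: int

    def __post_init__(self):
        if "copy_state" not in self.cnv_segments.regions.columns:
            raise ValidationError("cnv_segments must carry a copy_state column")


@dataclass
class SyntheticCohort:
    """A complete simulated study: samples, per-sample data, and ground truth."""

    samples: list[SampleRecord]
    fragment_profiles: dict[str, FragmentProfile]
    bin_tracks: dict[str, BinCountTrack]
    bin_tracks_size_selected: dict[str, BinCountTrack] = field(default_factory=dict)
    methylation: MethylWindowMatrix | None = None
    truth: CohortTruth | None = None

    def sample_ids(self, fluid: Fluid | None = None, cohort: Cohort | None = None) -> list[str]:
        out = []
        for r in self.samples:
            if fluid is not None and r.fluid != fluid:
                continue
            if cohort is not None and r.cohort != cohort:
                continue
            out.append(r.sample_id)
        return out

    def sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.samples],
                "patient_id": [r.patient_id for r in self.samples],
                "fluid": [r.fluid.value for r in self.samples],
                "cohort": [r.cohort.value for r in self.samples],
                "psa": [r.psa for r in self.samples],
                "stage_t": [r.stage_t for r in self.samples],
                "gleason": [r.gleason for r in self.samples],
                "metastasis": [r.metastasis.value if r.metastasis else None for r in self.samples],
            }
        )
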