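"""File readers and writers.

Formats are deliberately plain: CSV sample sheets, two-column TSV fragment
histograms, BED-like TSV for bins/windows/regions, CSV feature tables. All
coordinates on disk and in memory are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    LENGTH_GRID,
    LENGTH_GRID_HI,
    LENGTH_GRID_LO,
    BinCountTrack,
    Cohort,
    FeatureTable,
    Fluid,
    FragmentProfile,
    Metastasis,
    MethylWindowMatrix,
    RegionSet,
    SampleRecord,
    ValidationError,
    validate_sample_sheet,
)

logger = logging.getLogger(__name__)

_REQUIRED_SHEET_COLUMNS = ["sample_id", "patient_id", "fluid", "cohort"]


class SchemaError(ValueError):
    """Raised when a file does not match its expected schema."""


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read and validate a cohort sample sheet (CSV, header required)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in _REQUIRED_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet missing required column(s): {missing}")

    def _enum(cls, value, column, row):
        try:
            return cls(value)
        except ValueError as exc:
            allowed = ", ".join(m.value for m in cls)
            raise SchemaError(
                f"row {row}: unknown {column} {value!r} (allowed: {allowed})"
            ) from exc

    records = []
    for i, row in df.iterrows():
        psa = row.get("psa", np.nan)
        psa = None if pd.isna(psa) else float(psa)
        met = row.get("metastasis", None)
        met = None if pd.isna(met) else _enum(Metastasis, met, "metastasis", i)
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                fluid=_enum(Fluid, row["fluid"], "fluid", i),
                cohort=_enum(Cohort, row["cohort"], "cohort", i),
                psa=psa,
                stage_t=None if pd.isna(row.get("stage_t", None)) else str(row["stage_t"]),
                gleason=None if pd.isna(row.get("gleason", None)) else str(row["gleason"]),
                metastasis=met,
            )
        )
    return validate_sample_sheet(records)


def write_sample_sheet(records: list[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "fluid": r.fluid.value,
            "cohort": r.cohort.value,
            "psa": r.psa,
            "stage_t": r.stage_t,
            "gleason": r.gleason,
            "metastasis": r.metastasis.value if r.metastasis else None,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fragment_histogram(path: str | Path, sample_id: str | None = None) -> FragmentProfile:
    """Read a length<TAB>count histogram and normalize on the 30-700 bp grid.

    Counts outside 30-700 bp are discarded before normalization.
    """
    df = pd.read_csv(path, sep="\t")
    for c in ("length", "count"):
        if c not in df.columns:
            raise SchemaError(f"fragment histogram missing column {c!r}")
    if (df["count"] < 0).any():
        raise ValidationError("fragment counts must be nonnegative")
    keep = (df["length"] >= LENGTH_GRID_LO) & (df["length"] <= LENGTH_GRID_HI)
    df = df[keep]
    counts = np.zeros(LENGTH_GRID.size)
    np.add.at(counts, df["length"].to_numpy(dtype=int) - LENGTH_GRID_LO, df["count"].to_numpy(float))
    return profile_from_counts(counts, sample_id or Path(path).stem)


def profile_from_counts(counts: np.ndarray, sample_id: str) -> FragmentProfile:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError(
            f"sample {sample_id}: no fragments in the {LENGTH_GRID_LO}-{LENGTH_GRID_HI} bp range"
        )
    return FragmentProfile(
        sample_id=sample_id, rel_freq=counts / total, n_fragments=int(round(total))
    )


def write_fragment_histogram(profile: FragmentProfile, path: str | Path) -> None:
    counts = np.rint(profile.rel_freq * profile.n_fragments).astype(int)
    pd.DataFrame({"length": LENGTH_GRID, "count": counts}).to_csv(path, sep="\t", index=False)


def _read_bedlike(path: str | Path, columns: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing column(s): {missing}")
    out = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(out):
        logger.warning("%s file %s was not coordinate-sorted; sorting", what, path)
    return out


def read_bin_counts(path: str | Path, sample_id: str | None = None, bin_size: int = 1_000_000) -> BinCountTrack:
    df = _read_bedlike(
        path, ["chrom", "start", "end", "raw_count", "gc", "mappability"], "bin counts"
    )
    return BinCountTrack(sample_id=sample_id or Path(path).stem, bins=df, bin_size=bin_size)


def write_bin_counts(track: BinCountTrack, path: str | Path) -> None:
    track.bins.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED3(+) TSV. A 4th column, if present, is kept as ``label``."""
    first = pd.read_csv(path, sep="\t", nrows=1)
    if "chrom" in first.columns:
        df = _read_bedlike(path, ["chrom", "start", "end"], "regions")
    else:  # headerless BED (possibly ragged: optional label column)
        with open(path) as fh:
            width = max(len(line.rstrip("\n").split("\t")) for line in fh if line.strip())
        names = (["chrom", "start", "end", "label"]
                 + [f"col{i}" for i in range(4, width)])[:width]
        df = pd.read_csv(path, sep="\t", header=None, names=names, index_col=False)
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return RegionSet(name=name or Path(path).stem, regions=df)


def write_regions(regions: RegionSet, path: str | Path, header: bool = True) -> None:
    regions.regions.to_csv(path, sep="\t", index=False, header=header)


def read_methyl_windows(path: str | Path, sample_id: str | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Read one sample's window table (chrom, start, end, cpg_count and either
    an ``nrpkm`` or a raw ``count`` column).

    Returns (window table, per-window signal series). Assembling a
    :class:`MethylWindowMatrix` across samples is done by the caller.
    """
    df = _read_bedlike(path, ["chrom", "start", "end", "cpg_count"], "methylation windows")
    if "nrpkm" in df.columns:
        sig = df["nrpkm"].astype(float)
    elif "count" in df.columns:
        if (df["count"] < 0).any():
            raise ValidationError("window counts must be nonnegative")
        from .methylation import nrpkm

        sig = pd.Series(
            nrpkm(
                df["count"].to_numpy(float),
                window_width=int((df["end"] - df["start"]).iloc[0]),
                library_size=float(df["count"].sum()),
            )
        )
    else:
        raise SchemaError("methylation window file needs an 'nrpkm' or 'count' column")
    sig.name = sample_id or Path(path).stem
    return df[["chrom", "start", "end", "cpg_count"]], sig


def assemble_methyl_matrix(
    tables: list[tuple[pd.DataFrame, pd.Series]]
) -> MethylWindowMatrix:
    """Combine per-sample window tables into one matrix; windows must agree."""
    windows = tables[0][0]
    for w, _ in tables[1:]:
        if not w[["chrom", "start", "end"]].equals(windows[["chrom", "start", "end"]]):
            raise ValidationError("samples have inconsistent window definitions")
    signal = pd.DataFrame({s.name: s.to_numpy(float) for _, s in tables}).T
    return MethylWindowMatrix(windows=windows, signal=signal)


_FEATURE_COLUMN_ORDER = [
    "tfx",
    "tfx_size_selected",
    "cia_score",
    "methylation_score",
    "oscillation_score",
    "p163_169",
]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    ordered = [c for c in _FEATURE_COLUMN_ORDER if c in table.df.columns]
    rest = [c for c in table.df.columns if c not in ordered]
    table.df[ordered + rest].reset_index().to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for c in ("patient_id", "fluid"):
        if c not in df.columns:
            raise SchemaError(f"feature table missing column {c!r}")
    return FeatureTable(df=df.set_index(["patient_id", "fluid"]))
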