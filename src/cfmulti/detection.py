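"""Percentile-calibrated ctDNA detection and plasma/urine integration.

Thresholds are calibrated on control samples only: the 95th percentile for
features elevated in tumor samples, the 5th percentile for the plasma
10 bp-oscillation score (which decreases with tumor content). Calls use a
strict comparison ("beyond" the threshold). The four feature families
(tumor fraction, chromosomal instability, methylation score, fragmentation)
are integrated complementarily across fluids: a family is positive for a
patient if it is positive in plasma OR urine, giving a 0-4 positivity count
per patient and the oncoprint matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import FeatureTable, ValidationError

#: feature family -> fluid -> (feature column, direction of tumor signal)
FEATURE_FAMILIES: dict[str, dict[str, tuple[str, str]]] = {
    "tfx": {"plasma": ("tfx_size_selected", "above"), "urine": ("tfx", "above")},
    "cia": {"plasma": ("cia_score", "above"), "urine": ("cia_score", "above")},
    "methylation": {
        "plasma": ("methylation_score", "above"),
        "urine": ("methylation_score", "above"),
    },
    "fragmentation": {
        "plasma": ("oscillation_score", "below"),
        "urine": ("p163_169", "above"),
    },
}

#: families reported as cross-fluid max-z (strongest signal per patient)
MAX_Z_FEATURES = ["tfx", "cia", "methylation"]

PSA_STRATA = [("<4", 0.0, 4.0), ("4-10", 4.0, 10.0), (">10", 10.0, np.inf)]


@dataclass
class DetectionThresholds:
    """Per-(family, fluid) calibrated thresholds with audit information."""

    table: pd.DataFrame  # index (family, fluid); columns value, direction, percentile
    calibration_ids: dict[str, list[str]]  # fluid -> control sample ids

    def lookup(self, family: str, fluid: str) -> tuple[float, str]:
        row = self.table.loc[(family, fluid)]
        return float(row["value"]), str(row["direction"])


def _feature_values(df: pd.DataFrame, fluid: str, column: str) -> pd.Series:
    try:
        sub = df.xs(fluid, level="fluid")
    except KeyError:
        return pd.Series(dtype=float)
    if column not in sub.columns:
        return pd.Series(dtype=float)
    return sub[column].dropna()


def calibrate_thresholds(
    control_features: FeatureTable, min_controls: int = 2
) -> DetectionThresholds:
    """Percentile thresholds from control samples.

    95th percentile ("above" direction) for all features except the plasma
    oscillation score (5th percentile, "below"). Percentiles use linear
    interpolation between order statistics.
    """
    rows = []
    calib: dict[str, list[str]] = {}
    for family, by_fluid in FEATURE_FAMILIES.items():
        for fluid, (column, direction) in by_fluid.items():
            vals = _feature_values(control_features.df, fluid, column)
            if len(vals) < min_controls:
                raise ValidationError(
                    f"need >= {min_controls} control values for {column}/{fluid}, "
                    f"got {len(vals)}"
                )
            pct = 5.0 if direction == "below" else 95.0
            thr = float(np.percentile(vals.to_numpy(float), pct, method="linear"))
            rows.append({"family": family, "fluid": fluid, "feature": column,
                         "value": thr, "direction": direction, "percentile": pct,
                         "n_controls": len(vals)})
            calib.setdefault(fluid, sorted(set(vals.index.astype(str))))
    table = pd.DataFrame(rows).set_index(["family", "fluid"])
    return DetectionThresholds(table=table, calibration_ids=calib)


def call_positivity(features: FeatureTable, thresholds: DetectionThresholds) -> pd.DataFrame:
    """Per-(patient, family, fluid) calls: positive / negative / not_available.

    Strictly beyond the threshold counts as positive; a value exactly at the
    threshold is negative; a missing fluid or feature is not_available.
    """
    patients = features.df.index.get_level_values("patient_id").unique()
    records = []
    for family, by_fluid in FEATURE_FAMILIES.items():
        for fluid, (column, _) in by_fluid.items():
            thr, direction = thresholds.lookup(family, fluid)
            vals = _feature_values(features.df, fluid, column)
            for pid in patients:
                if pid not in vals.index:
                    call = "not_available"
                else:
                    v = float(vals.loc[pid])
                    hit = v > thr if direction == "above" else v < thr
                    call = "positive" if hit else "negative"
                records.append({"patient_id": pid, "family": family, "fluid": fluid,
                                "call": call})
    return pd.DataFrame(records)


def integrate_complementary(calls: pd.DataFrame) -> pd.DataFrame:
    """Patient-level complementary integration across fluids.

    A family is positive if positive in any fluid, negative if at least one
    fluid was evaluable and none positive, not_available otherwise.
    n_positive counts each family at most once (0-4); any_positive is
    n_positive >= 1.
    """
    rows = []
    for pid, sub in calls.groupby("patient_id", sort=False):
        row: dict = {"patient_id": pid}
        n_pos = 0
        for family in FEATURE_FAMILIES:
            fam = sub[sub["family"] == family]["call"]
            if (fam == "positive").any():
                row[family] = "positive"
                n_pos += 1
            elif (fam == "negative").any():
                row[family] = "negative"
            else:
                row[family] = "not_available"
        row["n_positive"] = n_pos
        row["any_positive"] = n_pos >= 1
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def control_feature_stats(control_features: FeatureTable) -> pd.DataFrame:
    """Control mean/SD per (family, fluid) used for z-standardization.

    A feature whose control distribution is degenerate (zero SD — e.g. the
    estimated tumor fraction, which is exactly 0 on flat control genomes)
    is centered but not scaled (SD set to 1) and flagged.
    """
    rows = []
    for family, by_fluid in FEATURE_FAMILIES.items():
        for fluid, (column, _) in by_fluid.items():
            vals = _feature_values(control_features.df, fluid, column)
            if len(vals) < 2:
                raise ValidationError(
                    f"cannot z-standardize {column}/{fluid}: need >= 2 control values"
                )
            sd = float(vals.std(ddof=1))
            rows.append({"family": family, "fluid": fluid, "feature": column,
                         "mean": float(vals.mean()), "sd": sd if sd > 0 else 1.0,
                         "degenerate": sd == 0})
    return pd.DataFrame(rows).set_index(["family", "fluid"])


def max_z_features(features: FeatureTable, control_stats: pd.DataFrame) -> pd.DataFrame:
    """Strongest control-standardized signal per patient across fluids.

    For each of the cross-fluid families (tumor fraction, CIA score,
    methylation score) the per-fluid values are z-scored against control
    mean/SD of that (feature, fluid) and the per-patient maximum over
    available fluids is taken; with one fluid missing, the other fluid's z
    is used.
    """
    patients = features.df.index.get_level_values("patient_id").unique()
    out = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    for family in MAX_Z_FEATURES:
        zcols = []
        for fluid, (column, _) in FEATURE_FAMILIES[family].items():
            mu = control_stats.loc[(family, fluid), "mean"]
            sd = control_stats.loc[(family, fluid), "sd"]
            vals = _feature_values(features.df, fluid, column)
            zcols.append(((vals - mu) / sd).rename(fluid))
        z = pd.concat(zcols, axis=1).reindex(patients)
        out[f"max_z_{family}"] = z.max(axis=1, skipna=True)
    return out


def detection_report(
    calls: pd.DataFrame, sheet: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Summary tables: per-(family, fluid) and complementary detection rates
    by cohort, positivity-count distribution by PSA stratum, and the
    oncoprint matrix (tumor patients x family/fluid calls).

    ``sheet`` is a sample-sheet DataFrame with patient_id, cohort and psa.
    """
    patients = (
        sheet[["patient_id", "cohort", "psa"]]
        .drop_duplicates("patient_id")
        .set_index("patient_id")
    )
    merged = calls.merge(patients, left_on="patient_id", right_index=True)
    tumor = merged[merged["cohort"] != "control"]

    def _rate(sub: pd.DataFrame) -> tuple[float, int, int]:
        evaluable = sub[sub["call"] != "not_available"]
        n_pos = int((evaluable["call"] == "positive").sum())
        return (100.0 * n_pos / len(evaluable) if len(evaluable) else np.nan,
                n_pos, len(evaluable))

    rate_rows = []
    for (cohort, family, fluid), sub in tumor.groupby(["cohort", "family", "fluid"]):
        r, n_pos, n_eval = _rate(sub)
        rate_rows.append({"cohort": cohort, "family": family, "fluid": fluid,
                          "rate_pct": r, "n_positive": n_pos, "n_evaluable": n_eval})
    integrated = integrate_complementary(calls)
    integ = integrated.merge(patients, left_index=True, right_index=True)
    tumor_integ = integ[integ["cohort"] != "control"]
    for cohort, sub in tumor_integ.groupby("cohort"):
        for family in FEATURE_FAMILIES:
            ev = sub[sub[family] != "not_available"]
            n_pos = int((ev[family] == "positive").sum())
            rate_rows.append({
                "cohort": cohort, "family": family, "fluid": "complementary",
                "rate_pct": 100.0 * n_pos / len(ev) if len(ev) else np.nan,
                "n_positive": n_pos, "n_evaluable": len(ev)})
        rate_rows.append({
            "cohort": cohort, "family": "any", "fluid": "complementary",
            "rate_pct": 100.0 * sub["any_positive"].mean(),
            "n_positive": int(sub["any_positive"].sum()), "n_evaluable": len(sub)})
    rates = pd.DataFrame(rate_rows)

    psa_rows = []
    for name, lo, hi in PSA_STRATA:
        sub = tumor_integ[(tumor_integ["psa"] >= lo) & (tumor_integ["psa"] < hi)]
        for cohort, csub in sub.groupby("cohort"):
            counts = csub["n_positive"].value_counts().to_dict()
            psa_rows.append({
                "psa_stratum": name, "cohort": cohort, "n_patients": len(csub),
                **{f"n_pos_{k}": int(counts.get(k, 0)) for k in range(5)}})
    psa_table = pd.DataFrame(psa_rows)

    oncoprint = tumor.pivot_table(
        index="patient_id", columns=["family", "fluid"], values="call",
        aggfunc="first",
    )
    oncoprint.columns = [f"{fam}_{fl}" for fam, fl in oncoprint.columns]
    oncoprint = oncoprint.join(integrated["n_positive"])
    return {"rates": rates, "psa": psa_table, "oncoprint": oncoprint,
            "integrated": integrated}


class PercentileDetector(BaseEstimator):
    """Control-calibrated percentile ctDNA caller.

    scikit-learn-style: ``fit`` learns per-(family, fluid) thresholds from a
    control FeatureTable (95th percentile, 5th for the plasma oscillation
    score) and control mean/SD for z-standardization; ``predict`` returns
    per-patient family/fluid calls and ``transform`` the max-z cross-fluid
    features.
    """

    def __init__(self, min_controls: int = 2):
        self.min_controls = min_controls

    def fit(self, control_features: FeatureTable, y=None) -> "PercentileDetector":
        self.thresholds_ = calibrate_thresholds(control_features, self.min_controls)
        self.control_stats_ = control_feature_stats(control_features)
        return self

    def predict(self, features: FeatureTable) -> pd.DataFrame:
        return call_positivity(features, self.thresholds_)

    def transform(self, features: FeatureTable) -> pd.DataFrame:
        return max_z_features(features, self.control_stats_)
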