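"""Discrimination models combining PSA with cfDNA features.

Builds the paired logistic comparisons of the study: a PSA-only model
against PSA plus five quantitative cfDNA features (the per-patient max-z
tumor fraction, CIA score and methylation score across fluids, the plasma
10 bp-oscillation score, and urinary P163-169), for two contrasts —
localized vs advanced disease, and cancer vs controls — optionally within
a PSA stratum (e.g. PSA < 10 ng/mL). Models are compared by ROC AUC with
DeLong's test, a stratified bootstrap of the AUC, and a likelihood-ratio
test of the nested fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Cohort, FeatureTable, SampleRecord
from .detection import PercentileDetector
from .stats import (
    bootstrap_auc,
    delong_auc_ci,
    delong_test,
    fit_logistic,
    likelihood_ratio_test,
    roc_auc,
)

#: default quantitative cfDNA predictors added to PSA (config-driven)
CFDNA_PREDICTORS = [
    "max_z_tfx",
    "max_z_cia",
    "max_z_methylation",
    "oscillation_score",
    "p163_169",
]


def patient_model_frame(table: FeatureTable, records: list[SampleRecord]) -> pd.DataFrame:
    """One row per patient: PSA, cohort, max-z cross-fluid features, and the
    fluid-specific fragmentation features."""
    sheet = pd.DataFrame(
        [
            {"patient_id": r.patient_id, "cohort": r.cohort.value, "psa": r.psa}
            for r in records
        ]
    ).drop_duplicates("patient_id").set_index("patient_id")
    control_pids = {r.patient_id for r in records if r.cohort == Cohort.CONTROL}
    is_ctrl = table.df.index.get_level_values("patient_id").isin(control_pids)
    det = PercentileDetector().fit(FeatureTable(df=table.df[is_ctrl]))
    frame = det.transform(table)
    for fluid, col in (("plasma", "oscillation_score"), ("urine", "p163_169")):
        try:
            vals = table.df.xs(fluid, level="fluid")[col]
        except KeyError:
            continue
        frame[col] = vals.reindex(frame.index)
    return frame.join(sheet)


def _contrast_labels(frame: pd.DataFrame, contrast: str) -> pd.Series:
    if contrast == "lpca-vs-apca":
        sub = frame[frame["cohort"].isin(["lPCa", "aPCa"])]
        return (sub["cohort"] == "aPCa").astype(int)
    if contrast == "pca-vs-controls":
        return (frame["cohort"] != "control").astype(int)
    raise ValueError(f"unknown contrast {contrast!r}")


def discrimination_models(
    table: FeatureTable,
    records: list[SampleRecord],
    contrast: str = "lpca-vs-apca",
    psa_max: float | None = None,
    predictors: list[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Fit and compare the PSA-only and PSA+cfDNA logistic models.

    Returns a JSON-serializable dict with coefficients, AUCs (DeLong CI and
    stratified bootstrap), the DeLong comparison and the likelihood-ratio
    test of the nested fits.
    """
    predictors = predictors or CFDNA_PREDICTORS
    frame = patient_model_frame(table, records)
    y = _contrast_labels(frame, contrast)
    frame = frame.loc[y.index]
    if psa_max is not None:
        keep = frame["psa"] < psa_max
        frame, y = frame[keep], y[keep]
    used = [p for p in predictors if p in frame.columns]
    cols = ["psa"] + used
    complete = frame[cols].notna().all(axis=1)
    frame, y = frame[complete], y[complete]
    if y.nunique() < 2:
        raise ValueError("contrast has only one class after filtering")

    fit_psa = fit_logistic(y.to_numpy(), frame[["psa"]].to_numpy(),
                           names=["psa"], label="psa_only")
    fit_full = fit_logistic(y.to_numpy(), frame[cols].to_numpy(),
                            names=cols, label="psa_plus_cfdna")
    auc_psa, _ = roc_auc(fit_psa.fitted, y.to_numpy())
    auc_full, _ = roc_auc(fit_full.fitted, y.to_numpy())
    fit_psa.auc, fit_full.auc = auc_psa, auc_full
    dl = delong_test(fit_full.fitted, fit_psa.fitted, y.to_numpy())
    chi2, df, p_lrt = likelihood_ratio_test(fit_psa, fit_full)
    rng = np.random.default_rng(seed)
    boot_psa = bootstrap_auc(fit_psa.fitted, y.to_numpy(), n_boot=n_boot, seed=rng)
    boot_full = bootstrap_auc(fit_full.fitted, y.to_numpy(), n_boot=n_boot, seed=rng)
    _, ci_psa = delong_auc_ci(fit_psa.fitted, y.to_numpy())
    _, ci_full = delong_auc_ci(fit_full.fitted, y.to_numpy())
    return {
        "contrast": contrast,
        "psa_max": psa_max,
        "n": int(y.size),
        "n_pos": int(y.sum()),
        "predictors": cols,
        "psa_only": {
            "coef": dict(zip(["intercept"] + fit_psa.names, fit_psa.coef.tolist())),
            "auc": auc_psa, "auc_ci_delong": ci_psa,
            "auc_boot_mean": boot_psa["mean_auc"], "auc_boot_ci": boot_psa["ci"],
            "deviance": fit_psa.deviance, "separation": fit_psa.separation,
        },
        "psa_plus_cfdna": {
            "coef": dict(zip(["intercept"] + fit_full.names, fit_full.coef.tolist())),
            "auc": auc_full, "auc_ci_delong": ci_full,
            "auc_boot_mean": boot_full["mean_auc"], "auc_boot_ci": boot_full["ci"],
            "deviance": fit_full.deviance, "separation": fit_full.separation,
        },
        "delong": {"z": dl["z"], "p": dl["p"], "diff": dl["diff"],
                   "degenerate": dl["degenerate"]},
        "lrt": {"chi2": chi2, "df": df, "p": p_lrt},
    }
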