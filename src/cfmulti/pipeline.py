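"""End-to-end feature extraction: cohort -> per-(patient, fluid) FeatureTable.

Ties the stages together the way the study design prescribes:

* fragmentation features per profile (plasma: 10 bp-oscillation score;
  urine: P163-169);
* copy-number tumor fraction against a per-fluid panel of normals built
  from the control samples (leave-one-out for controls), with in-silico
  size selection for plasma;
* CIA score against the same panel;
* methylation score (median beta over marker windows).

Feature extraction never sees cohort labels or ground truth; controls are
used only as the copy-neutral reference, exactly as a real study would.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnv import CopyNumberEstimator
from .datatypes import (
    Cohort,
    FeatureTable,
    Fluid,
    MethylWindowMatrix,
    RegionSet,
    SyntheticCohort,
)
from .fragmentomics import oscillation_score, p163_169
from .methylation import methylation_score


def compute_feature_table(
    cohort: SyntheticCohort,
    markers: RegionSet | None = None,
    skip_cnv: bool = False,
    cnv_kwargs: dict | None = None,
) -> FeatureTable:
    """Extract the full multimodal feature table from a cohort.

    ``markers`` defaults to the cohort's planted marker windows (the
    tissue-informed marker set in a real study). ``skip_cnv`` omits the
    HMM-based tumor-fraction and CIA columns (used where only the cheap
    features are needed).
    """
    if markers is None:
        if cohort.truth is None:
            raise ValueError("markers must be given when the cohort carries no truth")
        markers = cohort.truth.marker_windows

    estimators: dict[Fluid, CopyNumberEstimator] = {}
    if not skip_cnv:
        for fluid in (Fluid.PLASMA, Fluid.URINE):
            control_ids = cohort.sample_ids(fluid=fluid, cohort=Cohort.CONTROL)
            if len(control_ids) >= 2:
                est = CopyNumberEstimator(**(cnv_kwargs or {}))
                est.fit([cohort.bin_tracks[s] for s in control_ids])
                estimators[fluid] = est

    meth_scores = None
    if cohort.methylation is not None:
        meth_scores = methylation_score(cohort.methylation, markers)

    rows = []
    for rec in cohort.samples:
        sid = rec.sample_id
        row: dict = {"patient_id": rec.patient_id, "fluid": rec.fluid.value}
        profile = cohort.fragment_profiles.get(sid)
        if profile is not None:
            if rec.fluid == Fluid.PLASMA:
                row["oscillation_score"] = oscillation_score(profile).score
            elif rec.fluid == Fluid.URINE:
                row["p163_169"] = p163_169(profile)
        est = estimators.get(rec.fluid)
        if est is not None and sid in cohort.bin_tracks:
            res = est.predict(cohort.bin_tracks[sid])
            row["tfx"] = res.tfx_hat
            row["cia_score"] = est.score_instability(cohort.bin_tracks[sid]).cia_score
            if sid in cohort.bin_tracks_size_selected:
                sel = est.predict(cohort.bin_tracks_size_selected[sid], size_selected=True)
                row["tfx_size_selected"] = sel.tfx_hat
        if meth_scores is not None and sid in meth_scores.index:
            row["methylation_score"] = float(meth_scores.loc[sid])
        rows.append(row)
    df = pd.DataFrame(rows).set_index(["patient_id", "fluid"])
    return FeatureTable(df=df)


def attach_z_scores(table: FeatureTable, control_patient_ids: set[str]) -> FeatureTable:
    """Add ``_z`` columns standardized against the control samples per fluid."""
    df = table.df.copy()
    is_control = df.index.get_level_values("patient_id").isin(control_patient_ids)
    for col in [c for c in df.columns if df[c].dtype.kind == "f"]:
        for fluid in df.index.get_level_values("fluid").unique():
            sel = df.index.get_level_values("fluid") == fluid
            ctrl = df.loc[sel & is_control, col].dropna()
            if len(ctrl) < 2 or ctrl.std(ddof=1) == 0:
                continue
            df.loc[sel, f"{col}_z"] = (df.loc[sel, col] - ctrl.mean()) / ctrl.std(ddof=1)
    return FeatureTable(df=df)
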