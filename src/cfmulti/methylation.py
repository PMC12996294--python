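"""Windowed methylation analysis from enrichment sequencing.

Covers the window-level workflow of methylated-DNA immunoprecipitation data:
nrpkm normalization, a saturating CpG-density-adjusted beta transform,
group DMR calling with Benjamini-Hochberg control, tissue-informed marker
selection by interval overlap against an external top-ranked DMR list, the
synoptic per-sample methylation score (median beta over marker windows),
and genomic / CpG-landscape annotation of regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import MethylWindowMatrix, RegionSet, ValidationError


def nrpkm(counts: np.ndarray, window_width: int, library_size: float) -> np.ndarray:
    """Normalized reads per kilobase per million mapped reads."""
    if library_size <= 0:
        raise ValidationError("library size must be positive")
    width_kb = window_width / 1000.0
    return np.asarray(counts, dtype=float) / (width_kb * library_size / 1e6)


def beta_transform(matrix: MethylWindowMatrix) -> MethylWindowMatrix:
    """Absolute methylation levels (beta in [0, 1]) from nrpkm signal.

    Per sample, the CpG-density-adjusted signal is
    ``s_w = nrpkm_w / cpg_w * median(cpg)`` and
    ``beta_w = s_w / (s_w + m)`` where m is the sample's median adjusted
    signal over CpG-containing windows. The transform is monotone in signal
    and anchors the typical window at beta = 0.5. Windows without CpGs are
    masked (NaN).
    """
    cpg = matrix.windows["cpg_count"].to_numpy(float)
    has_cpg = cpg > 0
    if not has_cpg.any():
        raise ValidationError("no CpG-containing windows")
    med_cpg = np.median(cpg[has_cpg])
    adj = matrix.signal.to_numpy(float) / np.where(has_cpg, cpg, np.nan) * med_cpg
    m = np.nanmedian(adj, axis=1, keepdims=True)
    if np.any(m <= 0):
        bad = matrix.signal.index[np.flatnonzero(m.ravel() <= 0)]
        raise ValidationError(f"all-zero methylation signal for sample(s): {list(bad)}")
    beta = adj / (adj + m)
    beta_df = pd.DataFrame(beta, index=matrix.signal.index, columns=matrix.signal.columns)
    return MethylWindowMatrix(windows=matrix.windows, signal=matrix.signal, beta=beta_df)


@dataclass
class DMRTable:
    """Per-window differential-methylation results for one comparison."""

    comparison: str
    table: pd.DataFrame  # columns: window index cols + logFC, p, p_adj, direction

    def significant(self, p_adj_max: float = 0.05, min_logfc: float | None = None,
                    direction: str | None = None) -> pd.DataFrame:
        t = self.table
        keep = t["p_adj"] < p_adj_max
        if min_logfc is not None:
            keep &= t["logFC"].abs() > min_logfc
        if direction is not None:
            keep &= t["direction"] == direction
        return t[keep]


def call_dmrs(
    matrix: MethylWindowMatrix,
    group_a: list[str],
    group_b: list[str],
    comparison: str = "a_vs_b",
    test: str = "ranksum",
    paired: bool = False,
    pseudocount: float = 0.1,
) -> DMRTable:
    """Window-wise differential methylation of group_a relative to group_b.

    ``test`` selects the per-window statistic on beta-values:

    * ``"ranksum"`` — Mann-Whitney rank-sum (exact when group sizes permit),
      or Wilcoxon signed-rank when ``paired=True``; distribution-free, the
      default for biofluid comparisons at p < 0.05;
    * ``"t"`` — Welch t (paired t when ``paired=True``); needed when the
      comparison must resolve adjusted p well below the exact rank-test
      floor of small groups (e.g. tissue marker derivation at n=8 with an
      adjusted p < 0.01 filter).

    logFC is log2 of the (pseudocounted) mean nrpkm ratio a/b; positive
    logFC means hypermethylation in group_a. P-values are BH-adjusted
    across all tested windows. Effect-size/significance filters are applied
    downstream, not here.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if paired and len(group_a) != len(group_b):
        raise ValidationError("paired mode requires equal, matched sample lists")
    if matrix.beta is None:
        matrix = beta_transform(matrix)
    beta_a = matrix.beta.loc[group_a].to_numpy(float)
    beta_b = matrix.beta.loc[group_b].to_numpy(float)
    sig_a = matrix.signal.loc[group_a].to_numpy(float)
    sig_b = matrix.signal.loc[group_b].to_numpy(float)

    n_win = beta_a.shape[1]
    tested = ~(np.isnan(beta_a).any(axis=0) | np.isnan(beta_b).any(axis=0))
    a, b = beta_a[:, tested], beta_b[:, tested]
    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "t":
            if paired:
                res = sps.ttest_rel(a, b, axis=0).pvalue
            else:
                res = sps.ttest_ind(a, b, axis=0, equal_var=False).pvalue
        elif test == "ranksum":
            if paired:
                res = sps.wilcoxon(a, b, axis=0).pvalue
            else:
                res = sps.mannwhitneyu(a, b, axis=0, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    pvals = np.ones(n_win)
    pvals[tested] = np.nan_to_num(np.asarray(res, dtype=float), nan=1.0)

    p_adj = np.ones(n_win)
    if tested.any():
        p_adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    logfc = np.log2((sig_a.mean(axis=0) + pseudocount) / (sig_b.mean(axis=0) + pseudocount))
    out = matrix.windows[["chrom", "start", "end"]].copy()
    out["logFC"] = logfc
    out["p"] = pvals
    out["p_adj"] = p_adj
    out["direction"] = np.where(logfc > 0, "hyper", "hypo")
    out.loc[~tested, ["p", "p_adj"]] = np.nan
    return DMRTable(comparison=comparison, table=out)


@dataclass
class MarkerSet:
    regions: RegionSet
    provenance: dict


def _to_pyranges(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {"Chromosome": df["chrom"], "Start": df["start"], "End": df["end"]}
        )
    )


def select_markers(
    dmrs: DMRTable,
    external: RegionSet,
    p_adj_max: float = 0.01,
    min_logfc: float = 2.0,
) -> MarkerSet:
    """Tissue-informed marker windows: significant hypermethylated DMRs that
    overlap (>= 1 bp, half-open coordinates) the external top-ranked list."""
    hyper = dmrs.significant(p_adj_max=p_adj_max, min_logfc=min_logfc, direction="hyper")
    if len(hyper) == 0 or len(external) == 0:
        regions = RegionSet(name="markers", regions=pd.DataFrame(columns=["chrom", "start", "end"]))
        return MarkerSet(regions=regions, provenance={
            "comparison": dmrs.comparison, "external": external.name,
            "p_adj_max": p_adj_max, "min_logfc": min_logfc, "n_internal": len(hyper)})
    joined = _to_pyranges(hyper).join(_to_pyranges(external.regions)).df
    if len(joined) == 0:
        sel = pd.DataFrame(columns=["chrom", "start", "end"])
    else:
        sel = (
            joined[["Chromosome", "Start", "End"]]
            .drop_duplicates()
            .rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
        )
        sel["chrom"] = sel["chrom"].astype(str)
    regions = RegionSet(name="markers", regions=sel.reset_index(drop=True))
    return MarkerSet(regions=regions, provenance={
        "comparison": dmrs.comparison, "external": external.name,
        "p_adj_max": p_adj_max, "min_logfc": min_logfc, "n_internal": len(hyper)})


def derive_markers(
    matrix: MethylWindowMatrix,
    tissue_ids: list[str],
    buffy_ids: list[str],
    external: RegionSet,
    test: str = "t",
    paired: bool = True,
    p_adj_max: float = 0.01,
    min_logfc: float = 2.0,
) -> MarkerSet:
    """Full tissue-vs-buffy marker derivation (DMR call + external overlap)."""
    dmrs = call_dmrs(matrix, tissue_ids, buffy_ids, comparison="tissue_vs_buffy",
                     test=test, paired=paired)
    return select_markers(dmrs, external, p_adj_max=p_adj_max, min_logfc=min_logfc)


def methylation_score(matrix: MethylWindowMatrix, markers: RegionSet | MarkerSet) -> pd.Series:
    """Per-sample methylation score: median beta over the marker windows."""
    if isinstance(markers, MarkerSet):
        markers = markers.regions
    if matrix.beta is None:
        matrix = beta_transform(matrix)
    keys = matrix.window_keys
    marker_keys = markers.keys()
    idx = np.flatnonzero(keys.isin(marker_keys))
    if idx.size == 0:
        raise ValidationError("no marker regions match the methylation windows")
    scores = matrix.beta.iloc[:, idx].median(axis=1)
    scores.name = "methylation_score"
    return scores


_GENOMIC_PRIORITY = ["promoter", "5UTR", "3UTR", "exon", "intron", "downstream"]


def annotate_regions(
    regions: RegionSet,
    gene_features: RegionSet,
    cpg_islands: RegionSet,
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> pd.DataFrame:
    """Genomic and CpG-landscape labels per region.

    ``gene_features`` must carry a ``label`` column with values among
    promoter / 5UTR / 3UTR / exon / intron / downstream; overlaps are
    resolved by that priority order, regions overlapping nothing are
    "distal_intergenic". The CpG label is island (>= 1 bp overlap),
    shore (within 2 kb), shelf (2-4 kb) or open_sea (> 4 kb).
    """
    if "label" not in gene_features.regions.columns:
        raise ValidationError("gene_features needs a 'label' column")
    out = regions.regions[["chrom", "start", "end"]].copy()
    keys = regions.keys()

    genomic = pd.Series("distal_intergenic", index=keys)
    gf = gene_features.regions
    reg_pr = _to_pyranges(out)
    for label in reversed(_GENOMIC_PRIORITY):  # apply highest priority last
        sub = gf[gf["label"] == label]
        if len(sub) == 0:
            continue
        hit = reg_pr.join(_to_pyranges(sub)).df
        if len(hit) == 0:
            continue
        hit_keys = (
            hit["Chromosome"].astype(str) + ":" + hit["Start"].astype(str)
            + "-" + hit["End"].astype(str)
        )
        genomic.loc[genomic.index.isin(hit_keys)] = label
    out["genomic"] = genomic.to_numpy()

    # CpG landscape by overlap with / gap distance to the nearest island
    overlap = pd.Series(False, index=keys)
    gap = pd.Series(np.inf, index=keys)
    if len(cpg_islands) > 0:
        near = reg_pr.nearest(_to_pyranges(cpg_islands.regions)).df
        if len(near) > 0:
            near_keys = (
                near["Chromosome"].astype(str) + ":" + near["Start"].astype(str)
                + "-" + near["End"].astype(str)
            )
            rawd = near["Distance"].to_numpy(float)
            overlap.loc[near_keys] = rawd == 0
            # pyranges reports gap+1 for non-overlapping pairs
            gap.loc[near_keys] = np.maximum(rawd - 1, 0)
    out["cpg"] = np.select(
        [overlap.to_numpy(), gap.to_numpy() <= shore_bp, gap.to_numpy() <= shelf_bp],
        ["island", "shore", "shelf"],
        default="open_sea",
    )
    return out
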