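import numpy as np
import pandas as pd
import pytest

from cfmulti.datatypes import MethylWindowMatrix, RegionSet, ValidationError
from cfmulti.methylation import (
    DMRTable,
    annotate_regions,
    beta_transform,
    call_dmrs,
    derive_markers,
    methylation_score,
    nrpkm,
    select_markers,
)
from cfmulti.simulate import GeneratorConfig, gen_methyl_matrix, gen_tissue_experiment, make_methyl_windows


def make_matrix(signal: np.ndarray, cpg=None, width=300) -> MethylWindowMatrix:
    n_samples, n_win = signal.shape
    windows = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_win,
            "start": np.arange(n_win) * width,
            "end": (np.arange(n_win) + 1) * width,
            "cpg_count": cpg if cpg is not None else np.full(n_win, 8),
        }
    )
    sig = pd.DataFrame(signal, index=[f"s{i}" for i in range(n_samples)])
    return MethylWindowMatrix(windows=windows, signal=sig)


class TestNrpkm:
    def test_arithmetic(self):
        # oracle: 30 / (0.3 kb * 10 M reads)
        assert nrpkm(np.array([30.0]), 300, 10_000_000)[0] == pytest.approx(10.0)

    def test_zero_counts(self):
        assert nrpkm(np.array([0.0]), 300, 1_000_000)[0] == 0.0

    def test_doubling_library_size_halves_signal(self):
        a = nrpkm(np.array([50.0]), 300, 1_000_000)[0]
        b = nrpkm(np.array([50.0]), 300, 2_000_000)[0]
        assert b == pytest.approx(a / 2)


class TestBetaTransform:
    def test_median_signal_maps_to_half(self):
        sig = np.array([[1.0, 2.0, 3.0]])  # median adjusted signal = 2
        m = beta_transform(make_matrix(sig))
        assert m.beta.iloc[0, 1] == pytest.approx(0.5)

    def test_zero_signal_maps_to_zero(self):
        m = beta_transform(make_matrix(np.array([[0.0, 1.0, 2.0]])))
        assert m.beta.iloc[0, 0] == 0.0

    def test_three_times_median_maps_to_three_quarters(self):
        # oracle: 3m / (3m + m) = 0.75
        sig = np.array([[3.0, 1.0, 0.5, 1.5]])  # median 1.25 -> use explicit
        sig = np.array([[3.0, 1.0, 1.0, 1.0]])  # median 1
        m = beta_transform(make_matrix(sig))
        assert m.beta.iloc[0, 0] == pytest.approx(0.75)

    def test_monotone_in_signal_per_sample(self):
        rng = np.random.default_rng(0)
        sig = rng.gamma(2, 1, size=(1, 100))
        m = beta_transform(make_matrix(sig))
        order = np.argsort(sig[0])
        assert np.all(np.diff(m.beta.iloc[0].to_numpy()[order]) >= -1e-12)

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValidationError, match="all-zero"):
            beta_transform(make_matrix(np.zeros((1, 5))))

    def test_cpg_free_windows_masked(self):
        cpg = np.array([8, 0, 8])
        m = beta_transform(make_matrix(np.array([[1.0, 1.0, 2.0]]), cpg=cpg))
        assert np.isnan(m.beta.iloc[0, 1])


class TestCallDmrs:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(0)
        sig = np.tile(rng.gamma(2, 1, size=(1, 50)), (8, 1))  # groups identical
        m = make_matrix(sig)
        res = call_dmrs(m, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert (res.table["p"] >= 0.99).all()
        assert res.table["logFC"].abs().max() < 1e-12

    def test_ranksum_p_matches_permutation_enumeration(self):
        # oracle: exact two-sided rank-sum p by enumerating all 4-subsets
        import itertools

        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 4)
        b = rng.normal(1.5, 1, 4)
        sig = np.abs(np.vstack([a, b]).reshape(8, 1)) + 0.5
        m = make_matrix(np.hstack([sig, np.ones((8, 1))]))
        res = call_dmrs(m, ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"])

        values = m.beta.to_numpy()[:, 0] if m.beta is not None else None
        m2 = beta_transform(m)
        values = m2.beta.to_numpy()[:, 0]
        obs_u = sum(1 for x in values[:4] for y in values[4:] if x > y) + 0.5 * sum(
            1 for x in values[:4] for y in values[4:] if x == y
        )
        us = []
        for comb in itertools.combinations(range(8), 4):
            grp = values[list(comb)]
            rest = values[[i for i in range(8) if i not in comb]]
            us.append(sum(1 for x in grp for y in rest if x > y))
        us = np.array(us)
        p_exact = np.mean(np.abs(us - 8.0) >= abs(obs_u - 8.0) - 1e-12)
        assert res.table["p"].iloc[0] == pytest.approx(p_exact, abs=1e-9)

    def test_planted_shift_recovered_at_bh_threshold(self):
        cfg = GeneratorConfig(n_windows=2000, n_marker_windows=50, beta_noise_sd=0.05,
                              beta_tumor=0.8)
        rng = np.random.default_rng(2)
        windows = make_methyl_windows(cfg, rng)
        planted = np.sort(rng.choice(2000, 50, replace=False))
        base = np.full(2000, 0.1)
        ids_a = [f"t{i}" for i in range(8)]
        ids_b = [f"n{i}" for i in range(8)]
        tfx = {**{s: 1.0 for s in ids_a}, **{s: 0.0 for s in ids_b}}
        m = gen_methyl_matrix(windows, planted, tfx, cfg, rng, base_beta=base)
        res = call_dmrs(m, ids_a, ids_b, test="ranksum")
        hits = np.flatnonzero((res.table["p_adj"] < 0.05) & (res.table["logFC"] > 0))
        assert len(np.intersect1d(hits, planted)) >= 45
        false = np.setdiff1d(hits, planted)
        assert len(false) <= 5

    def test_paired_mode_requires_matched_lists(self):
        m = make_matrix(np.random.default_rng(0).gamma(2, 1, (6, 10)))
        with pytest.raises(ValidationError):
            call_dmrs(m, ["s0", "s1", "s2"], ["s3", "s4"], paired=True)


class TestSelectMarkers:
    def _dmr_table(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["logFC"] = 3.0
        df["p"] = 1e-6
        df["p_adj"] = 1e-5
        df["direction"] = "hyper"
        return DMRTable(comparison="toy", table=df)

    def test_overlap_selects_both_windows(self):
        # oracle: interval sweep; [0,300) and [600,900) both intersect [250,750)
        dmrs = self._dmr_table([("chr1", 0, 300), ("chr1", 600, 900)])
        ext = RegionSet(name="e", regions=pd.DataFrame(
            {"chrom": ["chr1"], "start": [250], "end": [750]}))
        ms = select_markers(dmrs, ext)
        assert len(ms.regions) == 2

    def test_disjoint_sets_give_empty_markers(self):
        dmrs = self._dmr_table([("chr1", 0, 300)])
        ext = RegionSet(name="e", regions=pd.DataFrame(
            {"chrom": ["chr2"], "start": [0], "end": [500]}))
        assert len(select_markers(dmrs, ext).regions) == 0

    def test_half_open_abutment_not_selected(self):
        dmrs = self._dmr_table([("chr1", 0, 300)])
        ext = RegionSet(name="e", regions=pd.DataFrame(
            {"chrom": ["chr1"], "start": [300], "end": [600]}))
        assert len(select_markers(dmrs, ext).regions) == 0

    def test_self_overlap_identity(self):
        rows = [("chr1", i * 300, (i + 1) * 300) for i in range(5)]
        dmrs = self._dmr_table(rows)
        ext = RegionSet(name="self", regions=pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        ms = select_markers(dmrs, ext)
        assert len(ms.regions) == 5

    def test_filters_applied_before_overlap(self):
        df = pd.DataFrame([("chr1", 0, 300), ("chr1", 300, 600)],
                          columns=["chrom", "start", "end"])
        df["logFC"] = [3.0, 1.0]  # second fails the fold-change filter
        df["p"] = 1e-6
        df["p_adj"] = 1e-5
        df["direction"] = "hyper"
        dmrs = DMRTable(comparison="toy", table=df)
        ext = RegionSet(name="e", regions=pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [600]}))
        ms = select_markers(dmrs, ext)
        assert len(ms.regions) == 1


class TestMarkerPipeline:
    def test_tissue_experiment_recovers_planted_markers(self):
        cfg = GeneratorConfig(n_windows=3000)
        exp = gen_tissue_experiment(cfg, seed=3)
        ms = derive_markers(exp.matrix, exp.tissue_ids, exp.buffy_ids, exp.external_top)
        planted = exp.matrix.windows.iloc[exp.planted_idx]
        planted_keys = set(
            planted["chrom"].astype(str) + ":" + planted["start"].astype(str)
            + "-" + planted["end"].astype(str)
        )
        got = set(ms.regions.keys())
        assert len(got & planted_keys) >= 60
        assert len(got - planted_keys) <= 5


class TestMethylationScore:
    def test_constant_marker_beta(self):
        sig = np.ones((1, 5))
        m = make_matrix(sig)
        beta = pd.DataFrame(np.full((1, 5), 0.2), index=m.signal.index)
        m = MethylWindowMatrix(windows=m.windows, signal=m.signal, beta=beta)
        markers = RegionSet(name="mk", regions=m.windows[["chrom", "start", "end"]])
        assert methylation_score(m, markers).iloc[0] == pytest.approx(0.2)

    def test_median_oracle(self):
        m = make_matrix(np.ones((1, 3)))
        beta = pd.DataFrame(np.array([[0.1, 0.2, 0.9]]), index=m.signal.index)
        m = MethylWindowMatrix(windows=m.windows, signal=m.signal, beta=beta)
        markers = RegionSet(name="mk", regions=m.windows[["chrom", "start", "end"]])
        assert methylation_score(m, markers).iloc[0] == pytest.approx(0.2)

    def test_no_matching_markers_is_error(self):
        m = beta_transform(make_matrix(np.random.default_rng(0).gamma(2, 1, (1, 5))))
        markers = RegionSet(name="mk", regions=pd.DataFrame(
            {"chrom": ["chr9"], "start": [0], "end": [300]}))
        with pytest.raises(ValidationError):
            methylation_score(m, markers)


class TestAnnotateRegions:
    def _world(self):
        genes = RegionSet(name="genes", regions=pd.DataFrame(
            [
                ("chr1", 1000, 2000, "promoter"),
                ("chr1", 1500, 4000, "exon"),
                ("chr1", 4000, 9000, "intron"),
            ],
            columns=["chrom", "start", "end", "label"],
        ))
        islands = RegionSet(name="cpg", regions=pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [1500]}))
        return genes, islands

    def test_exon_label(self):
        genes, islands = self._world()
        regions = RegionSet(name="r", regions=pd.DataFrame(
            {"chrom": ["chr1"], "start": [2500], "end": [2800]}))
        out = annotate_regions(regions, genes, islands)
        assert out["genomic"].iloc[0] == "exon"

    def test_promoter_wins_priority_conflict(self):
        # oracle: priority list promoter > exon
        genes, islands = self._world()
        regions = RegionSet(name="r", regions=pd.DataFrame(
            {"chrom": ["chr1"], "start": [1600], "end": [1900]}))
        out = annotate_regions(regions, genes, islands)
        assert out["genomic"].iloc[0] == "promoter"

    def test_intergenic_fallback(self):
        genes, islands = self._world()
        regions = RegionSet(name="r", regions=pd.DataFrame(
            {"chrom": ["chr1"], "start": [50000], "end": [50300]}))
        out = annotate_regions(regions, genes, islands)
        assert out["genomic"].iloc[0] == "distal_intergenic"

    def test_cpg_landscape_distance_rules(self):
        genes, islands = self._world()
        regions = RegionSet(name="r", regions=pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [1200, 2500, 4500, 30000],  # overlap, 1 kb, 3 kb, far
                "end": [1400, 2800, 4800, 30300],
            }
        ))
        out = annotate_regions(regions, genes, islands)
        assert list(out["cpg"]) == ["island", "shore", "shelf", "open_sea"]
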