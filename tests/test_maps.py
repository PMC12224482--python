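"""Stability maps: batch fits, summaries, dispersion, rank order, lobes."""

import numpy as np
import pandas as pd
import pytest

from icedpy import (
    ConfigurationError,
    InsufficientDataError,
    SimulationConfig,
    aggregate_lobes,
    apply_rescaling,
    build_estimate_matrix,
    dispersion_decomposition,
    fit_iced,
    fit_region_map,
    generate_dataset,
    load_lobe_mapping,
    rank_order_stability,
    split_holdout,
    summarize_map,
    summarize_two_timepoint,
)

from .oracles import anova_icc


class TestFitRegionMap:
    def test_cardinality_site_grouping(self):
        config = SimulationConfig(
            n_sites=5, n_per_site=50,
            regions=tuple(f"r{i}" for i in range(8)),
            measures=("thickness",), seed=2,
        )
        table = fit_region_map(generate_dataset(config), grouping="site", ci=False)
        assert len(table) == 40
        assert set(table["status"]) == {"ok"}

    def test_known_icc_recovered_pooled(self):
        config = SimulationConfig(
            n_sites=1, n_per_site=7000, regions=("hot",),
            measures=("thickness",), sigma_b2=9.0, sigma_e2=1.0, seed=5,
        )
        table = fit_region_map(generate_dataset(config), grouping="pooled")
        assert table.loc[0, "icc"] == pytest.approx(0.9, abs=0.03)
        assert table.loc[0, "ci_low"] < 0.9 < table.loc[0, "ci_high"]

    def test_constant_region_degenerate_status(self, tiny_dataset):
        df = tiny_dataset.copy()
        mask = df["region"] == "regB"
        df.loc[mask, ["value_t1", "value_t2"]] = 3.14
        table = fit_region_map(df, grouping="pooled", ci=False)
        by_region = table.set_index("region")
        assert by_region.loc["regB", "status"] == "degenerate"
        assert by_region.loc["regA", "status"] == "ok"

    def test_unknown_measure_rejected(self, tiny_dataset):
        with pytest.raises(ConfigurationError):
            fit_region_map(tiny_dataset, measure="nonexistent")

    def test_region_order_invariance(self, tiny_dataset):
        shuffled = tiny_dataset.sample(frac=1.0, random_state=1)
        a = fit_region_map(tiny_dataset, grouping="site", ci=False)
        b = fit_region_map(shuffled, grouping="site", ci=False)
        key = ["measure", "region", "group"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        pd.testing.assert_series_equal(a["icc"], b["icc"], atol=1e-9)


class TestSummarizeMap:
    def test_mean_and_range(self):
        table = pd.DataFrame({
            "measure": ["m"] * 3, "region": list("abc"), "group": ["pooled"] * 3,
            "icc": [0.5, 0.7, 0.9], "icc2": [0.6, 0.8, 0.95],
            "status": ["ok"] * 3,
        })
        out = summarize_map(table).iloc[0]
        assert out["icc_mean"] == pytest.approx(0.7)
        assert (out["icc_min"], out["icc_max"]) == (0.5, 0.9)

    def test_single_row(self):
        table = pd.DataFrame({
            "measure": ["m"], "region": ["a"], "group": ["pooled"],
            "icc": [0.42], "icc2": [0.5], "status": ["ok"],
        })
        out = summarize_map(table).iloc[0]
        assert out["icc_mean"] == out["icc_min"] == out["icc_max"] == 0.42

    def test_all_failed_measure_warns(self):
        table = pd.DataFrame({
            "measure": ["m"], "region": ["a"], "group": ["pooled"],
            "icc": [np.nan], "icc2": [np.nan], "status": ["degenerate"],
        })
        with pytest.warns(UserWarning, match="no successful fits"):
            out = summarize_map(table)
        assert out.empty


class TestDispersion:
    def _table(self, sigma_b2_by_region, sigma_e2_by_site, seed=0, n=500):
        regions = tuple(sigma_b2_by_region)
        sites = len(sigma_e2_by_site)
        config = SimulationConfig(
            n_sites=sites, n_per_site=n, regions=regions,
            measures=("thickness",),
            sigma_b2=sigma_b2_by_region,
            sigma_e2={f"site{i:02d}": v for i, v in
                      enumerate(sigma_e2_by_site, start=1)},
            seed=seed,
        )
        return fit_region_map(generate_dataset(config), grouping="site", ci=False)

    def test_region_axis_dominated_by_between_heterogeneity(self):
        table = self._table(
            {"a": 0.5, "b": 1.0, "c": 1.5, "d": 2.0},
            [0.3, 0.3, 0.3, 0.3], seed=3,
        )
        rep = dispersion_decomposition(table)
        assert rep.by_region.ratio_between_over_error > 5

    def test_site_axis_dominated_by_error_heterogeneity(self):
        table = self._table(
            {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0},
            [0.15, 0.25, 0.4, 0.6], seed=4,
        )
        rep = dispersion_decomposition(table)
        assert rep.by_site.ratio_error_over_between > 5

    def test_heterogeneity_inflates_ratio_relative_to_null(self):
        null = self._table({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0},
                           [0.3] * 4, seed=5)
        hot = self._table({"a": 0.5, "b": 1.0, "c": 1.5, "d": 2.0},
                          [0.3] * 4, seed=5)
        r_null = dispersion_decomposition(null).by_region.ratio_between_over_error
        r_hot = dispersion_decomposition(hot).by_region.ratio_between_over_error
        assert r_hot > 10 * r_null

    def test_identical_rows_give_missing_ratio(self):
        table = pd.DataFrame({
            "measure": ["m"] * 4,
            "region": ["a", "a", "b", "b"],
            "group": ["s1", "s2", "s1", "s2"],
            "sigma_b2": [1.0] * 4, "sigma_e2": [0.5] * 4,
            "status": ["ok"] * 4,
        })
        rep = dispersion_decomposition(table)
        assert np.isnan(rep.by_region.ratio_between_over_error)

    def test_single_axis_rejected(self, tiny_dataset):
        table = fit_region_map(tiny_dataset, grouping="pooled", ci=False)
        with pytest.raises(InsufficientDataError):
            dispersion_decomposition(table)


class TestRankOrderStability:
    def test_identical_columns_perfect_agreement(self):
        m = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
        icc21, icc31 = rank_order_stability(m)
        assert icc21 == pytest.approx(1.0)
        assert icc31 == pytest.approx(1.0)

    def test_constant_shift_breaks_absolute_but_not_consistency(self):
        base = np.array([1.0, 2.0, 3.0, 6.0])
        m = np.column_stack([base, base + 2.0])
        icc21, icc31 = rank_order_stability(m)
        assert icc31 == pytest.approx(1.0)
        assert icc21 < 1.0

    def test_matches_brute_force_anova_oracle(self, rng):
        for _ in range(5):
            m = rng.normal(size=(6, 4))
            got = rank_order_stability(m)
            want = anova_icc(m)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(size=(8, 3))
        long = pd.DataFrame({
            "target": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "score": m.ravel(),
        })
        res = pingouin.intraclass_corr(
            long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        icc21, icc31 = rank_order_stability(m)
        # pingouin labels: ICC(A,1) = absolute agreement, ICC(C,1) = consistency
        assert icc21 == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-6)
        assert icc31 == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-6)

    def test_transpose_changes_consistency_in_general(self, rng):
        m = rng.normal(size=(6, 4)) + np.arange(4)  # rater offsets
        _, icc31 = rank_order_stability(m)
        _, icc31_t = rank_order_stability(m.T)
        assert abs(icc31 - icc31_t) > 1e-6

    def test_zero_between_target_variance_missing(self):
        m = np.ones((4, 3))
        icc21, icc31 = rank_order_stability(m)
        assert np.isnan(icc21) and np.isnan(icc31)

    def test_estimate_matrix_orientation(self, multisite_dataset):
        table = fit_region_map(multisite_dataset, measure="thickness",
                               grouping="site", ci=False)
        by_region = build_estimate_matrix(table, "icc", targets="region")
        assert by_region.shape == (4, 5)  # regions x sites
        by_site = build_estimate_matrix(table, "icc", targets="group")
        assert by_site.shape == (5, 4)


class TestLobes:
    def _lobe_dataset(self, regions, seed=0, n=300, **kw):
        config = SimulationConfig(
            n_sites=1, n_per_site=n, regions=tuple(regions),
            measures=("thickness", "volume"), seed=seed, **kw,
        )
        return generate_dataset(config)

    def test_thickness_mean_and_volume_sum(self):
        df = pd.DataFrame({
            "participant_id": ["p1"] * 4,
            "site": ["s"] * 4, "scanner": ["X"] * 4,
            "measure": ["thickness", "thickness", "volume", "volume"],
            "region": ["a", "b", "a", "b"],
            "value_t1": [2.0, 3.0, 10.0, 20.0],
            "value_t2": [2.0, 3.0, 10.0, 20.0],
        })
        out = aggregate_lobes(df, {"a": "lobe1", "b": "lobe1"})
        thick = out[out["measure"] == "thickness"]["value_t1"].iloc[0]
        vol = out[out["measure"] == "volume"]["value_t1"].iloc[0]
        assert thick == 2.5
        assert vol == 30.0

    def test_total_volume_preserved_exactly(self):
        df = self._lobe_dataset(["a", "b", "c"], seed=8)
        mapping = {"a": "l1", "b": "l1", "c": "l2"}
        out = aggregate_lobes(df, mapping)
        vol_in = df[df["measure"] == "volume"]["value_t1"].sum()
        vol_out = out[out["measure"] == "volume"]["value_t1"].sum()
        assert vol_out == pytest.approx(vol_in, rel=1e-12)

    def test_unmapped_region_rejected(self):
        df = self._lobe_dataset(["a", "b"])
        with pytest.raises(ConfigurationError, match="b"):
            aggregate_lobes(df, {"a": "l1"})

    def test_bundled_mapping_covers_both_hemispheres(self):
        mapping = load_lobe_mapping()
        assert len(mapping) == 68
        lobes = set(mapping.values())
        assert len(lobes) == 10  # 5 per hemisphere
        assert all(l.startswith(("lh_", "rh_")) for l in lobes)

    def test_aggregation_improves_icc_over_worst_member(self):
        wins = 0
        for seed in range(10):
            df = self._lobe_dataset(
                ["weak", "strong"], seed=seed, n=400,
                sigma_b2={"weak": 1.0, "strong": 4.0},
                sigma_e2=1.0,
            )
            thick = df[df["measure"] == "thickness"]
            member_iccs = []
            for region in ("weak", "strong"):
                s = summarize_two_timepoint(thick[thick["region"] == region])
                member_iccs.append(fit_iced(s, ci=False).icc)
            lobe = aggregate_lobes(thick, {"weak": "l", "strong": "l"})
            s = summarize_two_timepoint(lobe)
            lobe_icc = fit_iced(s, ci=False).icc
            wins += lobe_icc >= min(member_iccs)
        assert wins >= 9


class TestPreprocessing:
    def test_rescaling_changes_components_not_icc(self, multisite_dataset):
        scaled = apply_rescaling(multisite_dataset, measures=("volume",),
                                 constant=0.001)
        raw_vol = multisite_dataset[multisite_dataset["measure"] == "volume"]
        new_vol = scaled[scaled["measure"] == "volume"]
        f_raw = fit_iced(summarize_two_timepoint(
            raw_vol[raw_vol["region"] == "r1"]), ci=False)
        f_new = fit_iced(summarize_two_timepoint(
            new_vol[new_vol["region"] == "r1"]), ci=False)
        assert f_new.components.sigma_b2 == pytest.approx(
            1e-6 * f_raw.components.sigma_b2, rel=1e-6
        )
        assert f_new.icc == pytest.approx(f_raw.icc, abs=1e-9)
        # thickness untouched
        pd.testing.assert_frame_equal(
            scaled[scaled["measure"] == "thickness"],
            multisite_dataset[multisite_dataset["measure"] == "thickness"],
        )

    def test_holdout_split_partitions_participants(self, multisite_dataset):
        analysis, held = split_holdout(multisite_dataset, 100, seed=3)
        a = set(analysis["participant_id"])
        h = set(held["participant_id"])
        assert len(h) == 100
        assert not a & h
        assert len(analysis) + len(held) == len(multisite_dataset)
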