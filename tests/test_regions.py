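"""Region splitting, binning, binwise tests and group summaries."""

import numpy as np
import pandas as pd
import pytest

import tubulometry as tm
from tubulometry.stats import anova_dunnett, benjamini_hochberg, five_number_summary, welch_ttest


def _profile(s, area):
    return pd.DataFrame({"s_um": np.asarray(s, dtype=float),
                         "area_um2": np.asarray(area, dtype=float)})


class TestSplitRegions:
    def test_split_at_175_partitions_the_printed_window(self):
        s = np.linspace(-100, 300, 401)
        labels = tm.split_regions(s, 175.0)
        assert (labels[s < 175] == "PCT").all() and (labels[s >= 175] == "PST").all()

    def test_split_at_max_puts_everything_in_pct(self):
        s = np.linspace(-100, 300, 11)
        labels = tm.split_regions(s, 300.0)
        assert (labels[:-1] == "PCT").all()

    def test_partition_is_exhaustive(self):
        s = np.linspace(-50, 50, 21)
        labels = tm.split_regions(s, 0.0)
        assert set(labels) == {"PCT", "PST"}

    def test_split_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tm.split_regions(np.linspace(0, 10, 5), 50.0)


class TestBinProfiles:
    def test_constant_profile_fills_every_covered_bin(self):
        binned = tm.bin_profiles({"a": _profile(np.linspace(-100, 300, 401), 7.0)})
        np.testing.assert_allclose(binned.means.loc["a"].dropna(), 7.0)

    def test_group_mean_of_two_specimens(self):
        s = np.linspace(0, 100, 101)
        binned = tm.bin_profiles({"a": _profile(s, np.full(101, 10.0)),
                                  "b": _profile(s, np.full(101, 30.0))})
        np.testing.assert_allclose(binned.means.mean(axis=0).dropna(), 20.0)

    def test_sixteen_bins_for_the_default_span(self):
        binned = tm.bin_profiles({"a": _profile(np.linspace(-100, 300, 801), 1.0)},
                                 bin_width_um=25.0)
        assert len(binned.bin_centers) == 16

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            tm.bin_profiles({"a": _profile([0, 1], [1, 1])}, bin_width_um=0)

    def test_binning_conserves_mass(self):
        """Count-weighted mean of bin means equals the overall profile mean."""
        rng = np.random.default_rng(3)
        s = np.sort(rng.uniform(-90, 290, 500))
        v = rng.lognormal(3, 0.5, 500)
        binned = tm.bin_profiles({"a": _profile(s, v)})
        m = binned.means.loc["a"].to_numpy(dtype=float)
        c = binned.counts.loc["a"].to_numpy(dtype=float)
        ok = c > 0
        assert np.sum(m[ok] * c[ok]) / c.sum() == pytest.approx(v.mean(), rel=1e-9)


class TestCompareBins:
    def _binned(self, control_vals, treated_vals, jitter=0.1, seed=0):
        rng = np.random.default_rng(seed)
        s = np.linspace(0, 100, 101)
        profiles, groups = {}, {}
        for i, v in enumerate(control_vals):
            profiles[f"c{i}"] = _profile(s, v + rng.normal(0, jitter, s.size))
            groups[f"c{i}"] = "control"
        for i, v in enumerate(treated_vals):
            profiles[f"t{i}"] = _profile(s, v + rng.normal(0, jitter, s.size))
            groups[f"t{i}"] = "treated"
        return tm.bin_profiles(profiles), groups

    def test_identical_groups_not_significant(self):
        binned, groups = self._binned([10, 10, 10, 10], [10, 10, 10, 10], jitter=0.0)
        comp = tm.compare_bins(binned, groups, split_s_um=50.0)
        assert (comp.table.loc[comp.table.testable, "p_value"] == 1.0).all()
        assert not any(comp.region_verdicts.values())

    def test_strong_shift_detected_and_matches_closed_form(self):
        """Welch p from the pipeline equals the textbook closed form per bin."""
        binned, groups = self._binned([10, 10, 10, 10], [30, 30, 30, 30], jitter=0.1, seed=1)
        comp = tm.compare_bins(binned, groups, split_s_um=50.0)
        assert (comp.table.loc[comp.table.testable, "p_value"] < 0.05).all()
        from scipy import stats as sps
        center = binned.means.columns[1]
        c = binned.means.loc[[f"c{i}" for i in range(4)], center].to_numpy()
        t = binned.means.loc[[f"t{i}" for i in range(4)], center].to_numpy()
        se2 = c.var(ddof=1) / 4 + t.var(ddof=1) / 4
        tstat = (c.mean() - t.mean()) / np.sqrt(se2)
        dof = se2**2 / ((c.var(ddof=1) / 4) ** 2 / 3 + (t.var(ddof=1) / 4) ** 2 / 3)
        p_closed = 2 * sps.t.sf(abs(tstat), dof)
        row = comp.table[comp.table.bin_center_um == center].iloc[0]
        assert row.p_value == pytest.approx(p_closed, rel=1e-9)

    def test_group_relabeling_leaves_p_unchanged(self):
        binned, groups = self._binned([10, 11, 9, 10], [14, 15, 13, 14], seed=2)
        swapped = {k: ("treated" if g == "control" else "control") for k, g in groups.items()}
        p1 = tm.compare_bins(binned, groups, split_s_um=50.0).table.p_value
        p2 = tm.compare_bins(binned, swapped, split_s_um=50.0).table.p_value
        np.testing.assert_allclose(p1, p2)

    def test_underpowered_bins_marked_untestable(self):
        binned, groups = self._binned([10], [30, 30], jitter=0.1)
        comp = tm.compare_bins(binned, groups, split_s_um=50.0)
        assert not comp.table.testable.any()

    def test_bh_correction_never_decreases_p(self):
        binned, groups = self._binned([10, 10, 10], [11, 11, 11], seed=3)
        raw = tm.compare_bins(binned, groups, split_s_um=50.0).table.p_value
        adj = tm.compare_bins(binned, groups, split_s_um=50.0, correction="bh").table.p_value
        assert (adj.to_numpy() >= raw.to_numpy() - 1e-12).all()


class TestSummarizeGroups:
    def _summaries(self, control, treated, metric="mean_diameter_um"):
        rows = []
        for i, v in enumerate(control):
            rows.append({"specimen_id": f"c{i}", "group": "control", metric: v})
        for i, v in enumerate(treated):
            rows.append({"specimen_id": f"t{i}", "group": "treated", metric: v})
        return pd.DataFrame(rows)

    def test_printed_fold_arithmetic(self):
        df = self._summaries([1, 1, 1, 1], [1.75] * 8)
        gs = tm.summarize_groups(df, metrics=("mean_diameter_um",))
        assert gs.fold_treated["mean_diameter_um"] == pytest.approx(1.75)

    def test_treated_equal_control_gives_unit_folds(self):
        df = self._summaries([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        gs = tm.summarize_groups(df, metrics=("mean_diameter_um",))
        assert gs.fold_treated["mean_diameter_um"] == pytest.approx(1.0)
        assert gs.p_values["mean_diameter_um"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        df = self._summaries([1.0, 2.0], [])
        with pytest.raises(ValueError):
            tm.summarize_groups(df, metrics=("mean_diameter_um",))

    def test_five_number_summary_of_small_sample(self):
        fn = five_number_summary([1, 2, 3, 4, 5])
        assert (fn["min"], fn["q1"], fn["median"], fn["q3"], fn["max"]) == (1, 2, 3, 4, 5)


class TestStats:
    def test_welch_flat_samples(self):
        assert welch_ttest([1, 1, 1], [1, 1]) == 1.0
        assert welch_ttest([1, 1, 1], [2, 2]) == 0.0

    def test_anova_dunnett_flags_the_shifted_dose(self):
        rng = np.random.default_rng(0)
        control = rng.normal(10, 1, 10)
        res = anova_dunnett(control, {
            "low": rng.normal(10, 1, 10),
            "high": rng.normal(16, 1, 10),
        })
        assert res.anova_p < 0.001
        assert res.dunnett_p["high"] < 0.001 < res.dunnett_p["low"]

    def test_bh_is_monotone_transform(self):
        p = np.array([0.001, 0.02, 0.04, 0.2, 0.9])
        adj = benjamini_hochberg(p)
        assert (np.diff(adj) >= -1e-12).all() and (adj >= p - 1e-12).all()
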