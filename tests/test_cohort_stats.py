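"""Descriptive statistics, mixed ANOVA and pairwise contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from urethrakin import cohort_stats as cs
from urethrakin import reference_cohort as ref
from urethrakin.errors import ArgumentError, MissingDataError


def _long_table(data, groups, levels=("cough", "valsalva", "pmc"),
                roi="proximal", metric="dmag_mm"):
    """data: (n_subjects, n_levels) array; groups: per-subject labels."""
    rows = []
    for i, (row, g) in enumerate(zip(np.asarray(data, float), groups)):
        for level, value in zip(levels, row):
            rows.append({"subject": f"s{i:02d}", "group": g, "maneuver": level,
                         "roi": roi, "metric": metric, "value": value})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_hand_computed_example(self):
        s = cs.summarize([2, 4, 6])
        assert s.mean == 4.0
        assert s.sd == pytest.approx(2.0)
        assert s.sem == pytest.approx(1.1547, abs=1e-4)
        assert s.range == 4.0
        assert s.cv_percent == pytest.approx(50.0)

    def test_constant_sample(self):
        s = cs.summarize([3.25, 3.25, 3.25])
        assert s.sd == 0.0 and s.cv_percent == 0.0 and s.range == 0.0

    @given(st.lists(st.floats(0.5, 100), min_size=2, max_size=30),
           st.floats(0.1, 7.0))
    @hsettings(max_examples=50, deadline=None)
    def test_cv_scale_invariant_and_matches_brute_force(self, values, k):
        s = cs.summarize(values)
        scaled = cs.summarize([k * v for v in values])
        assert scaled.cv_percent == pytest.approx(s.cv_percent, rel=1e-9)
        n = len(values)
        mean = sum(values) / n
        sd = (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.sd == pytest.approx(sd, rel=1e-12)
        assert s.sem == pytest.approx(sd / n ** 0.5, rel=1e-12)

    def test_small_or_nonfinite_samples_rejected(self):
        with pytest.raises(ArgumentError):
            cs.summarize([1.0])
        with pytest.raises(ArgumentError):
            cs.summarize([1.0, np.nan])


class TestCoefficientOfVariation:
    @pytest.mark.parametrize("mean, sd, expected", [
        (4.88, 1.64, 34),     # proximal control cough
        (10.64, 3.69, 35),    # proximal SUI valsalva
        (-79.55, 18.39, 23),  # negative-mean direction metric
        (7.0, 0.0, 0),
    ])
    def test_reference_rows(self, mean, sd, expected):
        assert cs.coefficient_of_variation(mean, sd) == expected

    def test_zero_mean_undefined(self):
        with pytest.raises(ArgumentError):
            cs.coefficient_of_variation(0.0, 1.0)

    def test_printed_reference_cvs_within_rounding(self):
        """Every printed CV is within 1 unit of round(100*SD/|mean|)."""
        for table in (ref.MAGNITUDE_MM, ref.DIRECTION_DEG):
            for (_m, _r, _g), (mean, sd, _rng, cv) in table.items():
                assert abs(cs.coefficient_of_variation(mean, sd) - cv) <= 1


def _brute_force_mixed_anova(data, groups):
    """Split-plot sums of squares by explicit loops (oracle)."""
    data = np.asarray(data, float)
    groups = np.asarray(groups)
    names = list(dict.fromkeys(groups))
    N, b = data.shape
    a = len(names)
    grand = data.mean()
    ss_total = sum((data[i, j] - grand) ** 2 for i in range(N) for j in range(b))
    subj_mean = data.mean(axis=1)
    ss_bs = sum(b * (subj_mean[i] - grand) ** 2 for i in range(N))
    ss_group = 0.0
    for g in names:
        sel = groups == g
        ss_group += b * sel.sum() * (subj_mean[sel].mean() - grand) ** 2
    lev_mean = data.mean(axis=0)
    ss_lev = sum(N * (lev_mean[j] - grand) ** 2 for j in range(b))
    ss_int = 0.0
    for g in names:
        sel = groups == g
        gm = subj_mean[sel].mean()
        for j in range(b):
            cell = data[sel, j].mean()
            ss_int += sel.sum() * (cell - gm - lev_mean[j] + grand) ** 2
    ss_eb = ss_bs - ss_group
    ss_ew = ss_total - ss_bs - ss_lev - ss_int
    F_group = (ss_group / (a - 1)) / (ss_eb / (N - a))
    F_lev = (ss_lev / (b - 1)) / (ss_ew / ((N - a) * (b - 1)))
    F_int = (ss_int / ((a - 1) * (b - 1))) / (ss_ew / ((N - a) * (b - 1)))
    return F_group, F_lev, F_int


class TestMixedAnova:
    def test_matches_brute_force_oracle_on_balanced_integers(self):
        data = np.array([[3, 5, 4], [2, 6, 5], [4, 4, 3],
                         [7, 9, 8], [6, 10, 9], [8, 8, 7]])
        groups = ["control"] * 3 + ["sui"] * 3
        out = cs.rm_anova_2x3(_long_table(data, groups), "proximal", "dmag_mm")
        F = dict(zip(out["effect"], out["F"]))
        Fg, Fl, Fi = _brute_force_mixed_anova(data, groups)
        assert F["group"] == pytest.approx(Fg, abs=1e-8)
        assert F["maneuver"] == pytest.approx(Fl, abs=1e-8)
        assert F["interaction"] == pytest.approx(Fi, abs=1e-8)

    @pytest.mark.parametrize("n_per_group", [(6, 6), (10, 11)])
    def test_matches_pingouin_mixed_anova(self, n_per_group):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        n = sum(n_per_group)
        data = rng.normal(5, 2, (n, 3)) + rng.normal(0, 1, (n, 1))
        groups = ["control"] * n_per_group[0] + ["sui"] * n_per_group[1]
        table = _long_table(data, groups)
        ours = cs.rm_anova_2x3(table, "proximal", "dmag_mm")
        F = dict(zip(ours["effect"], ours["F"]))
        theirs = pingouin.mixed_anova(
            table, dv="value", within="maneuver", subject="subject",
            between="group")
        theirs = dict(zip(theirs["Source"], theirs["F"]))
        assert F["group"] == pytest.approx(theirs["group"], rel=1e-6)
        assert F["maneuver"] == pytest.approx(theirs["maneuver"], rel=1e-6)
        assert F["interaction"] == pytest.approx(theirs["Interaction"], rel=1e-6)

    def test_degenerate_variance_structure(self):
        """Groups differ by a constant, no within-subject variation."""
        data = np.array([[2.0, 2.0, 2.0]] * 4 + [[5.0, 5.0, 5.0]] * 4)
        groups = ["control"] * 4 + ["sui"] * 4
        out = cs.rm_anova_2x3(_long_table(data, groups), "proximal", "dmag_mm")
        res = {r["effect"]: r for _i, r in out.iterrows()}
        assert res["group"]["p"] == pytest.approx(0.0)
        assert res["maneuver"]["F"] == 0.0
        assert res["interaction"]["F"] == 0.0

    def test_missing_cells_rejected(self):
        data = np.array([[3.0, 5, 4], [2, 6, 5], [7, 9, 8], [6, 10, 9]])
        table = _long_table(data, ["control"] * 2 + ["sui"] * 2)
        table = table[~((table.subject == "s01") & (table.maneuver == "pmc"))]
        with pytest.raises(MissingDataError, match="s01"):
            cs.rm_anova_2x3(table, "proximal", "dmag_mm")


class TestPairwiseCompare:
    def _table(self, control, sui, maneuver="valsalva"):
        rows = []
        for g, vals in (("control", control), ("sui", sui)):
            for i, v in enumerate(vals):
                rows.append({"subject": f"{g}{i}", "group": g,
                             "maneuver": maneuver, "roi": "proximal",
                             "metric": "dmag_mm", "value": v})
        return pd.DataFrame(rows)

    def test_identical_samples_give_t0_p1(self):
        table = self._table([1.0, 2, 3], [1.0, 2, 3])
        con = [cs.Contrast("independent", "proximal", "dmag_mm",
                           maneuver="valsalva")]
        out = cs.pairwise_compare(table, con)
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_bonferroni_definition_and_cap(self):
        assert min(1.0, 3 * 0.01) == pytest.approx(0.03)
        table = self._table([1.0, 2, 3, 4], [1.1, 2.1, 3.1, 4.1])
        fam = [cs.Contrast("independent", "proximal", "dmag_mm",
                           maneuver="valsalva")] * 3
        out = cs.pairwise_compare(table, fam)
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(1.0, 3 * out["p_raw"]))
        assert out["p_bonferroni"].max() <= 1.0

    def test_paired_contrast_uses_matched_subjects(self):
        rows = []
        for i, (c, v) in enumerate([(2, 4), (3, 5.2), (2.5, 4.4)]):
            for maneuver, val in (("cough", c), ("valsalva", v)):
                rows.append({"subject": f"s{i}", "group": "sui",
                             "maneuver": maneuver, "roi": "proximal",
                             "metric": "dmag_mm", "value": val})
        out = cs.pairwise_compare(pd.DataFrame(rows), [
            cs.Contrast("paired", "proximal", "dmag_mm", group="sui",
                        maneuver_pair=("cough", "valsalva"))])
        assert out.loc[0, "df"] == 2
        assert out.loc[0, "p_raw"] < 0.05

    def test_underpowered_arm_rejected(self):
        table = self._table([1.0], [1.0, 2.0])
        with pytest.raises(ArgumentError):
            cs.pairwise_compare(table, [cs.Contrast(
                "independent", "proximal", "dmag_mm", maneuver="valsalva")])

    def test_default_family_is_five_contrasts(self):
        fam = cs.default_contrast_family("proximal")
        assert len(fam) == 5
        assert sum(c.kind == "independent" for c in fam) == 3
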