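"""Two-group t-tests and covariate-adjusted partial correlations."""

import numpy as np
import pytest
from scipy import stats

import metcovnet as mc


class TestTwoGroupTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2, 3, 4, 5])
        t, df, p, mode = mc.two_group_test(a, a.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_student(self):
        # pooled sd = sqrt(2.5): t = -2 / sqrt(2.5 * 2/5) = -2.0 on df = 8
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([3.0, 4, 5, 6, 7])
        t, df, p, mode = mc.two_group_test(a, b, variance_rule="student")
        assert t == pytest.approx(-2.0)
        assert df == 8
        assert p == pytest.approx(2 * stats.t.sf(2.0, 8))
        assert mode == "student"

    def test_welch_df_matches_satterthwaite_formula(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 5, 40)
        t, df, p, mode = mc.two_group_test(a, b, variance_rule="welch")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df_oracle = (va / 12 + vb / 40) ** 2 / (
            (va / 12) ** 2 / 11 + (vb / 40) ** 2 / 39
        )
        assert df == pytest.approx(df_oracle, rel=1e-12)
        assert df < 12 + 40 - 2
        assert mode == "welch"

    def test_auto_selects_welch_under_variance_inequality(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 6, 30)
        *_, mode = mc.two_group_test(a, b)
        assert mode == "welch"

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.4, 1.3, 14)
        ta, dfa, pa, _ = mc.two_group_test(a, b)
        tb, dfb, pb, _ = mc.two_group_test(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_degenerate_inputs(self):
        t, df, p, _ = mc.two_group_test([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            mc.two_group_test([1.0], [1.0, 2.0])


class TestScreenRegions:
    def test_null_false_positive_rate(self):
        # 90-region null at alpha 0.05: flagged count expectation 4.5/screen
        rates = []
        for seed in range(60):
            cfg = mc.preset_scenario("null", n_regions=30, seed=seed)
            recs, table = mc.generate_cohort(cfg)
            ids = {
                g: [r.subject_id for r in recs if r.group == g]
                for g in ("disease", "control")
            }
            res = mc.screen_regions(table.subset(ids["disease"]), table.subset(ids["control"]))
            rates.append(np.mean([r.significant for r in res]))
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_planted_effects_flagged_with_direction(self):
        cfg = mc.preset_scenario("hypertension_like", seed=11)
        recs, table = mc.generate_cohort(cfg)
        model = mc.fit_correction(table, recs, ["hypertension", "control"], "pooled")
        out = mc.apply_correction(model, table, recs)
        ids = {
            g: [r.subject_id for r in recs if r.group == g]
            for g in ("hypertension", "control")
        }
        res = mc.screen_regions(out.subset(ids["hypertension"]), out.subset(ids["control"]))
        planted_down = [i for i in range(50) if i != 41]
        n_ok = sum(res[i].significant and res[i].direction == -1 for i in planted_down)
        assert n_ok >= 47  # near-complete recovery of the planted decreases
        assert res[41].direction == 1

    def test_alpha_zero_flags_nothing(self, small_cohort):
        recs, table = small_cohort
        ids = {g: [r.subject_id for r in recs if r.group == g] for g in ("disease", "control")}
        res = mc.screen_regions(
            table.subset(ids["disease"]), table.subset(ids["control"]), alpha=0.0
        )
        assert not any(r.significant for r in res)

    def test_atlas_mismatch_rejected(self, small_cohort):
        recs, table = small_cohort
        other = mc.SUVRTable(
            table.subject_ids, mc.synthetic_atlas(10, n_reference=1), table.values
        )
        other.atlas.regions[0] = mc.Region(999, "alien", (0, 0, 0))
        with pytest.raises(ValueError, match="atlas"):
            mc.screen_regions(table, other)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, t, df, p = mc.partial_correlation(x, y)
        r_sp, p_sp = stats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)
        assert df == 48

    def test_identical_variables_give_unit_correlation(self, rng):
        x = rng.normal(size=30)
        C = rng.normal(size=(30, 3))
        r, *_ = mc.partial_correlation(x, x.copy(), C)
        assert r == pytest.approx(1.0)

    def test_residual_and_precision_methods_agree(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=40), rng.normal(size=40)
            C = rng.normal(size=(40, 2))
            r, *_ = mc.partial_correlation(x, y, C)
            assert r == pytest.approx(mc.partial_correlation_precision(x, y, C), abs=1e-10)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(
            dict(x=rng.normal(size=60), y=rng.normal(size=60),
                 c1=rng.normal(size=60), c2=rng.normal(size=60))
        )
        out = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        r, t, dof, p = mc.partial_correlation(df.x, df.y, df[["c1", "c2"]].to_numpy())
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), rel=1e-6)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        C = rng.normal(size=(40, 2))
        r1, *_ = mc.partial_correlation(x, y, C)
        r2, *_ = mc.partial_correlation(3 * x - 1, 0.5 * y + 7, 2 * C + 5)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_planted_rho_half_recovered(self):
        cfg = mc.ScenarioConfig(
            group_sizes={"g": 500}, n_regions=5,
            biomarker_links=[mc.BiomarkerLink("bm", region=1, rho=0.5)], seed=4,
        )
        recs, table = mc.generate_cohort(cfg)
        y = np.array([r.biomarkers["bm"] for r in recs])
        C = np.column_stack([[r.age for r in recs], [r.sex for r in recs], [r.bmi for r in recs]])
        r, *_ = mc.partial_correlation(table.values[:, 1], y, C)
        assert 0.41 <= r <= 0.58

    def test_constant_variable_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            mc.partial_correlation(np.ones(20), rng.normal(size=20))

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError, match="k"):
            mc.partial_correlation(rng.normal(size=4), rng.normal(size=4), rng.normal(size=(4, 2)))


class TestScreenBiomarkers:
    @pytest.fixture
    def cohort_with_links(self):
        links = [mc.BiomarkerLink("uric_acid", region=4, rho=0.5, missing_rate=0.1)]
        links += [
            mc.BiomarkerLink(f"null_{i}", region=0, rho=0.0, missing_rate=0.1)
            for i in range(10)
        ]
        cfg = mc.ScenarioConfig(
            group_sizes={"g": 300}, n_regions=10, biomarker_links=links, seed=17
        )
        return mc.generate_cohort(cfg)

    def test_planted_link_recovered_among_nulls(self, cohort_with_links):
        recs, table = cohort_with_links
        ids = table.atlas.analysis_ids
        res = mc.screen_biomarkers(
            table, recs, ids, ["uric_acid"] + [f"null_{i}" for i in range(10)]
        )
        planted = [r for r in res if r.variable == "uric_acid" and r.region_id == ids[4]]
        assert planted[0].significant and planted[0].r_partial > 0.3
        nulls = [r for r in res if r.variable.startswith("null_")]
        fp = np.mean([r.significant for r in nulls])
        assert fp < 0.15

    def test_fully_missing_biomarker_skipped_with_warning(self, atlas5, rng, caplog):
        recs = [
            mc.SubjectRecord(f"s{i}", "g", 50.0 + i, i % 2, 24.0, {"gone": np.nan})
            for i in range(10)
        ]
        table = mc.SUVRTable(
            [r.subject_id for r in recs], atlas5, rng.uniform(1, 2, (10, 5))
        )
        with caplog.at_level("WARNING"):
            res = mc.screen_biomarkers(table, recs, [atlas5.analysis_ids[0]], ["gone"])
        assert res == []
        assert "skipping" in caplog.text

    def test_no_missingness_gives_constant_n(self, cohort_with_links):
        recs, table = cohort_with_links
        for r in recs:
            r.biomarkers = {k: (0.0 if np.isnan(v) else v) for k, v in r.biomarkers.items()}
        res = mc.screen_biomarkers(table, recs, table.atlas.analysis_ids[:3], ["uric_acid"])
        assert {r.n for r in res} == {300}

    def test_missingness_varies_n_per_pair(self, cohort_with_links):
        recs, table = cohort_with_links
        res = mc.screen_biomarkers(
            table, recs, table.atlas.analysis_ids[:1], ["uric_acid", "null_0"]
        )
        assert all(r.n < 300 for r in res)
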