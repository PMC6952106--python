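"""Cohort statistics: ANCOVA elimination, bootstrap, Tukey letters, ΔΔCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from placentometry import stats
from placentometry.datamodel import BiometryRecord, CtRecord
from placentometry.io import biometry_frame
from placentometry.synthgen import CohortEffects, make_cohort


def _cohort_frame(n_litters=14, pups=8, seed=0, **eff_kwargs):
    eff = CohortEffects(**eff_kwargs)
    records, _ = make_cohort(n_litters, pups, effects=eff, seed=seed)
    return biometry_frame(records)


class TestFpRatio:
    def test_elementwise_ratio(self):
        rec = BiometryRecord("c0", "L0", 18.5, "M", "Con", 1.0, 0.1, 25.0, 8)
        [out] = stats.fp_ratio([rec])
        assert out.fp_ratio == pytest.approx(10.0)

    def test_equal_weights_unity(self):
        rec = BiometryRecord("c0", "L0", 18.5, "M", "Con", 0.5, 0.5, 25.0, 8)
        assert stats.fp_ratio([rec])[0].fp_ratio == 1.0

    def test_sex_ordering_preserved(self):
        # females generated with lighter placentas -> higher efficiency
        records, _ = make_cohort(40, 8, seed=5)
        ratios = {
            s: np.mean([
                r.fetal_weight / r.placental_weight
                for r in records if r.sex == s
            ])
            for s in ("M", "F")
        }
        assert ratios["F"] > ratios["M"]


class TestAncovaBackward:
    def test_null_data_drops_all_interactions(self):
        rng = np.random.default_rng(3)
        n = 200
        df = pd.DataFrame(
            {
                "diet": rng.choice(["Con", "LP"], n),
                "sex": rng.choice(["M", "F"], n),
                "placental_weight": rng.uniform(0.08, 0.12, n),
                "maternal_weight": rng.uniform(20, 30, n),
                "litter_size": rng.integers(4, 12, n),
                "fetal_weight": rng.normal(1.1, 0.1, n),
            }
        )
        res = stats.ancova_backward(df, "fetal_weight")
        assert len(res.dropped_interactions) == 3
        assert set(res.retained_terms) == {
            "diet", "sex", "placental_weight", "maternal_weight", "litter_size"
        }

    def test_diet_main_effect_recovered(self):
        df = _cohort_frame(
            n_litters=26, seed=1,
            beta_sex=0.0, maternal_lp_loss=0.0, litter_sd=0.0,
        )
        res = stats.ancova_backward(df, "fetal_weight")
        assert res.p_values["diet"] < 0.05
        assert "diet:sex" in res.dropped_interactions
        assert res.coefficients["diet"] == pytest.approx(-0.10, abs=0.05)

    def test_sex_sign_on_placental_weight(self):
        # males generated heavier: the female indicator coefficient is negative
        df = _cohort_frame(n_litters=30, seed=2, maternal_lp_loss=0.0)
        res = stats.ancova_backward(
            df, "placental_weight", predictors=("diet", "sex"),
        )
        assert res.coefficients["sex"] < 0

    def test_drop_decisions_invariant_to_predictor_shift(self):
        # internal mean-centring makes results invariant to affine shifts
        df = _cohort_frame(n_litters=16, seed=4)
        shifted = df.copy()
        shifted["placental_weight"] = shifted["placental_weight"] + 10.0
        a = stats.ancova_backward(df, "fetal_weight")
        b = stats.ancova_backward(shifted, "fetal_weight")
        assert a.dropped_interactions == b.dropped_interactions
        for t in a.p_values:
            assert a.p_values[t] == pytest.approx(b.p_values[t], abs=1e-8)

    def test_rank_deficient_design_names_aliased_terms(self):
        df = _cohort_frame(n_litters=10, seed=5)
        df["litter_size"] = 8  # constant covariate aliases the intercept
        with pytest.raises(ValueError, match="litter_size"):
            stats.ancova_backward(df, "fetal_weight")

    def test_main_effects_never_removed(self):
        df = _cohort_frame(n_litters=10, seed=6)
        res = stats.ancova_backward(df, "fetal_weight")
        for main in ("diet", "sex", "placental_weight"):
            assert main in res.retained_terms


class TestBootstrap:
    @staticmethod
    def _null_dataset(i, n=400, n_litters=10):
        r = np.random.default_rng(20_000 + i)
        return pd.DataFrame(
            {
                "diet": r.choice(["Con", "LP"], n),
                "sex": r.choice(["M", "F"], n),
                "litter_id": r.choice([f"L{j}" for j in range(n_litters)], n),
                "y": r.normal(0.0, 1.0, n),
            }
        )

    def test_same_seed_identical_ci(self):
        df = self._null_dataset(0)
        a = stats.bootstrap_coefficients(df, "y", n_resamples=500, seed=7)
        b = stats.bootstrap_coefficients(df, "y", n_resamples=500, seed=7)
        assert a["diet"].ci_95 == b["diet"].ci_95
        assert a["diet"].p_value == b["diet"].p_value

    def test_type_i_error_calibrated(self):
        reps, rej = 1000, 0
        for i in range(reps):
            res = stats.bootstrap_coefficients(
                self._null_dataset(i), "y", n_resamples=1000, seed=1000 + i
            )
            rej += res["diet"].p_value < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.02)

    def test_ci_coverage_nominal(self):
        reps, cov = 500, 0
        for i in range(reps):
            r = np.random.default_rng(5000 + i)
            n = 60
            diet = r.choice(["Con", "LP"], n)
            sex = r.choice(["M", "F"], n)
            y = -0.5 * (diet == "LP") + 0.2 * (sex == "F") + r.normal(0, 0.5, n)
            df = pd.DataFrame(
                {"diet": diet, "sex": sex,
                 "litter_id": r.choice(list("ABCDEF"), n), "y": y}
            )
            res = stats.bootstrap_coefficients(df, "y", n_resamples=2000, seed=9000 + i)
            lo, hi = res["diet"].ci_95
            cov += lo <= -0.5 <= hi
        assert 0.93 <= cov / reps <= 0.97

    def test_power_for_two_sd_effect(self):
        reps, rej = 200, 0
        for i in range(reps):
            r = np.random.default_rng(7000 + i)
            n = 50
            diet = r.choice(["Con", "LP"], n)
            y = 2.0 * (diet == "LP") + r.normal(0, 1, n)
            df = pd.DataFrame({"diet": diet, "sex": r.choice(["M", "F"], n), "y": y})
            res = stats.bootstrap_coefficients(
                df, "y", n_resamples=500, seed=3000 + i, stratify=None
            )
            rej += res["diet"].p_value < 0.05
        assert rej / reps > 0.9

    def test_single_level_resamples_redrawn(self):
        # a tiny dataset where degenerate resamples are common still succeeds
        df = pd.DataFrame(
            {"diet": ["Con", "Con", "Con", "LP"], "y": [1.0, 1.1, 0.9, 0.5]}
        )
        res = stats.bootstrap_coefficients(
            df, "y", predictors=("diet",), n_resamples=200, seed=0, stratify=None
        )
        assert np.isfinite(res["diet"].ci_95).all()


class TestAnovaTukey:
    def test_identical_distributions_share_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        tk = stats.anova_tukey({"a": base, "b": base.copy(), "c": base.copy()})
        assert tk.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert len(set(tk.letters.values())) == 1

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(1)
        groups = {
            "g1": rng.normal(0, 1, 25),
            "g2": rng.normal(0, 1, 25),
            "g3": rng.normal(5, 1, 25),  # 5 SD away
        }
        tk = stats.anova_tukey(groups)
        assert tk.letters["g3"] not in {tk.letters["g1"], tk.letters["g2"]}
        assert tk.letters["g1"] == tk.letters["g2"]

    def test_letters_invariant_under_group_order(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 20) for i, k in enumerate("abcd")}
        tk1 = stats.anova_tukey(groups)
        tk2 = stats.anova_tukey(dict(reversed(list(groups.items()))))
        assert tk1.letters == tk2.letters

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stats.anova_tukey({"only": [1, 2, 3]})

    def test_kruskal_wallis_detects_shift(self):
        rng = np.random.default_rng(3)
        h, p = stats.kruskal_wallis(
            {"a": rng.normal(0, 1, 30), "b": rng.normal(3, 1, 30)}
        )
        assert p < 0.001


class TestDdct:
    def _records(self, lp_dct_shift, n=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            out.append(CtRecord(f"c{i}", "Con", "M", 16.5, "Glut1",
                                25.0 + rng.normal(0, noise), 20.0))
        for i in range(n):
            out.append(CtRecord(f"l{i}", "LP", "M", 16.5, "Glut1",
                                25.0 + lp_dct_shift + rng.normal(0, noise), 20.0))
        return out

    def test_one_cycle_doubling(self):
        df = stats.ddct(self._records(-1.0))
        assert df.loc[df.group == "LP", "fold"].mean() == pytest.approx(2.0)

    def test_identical_groups_unity(self):
        df = stats.ddct(self._records(0.0))
        assert df["fold"].unique() == pytest.approx([1.0])

    def test_control_geometric_mean_is_one(self):
        df = stats.ddct(self._records(-2.0, noise=0.3, seed=1))
        con = df.loc[df.group == "Con", "fold"]
        assert np.exp(np.log(con).mean()) == pytest.approx(1.0, abs=1e-9)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_global_ct_shift(self, shift):
        base = self._records(-2.0, noise=0.2, seed=2)
        shifted = [
            CtRecord(r.sample_id, r.group, r.sex, r.embryonic_day, r.gene,
                     r.ct_target + shift, r.ct_reference + shift)
            for r in base
        ]
        a = stats.ddct(base)["fold"].to_numpy()
        b = stats.ddct(shifted)["fold"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_fourfold_upregulation_recovered(self):
        df = stats.ddct(self._records(-2.0, n=6, noise=0.2, seed=3))
        lp_fold = np.exp(np.log(df.loc[df.group == "LP", "fold"]).mean())
        assert lp_fold == pytest.approx(4.0, rel=0.15)

    def test_efficiency_corrected_variant(self):
        df = stats.ddct(self._records(-1.0), efficiency=0.9)
        assert df.loc[df.group == "LP", "fold"].mean() == pytest.approx(1.9)
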