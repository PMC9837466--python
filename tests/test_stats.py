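"""Quantification and the statistical battery against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from simonstop.stats import (
    ComponentDef,
    effect_table,
    grand_average_and_difference,
    masson_pbic,
    permutation_paired_test,
    posthoc_tests,
    quantify_amplitude,
    rm_anova_2x2,
)

TIMES = -2000.0 + np.arange(1024) * 1000.0 / 256.0


def random_table(seed, n=12):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        base = rng.normal(0, 2)
        for a in ("go", "stop"):
            for b in ("congruent", "incongruent"):
                rows.append(
                    {"subject": s, "response": a, "congruency": b, "value": base + rng.normal(0, 1)}
                )
    return pd.DataFrame(rows)


class TestQuantification:
    def test_flat_waveform_returns_its_value(self):
        wave = np.full((2, 1024), 1.7)
        comp = ComponentDef("P3", "C", ("FCz",), (530.0, 650.0))
        assert quantify_amplitude(wave, comp, ["FCz", "Pz"], TIMES) == pytest.approx(1.7)

    def test_electrode_averaging(self):
        wave = np.vstack([np.full(1024, 2.0), np.full(1024, 4.0)])
        comp = ComponentDef("P1", "S", ("P7", "P8"), (100.0, 120.0))
        assert quantify_amplitude(wave, comp, ["P7", "P8"], TIMES) == pytest.approx(3.0)

    def test_missing_electrode_named_in_error(self):
        comp = ComponentDef("P3", "C", ("Pz",), (530.0, 650.0))
        with pytest.raises(KeyError, match="Pz"):
            quantify_amplitude(np.zeros((1, 1024)), comp, ["FCz"], TIMES)

    def test_electrode_averaging_commutes_with_subject_averaging(self):
        # averaging across electrodes before or after averaging subjects is
        # the same by linearity
        rng = np.random.default_rng(0)
        waves = rng.normal(size=(5, 2, 1024))
        comp = ComponentDef("P1", "S", ("P7", "P8"), (100.0, 120.0))
        per_subject = [quantify_amplitude(w, comp, ["P7", "P8"], TIMES) for w in waves]
        pooled = quantify_amplitude(waves.mean(axis=0), comp, ["P7", "P8"], TIMES)
        assert np.mean(per_subject) == pytest.approx(pooled)


class TestRmAnova:
    def test_hand_built_four_subject_table(self):
        # frozen oracle values from an independent SS decomposition of this
        # table (cross-checked against pingouin.rm_anova)
        vals = {
            (1, "go", "congruent"): 10, (1, "go", "incongruent"): 12,
            (1, "stop", "congruent"): 11, (1, "stop", "incongruent"): 16,
            (2, "go", "congruent"): 8, (2, "go", "incongruent"): 9,
            (2, "stop", "congruent"): 10, (2, "stop", "incongruent"): 13,
            (3, "go", "congruent"): 11, (3, "go", "incongruent"): 12,
            (3, "stop", "congruent"): 12, (3, "stop", "incongruent"): 15,
            (4, "go", "congruent"): 9, (4, "go", "incongruent"): 11,
            (4, "stop", "congruent"): 9, (4, "stop", "incongruent"): 14,
        }
        df = pd.DataFrame(
            [{"subject": s, "response": a, "congruency": b, "value": v} for (s, a, b), v in vals.items()]
        )
        res = rm_anova_2x2(df)
        assert res["response"].F == pytest.approx(48.6)
        assert res["response"].ss_effect == pytest.approx(20.25)
        assert res["response"].ss_error == pytest.approx(1.25)
        assert res["response"].p == pytest.approx(0.0060568488)
        assert res["congruency"].F == pytest.approx(40.0 + 1.0 / 3.0)
        assert res["congruency"].p == pytest.approx(0.0078978382)
        inter = res["response x congruency"]
        assert inter.F == pytest.approx(75.0)
        assert inter.df == (1, 3)
        assert inter.p == pytest.approx(0.0032390371)
        assert inter.partial_eta_sq == pytest.approx(6.25 / (6.25 + 0.25))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_f_equals_squared_paired_t_on_contrasts(self, seed):
        df = random_table(seed)
        res = rm_anova_2x2(df)
        piv = df.pivot_table(index="subject", columns=["response", "congruency"], values="value")
        contrasts = {
            "response": (piv[("stop", "congruent")] + piv[("stop", "incongruent")])
            - (piv[("go", "congruent")] + piv[("go", "incongruent")]),
            "congruency": (piv[("go", "incongruent")] + piv[("stop", "incongruent")])
            - (piv[("go", "congruent")] + piv[("stop", "congruent")]),
            "response x congruency": (piv[("stop", "incongruent")] - piv[("stop", "congruent")])
            - (piv[("go", "incongruent")] - piv[("go", "congruent")]),
        }
        for effect, d in contrasts.items():
            t, p = sps.ttest_1samp(d, 0.0)
            assert res[effect].F == pytest.approx(t**2, rel=1e-9)
            assert res[effect].p == pytest.approx(p, rel=1e-9)

    def test_subject_constant_invariance(self):
        df = random_table(7)
        res0 = rm_anova_2x2(df)
        df2 = df.copy()
        df2.loc[df2["subject"] == 3, "value"] += 100.0
        res1 = rm_anova_2x2(df2)
        for effect in res0:
            assert res0[effect].F == pytest.approx(res1[effect].F)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = random_table(11)
        res = rm_anova_2x2(df)
        ref = pg.rm_anova(
            dv="value", within=["response", "congruency"], subject="subject", data=df, detailed=True
        ).set_index("Source")
        assert res["response"].F == pytest.approx(ref.loc["response", "F"])
        assert res["congruency"].F == pytest.approx(ref.loc["congruency", "F"])
        assert res["response x congruency"].F == pytest.approx(ref.loc["response * congruency", "F"])

    def test_incomplete_table_rejected(self):
        df = random_table(1).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_2x2(df)

    def test_effect_table_drops_incomplete_subjects(self):
        cells = {
            0: {("go", "congruent"): 1.0, ("go", "incongruent"): 2.0, ("stop", "congruent"): 1.5, ("stop", "incongruent"): 2.5},
            1: {("go", "congruent"): 1.0, ("go", "incongruent"): np.nan, ("stop", "congruent"): 1.5, ("stop", "incongruent"): 2.5},
        }
        frame = effect_table(cells)
        assert frame.attrs["dropped"] == [1]
        assert set(frame["subject"]) == {0}


class TestPosthocs:
    def test_identical_pairs_degenerate(self):
        res = posthoc_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.p == 1.0

    def test_wilcoxon_matches_exact_sign_enumeration(self):
        a = np.array([3.0, 5.0, 1.0, 7.0, 2.0, 9.0])
        b = np.array([1.0, 2.0, 2.5, 3.0, 2.4, 4.0])
        res = posthoc_tests(a, b, normality=False)
        d = a - b
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        # exhaustive null: all 2^6 sign assignments of the ranks
        stats = [
            sum(r for r, s in zip(ranks, signs) if s > 0)
            for signs in itertools.product([-1, 1], repeat=6)
        ]
        mean_w = np.mean(stats)
        p_exact = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in stats])
        assert res.method == "wilcoxon"
        assert res.p == pytest.approx(p_exact)

    def test_separated_pairs_are_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10.0, 0.1, 30)
        b = rng.normal(0.0, 0.1, 30)
        assert posthoc_tests(a, b).p < 1e-3

    def test_normality_flag_selects_method(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        assert posthoc_tests(a, b, normality=True).method == "paired_t"
        assert posthoc_tests(a, b, normality=False).method == "wilcoxon"


class TestMassonPbic:
    def test_zero_effect_closed_form(self):
        # ss_effect = 0, n = 27: delta BIC = ln 27, BF01 = sqrt(27),
        # P(H0|D) = sqrt(27) / (1 + sqrt(27)) ~= 0.839
        res = masson_pbic(0.0, 10.0, 27)
        assert res.delta_bic == pytest.approx(np.log(27))
        assert res.p_h0_given_d == pytest.approx(np.sqrt(27) / (1 + np.sqrt(27)))
        assert res.p_h0_given_d == pytest.approx(0.839, abs=5e-4)

    def test_dominant_effect_drives_posterior_to_zero(self):
        res = masson_pbic(1e6, 1.0, 27)
        assert res.p_h0_given_d < 1e-6

    def test_evidence_bands(self):
        assert masson_pbic(1e6, 1.0, 27).evidence == "favors alternative"
        assert masson_pbic(0.0, 1.0, 27).evidence == "positive evidence for null"
        weak = masson_pbic(0.0, 1.0, 4)  # BF01 = 2 -> p = 2/3
        assert weak.evidence == "weak evidence for null"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            masson_pbic(-1.0, 1.0, 10)
        with pytest.raises(ValueError):
            masson_pbic(1.0, 0.0, 10)
        with pytest.raises(ValueError):
            masson_pbic(1.0, 1.0, 1)


class TestPermutation:
    def test_equal_conditions_give_p_one(self):
        x = np.random.default_rng(4).normal(size=(10, 3))
        res = permutation_paired_test(x, x, n_perm=500, seed=0)
        assert np.all(res["p"] == 1.0)

    def test_matches_exact_enumeration_at_n8(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.6, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        d = a - b
        obs = d.mean()
        exact_stats = [
            np.mean(d * np.array(signs)) for signs in itertools.product([-1, 1], repeat=8)
        ]
        p_exact = np.mean([abs(s) >= abs(obs) - 1e-12 for s in exact_stats])
        res = permutation_paired_test(a, b, n_perm=2500, seed=1)
        # Monte-Carlo tolerance at 2500 permutations
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / 2500) + 1.0 / 2501
        assert abs(res["p"][0] - p_exact) <= mc_err

    def test_minimum_attainable_p(self):
        # a huge uniform shift: no random sign flip can reach the observed
        # mean, so p bottoms out at 1 / (n_perm + 1)
        rng = np.random.default_rng(10)
        b = rng.normal(0.0, 1.0, 20)
        a = b + 50.0 + rng.uniform(0, 1, 20)
        res = permutation_paired_test(a, b, n_perm=2500, seed=2)
        assert res["p"][0] == pytest.approx(1.0 / 2501.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.3, 1, size=(9, 4))
        b = rng.normal(0.0, 1, size=(9, 4))
        r1 = permutation_paired_test(a, b, seed=3)
        r2 = permutation_paired_test(a, b, seed=3)
        assert np.array_equal(r1["p"], r2["p"])


class TestGrandAverages:
    def test_identical_subjects(self):
        w = np.random.default_rng(7).normal(size=(1, 2, 100))
        cells = {("go", "congruent"): np.repeat(w, 5, axis=0)}
        out = grand_average_and_difference(cells)
        assert np.allclose(out["grand_average"][("go", "congruent")], w[0])

    def test_stop_only_effect_appears_only_in_stop_difference(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(6, 2, 100))
        implant = np.zeros((2, 100))
        implant[0, 40:60] = 1.0
        cells = {
            ("go", "congruent"): base,
            ("go", "incongruent"): base.copy(),
            ("stop", "congruent"): base,
            ("stop", "incongruent"): base + implant[None, :, :],
        }
        out = grand_average_and_difference(cells)
        assert np.allclose(out["difference_waves"]["go"], 0.0)
        assert np.allclose(out["difference_waves"]["stop"], implant)

    def test_difference_of_differences_is_interaction_contrast(self):
        rng = np.random.default_rng(9)
        cells = {
            (r, c): rng.normal(size=(4, 2, 50))
            for r in ("go", "stop")
            for c in ("congruent", "incongruent")
        }
        out = grand_average_and_difference(cells)
        inter = out["difference_waves"]["stop"] - out["difference_waves"]["go"]
        manual = (
            cells[("stop", "incongruent")].mean(0)
            - cells[("stop", "congruent")].mean(0)
            - cells[("go", "incongruent")].mean(0)
            + cells[("go", "congruent")].mean(0)
        )
        assert np.allclose(inter, manual)
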