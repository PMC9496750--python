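"""Differential-abundance statistics: detection filter, imputation,
t-statistics, permutation FDR, affected-protein calls and triage."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erclients import TruthConfig, generate_cohort, generate_null_cohort
from erclients import diff as da
from erclients.diff import (
    _label_arrangements,
    _two_sample_t,
    call_affected,
    filter_detected,
    impute_missing,
    per_sirna_stats,
    permutation_fdr,
    triage_candidates,
    volcano_table,
)
from erclients.proteome_io import LfqCohort, SampleDesign

from conftest import make_cohort, make_design

NO_MISSING = dict(mnar_slope=0.0, mcar_rate=0.0)


class TestFilterDetected:
    def _two_experiment_cohort(self):
        # 5 proteins, 2 experiments x 3 groups x 2 replicates
        samples = make_design(n_replicates=2, n_experiments=2)
        rng = np.random.default_rng(0)
        intensity = rng.uniform(10, 100, size=(5, len(samples)))
        # P5 missing everywhere in experiment 2
        exp2 = [j for j, s in enumerate(samples) if s.experiment == 2]
        intensity[4, exp2] = np.nan
        return LfqCohort([f"P{i+1}" for i in range(5)], samples, intensity)

    def test_protein_absent_from_one_experiment_excluded(self):
        cohort = self._two_experiment_cohort()
        assert filter_detected(cohort) == {"P1", "P2", "P3", "P4"}

    def test_single_experiment_keeps_all_quantified(self):
        intensity = np.random.default_rng(1).uniform(10, 100, size=(4, 9))
        cohort = make_cohort(intensity)
        assert filter_detected(cohort) == {"P1", "P2", "P3", "P4"}

    def test_one_value_per_group_per_experiment_suffices(self):
        intensity = np.full((1, 9), np.nan)
        intensity[0, [0, 3, 6]] = 50.0  # one value in each group
        cohort = make_cohort(intensity)
        assert filter_detected(cohort) == {"P1"}

    def test_empty_intersection_warns_and_returns_empty(self, caplog):
        intensity = np.full((1, 9), np.nan)
        intensity[0, [0, 3, 6]] = 50.0
        c1 = make_cohort(intensity, proteins=["P1"])
        c2 = make_cohort(intensity, proteins=["P2"])
        with caplog.at_level("WARNING"):
            assert filter_detected([c1, c2]) == set()
        assert "empty" in caplog.text


class TestImputation:
    def test_no_missing_cells_identity(self):
        intensity = np.random.default_rng(2).uniform(10, 100, size=(5, 9))
        cohort = make_cohort(intensity)
        out = impute_missing(cohort, seed=0)
        np.testing.assert_allclose(out.intensity, intensity, rtol=1e-12)

    def test_fixed_seed_reproducible(self):
        intensity = np.random.default_rng(3).uniform(10, 100, size=(5, 9))
        intensity[0, 0] = np.nan
        cohort = make_cohort(intensity)
        a = impute_missing(cohort, seed=5).intensity
        b = impute_missing(cohort, seed=5).intensity
        np.testing.assert_array_equal(a, b)
        c = impute_missing(cohort, seed=6).intensity
        assert not np.array_equal(a, c)

    def test_downshifted_distribution_matches_stated_normal(self):
        # one sample column with many observed N(25, 2) log2 values and many
        # missing cells; imputed draws must follow N(mu - 1.8 s, (0.3 s)^2)
        rng = np.random.default_rng(4)
        n = 20000
        log2 = rng.normal(25.0, 2.0, size=(n, 9))
        intensity = np.exp2(log2)
        missing = np.zeros(n, dtype=bool)
        missing[:8000] = True
        intensity[missing, 0] = np.nan
        cohort = make_cohort(intensity)
        observed = log2[~missing, 0]
        mu, sd = observed.mean(), observed.std(ddof=1)
        out = np.log2(impute_missing(cohort, seed=7).intensity)
        imputed = out[missing, 0]
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=0.03)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)
        # ~Phi(0.517) of draws fall below the observed 5th percentile, and
        # >=95% fall below mu - 0.9 sd (Phi(3) ~= 0.9987)
        frac_below_q05 = np.mean(imputed < np.percentile(observed, 5))
        assert frac_below_q05 == pytest.approx(stats.norm.cdf((1.8 - 1.645) / 0.3), abs=0.02)
        assert np.mean(imputed < mu - 0.9 * sd) >= 0.95

    def test_sample_with_too_few_observed_values_errors(self):
        intensity = np.random.default_rng(5).uniform(10, 100, size=(3, 9))
        intensity[:, 0] = np.nan
        cohort = make_cohort(intensity)
        with pytest.raises(ValueError, match="observed"):
            impute_missing(cohort, seed=0)


class TestPerSirnaStats:
    def test_linear_scale_halving_gives_minus_one_log2fc(self):
        intensity = np.array([[4, 4, 4, 2, 2, 2, 3, 3, 3]], dtype=float)
        cohort = make_cohort(intensity)
        table = per_sirna_stats(cohort, "sirna1")
        assert table.loc["P1", "mean_log2fc"] == pytest.approx(-1.0)
        # zero variance with unequal means: documented infinite-t sentinel
        assert np.isinf(table.loc["P1", "t_stat"])
        assert table.loc["P1", "p_value"] == pytest.approx(np.finfo(float).eps)

    def test_identical_groups_give_t0_p1(self):
        intensity = np.tile([4.0, 5.0, 6.0], (1, 3))
        cohort = make_cohort(intensity)
        table = per_sirna_stats(cohort, "sirna1")
        assert table.loc["P1", "t_stat"] == 0.0
        assert table.loc["P1", "p_value"] == 1.0

    def test_hand_computed_pooled_t(self):
        # control log2 (10, 11, 12) vs siRNA log2 (8, 9, 10):
        # diff = -2, pooled var = 1, se = sqrt(2/3), t = -sqrt(6)
        intensity = np.exp2(np.array([[10, 11, 12, 8, 9, 10, 10, 10, 10]], dtype=float))
        cohort = make_cohort(intensity)
        table = per_sirna_stats(cohort, "sirna1")
        assert table.loc["P1", "mean_log2fc"] == pytest.approx(-2.0)
        assert table.loc["P1", "t_stat"] == pytest.approx(-math.sqrt(6.0))
        assert table.loc["P1", "p_value"] == pytest.approx(2 * stats.t.sf(math.sqrt(6), 4))

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            na, nb = rng.integers(2, 6), rng.integers(2, 6)
            a = rng.normal(0, 1, size=(1, na))
            b = rng.normal(0.5, 2, size=(1, nb))
            _, t, p = _two_sample_t(a, b, method="student", s0=0.0)
            ref = stats.ttest_ind(a[0], b[0], equal_var=True)
            assert t[0] == pytest.approx(ref.statistic, abs=1e-10)
            assert p[0] == pytest.approx(ref.pvalue, abs=1e-10)
            _, tw, pw = _two_sample_t(a, b, method="welch", s0=0.0)
            refw = stats.ttest_ind(a[0], b[0], equal_var=False)
            assert tw[0] == pytest.approx(refw.statistic, abs=1e-10)
            assert pw[0] == pytest.approx(refw.pvalue, abs=1e-10)

    def test_missing_values_rejected(self):
        intensity = np.random.default_rng(9).uniform(10, 100, size=(2, 9))
        intensity[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            per_sirna_stats(make_cohort(intensity), "sirna1")


class TestPermutationFdr:
    def test_q_non_increasing_in_abs_t(self):
        cohort = generate_null_cohort(300, seed=12, config=TruthConfig(**NO_MISSING))
        table = per_sirna_stats(cohort, "sirna1")
        q = permutation_fdr(cohort, "sirna1", table["t_stat"], seed=0)
        order = np.argsort(-np.abs(table["t_stat"].to_numpy()))
        assert np.all(np.diff(q.to_numpy()[order]) >= -1e-12)
        assert ((q >= 0) & (q <= 1)).all()

    def test_spiked_protein_gets_tiny_q(self):
        rng = np.random.default_rng(13)
        log2 = rng.normal(25, 0.25, size=(400, 9)) + rng.normal(25, 2, size=(400, 1)) - 25
        log2[0, 3:6] -= 5.0  # enormous knockdown of one protein
        cohort = make_cohort(np.exp2(log2))
        q = permutation_fdr(cohort, "sirna1", None, seed=1)
        assert q.loc["P1"] < 0.01

    def test_exhaustive_arrangements_for_3v3(self):
        arrangements = _label_arrangements(6, 3, None, np.random.default_rng(0))
        assert len(arrangements) == 20
        assert len(set(arrangements)) == 20

    def test_fewer_than_two_arrangements_error(self):
        with pytest.raises(ValueError, match="arrangements"):
            _label_arrangements(2, 2, None, np.random.default_rng(0))

    def test_null_cohort_rarely_yields_discoveries(self):
        # weaker, fast version of the calibration acceptance check
        false_rates = []
        for seed in range(5):
            cohort = generate_null_cohort(500, seed=40 + seed)
            imputed = impute_missing(cohort, seed=seed)
            q = da.diff_table(imputed, "sirna1", seed=seed)["q_value"]
            false_rates.append(np.mean(q < 0.05))
        assert np.mean(false_rates) <= 0.05 + 3 * np.std(false_rates) / np.sqrt(5) + 0.01


class TestCallAffected:
    @staticmethod
    def _frame(rows):
        df = pd.DataFrame(rows, columns=["accession", "mean_log2fc", "t_stat",
                                         "p_value", "q_value"])
        return df.set_index("accession")

    def test_call_rules(self):
        d1 = self._frame([("A", -1.2, -5, 0.001, 0.01), ("B", -1.2, -5, 0.001, 0.01),
                          ("C", -1.0, -4, 0.002, 0.01), ("D", 2.0, 6, 0.001, 0.01)])
        d2 = self._frame([("A", -0.8, -4, 0.002, 0.02), ("B", 0.8, 4, 0.002, 0.02),
                          ("C", -1.0, -4, 0.002, 0.20), ("D", 1.5, 5, 0.001, 0.02)])
        calls = call_affected(d1, d2, alpha=0.05)
        assert calls.loc["A", "call"] == "negative"   # both q < alpha, both down
        assert calls.loc["B", "call"] == "ns"         # direction conflict
        assert calls.loc["C", "call"] == "ns"         # one q >= alpha
        assert calls.loc["D", "call"] == "positive"

    def test_protein_in_one_set_only_excluded(self, caplog):
        d1 = self._frame([("A", -1, -5, 0.001, 0.01), ("B", -1, -5, 0.001, 0.01)])
        d2 = self._frame([("A", -1, -5, 0.001, 0.01)])
        with caplog.at_level("INFO"):
            calls = call_affected(d1, d2)
        assert list(calls.index) == ["A"]
        assert "excluded 1" in caplog.text

    def test_negating_effects_swaps_call_sets_exactly(self):
        # mirror every protein's log2 profile around its control mean: all
        # mean differences negate while group variances are preserved, so
        # every t negates and the negative/positive call sets must swap.
        # pi0 fixed and s0 = 0: the two data-adaptive estimates are the only
        # components not exactly mirror-symmetric under negation.
        # strong planted effects so both call directions are populated even
        # under the plain (s0 = 0) statistic
        config = TruthConfig(client_fraction=0.05, upregulated_fraction=0.02,
                             effect_log2=-2.5, upregulated_effect_log2=2.5,
                             noise_sd_log2=0.15, **NO_MISSING)
        down, _, _ = generate_cohort(400, config=config, seed=14)
        log2 = down.log2_intensity()
        ctrl = down.sample_index(group="control")
        mirrored = 2 * log2[:, ctrl].mean(axis=1, keepdims=True) - log2
        up = down.with_intensity(np.exp2(mirrored))
        kwargs = dict(s0=0.0, pi0=1.0)
        calls_down = call_affected(
            da.diff_table(down, "sirna1", seed=1, **kwargs),
            da.diff_table(down, "sirna2", seed=2, **kwargs))
        calls_up = call_affected(
            da.diff_table(up, "sirna1", seed=1, **kwargs),
            da.diff_table(up, "sirna2", seed=2, **kwargs))
        neg_d, pos_d = da.affected_sets(calls_down)
        neg_u, pos_u = da.affected_sets(calls_up)
        assert neg_d and pos_d  # both directions represented
        assert neg_d == pos_u
        assert pos_d == neg_u


class TestTriage:
    @staticmethod
    def _frame(rows):
        df = pd.DataFrame(rows, columns=["accession", "mean_log2fc", "p_value"])
        return df.set_index("accession")

    def test_hand_enumerated_three_protein_toy(self):
        # thresholds p < 0.01 and log2fc < -1 (i.e. >50% reduction);
        # candidate must pass both siRNAs in both datasets AND be a partner.
        # A: passes everywhere, in partner list         -> candidate
        # B: fails p in the double dataset's siRNA-2    -> out
        # C: passes everywhere but not a partner        -> out
        single = (
            self._frame([("A", -1.5, 0.001), ("B", -1.4, 0.002), ("C", -2.0, 0.001)]),
            self._frame([("A", -1.2, 0.005), ("B", -1.1, 0.004), ("C", -1.8, 0.003)]),
        )
        double = (
            self._frame([("A", -1.3, 0.002), ("B", -1.2, 0.003), ("C", -1.6, 0.002)]),
            self._frame([("A", -1.1, 0.008), ("B", -1.0, 0.05), ("C", -1.5, 0.001)]),
        )
        result = triage_candidates(single, double, partner_list={"A", "B"})
        assert result.candidates == {"A"}
        assert bool(result.trace.loc["C", "passed_single"])
        assert not bool(result.trace.loc["C", "in_partner_list"])
        assert not bool(result.trace.loc["B", "passed_double"])

    def test_reduction_threshold_maps_to_log2_cut(self):
        # 50% reduction <=> log2fc < -1: a protein at exactly -1 fails
        single = (self._frame([("A", -1.0, 0.001)]), self._frame([("A", -1.0, 0.001)]))
        result = triage_candidates(single, single, partner_list={"A"})
        assert result.candidates == set()

    def test_empty_partner_list_warns_and_empties(self, caplog):
        single = (self._frame([("A", -2.0, 0.001)]), self._frame([("A", -2.0, 0.001)]))
        with caplog.at_level("WARNING"):
            result = triage_candidates(single, single, partner_list=set())
        assert result.candidates == set()
        assert "partner" in caplog.text


class TestVolcano:
    def test_projection_shape_and_signs(self):
        cohort, _, _ = generate_cohort(150, config=TruthConfig(**NO_MISSING), seed=15)
        diffs = {g: da.diff_table(cohort, g, seed=i)
                 for i, g in enumerate(("sirna1", "sirna2"))}
        table = volcano_table(diffs)
        assert len(table) == 150 * 2
        calls = call_affected(diffs["sirna1"], diffs["sirna2"])
        neg, _ = da.affected_sets(calls)
        sub = table[table["accession"].isin(neg)]
        assert (sub["mean_log2fc"] < 0).all()

    def test_round_trips_through_tsv(self, tmp_path):
        cohort, _, _ = generate_cohort(50, config=TruthConfig(**NO_MISSING), seed=16)
        table = volcano_table({"sirna1": da.diff_table(cohort, "sirna1", seed=0)})
        path = tmp_path / "volcano.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, table)
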