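"""Trigger-pattern classification, the tiered screen, and ratio trajectories."""

import numpy as np
import pytest

from cet import synthdata as sd
from cet.screen import (ScreenCriteria, classify_trigger_pattern, ratio_trajectory,
                        run_screen)

from conftest import STAGES, make_single_gene_series, panel_from_matrix


def brute_force_trigger(means, criteria=ScreenCriteria()):
    """Independent oracle: direct evaluation of the trigger criteria on a
    stage-ordered mean-TPM list (plain scalar arithmetic, no pandas)."""
    pc = criteria.pseudocount
    i_pre_a = STAGES.index(criteria.pre_window[0])
    i_pre_b = STAGES.index(criteria.pre_window[1])
    i_trig = STAGES.index(criteria.trigger_stage)
    pre_fc = (means[i_pre_b] + pc) / (means[i_pre_a] + pc)
    if abs(np.log(pre_fc)) > np.log(criteria.unchanged_max_fc):
        return False
    trig_fc = (means[i_trig] + pc) / (means[i_pre_b] + pc)
    if trig_fc < criteria.increase_min_fc:
        return False
    if criteria.sustained:
        for m in means[i_trig + 1:]:
            if m < means[i_trig] * criteria.retention_fraction:
                return False
    return True


class TestClassifyTriggerPattern:
    @pytest.mark.parametrize("series,expected,failing", [
        ([10, 10, 10, 10, 10, 10, 10], False, "trigger-stage increase"),
        ([10, 10, 10, 20, 25, 30, 30], True, None),
        ([30, 20, 10, 5, 5, 5, 5], False, "pre-window unchanged"),
        ([10, 10, 10, 20, 12, 30, 30], False, "not sustained at 75pct"),
        ([10, 10, 10, 10, 30, 30, 30], False, "trigger-stage increase"),  # late riser
    ])
    def test_hand_examples(self, series, expected, failing):
        call = classify_trigger_pattern(make_single_gene_series(series), STAGES,
                                        ScreenCriteria())
        assert call.is_trigger is expected
        assert call.failing_criterion == failing

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        crit = ScreenCriteria()
        for _ in range(300):
            means = rng.lognormal(2.5, 1.0, len(STAGES))
            call = classify_trigger_pattern(make_single_gene_series(means), STAGES, crit)
            assert call.is_trigger == brute_force_trigger(list(means), crit)

    def test_missing_stage_errors(self):
        gs = make_single_gene_series([10] * 7)
        gs = gs[gs["stage"] != "shield"]
        with pytest.raises(ValueError, match="shield"):
            classify_trigger_pattern(gs, STAGES, ScreenCriteria())

    def test_all_zero_without_pseudocount_is_below_detection(self):
        gs = make_single_gene_series([0] * 7)
        call = classify_trigger_pattern(gs, STAGES, ScreenCriteria(pseudocount=0.0))
        assert not call.is_trigger
        assert call.failing_criterion == "below detection"

    def test_replicate_test_mode_demotes_noisy_increase(self):
        # large replicate scatter at the key stages -> Welch test cannot reject
        rng = np.random.default_rng(0)
        rows = make_single_gene_series([10, 10, 10, 18, 20, 20, 20], n_replicates=3)
        jitter = rng.uniform(0.1, 4.0, len(rows))
        rows.loc[rows["stage"].isin(["50pct", "shield"]), "tpm"] *= \
            jitter[rows["stage"].isin(["50pct", "shield"]).to_numpy()]
        crit = ScreenCriteria(significance_mode="replicate_test", alpha=1e-6)
        call = classify_trigger_pattern(rows, STAGES, crit)
        assert not call.is_trigger


class TestRunScreen:
    def test_noiseless_planted_recovery_and_tier_nesting(self):
        spec = sd.SimExpressionSpec(n_genes=120, noise_cv=0.0, seed=7,
                                    planted_triggers=frozenset({3, 17, 40, 41, 99}))
        panel = sd.gen_expression_panel(spec)
        panels = {c: panel.subset(c) for c in ("uninjected", "acvr1b", "ndr2")}
        res = run_screen(panels, panel.subset("embryo"))
        assert res.tier1 == sorted(sd.planted_gene_ids(spec))
        assert set(res.tier3) <= set(res.tier2) <= set(res.tier1)

    def test_tier1_matches_brute_force_oracle_under_noise(self):
        spec = sd.SimExpressionSpec(n_genes=60, noise_cv=0.25, seed=11,
                                    planted_triggers=frozenset(range(6)))
        panel = sd.gen_expression_panel(spec)
        conds = ("uninjected", "acvr1b", "ndr2")
        panels = {c: panel.subset(c) for c in conds}
        res = run_screen(panels, panel.subset("embryo"))
        expected = []
        for g in panel.genes:
            ok = all(
                brute_force_trigger(
                    panels[c].replicate_means(c).loc[g].tolist())
                for c in conds)
            if ok:
                expected.append(g)
        assert res.tier1 == expected

    def test_noisy_specificity_bound(self):
        # at replicate CV 0.2, false positives stay rare even though hard
        # fold thresholds lose true triggers to noise
        fps, negs = 0, 0
        for k in range(10):
            spec = sd.SimExpressionSpec(n_genes=200, noise_cv=0.2, seed=900 + k,
                                        planted_triggers=frozenset(range(0, 200, 10)))
            panel = sd.gen_expression_panel(spec)
            res = run_screen({c: panel.subset(c) for c in ("uninjected", "acvr1b", "ndr2")},
                             panel.subset("embryo"))
            truth = sd.planted_gene_ids(spec)
            fps += len(set(res.tier1) - truth)
            negs += spec.n_genes - len(truth)
        assert 1 - fps / negs > 0.9

    def test_infinite_tpm_min_empties_tier3(self):
        spec = sd.SimExpressionSpec(n_genes=30, noise_cv=0.0, seed=1,
                                    planted_triggers=frozenset({0, 1, 2}))
        panel = sd.gen_expression_panel(spec)
        panels = {c: panel.subset(c) for c in ("uninjected", "acvr1b", "ndr2")}
        res = run_screen(panels, panel.subset("embryo"),
                         ScreenCriteria(tpm_min=np.inf))
        assert res.tier3 == []
        assert res.tier1  # the vacuous filter only affects tier 3

    def test_screen_invariant_to_uniform_rescaling(self):
        spec = sd.SimExpressionSpec(n_genes=40, noise_cv=0.2, seed=3,
                                    planted_triggers=frozenset({5, 6}))
        panel = sd.gen_expression_panel(spec)
        conds = ("uninjected", "acvr1b", "ndr2")
        base = run_screen({c: panel.subset(c) for c in conds}, panel.subset("embryo"),
                          ScreenCriteria(pseudocount=0.0, tpm_min=0.0))
        scaled = panel.data.copy()
        scaled["tpm"] *= 37.0
        from cet.panel import ExpressionPanel
        p2 = ExpressionPanel(scaled, dict(panel.stage_hpf), list(panel.conditions))
        res2 = run_screen({c: p2.subset(c) for c in conds}, p2.subset("embryo"),
                          ScreenCriteria(pseudocount=0.0, tpm_min=0.0))
        assert base.tier1 == res2.tier1 and base.tier2 == res2.tier2

    def test_disjoint_universes_error(self):
        a = panel_from_matrix([[10] * 7], genes=["a"])
        b = panel_from_matrix([[10] * 7], genes=["b"])
        with pytest.raises(ValueError, match="disjoint"):
            run_screen({"c": a}, b)


class TestRatioTrajectory:
    def test_hand_example(self):
        # ratios [0.125, 0.25, 2, 3] over the first four stages
        num = [1, 2, 8, 6, 6, 6, 6]
        den = [8, 8, 4, 2, 2, 2, 2]
        panel = panel_from_matrix([num, den], genes=["n", "d"])
        traj = ratio_trajectory(panel, "n", "d", pseudocount=0.0)
        np.testing.assert_allclose(traj.ratio[:4], [0.125, 0.25, 2.0, 3.0])
        # peak among the first four stages is stage index 3; later stages tie at 3
        assert traj.peak_stage == STAGES[3]
        # inversion interpolated between stages 2 and 3 (hpf 4.3 and 5.3)
        t2, t3 = 4.3, 5.3
        expected = t2 + (1 - 0.25) / (2.0 - 0.25) * (t3 - t2)
        assert traj.inversion_hpf == pytest.approx(expected)

    def test_identical_genes_ratio_is_one_no_inversion(self):
        panel = panel_from_matrix([[5, 6, 7, 8, 9, 10, 11]] * 2, genes=["a", "b"])
        traj = ratio_trajectory(panel, "a", "b")
        np.testing.assert_allclose(traj.ratio, 1.0)
        assert traj.inversion_hpf is None
        assert traj.peak_stage == STAGES[0]  # earliest stage wins ties

    def test_all_zero_denominator_errors(self):
        panel = panel_from_matrix([[1] * 7, [0] * 7], genes=["a", "b"])
        with pytest.raises(ValueError, match="ratio undefined"):
            ratio_trajectory(panel, "a", "b", pseudocount=0.0)

    def test_planted_inversion_recovered(self):
        # numerator overtakes denominator between 50pct (5.3) and shield (6.0)
        num = [2, 2, 2, 12, 12, 12, 12]
        den = [8, 8, 8, 8, 8, 8, 8]
        panel = panel_from_matrix([num, den], genes=["n", "d"])
        traj = ratio_trajectory(panel, "n", "d", pseudocount=0.0)
        assert 5.3 < traj.inversion_hpf < 6.0
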