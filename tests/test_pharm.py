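"""Viability normalisation, 4PL EC50 fitting, nonparametric tests, quadrants."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from ddrstress.pharm import (
    assign_quadrant,
    association_test,
    call_platinum_sensitivity,
    compare_groups,
    fit_4pl,
    normalize_viability,
)
from ddrstress.simulate import generate_dose_response, half_log_doses

from _oracles import fisher_exact_two_sided_p, mann_whitney_exact_p


def _plate(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "compound", "dose", "well_role", "replicate", "raw_signal"]
    )


class TestNormalize:
    def test_anchor_wells_map_to_0_and_100(self):
        plate = _plate(
            [
                ("s", "d", 0.0, "media_blank", 1, 0.1),
                ("s", "d", 0.0, "vehicle", 1, 1.2),
                ("s", "d", 0.0, "actD_kill", 1, 0.2),
                ("s", "d", 1.0, "treated", 1, 1.2),
                ("s", "d", 10.0, "treated", 1, 0.2),
            ]
        )
        out = normalize_viability(plate).set_index("dose")["viability"]
        assert out[1.0] == pytest.approx(100.0)
        assert out[10.0] == pytest.approx(0.0)

    def test_worked_arithmetic_example(self):
        plate = _plate(
            [
                ("s", "d", 0.0, "media_blank", 1, 0.1),
                ("s", "d", 0.0, "vehicle", 1, 1.2),
                ("s", "d", 0.0, "actD_kill", 1, 0.2),
                ("s", "d", 1.0, "treated", 1, 0.7),
            ]
        )
        out = normalize_viability(plate)
        assert out["viability"].iloc[0] == pytest.approx(50.0)

    def test_inverted_controls_rejected(self):
        plate = _plate(
            [
                ("s", "d", 0.0, "media_blank", 1, 0.1),
                ("s", "d", 0.0, "vehicle", 1, 0.2),
                ("s", "d", 0.0, "actD_kill", 1, 1.2),
                ("s", "d", 1.0, "treated", 1, 0.7),
            ]
        )
        with pytest.raises(ValueError, match="inverted controls"):
            normalize_viability(plate)

    def test_missing_control_rejected(self):
        plate = _plate(
            [
                ("s", "d", 0.0, "vehicle", 1, 1.2),
                ("s", "d", 1.0, "treated", 1, 0.7),
            ]
        )
        with pytest.raises(ValueError, match="missing"):
            normalize_viability(plate)

    def test_overshoot_kept_unclipped(self):
        plate = _plate(
            [
                ("s", "d", 0.0, "media_blank", 1, 0.0),
                ("s", "d", 0.0, "vehicle", 1, 1.0),
                ("s", "d", 0.0, "actD_kill", 1, 0.1),
                ("s", "d", 1.0, "treated", 1, 1.3),
            ]
        )
        out = normalize_viability(plate)
        assert out["viability"].iloc[0] > 100.0

    def test_scale_invariance_after_blank_subtraction(self):
        rows = [
            ("s", "d", 0.0, "media_blank", 1, 0.0),
            ("s", "d", 0.0, "vehicle", 1, 1.0),
            ("s", "d", 0.0, "actD_kill", 1, 0.1),
            ("s", "d", 1.0, "treated", 1, 0.6),
        ]
        base = normalize_viability(_plate(rows))
        scaled_rows = [(s, c, d, w, r, 7.5 * v) for s, c, d, w, r, v in rows]
        scaled = normalize_viability(_plate(scaled_rows))
        np.testing.assert_allclose(base["viability"], scaled["viability"], rtol=1e-12)


class TestFit4PL:
    def test_noiseless_recovery_to_numerical_precision(self):
        doses = np.array(half_log_doses(center=1.0))
        truth = dict(ec50=1.0, hill=1.3, top=98.0, bottom=4.0)
        v = truth["bottom"] + (truth["top"] - truth["bottom"]) / (
            1 + (doses / truth["ec50"]) ** truth["hill"]
        )
        fit = fit_4pl(doses, v)
        assert fit.status == "ok"
        assert fit.ec50 == pytest.approx(truth["ec50"], rel=1e-6)
        assert fit.hill == pytest.approx(truth["hill"], rel=1e-6)
        assert fit.top == pytest.approx(truth["top"], rel=1e-6)
        assert fit.bottom == pytest.approx(truth["bottom"], abs=1e-4)

    def test_dose_unit_equivariance(self):
        doses = np.array(half_log_doses(center=1.0))
        v = 100.0 / (1 + doses / 1.0)
        a = fit_4pl(doses, v)
        b = fit_4pl(doses * 10, v)
        assert b.ec50 == pytest.approx(10 * a.ec50, rel=1e-9)
        assert b.hill == pytest.approx(a.hill, rel=1e-9)

    def test_flat_response_is_no_response(self):
        doses = np.array(half_log_doses())
        fit = fit_4pl(doses, np.full_like(doses, 100.0))
        assert fit.status == "no_response"
        assert fit.converged

    def test_shallow_span_is_no_response(self):
        doses = np.array(half_log_doses(center=1.0))
        v = 95.0 + 5.0 / (1 + doses)  # 5-point span, far below 20
        fit = fit_4pl(doses, v)
        assert fit.status == "no_response"

    def test_degenerate_generated_curve_flagged(self):
        plate = generate_dose_response(ec50=1.0, top=80.0, bottom=80.0, cv=0.0, seed=2)
        norm = normalize_viability(plate)
        fit = fit_4pl(norm["dose"], norm["viability"])
        assert fit.status == "no_response"

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_4pl([1.0, 1.0, 2.0, 3.0], [90, 88, 50, 10])

    def test_noisy_recovery_within_15_percent(self):
        plate = generate_dose_response(ec50=1.0, cv=0.05, replicates=3, seed=11)
        norm = normalize_viability(plate)
        fit = fit_4pl(norm["dose"], norm["viability"])
        assert fit.status == "ok"
        assert abs(fit.ec50 - 1.0) < 0.15


class TestPlatinumCall:
    def test_strictly_below_threshold(self):
        assert call_platinum_sensitivity(9.9) is True
        assert call_platinum_sensitivity(10.0) is False

    def test_threshold_configurable(self):
        assert call_platinum_sensitivity(12.0, threshold=15.0) is True


class TestCompareGroups:
    def test_separated_triples_exact_p(self):
        stat, p = compare_groups([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        # pooled ties force the tie-corrected approximation; p is 1 by symmetry
        _, p = compare_groups([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(1.0)

    def test_exact_matches_full_enumeration_up_to_n6(self, rng):
        """Exhaustive cross-check of the exact path against permutation
        enumeration for tie-free samples of all sizes up to 6 vs 6."""
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (6, 6)]:
            values = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            labels = ["a"] * n1 + ["b"] * n2
            _, p = compare_groups(values, labels)
            assert p == pytest.approx(mann_whitney_exact_p(values[:n1], values[n1:]), abs=1e-12)

    def test_exact_and_approximation_agree_at_n8(self, rng):
        values = rng.normal(size=16)
        labels = ["a"] * 8 + ["b"] * 8
        _, p_exact = compare_groups(values, labels)  # n<=8 tie-free: exact path
        import scipy.stats

        p_asym = scipy.stats.mannwhitneyu(
            values[:8], values[8:], alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(p_exact - p_asym) < 0.02

    def test_kruskal_wallis_three_groups(self):
        stat, p = compare_groups(
            [1, 2, 3, 10, 11, 12, 20, 21, 22], ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            test="kruskal_wallis",
        )
        assert p < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], ["a", "a", "a"])


class TestAssociation:
    def test_diagonal_table_fisher_p(self):
        flags_a = [True] * 3 + [False] * 3
        table, p = association_test(flags_a, flags_a, test="fisher_exact")
        assert p == pytest.approx(0.1)
        assert table.to_numpy().tolist() == [[3, 0], [0, 3]]

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        for _ in range(20):
            flags_a = rng.random(12) < 0.5
            flags_b = rng.random(12) < 0.5
            try:
                table, p = association_test(flags_a, flags_b, test="fisher_exact")
            except ValueError:
                continue  # empty margin
            assert p == pytest.approx(
                fisher_exact_two_sided_p(table.to_numpy()), rel=1e-9
            )

    def test_balanced_independent_table_p_one(self):
        flags_a = [True] * 10 + [False] * 10
        flags_b = ([True] * 5 + [False] * 5) * 2
        _, p_fisher = association_test(flags_a, flags_b, test="fisher_exact")
        _, p_chi = association_test(flags_a, flags_b, test="chi_square")
        assert p_fisher == pytest.approx(1.0)
        assert p_chi == pytest.approx(1.0)

    def test_chi_square_agrees_with_fisher_on_strong_association(self):
        flags_a = [True] * 10 + [False] * 10
        _, p_fisher = association_test(flags_a, flags_a, test="fisher_exact")
        _, p_chi = association_test(flags_a, flags_a, test="chi_square")
        assert p_fisher < 0.05 and p_chi < 0.05

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="empty margin"):
            association_test([True, True], [True, False])


class TestQuadrants:
    @pytest.mark.parametrize(
        "ddr,rs,expected_drugs",
        [
            (True, True, {"platinum_parp_inhibitor", "atr_wee1_inhibitor"}),
            (True, False, {"platinum_parp_inhibitor"}),
            (False, True, {"atr_wee1_inhibitor"}),
            (False, False, set()),
        ],
    )
    def test_response_mapping(self, ddr, rs, expected_drugs):
        call = assign_quadrant(ddr, rs)
        assert set(call.predicted_responsive) == expected_drugs

    def test_unknown_flag_is_unassessable(self):
        call = assign_quadrant(None, True)
        assert call.quadrant == "unassessable"
        assert call.predicted_responsive == ()
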