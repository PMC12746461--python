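import math

import numpy as np
import pytest

from rrspace.counting import (
    AsymptoticUnreliable,
    CalibrationConstants,
    CalibrationRecord,
    DEFAULT_CALIBRATION,
    asymptotic_count,
    average_path_length,
    count_from_path_length,
    estimate_count,
    falling_factorial_sums,
    hydrogen_correction,
    log_asymptotic_count,
    monovalent_excess,
    nonpure_multiplier,
    nonpure_path_length,
    refit_calibration,
)
from rrspace.distance import edit_distance_bnb
from rrspace.exact import count_exact, enumerate_protomolecules
from rrspace.space import LabeledDegreeSequence


def seq(**kw):
    return LabeledDegreeSequence.from_valence_counts(
        {int(k[1:]): v for k, v in kw.items()}
    )


class TestFallingFactorials:
    @pytest.mark.parametrize(
        "k, r, expected",
        [
            ([1, 1], 1, 2),
            ([1, 1], 2, 0),
            ([4, 1, 1, 1, 1], 1, 8),
            ([4, 1, 1, 1, 1], 2, 12),
            ([4, 1, 1, 1, 1], 3, 24),
            ([2, 2], 3, 0),  # all k_i < r
        ],
    )
    def test_against_direct_sums(self, k, r, expected):
        assert falling_factorial_sums(k, r) == expected

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            falling_factorial_sums([1, 1], 0)


class TestAsymptoticCount:
    def test_single_bond_limit_equals_exact_count(self):
        # M = 2, M_2 = 0: prefactor 2!/(1! * 2) = 1, corrections vanish
        assert asymptotic_count([1, 1]) == pytest.approx(1.0)
        assert count_exact(seq(v1=[2])) == 1

    def test_corrections_vanish_for_all_monovalent(self):
        k = [1] * 6
        m = sum(k)
        logpref = (
            math.lgamma(m + 1) - math.lgamma(m // 2 + 1) - (m / 2) * math.log(2)
        )
        assert log_asymptotic_count(k) == pytest.approx(logpref)

    def test_log_space_matches_direct_where_finite(self):
        for k in ([1, 1], [2, 2], [4, 1, 1, 1, 1], [3, 3, 2, 2]):
            direct = asymptotic_count(k, guard=None)
            assert math.exp(log_asymptotic_count(k)) == pytest.approx(
                direct, rel=1e-10
            )

    def test_odd_degree_sum_rejected(self):
        with pytest.raises(ValueError):
            asymptotic_count([1, 1, 1])

    def test_guard_refuses_correction_dominated_regime(self):
        # four hexavalent atoms: the M_2/M_3 corrections dwarf the prefactor
        with pytest.raises(AsymptoticUnreliable):
            asymptotic_count([6, 6, 6, 6])
        assert asymptotic_count([6, 6, 6, 6], force=True) > 0


class TestNonpureRelations:
    @pytest.mark.parametrize(
        "per_valence, expected",
        [
            ({4: [2], 1: [6]}, 1),          # pure
            ({1: [1, 1]}, 2),               # binom(2,1)
            ({1: [2, 1]}, 3),               # binom(3,2)*binom(1,1)
            ({1: [2, 1], 2: [2, 1]}, 9),    # two such valences
            ({1: [2, 2], 4: [1]}, 6),       # binom(4,2)
        ],
    )
    def test_multiplier(self, per_valence, expected):
        d = LabeledDegreeSequence.from_valence_counts(per_valence)
        assert nonpure_multiplier(d) == expected

    def test_path_length_unchanged_for_pure(self):
        d = seq(v4=[2], v1=[6])
        assert nonpure_path_length(d, 3.0) == 3.0

    def test_path_length_stretch_direct_value(self):
        d = seq(v1=[1, 1])  # N_P = 2, sum of degrees = 2
        assert nonpure_path_length(d, 3.0) == pytest.approx(
            3.0 * (1 + math.log(2) / 2)
        )

    def test_linearity_in_pure_path_length(self):
        d = seq(v4=[1], v1=[2, 2])
        assert nonpure_path_length(d, 4.0) == pytest.approx(
            2 * nonpure_path_length(d, 2.0)
        )

    def test_multiplier_bounds_exact_counts(self):
        # N_P * |U(d_U)| >= |U(d)| with equality iff every pure graph is
        # asymmetric; the methane star is maximally symmetric, so strict
        d = seq(v4=[1], v1=[2, 2])
        bound = nonpure_multiplier(d) * count_exact(d.pure_counterpart())
        assert bound >= count_exact(d)
        assert bound > count_exact(d)  # |Aut(star)| = 24 > 1


class TestHydrogenCorrection:
    def test_values(self):
        assert hydrogen_correction(10.0, 0) == 10.0
        assert hydrogen_correction(10.0, 1) == 10.0
        assert hydrogen_correction(12.0, 3) == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hydrogen_correction(1.0, -1)

    def test_monovalent_excess_examples(self):
        # ethane-like: the C2 core is realizable bare, so all 6 H are excess
        assert monovalent_excess(seq(v4=[2], v1=[6])) == 6
        # two monovalent atoms alone: the minimal realizable pairing itself
        assert monovalent_excess(seq(v1=[2])) == 0
        # lone tetravalent core needs monovalent partners: 4 minimum
        assert monovalent_excess(seq(v4=[1], v1=[4])) == 0


class TestCountFromPathLength:
    def test_inversion_at_unit_count(self):
        cal = DEFAULT_CALIBRATION
        l0 = -cal.b7 / cal.a7
        assert count_from_path_length(l0, cal) == pytest.approx(1.0)

    def test_strictly_increasing(self):
        vals = [count_from_path_length(l) for l in (0.0, 1.0, 2.0, 5.0)]
        assert vals == sorted(vals)
        assert len(set(vals)) == len(vals)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            CalibrationConstants(a7=-1.0)


class TestAveragePathLength:
    def test_single_graph_universe_is_zero(self):
        assert average_path_length(seq(v1=[2]), seed=0).value == 0.0

    def test_two_graph_universe_converges_to_exact_distance(self):
        # a universe with exactly 2 graphs: one tetravalent core, two
        # divalent bridges, two monovalent caps
        d = seq(v4=[1], v2=[2], v1=[2])
        graphs = enumerate_protomolecules(d)
        assert len(graphs) == 2
        delta = edit_distance_bnb(graphs[0], graphs[1]).value
        est = average_path_length(d, n_pairs=30, seed=1)
        assert est.value == pytest.approx(delta)

    def test_matches_exact_mean_pairwise_distance(self):
        d = seq(v4=[5], v1=[12])
        graphs = enumerate_protomolecules(d, cap=17)
        exact_pairs = [
            edit_distance_bnb(g1, g2).value
            for i, g1 in enumerate(graphs)
            for g2 in graphs[i + 1 :]
        ]
        exact_mean = float(np.mean(exact_pairs))
        est = average_path_length(d, seed=2)
        assert abs(est.value - exact_mean) <= 2.5 * max(est.stderr, 0.2)

    def test_unrealizable_rejected(self):
        with pytest.raises(ValueError):
            average_path_length(seq(v4=[1], v1=[1]))


class TestEstimateCount:
    def test_exact_tier_dispatch(self):
        rec = estimate_count(seq(v4=[5], v1=[12]), exact_cap=17)
        assert rec.tier == "exact"
        assert rec.count == 3

    def test_unrealizable_counts_zero(self):
        rec = estimate_count(seq(v4=[1], v1=[1]))
        assert rec.count == 0

    def test_base_tier_uses_stored_path_length(self):
        from rrspace.counting import CountRecord

        d = seq(v4=[6], v1=[14])  # 20 atoms: beyond the exact cap
        db = {d.key: CountRecord(key=d.key, tier="base", count=0, l_G=5.0)}
        rec = estimate_count(d, db=db, measure_cap=0)
        assert rec.tier == "base"
        assert rec.count == pytest.approx(count_from_path_length(5.0))

    def test_pure_tier_stretches_stored_pure_path_length(self):
        from rrspace.counting import CountRecord

        d = seq(v4=[6], v1=[10, 4])
        du = d.pure_counterpart()
        db = {du.key: CountRecord(key=du.key, tier="base", count=0, l_G=5.0)}
        rec = estimate_count(d, db=db, measure_cap=0)
        assert rec.tier == "pure"
        l_expected = nonpure_path_length(d, 5.0)
        assert rec.count == pytest.approx(count_from_path_length(l_expected))

    def test_asymptotic_tier_when_nothing_stored(self):
        d = seq(v4=[6], v1=[14])
        rec = estimate_count(d, measure_cap=0)
        assert rec.tier == "asymptotic"
        assert rec.count > 0


class TestRefit:
    def test_recovers_exact_line(self):
        cal = CalibrationConstants(a7=2.0, b7=1.0)
        records = [
            CalibrationRecord(seq(v1=[2]), math.exp(2.0 * l + 1.0), l)
            for l in np.linspace(0.5, 6.0, 12)
        ]
        fit = refit_calibration(records)
        assert fit.constants.a7 == pytest.approx(2.0, abs=1e-9)
        assert fit.constants.b7 == pytest.approx(1.0, abs=1e-9)
        assert fit.r2_count == pytest.approx(1.0)

    def test_rejects_degenerate_predictor(self):
        records = [
            CalibrationRecord(seq(v1=[2]), 10.0**i, 3.0) for i in range(12)
        ]
        with pytest.raises(ValueError, match="degenerate|constant"):
            refit_calibration(records)

    def test_rejects_narrow_dynamic_range(self):
        records = [
            CalibrationRecord(seq(v1=[2]), 10.0 + i, float(i)) for i in range(12)
        ]
        with pytest.raises(ValueError, match="orders of magnitude"):
            refit_calibration(records)
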