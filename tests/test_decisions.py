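"""Cell-decision rules: fitness factor, thresholds, transitions, mitosis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheromet import decisions as dec
from spheromet.cpm import Lattice
from spheromet.metabolism import INTERNAL_SPECIES
from spheromet.params import CellType, DecisionParameters


@pytest.fixture
def params():
    return DecisionParameters()


def make_cell_lattice(ctype=CellType.PCANCER, block=(4, 4, 5, 5), size=20):
    lat = Lattice(size, size)
    cid = lat.new_cell(ctype, target_volume=25.0, target_surface=20.0,
                       temp=9)
    lat.place_block(cid, *block)
    lat.recount()
    lat.attach_metabolism(np.zeros(len(INTERNAL_SPECIES)))
    return lat, cid


class TestFitnessFactor:
    def test_zero_substrate(self):
        assert dec.fitness_factor(0.0, 5.0, 0.1) == 0.0

    @pytest.mark.parametrize("a", [1.0, 2.0, 4.0])
    def test_half_saturation_symmetry(self, a):
        assert dec.fitness_factor(0.3, 2.0, 0.3, a) == pytest.approx(1.0)

    def test_quiescent_amplitude_ratio(self, params):
        from spheromet.metabolism import perceived_vmax

        x = 0.05
        fq = dec.fitness_factor(x, params.V_atpmax * perceived_vmax(
            CellType.QCANCER), params.atpK)
        fp = dec.fitness_factor(x, params.V_atpmax * perceived_vmax(
            CellType.PCANCER), params.atpK)
        assert fq / fp == pytest.approx(0.75)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x1=st.floats(0.0, 10.0), x2=st.floats(0.0, 10.0),
           vmax=st.floats(0.01, 100.0), k=st.floats(1e-6, 10.0),
           a=st.floats(1.0, 4.0))
    def test_monotone_and_bounded(self, x1, x2, vmax, k, a):
        f1 = dec.fitness_factor(x1, vmax, k, a)
        f2 = dec.fitness_factor(x2, vmax, k, a)
        assert 0.0 <= f1 <= vmax * (1 + 1e-12)  # bounded up to FP rounding
        if x1 <= x2:
            assert f1 <= f2 + 1e-12

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            dec.fitness_factor(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            dec.fitness_factor(1.0, 1.0, 1.0, a=0.5)


class TestThresholds:
    """Closed-form threshold formulas vs independent arithmetic."""

    def test_baseline_values(self, params):
        # independent arithmetic with the baseline parameter values
        qcp = 95.0 * 0.6 * (0.0628 / (0.0628 + 0.021))
        pne = 95.0 * 0.6 * (0.00095 / (0.00095 + 0.021))
        pnea = 168.2 * 15.393 * (2.22 / (2.22 + 0.064))
        assert dec.proliferation_threshold(params) == pytest.approx(qcp)
        assert dec.necrosis_threshold_atp(params) == pytest.approx(pne)
        assert dec.necrosis_threshold_acid(params) == pytest.approx(pnea)
        assert pnea == pytest.approx(2516.6, abs=0.5)

    def test_random_parameter_draws_match_oracle(self, rng):
        for _ in range(100):
            p = DecisionParameters(
                Total_time=float(rng.uniform(50, 240)),
                V_atpmax=float(rng.uniform(0.01, 4.2)),
                Pos_conc=float(rng.uniform(0.006, 0.2)),
                atpK=float(rng.uniform(0.001, 0.1)),
                Neg_concATP=float(rng.uniform(1e-4, 0.015)),
                Total_timelac=float(rng.uniform(50, 240)),
                V_lacmax=float(rng.uniform(0.01, 28)),
                Pos_concLac=float(rng.uniform(0.13, 2.75)),
            )
            assert dec.proliferation_threshold(p) == pytest.approx(
                p.Total_time * p.V_atpmax * p.Pos_conc / (p.Pos_conc + p.atpK),
                rel=1e-12,
            )
            assert dec.necrosis_threshold_atp(p) == pytest.approx(
                p.Total_time * p.V_atpmax * p.Neg_concATP
                / (p.Neg_concATP + p.atpK), rel=1e-12,
            )
            assert dec.necrosis_threshold_acid(p) == pytest.approx(
                p.Total_timelac * p.V_lacmax * p.Pos_concLac
                / (p.Pos_concLac + p.LacK), rel=1e-12,
            )

    def test_saturation_limits(self, params):
        params.Pos_conc = 1e9
        assert dec.proliferation_threshold(params) == pytest.approx(
            95.0 * 0.6, rel=1e-6
        )
        params.Pos_conc = params.atpK
        assert dec.proliferation_threshold(params) == pytest.approx(28.5)

    def test_quiescent_necrosis_thresholds_higher(self, params):
        assert dec.necrosis_threshold_atp(params, quiescent=True) > \
            dec.necrosis_threshold_atp(params, quiescent=False)
        assert dec.necrosis_threshold_acid(params, quiescent=True) > \
            dec.necrosis_threshold_acid(params, quiescent=False)

    def test_zero_reference_concentration(self, params):
        params.Neg_concATP = 0.0
        assert dec.necrosis_threshold_atp(params) == 0.0


class TestAccumulation:
    def test_healthy_cell_gains_only_health(self, params):
        lat, cid = make_cell_lattice()
        dec.accumulate_attributes(lat, cid, atp=0.1, ext_lactate=0.0, p=params)
        assert lat.health[cid] > 0
        assert lat.starvation[cid] == 0
        assert lat.acidity[cid] == 0
        expected = np.exp(6.0) * dec.fitness_factor(0.1, 0.6, 0.021)
        assert lat.health[cid] == pytest.approx(expected)

    def test_starving_cell_gains_only_starvation(self, params):
        lat, cid = make_cell_lattice()
        dec.accumulate_attributes(lat, cid, atp=0.001, ext_lactate=0.0, p=params)
        assert lat.starvation[cid] > 0
        assert lat.health[cid] == 0

    def test_acidity_half_saturation(self, params):
        lat, cid = make_cell_lattice()
        params.LacDeath = 0.01  # below the test exposure
        dec.accumulate_attributes(lat, cid, atp=0.1,
                                  ext_lactate=params.LacK, p=params)
        assert lat.acidity[cid] == pytest.approx(params.V_lacmax / 2)

    def test_accumulators_monotone_between_resets(self, params):
        lat, cid = make_cell_lattice()
        prev = 0.0
        for atp in (0.1, 0.05, 0.2, 0.03):
            dec.accumulate_attributes(lat, cid, atp=atp, ext_lactate=0.0,
                                      p=params)
            assert lat.health[cid] >= prev
            prev = lat.health[cid]


class TestGrowthAndShrink:
    def test_growth_increment(self, params):
        lat, cid = make_cell_lattice()
        dec.growth_update(lat, cid, growth_sum=0.19983, p=params)
        assert lat.target_volume[cid] == pytest.approx(26.5)

    def test_no_growth_at_threshold(self, params):
        lat, cid = make_cell_lattice()
        dec.growth_update(lat, cid, growth_sum=params.PGrThr, p=params)
        assert lat.target_volume[cid] == 25.0

    def test_quiescent_cells_never_grow(self, params):
        lat, cid = make_cell_lattice(CellType.QCANCER)
        dec.growth_update(lat, cid, growth_sum=10.0, p=params)
        assert lat.target_volume[cid] == 25.0

    def test_necrotic_shrink_rate(self, params):
        lat, cid = make_cell_lattice(CellType.NECROTIC)
        dec.necrotic_shrink(lat, cid, params)
        assert lat.target_volume[cid] == pytest.approx(24.975)

    def test_core_cell_floors_at_quarter_volume(self, params):
        lat, cid = make_cell_lattice(CellType.NECROTIC)
        lat.at_periphery[cid] = False
        for _ in range(2000):
            dec.necrotic_shrink(lat, cid, params)
        assert lat.target_volume[cid] == pytest.approx(0.25 * params.V_normal)

    def test_periphery_cell_cleared_at_zero(self, params):
        lat, cid = make_cell_lattice(CellType.NECROTIC)
        lat.at_periphery[cid] = True
        removed = False
        for _ in range(1200):
            if dec.necrotic_shrink(lat, cid, params):
                removed = True
                break
        assert removed
        assert not lat.alive[cid]
        assert (lat.owner != cid).all()  # sites returned to Medium


class TestStress:
    def test_no_stress_below_neighbor_count(self, params):
        lat, cid = make_cell_lattice()
        for _ in range(100):
            dec.stress_update(lat, cid, neighbor_count=params.N, p=params)
        assert lat.stress[cid] == 0.0

    def test_necrosis_after_54_consecutive_crowded_steps(self, params):
        # smallest m with 0.95 * m > 50.5 is 54
        lat, cid = make_cell_lattice()
        for step in range(1, 60):
            dec.stress_update(lat, cid, neighbor_count=params.N + 1, p=params)
            flagged = lat.stress[cid] > params.StressThr
            if step < 54:
                assert not flagged
            else:
                assert flagged
                break

    def test_relief_resets_streak(self, params):
        lat, cid = make_cell_lattice()
        for _ in range(53):
            dec.stress_update(lat, cid, neighbor_count=9, p=params)
        dec.stress_update(lat, cid, neighbor_count=2, p=params)
        assert lat.stress[cid] == 0.0


class TestTransitions:
    def test_quiescent_wakes_at_health_threshold(self, params):
        lat, cid = make_cell_lattice(CellType.QCANCER)
        lat.health[cid] = dec.proliferation_threshold(params)
        new = dec.evaluate_transitions(lat, cid, params)
        assert new == CellType.PCANCER
        assert lat.health[cid] == 0.0  # attributes reset

    def test_qstem_wakes_to_pstem(self, params):
        lat, cid = make_cell_lattice(CellType.QSTEM)
        lat.health[cid] = dec.proliferation_threshold(params) + 1
        assert dec.evaluate_transitions(lat, cid, params) == CellType.PSTEM

    def test_starvation_necrosis(self, params):
        lat, cid = make_cell_lattice(CellType.PCANCER)
        lat.starvation[cid] = dec.necrosis_threshold_atp(params)
        assert dec.evaluate_transitions(lat, cid, params) == CellType.NECROTIC
        assert lat.starvation[cid] == 0.0

    def test_below_thresholds_no_change(self, params):
        lat, cid = make_cell_lattice(CellType.QCANCER)
        lat.health[cid] = 1.0
        lat.starvation[cid] = 1.0
        assert dec.evaluate_transitions(lat, cid, params) == CellType.QCANCER

    def test_necrosis_irreversible(self, params):
        lat, cid = make_cell_lattice(CellType.NECROTIC)
        lat.health[cid] = 1e9
        lat.starvation[cid] = 1e9
        for _ in range(10):
            assert dec.evaluate_transitions(lat, cid, params) == CellType.NECROTIC

    def test_quiescent_uses_higher_necrosis_threshold(self, params):
        lat, cid = make_cell_lattice(CellType.QCANCER)
        lat.starvation[cid] = dec.necrosis_threshold_atp(params) * 1.2
        # above the proliferating threshold but below the 1.5x quiescent one
        assert dec.evaluate_transitions(lat, cid, params) == CellType.QCANCER


class TestMitosis:
    def _grown_cell(self, ctype=CellType.PCANCER, temp=9):
        lat = Lattice(30, 30)
        cid = lat.new_cell(ctype, target_volume=50.0, target_surface=30.0,
                           temp=temp)
        lat.place_block(cid, 8, 8, 10, 5)  # 50 voxels, at doubling volume
        lat.recount()
        lat.attach_metabolism(np.full(len(INTERNAL_SPECIES), 0.3))
        return lat, cid

    def test_division_conserves_volume_and_state(self, params, rng):
        lat, cid = self._grown_cell()
        pre_volume = int(lat.volume[cid])
        pre_conc = lat.conc[cid].copy()
        did = dec.mitosis(lat, cid, rng, params)
        assert did is not None
        assert int(lat.volume[cid] + lat.volume[did]) == pre_volume
        assert abs(int(lat.volume[cid]) - int(lat.volume[did])) <= 1
        np.testing.assert_array_equal(lat.conc[cid], pre_conc)
        np.testing.assert_array_equal(lat.conc[did], pre_conc)
        # both cells quiescent, attributes reset
        assert CellType(lat.ctype[cid]) == CellType.QCANCER
        assert CellType(lat.ctype[did]) == CellType.QCANCER
        for arr in (lat.health, lat.starvation, lat.acidity, lat.stress):
            assert arr[cid] == 0.0 and arr[did] == 0.0

    def test_stem_differentiation_scripted_rng(self, params):
        class Scripted:
            def __init__(self, u):
                self.u = u

            def uniform(self, a, b):
                return (a + b) / 2

            def random(self):
                return self.u

            def normal(self, m, s):
                return m

        lat, cid = self._grown_cell(CellType.PSTEM)
        did = dec.mitosis(lat, cid, Scripted(0.4), params)  # 0.4 <= probstem
        assert CellType(lat.ctype[cid]) == CellType.QSTEM
        assert CellType(lat.ctype[did]) == CellType.QSTEM
        lat, cid = self._grown_cell(CellType.PSTEM)
        did = dec.mitosis(lat, cid, Scripted(0.9), params)  # 0.9 > probstem
        assert CellType(lat.ctype[did]) == CellType.QCANCER

    def test_senescence_turns_cell_necrotic(self, params, rng):
        lat, cid = self._grown_cell(temp=3)
        lat.divisions[cid] = 3
        did = dec.mitosis(lat, cid, rng, params)
        assert did is None
        assert CellType(lat.ctype[cid]) == CellType.NECROTIC

    def test_non_proliferating_cell_rejected(self, params, rng):
        lat, cid = self._grown_cell(CellType.QCANCER)
        with pytest.raises(ValueError):
            dec.mitosis(lat, cid, rng, params)

    def test_temp_draw_integerized_gaussian(self, params, rng):
        draws = np.array([dec.draw_temp(rng, params) for _ in range(4000)])
        assert draws.dtype.kind == "i"
        assert abs(draws.mean() - params.maxdiv) < 0.15
        assert abs(draws.std() - 2.0) < 0.15

    def test_doubling_volume_trigger_constant(self, params):
        assert params.Pvolmaxmit == 2.0 * params.V_normal
        assert params.Svolmaxmit == params.Pvolmaxmit
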