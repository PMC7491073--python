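"""Turn propagation: labeling patterns, normalization, label balance."""

from dataclasses import replace

import numpy as np
import pytest

from tracemet.network import distribution_to_mid
from tracemet.propagate import (
    POOL_NAMES,
    FluxParameterSet,
    glucose_tracer,
    glutamate_tracer,
    glutamine_tracer,
    initial_state,
    propagate_turn,
    simulate_experiment,
)


def pure_glucose_params(n_turns=1, **overrides):
    """All pyruvate from glucose, all alpha-KG from citrate, no dilution."""
    defaults = dict(
        f_glycolysis=1.0,
        f_accoa_dilution=0.0,
        w_cit=1.0,
        w_glu_in=0.0,
        w_dil=0.0,
        n_turns=n_turns,
    )
    defaults.update(overrides)
    return FluxParameterSet(**defaults)


def labeled_masses(mid, atol=1e-12):
    return {i for i, f in enumerate(mid) if i > 0 and f > atol}


class TestFirstTurn:
    def test_glucose_turn1_m2_and_m3_pattern(self):
        """Turn 1: lactate M+3; alpha-KG, succinate, OAA, glutamate, aspartate
        pure M+2 among labeled species."""
        mids = simulate_experiment(glucose_tracer(purity=1.0), pure_glucose_params(1))
        assert labeled_masses(mids["lactate"]) == {3}
        assert labeled_masses(mids["alanine"]) == {3}
        for met in ("akg", "succinate", "fumarate", "malate", "oaa", "glutamate", "aspartate"):
            assert labeled_masses(mids[met]) == {2}, met

    def test_glucose_turn2_introduces_m3_m4(self):
        """Turn 2: labeled OAA condenses again -> alpha-KG gains M+3 and M+4
        while succinate/fumarate/malate/aspartate gain M+3."""
        turn1 = simulate_experiment(glucose_tracer(purity=1.0), pure_glucose_params(1))
        mids = simulate_experiment(glucose_tracer(purity=1.0), pure_glucose_params(2))
        assert labeled_masses(turn1["akg"]) == {2}
        assert {2, 3, 4} <= labeled_masses(mids["akg"])
        for met in ("succinate", "fumarate", "malate", "aspartate"):
            assert 3 not in labeled_masses(turn1[met]), met
            assert 3 in labeled_masses(mids[met]), met

    def test_glutamine_tracer_m5_chain(self):
        """Glutamine -> glutamate M+5 -> alpha-KG M+5 -> succinate M+4."""
        params = FluxParameterSet(n_turns=2)
        mids = simulate_experiment(glutamine_tracer(purity=1.0), params)
        assert mids["glutamate"][5] > 0
        assert mids["akg"][5] > 0
        assert mids["succinate"][4] > 0

    def test_glutamate_tracer_labels_glutamate_directly(self):
        params = FluxParameterSet(n_turns=1)
        mids = simulate_experiment(glutamate_tracer(purity=1.0), params)
        assert mids["glutamate"][5] > 0
        assert mids["glutamine"][5] == pytest.approx(0.0, abs=1e-12)  # no GS in neurons


class TestEdgeCases:
    def test_zero_turns_all_unlabeled(self):
        mids = simulate_experiment(glucose_tracer(), FluxParameterSet(n_turns=0))
        for met, mid in mids.items():
            assert mid[0] == pytest.approx(1.0), met

    def test_zero_purity_rejected_but_tiny_purity_inert(self):
        with pytest.raises(ValueError):
            glucose_tracer(purity=0.0)
        mids = simulate_experiment(glucose_tracer(purity=1e-12), FluxParameterSet(n_turns=3))
        for met, mid in mids.items():
            assert mid[0] == pytest.approx(1.0, abs=1e-9), met

    def test_invalid_weight_sum_raises(self):
        with pytest.raises(ValueError):
            FluxParameterSet(w_cit=0.5, w_glu_in=0.5, w_dil=0.5)

    def test_missing_pool_raises(self):
        state = initial_state()
        del state["oaa"]
        with pytest.raises(ValueError, match="oaa"):
            propagate_turn(state, FluxParameterSet(), glucose_tracer())

    def test_lactate_m3_closed_form_single_turn(self):
        """Turn 1 lactate M+3 = (1-rho_lac) * (1-rho_pyr) * f_glycolysis * purity:
        the glucose-derived share of new pyruvate, passed once through LDH."""
        params = FluxParameterSet(f_glycolysis=0.7, rho=0.4, n_turns=1)
        mids = simulate_experiment(glucose_tracer(purity=0.98), params)
        assert mids["lactate"][3] == pytest.approx(0.6 * 0.6 * 0.7 * 0.98, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("tracer_factory", [glucose_tracer, glutamine_tracer, glutamate_tracer])
    def test_states_normalized_every_turn(self, tracer_factory, control_params):
        state = initial_state()
        cfg = tracer_factory()
        for _ in range(5):
            state, _ = propagate_turn(state, control_params, cfg)
            for met, dist in state.items():
                assert dist.sum() == pytest.approx(1.0, abs=1e-9), met
                assert np.all(dist >= -1e-15)

    @pytest.mark.parametrize("tracer_factory", [glucose_tracer, glutamine_tracer, glutamate_tracer])
    def test_label_balance_per_turn(self, tracer_factory, control_params):
        """13C inflow = pool-weighted 13C change + displaced 13C + labeled CO2."""
        state = initial_state()
        cfg = tracer_factory()
        for _ in range(4):
            state, audit = propagate_turn(state, control_params, cfg)
            assert audit.balance_residual() == pytest.approx(0.0, abs=1e-9)
            assert audit.co2_labeled >= 0.0

    def test_enrichment_nondecreasing_with_labeled_inflow(self):
        """With only labeled inflow and zero unlabeled dilution, fractional
        enrichment of every cycle pool is non-decreasing over turns."""
        params = pure_glucose_params(
            1, f_pag=0.3, f_glu_from_akg=0.4, f_uptake_glu=0.3, f_uptake_gln=1.0
        )
        cfg = glucose_tracer(purity=1.0)
        state = initial_state()
        prev = {m: 0.0 for m in POOL_NAMES}
        for _ in range(6):
            state, _ = propagate_turn(state, params, cfg)
            for met, dist in state.items():
                enrich = 1.0 - distribution_to_mid(dist)[0]
                assert enrich >= prev[met] - 1e-12, met
                prev[met] = enrich

    def test_succinate_fumarate_mids_symmetric_states(self):
        from tracemet.network import reverse_permutation

        cfg = glucose_tracer()
        state = simulate_experiment(cfg, FluxParameterSet(n_turns=3), return_positional=True)
        for met in ("fumarate", "malate"):
            dist = state[met]
            np.testing.assert_allclose(dist, dist[reverse_permutation(4)], atol=1e-12)

    def test_astrocyte_mode_synthesizes_glutamine_from_glutamate(self):
        """GS is active in astrocytes: the glutamate tracer labels glutamine
        M+5, and the disease preset's elevated uptake raises glutamate M+5."""
        from tracemet.presets import control_flux_params, ftd3_flux_params

        ctrl = control_flux_params("astrocyte")
        ftd = ftd3_flux_params("astrocyte")
        cfg = glutamate_tracer(cell_type="astrocyte")
        c = simulate_experiment(cfg, ctrl)
        f = simulate_experiment(cfg, ftd)
        assert c["glutamine"][5] > 0
        assert f["glutamine"][5] > c["glutamine"][5]  # GS conversion elevated
        assert f["glutamate"][5] > c["glutamate"][5]  # uptake elevated

    def test_deterministic(self, control_params, glucose_cfg):
        a = simulate_experiment(glucose_cfg, control_params)
        b = simulate_experiment(glucose_cfg, control_params)
        for met in a:
            np.testing.assert_array_equal(a[met], b[met])
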