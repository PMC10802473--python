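"""Circuit model: genotype overrides, derivatives, steady state, simulation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsrkit.model_core import (
    SPECIES,
    StrainGenotype,
    StressProtocol,
    SystemState,
    basal_steady_state,
    derivatives,
    make_parameters,
    simulate,
    stress_multiplier,
)


class TestGenotypes:
    def test_wild_type_is_identity(self, base_params):
        gt = StrainGenotype("WT", "WT")
        assert make_parameters(gt, base_params) == base_params

    def test_aux_mutant_scales_only_release_rate(self, base_params):
        gt = StrainGenotype("fes1_dHSE", "AUX_DHSE", release_scale=0.3)
        p = make_parameters(gt, base_params)
        assert p.k_rel == 0.3 * base_params.k_rel
        for f in dataclasses.fields(p):
            if f.name != "k_rel":
                assert getattr(p, f.name) == getattr(base_params, f.name)

    def test_hsp70_dfbl_preserves_basal_chaperone_pool(self, base_params, basal_state):
        p = make_parameters(StrainGenotype("dfbl", "HSP70_DFBL"), base_params)
        assert p.beta1 == 0.0
        mutant_ss = basal_steady_state(p)
        assert mutant_ss.total_hsp70 == pytest.approx(
            basal_state.total_hsp70, rel=0.01
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="x", kind="SOMETHING_ELSE"),
            dict(name="x", kind="AUX_DHSE"),                      # missing scale
            dict(name="x", kind="AUX_DHSE", release_scale=1.5),   # out of (0, 1]
            dict(name="x", kind="HSP70_DFBL", release_scale=0.5),
            dict(name="x", kind="WT", release_scale=0.5),
        ],
    )
    def test_invalid_genotypes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StrainGenotype(**kwargs)


class TestStressMultiplier:
    def test_schedule(self, base_params):
        heat = StressProtocol("heat", t_on=30.0, sample_times=[0, 30, 60])
        none = StressProtocol("none", sample_times=[0, 60])
        eth = StressProtocol("ethanol", t_on=0.0, sample_times=[0, 60])
        assert stress_multiplier(none, base_params, 100.0) == 1.0
        assert stress_multiplier(heat, base_params, 10.0) == 1.0
        assert stress_multiplier(heat, base_params, 30.0) == base_params.s_heat
        assert stress_multiplier(heat, base_params, 200.0) == base_params.s_heat
        # onset is inclusive
        assert stress_multiplier(eth, base_params, 0.0) == base_params.s_eth

    def test_negative_time_rejected(self, base_params, heat_protocol):
        with pytest.raises(ValueError):
            stress_multiplier(heat_protocol, base_params, -1.0)


class TestDerivatives:
    def test_zero_at_basal_fixed_point(self, base_params, basal_state):
        rates = derivatives(basal_state, base_params, 1.0)
        assert np.max(np.abs(rates.to_array())) < 1e-9

    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=7, max_size=7)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_hsf1_conservation_by_construction(self, values):
        from hsrkit import calibration as cal

        state = SystemState(*values)
        rates = derivatives(state, cal.default_parameters(), 5.0)
        assert rates.Ff + rates.HF == pytest.approx(0.0, abs=1e-12)

    def test_high_client_load_fully_derepresses_hsf1(self, base_params):
        # U >> K_sis: the affinity switch shuts binding off, so the only HF
        # flux left is dissociation and dilution
        state = SystemState(U=1e9, Hf=10.0, HU=1.0, HF=0.5, Ff=0.5, Y=1.0, Ym=1.0)
        rates = derivatives(state, base_params, 1.0)
        expected = -(base_params.k_uF + base_params.gamma) * state.HF
        assert rates.HF == pytest.approx(expected, rel=1e-12)


class TestBasalSteadyState:
    def test_residual_below_tolerance(self, base_params, basal_state):
        rates = derivatives(basal_state, base_params, 1.0)
        assert np.max(np.abs(rates.to_array())) < 1e-8
        assert basal_state.Ym > 0

    def test_state_persists_under_further_integration(self, base_params, basal_state):
        protocol = StressProtocol("none", sample_times=np.array([0.0, 50.0, 100.0]))
        traj = simulate(base_params, protocol, initial_state=basal_state)
        ref = basal_state.to_array()
        rel = np.abs(traj.states - ref) / (np.abs(ref) + 1e-12)
        assert rel.max() < 1e-6

    def test_hsf1_mostly_repressed_basally(self, base_params, basal_state):
        assert basal_state.Ff / base_params.F_tot < 0.5


class TestSimulate:
    def test_no_stress_reporter_flat(self, base_params):
        protocol = StressProtocol(
            "none", sample_times=np.linspace(0.0, 240.0, 9)
        )
        traj = simulate(base_params, protocol)
        assert np.all(traj.yfp_fold_change >= 0.999)
        assert np.all(traj.yfp_fold_change <= 1.001)

    def test_matches_fixed_step_rk4_oracle(
        self, base_params, heat_protocol, wt_traj, rk4_integrate
    ):
        rk4 = rk4_integrate(base_params, heat_protocol, dt=0.01)
        scale = np.maximum(np.abs(rk4), 1e-6)
        assert (np.abs(wt_traj.states - rk4) / scale).max() < 1e-4

    def test_reduced_release_elevates_reporter(self, traj_cache):
        assert (
            traj_cache(0.2).yfp_fold_change[-1] > traj_cache(1.0).yfp_fold_change[-1]
        )

    def test_fold_change_starts_at_one_exactly(self, wt_traj):
        assert wt_traj.yfp_fold_change[0] == 1.0

    def test_frames_round_trip(self, wt_traj):
        wide = wt_traj.to_wide_frame()
        tidy = wt_traj.to_tidy_frame()
        assert list(wide["time_min"]) == list(wt_traj.times)
        assert set(tidy["species"]) == set(SPECIES) | {"yfp_fold_change"}

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(stress_type="warp", sample_times=[0, 10]),
            dict(stress_type="heat", sample_times=[10, 20]),      # no t=0
            dict(stress_type="heat", sample_times=[0, 20, 20]),   # not increasing
            dict(stress_type="heat", t_on=-5.0, sample_times=[0, 20]),
        ],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StressProtocol(**kwargs)


class TestCircuitBehaviors:
    """The feedback phenotypes the circuit is built to reproduce."""

    def test_conservation_and_nonnegativity(self, base_params, traj_cache):
        dfbl = make_parameters(StrainGenotype("d", "HSP70_DFBL"), base_params)
        trajs = [traj_cache(1.0), traj_cache(0.3), traj_cache(1.0, params=dfbl)]
        for traj in trajs:
            total_hsf1 = traj.species("Ff") + traj.species("HF")
            drift = np.abs(total_hsf1 - traj.params.F_tot) / traj.params.F_tot
            assert drift.max() < 1e-6
            assert traj.states.min() >= 0.0  # clipped at -1e-9 solver noise

    def test_core_feedback_adapts_but_broken_loop_does_not(
        self, base_params, wt_traj, traj_cache
    ):
        dfbl = make_parameters(StrainGenotype("d", "HSP70_DFBL"), base_params)
        wt_rate = wt_traj.hse_transcription_rate
        dfbl_rate = traj_cache(1.0, params=dfbl).hse_transcription_rate
        assert wt_rate[-1] < 2.0 * wt_rate[0]
        assert dfbl_rate[-1] > 2.0 * dfbl_rate[0]

    @pytest.mark.parametrize("scale", [0.2, 0.3, 0.5])
    def test_broken_core_loop_dominates_auxiliary_mutants(
        self, base_params, traj_cache, scale
    ):
        dfbl = make_parameters(StrainGenotype("d", "HSP70_DFBL"), base_params)
        assert (
            traj_cache(1.0, params=dfbl).yfp_fold_change[-1]
            > traj_cache(scale).yfp_fold_change[-1]
        )

    def test_endpoint_monotone_in_release_rate(self, base_params, heat_protocol):
        # coarse grid here; the full 100-point grid runs in the acceptance suite
        scales = np.geomspace(0.01, 10.0, 12)
        fc240 = [
            simulate(
                base_params.replace(k_rel=base_params.k_rel * s), heat_protocol
            ).yfp_fold_change[-1]
            for s in scales
        ]
        assert np.all(np.diff(fc240) <= 1e-6)
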