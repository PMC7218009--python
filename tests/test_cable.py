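"""Cable engine: discretization, implicit integration, clamp, resistance."""

import math

import numpy as np
import pytest

from picloop import cable, morphology as mo
from picloop.biophysics import MembraneSpec, PassiveParams
from picloop.errors import ParameterError

UNIFORM = PassiveParams(rm_soma=10000.0, rm_dend=10000.0, ri=100.0)


def sealed_cable_tree(length_um=1500.0, diam=4.0):
    return mo.NeuriteTree([
        mo.Section(0, None, mo.SOMA, 30.0, 30.0, 30.0),
        mo.Section(1, 0, mo.DENDRITE, length_um, diam, diam),
    ])


def passive_spec(pas=UNIFORM):
    spec = MembraneSpec(passive=pas)
    for name in spec.channels:
        spec.channels[name] = spec.channels[name].__class__(
            **{**spec.channels[name].__dict__, "gbar": 0.0})
    return spec


class TestDiscretize:
    def test_segment_count_matches_bound(self):
        tree = sealed_cable_tree()
        model = cable.discretize(tree, MembraneSpec(passive=UNIFORM), 0.1)
        pas = UNIFORM
        lam_dc = math.sqrt(10000.0 * 4e-4 / 400.0)
        tau = 10.0
        w = 2 * math.pi * 0.1
        lam_ac = lam_dc / math.sqrt(0.5 * (1 + math.sqrt(1 + (w * tau) ** 2)))
        expected = math.ceil(0.15 / (0.1 * lam_ac))
        n_dend = int(np.sum(model.kind == 1))
        assert n_dend == expected

    def test_tightening_bound_increases_compartments(self):
        tree = mo.generate_synthetic_tree(n_stems=2, branch_depth=1, seed=1)
        spec = MembraneSpec()
        n_coarse = cable.discretize(tree, spec, 0.2).n
        n_fine = cable.discretize(tree, spec, 0.1).n
        assert n_fine >= n_coarse

    def test_bound_validation(self):
        tree = sealed_cable_tree()
        with pytest.raises(ParameterError):
            cable.discretize(tree, MembraneSpec(), 0.5)

    def test_membrane_area_preserved(self):
        tree = mo.generate_synthetic_tree(n_stems=3, branch_depth=2, seed=2)
        model = cable.discretize(tree, MembraneSpec(), 0.15)
        assert model.total_area() == pytest.approx(tree.total_area() * 1e-8,
                                                   rel=1e-3)

    def test_steady_state_matches_sealed_end_analytic(self):
        """Soma-injected current: V(x) ∝ cosh((L-X)/λ)/cosh(L/λ), < 1% error."""
        tree = sealed_cable_tree(length_um=2000.0)
        model = cable.discretize(tree, passive_spec(), 0.05)
        i = np.zeros(model.n)
        i[0] = 1.0
        v = cable.passive_steady_state(model, i) - UNIFORM.e_leak
        lam_um = math.sqrt(10000.0 * 4e-4 / 400.0) * 1e4
        dend = model.kind == 1
        x = model.path_um[dend] - 15.0  # from the soma surface
        L = 2000.0 / lam_um
        analytic = np.cosh(L - x / lam_um) / np.cosh(L)
        ratio = v[dend] / v[dend][0]
        analytic = analytic / analytic[0]
        assert np.max(np.abs(ratio - analytic)) < 0.01


class TestAdvance:
    def test_rc_charging_step(self):
        """Single passive compartment follows V = V_rest + IR(1-e^(-t/RC))."""
        tree = mo.NeuriteTree([mo.Section(0, None, mo.SOMA, 50.0, 50.0, 50.0)])
        spec = passive_spec(PassiveParams(rm_soma=10000.0, rm_dend=10000.0))
        model = cable.discretize(tree, spec, 0.1)
        traces, _ = cable.run(model, 40.0, dt=0.025, i_soma=1.0, mode="passive")
        area = model.area[0]
        R = 10000.0 / area / 1e6  # MΩ
        tau = 10.0  # ms: Rm*Cm
        t = traces.t
        expected = spec.passive.e_leak + 1.0 * R * (1 - np.exp(-t / tau))
        err = np.abs(traces.channels["v_soma"][1:] - expected[1:])
        assert np.max(err / (1.0 * R)) < 0.005

    def test_zero_drive_fixed_point(self):
        tree = sealed_cable_tree()
        model = cable.discretize(tree, passive_spec(), 0.1)
        st0 = model.initial_state()
        st1 = cable.advance(model, st0, {"mode": "passive"})
        assert np.allclose(st1.v, st0.v, atol=1e-12)

    def test_symmetric_two_branch_voltages_identical(self):
        tree = mo.NeuriteTree([
            mo.Section(0, None, mo.SOMA, 30.0, 30.0, 30.0),
            mo.Section(1, 0, mo.DENDRITE, 800.0, 4.0, 4.0),
            mo.Section(2, 0, mo.DENDRITE, 800.0, 4.0, 4.0),
        ])
        model = cable.discretize(tree, passive_spec(), 0.1)
        traces, state = cable.run(model, 20.0, dt=0.025, i_soma=2.0, mode="passive")
        b1 = state.v[model.kind == 1]
        half = len(b1) // 2
        assert np.allclose(b1[:half], b1[half:], atol=1e-9)

    def test_nan_reported_with_location(self):
        tree = sealed_cable_tree()
        model = cable.discretize(tree, MembraneSpec(passive=UNIFORM), 0.1)
        with pytest.raises(cable.IntegrationError, match="compartment"):
            cable.run(model, 5.0, dt=0.025, i_soma=1e9)


class TestRun:
    def test_suprathreshold_constant_current_periodic(self, calibrated):
        model = calibrated.model
        traces, _ = cable.run(model, 2000.0, dt=0.025, i_soma=15.0)
        sp = traces.spikes[traces.spikes > 1000.0]
        assert len(sp) >= 4
        isi = np.diff(sp)
        assert np.max(np.abs(isi - isi.mean())) / isi.mean() < 0.01

    def test_subthreshold_no_spikes(self, calibrated):
        traces, _ = cable.run(calibrated.model, 500.0, dt=0.025, i_soma=2.0)
        assert len(traces.spikes) == 0

    def test_determinism_prefix(self, calibrated):
        model = calibrated.model
        t1, _ = cable.run(model, 200.0, dt=0.05, i_soma=12.0)
        t2, _ = cable.run(model, 400.0, dt=0.05, i_soma=12.0)
        n = len(t1.channels["v_soma"])
        assert np.array_equal(t1.channels["v_soma"], t2.channels["v_soma"][:n])

    def test_duration_must_be_multiple_of_dt(self, calibrated):
        with pytest.raises(ParameterError):
            cable.run(calibrated.model, 10.013, dt=0.025)

    def test_spike_times_converge_under_dt_refinement(self, calibrated):
        """First spike moves < 0.1 ms when dt halves; later-spike phase
        drift shrinks with dt (temporal convergence)."""
        model = calibrated.model
        a, _ = cable.run(model, 600.0, dt=0.025, i_soma=14.0)
        b, _ = cable.run(model, 600.0, dt=0.0125, i_soma=14.0)
        c, _ = cable.run(model, 600.0, dt=0.00625, i_soma=14.0)
        n = min(len(a.spikes), len(b.spikes), len(c.spikes))
        assert n >= 3
        assert abs(a.spikes[0] - b.spikes[0]) < 0.1
        drift_ab = np.max(np.abs(a.spikes[:n] - b.spikes[:n]))
        drift_bc = np.max(np.abs(b.spikes[:n] - c.spikes[:n]))
        assert drift_bc < drift_ab


class TestVoltageClamp:
    def test_passive_compartment_holds_ohmic_current(self):
        tree = mo.NeuriteTree([mo.Section(0, None, mo.SOMA, 50.0, 50.0, 50.0)])
        spec = passive_spec(PassiveParams(rm_soma=10000.0, rm_dend=10000.0))
        model = cable.discretize(tree, spec, 0.1)
        vc = -50.0
        tr = cable.voltage_clamp(model, vc, 50.0, dt=0.025, mode="passive")
        g_uS = 1e6 * model.area[0] / 10000.0
        expected = g_uS * (vc - spec.passive.e_leak)
        assert tr.channels["i_clamp"][-1] == pytest.approx(expected, rel=1e-6)

    def test_clamp_at_rest_zero_current(self, calibrated):
        model = calibrated.model
        tr = cable.voltage_clamp(model, model.spec.passive.e_leak, 50.0,
                                 dt=0.05, mode="passive")
        assert abs(tr.channels["i_clamp"][-1]) < 1e-9

    def test_dendritic_synaptic_current_attenuates_to_soma(self, calibrated):
        """Clamp current from a distal conductance is below the current
        delivered at the synapse (passive attenuation)."""
        from picloop.protocols import measure_effective_synaptic_current

        model = calibrated.model
        i_n = measure_effective_synaptic_current(model, syn_density=0.2)[-1]
        idx = model.band_idx
        v_rest = model.spec.passive.e_leak
        delivered = np.sum(0.2 * model.g_syn_unit[idx]) * (0.0 - v_rest) * -1
        delivered = abs(delivered)
        assert 0 < i_n < delivered


class TestInputResistance:
    def test_isolated_compartment_exact(self):
        tree = mo.NeuriteTree([mo.Section(0, None, mo.SOMA, 50.0, 50.0, 50.0)])
        spec = passive_spec(PassiveParams(rm_soma=10000.0, rm_dend=10000.0))
        model = cable.discretize(tree, spec, 0.1)
        expected = 10000.0 / model.area[0] / 1e6  # MΩ
        assert cable.input_resistance(model, 0) == pytest.approx(expected, rel=1e-9)

    def test_sealed_end_exceeds_middle(self):
        tree = sealed_cable_tree(length_um=2000.0)
        model = cable.discretize(tree, passive_spec(), 0.05)
        dend = np.nonzero(model.kind == 1)[0]
        mid = dend[len(dend) // 2]
        end = dend[-1]
        assert cable.input_resistance(model, int(end)) > \
            cable.input_resistance(model, int(mid))

    def test_dendritic_input_resistance_grows_with_path(self, calibrated):
        model = calibrated.model
        r = []
        for dp in (0.2, 0.6, 1.0):
            idx = model.comps_in_band(dp, 0.1)
            r.append(cable.input_resistance(model, int(idx[0])))
        assert r[0] < r[1] < r[2]


def test_charge_balance_passive_steady_state(calibrated):
    """Axial currents into each compartment equal the membrane current."""
    model = calibrated.model
    i = np.zeros(model.n)
    i[0] = -0.5
    v = cable.passive_steady_state(model, i)
    resid = model.g_leak * (v - model.e_leak) - i
    for k in range(1, model.n):
        p = model.parent[k]
        flow = model.gax[k] * (v[p] - v[k])
        resid[k] -= flow
        resid[p] += flow
    assert np.max(np.abs(resid)) < 1e-9 * np.max(np.abs(i))


def test_distal_to_soma_attenuation_exceeds_reverse(calibrated):
    """Signal attenuation is direction-dependent on the passive tree."""
    model = calibrated.model
    distal = int(model.comps_in_band(1.0, 0.1)[0])
    i = np.zeros(model.n)
    i[0] = 1.0
    v_from_soma = cable.passive_steady_state(model, i) - model.spec.passive.e_leak
    att_out = v_from_soma[distal] / v_from_soma[0]
    i = np.zeros(model.n)
    i[distal] = 1.0
    v_from_distal = cable.passive_steady_state(model, i) - model.spec.passive.e_leak
    att_in = v_from_distal[0] / v_from_distal[distal]
    assert att_in < att_out


def test_traceset_export_roundtrip(tmp_path, calibrated):
    traces, _ = cable.run(calibrated.model, 50.0, dt=0.05, i_soma=12.0)
    csv = tmp_path / "tr.csv"
    traces.write_csv(csv, stride=10)
    import pandas as pd
    df = pd.read_csv(csv)
    assert "v_soma" in df.columns and len(df) == len(traces.t[::10])
    sp = tmp_path / "spikes.txt"
    traces.write_spikes(sp)
    got = np.loadtxt(sp, ndmin=1)
    assert np.allclose(got, traces.spikes, atol=1e-6)
    h5 = tmp_path / "tr.h5"
    traces.write_hdf5(h5)
    import h5py
    with h5py.File(h5) as fh:
        assert np.allclose(fh["v_soma"][:], traces.channels["v_soma"])
        assert fh.attrs["dt_ms"] == 0.05
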