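"""Index analysis on constructed fixtures: rates, thresholds, DCT/DCI/DFG."""

import numpy as np
import pytest

from picloop import analysis as an
from picloop.cable import TraceSet
from picloop.errors import ParameterError


def make_ramp_traces(duration=12000.0, dt=1.0, peak=12.0, spikes=(),
                     force=None):
    """A synthetic triangular-ramp TraceSet with a prescribed force trace."""
    n = int(duration / dt)
    t = np.arange(n + 1) * dt
    up = t / (duration / 2)
    i_s = peak * np.clip(np.where(t <= duration / 2, up, 2 - up), 0, 1)
    ch = {
        "v_soma": np.full(n + 1, -65.0),
        "v_band": np.full(n + 1, -60.0),
        "m_cal": np.zeros(n + 1),
        "i_clamp": np.zeros(n + 1),
        "ca": np.zeros(n + 1),
        "i_soma": i_s,
        "g_aff": np.zeros(n + 1),
        "g_syn": np.zeros(n + 1),
    }
    tr = TraceSet(dt=dt, channels=ch)
    tr.spikes = np.asarray(spikes, dtype=float)
    if force is None:
        force = np.zeros(n + 1)
    return tr, np.asarray(force, dtype=float)


def hysteretic_fixture(init=6.0, cess=2.0, s63=10.0, peak=12.0):
    """Force turning on at `init` on the ascent (63% at `s63`) and
    persisting down to `cess` on the descent."""
    tr, _ = make_ramp_traces(peak=peak)
    t = tr.t
    stim = tr.channels["i_soma"]
    asc = t <= 6000.0
    f = np.zeros_like(stim)
    f[asc] = np.clip((stim[asc] - init) / (s63 - init) * 0.63, 0.0, 1.0)
    f[~asc] = np.clip((stim[~asc] - cess) / (s63 - cess) * 0.8, 0.0, 1.0)
    # spikes: ascending from init, descending until cess
    spike_t = np.concatenate([
        np.arange(3000.0, 6000.0, 50.0),           # stim 6 → 12
        np.arange(6000.0, 11000.0, 50.0),          # stim 12 → 2
    ])
    tr.spikes = spike_t
    return tr, f


class TestInstantaneousRate:
    def test_uniform_train(self):
        r = an.instantaneous_rate([0.0, 100.0, 200.0])
        np.testing.assert_allclose(r, [[100.0, 10.0], [200.0, 10.0]])

    def test_single_spike_empty(self):
        assert an.instantaneous_rate([50.0]).size == 0

    def test_jittered_train_mean(self):
        rng = np.random.default_rng(0)
        isi = 50.0 + rng.uniform(-2.0, 2.0, 200)
        spikes = np.cumsum(isi)
        r = an.instantaneous_rate(spikes)
        assert abs(r[:, 1].mean() - 20.0) < 20.0 * (2.0 / 50.0)


class TestBuildIOCurve:
    def test_symmetric_force_has_identical_phases(self):
        tr, _ = make_ramp_traces()
        f = tr.channels["i_soma"] / 12.0  # force ∝ stimulus
        io = an.build_io_curve(tr, f, "somatic")
        np.testing.assert_allclose(io.force_asc, io.force_desc, atol=1e-9)

    def test_triangle_peak_maps_to_endpoint(self):
        tr, f = make_ramp_traces(peak=12.0)
        io = an.build_io_curve(tr, f, "somatic")
        assert io.stim[-1] == pytest.approx(12.0)

    def test_hysteretic_fixture_produces_positive_dct(self):
        tr, f = hysteretic_fixture()
        io = an.build_io_curve(tr, f, "somatic")
        th = an.thresholds(io)
        assert th.force_initiation - th.force_cessation > 0

    def test_dendritic_mode_requires_in_map(self):
        tr, f = make_ramp_traces()
        with pytest.raises(an.StateError):
            an.build_io_curve(tr, f, "dendritic", i_n_peak=None)


class TestThresholds:
    def test_linear_onset_at_5(self):
        tr, _ = make_ramp_traces()
        stim = tr.channels["i_soma"]
        f = np.clip(stim - 5.0, 0.0, None)
        io = an.build_io_curve(tr, f, "somatic")
        th = an.thresholds(io)
        assert th.force_initiation == pytest.approx(5.0, abs=0.15)
        assert th.force_cessation == pytest.approx(5.0, abs=0.15)

    def test_constructed_dct_is_4(self):
        tr, f = hysteretic_fixture(init=6.0, cess=2.0)
        io = an.build_io_curve(tr, f, "somatic")
        rep = an.compute_indices(io)
        assert rep.dct == pytest.approx(4.0, abs=0.15)

    def test_no_spikes_reports_no_recruitment(self):
        tr, f = make_ramp_traces(spikes=())
        io = an.build_io_curve(tr, f, "somatic")
        th = an.thresholds(io)
        assert th.recruitment is None and th.derecruitment is None


class TestPicOnset:
    def _io_with_rates(self, pts):
        tr, f = make_ramp_traces()
        io = an.build_io_curve(tr, f, "somatic")
        io.rate_points_asc = np.asarray(pts, dtype=float)
        return io

    def test_linear_fi_absent(self):
        s = np.linspace(4.0, 12.0, 40)
        io = self._io_with_rates(np.column_stack([s, 5.0 + 2.0 * s]))
        assert an.pic_onset_current(io) is None

    def test_slope_tripling_at_8(self):
        s = np.linspace(4.0, 12.0, 81)
        r = np.where(s < 8.0, 2.0 * s, 2.0 * 8.0 + 6.0 * (s - 8.0))
        io = self._io_with_rates(np.column_stack([s, r]))
        onset = an.pic_onset_current(io)
        assert onset == pytest.approx(8.0, abs=0.3)

    def test_unsustained_jump_rejected(self):
        s = np.linspace(4.0, 12.0, 81)
        r = 2.0 * s
        bump = (s > 8.0) & (s < 8.3)  # < 0.5 nA of acceleration
        r[bump] += 6.0 * (s[bump] - 8.0)
        io = self._io_with_rates(np.column_stack([s, r]))
        assert an.pic_onset_current(io) is None

    def test_too_few_samples_absent(self):
        io = self._io_with_rates(np.column_stack([[5.0, 6.0], [10.0, 12.0]]))
        assert an.pic_onset_current(io) is None


class TestComputeIndices:
    def test_no_hysteresis_zero_indices(self):
        tr, _ = make_ramp_traces()
        f = np.clip(tr.channels["i_soma"] - 5.0, 0.0, None)
        io = an.build_io_curve(tr, f, "somatic")
        rep = an.compute_indices(io)
        assert rep.dct == pytest.approx(0.0, abs=0.15)
        assert rep.dfg == 0.0

    def test_dci_definition(self):
        # ascending force rises linearly from init=6: F(s) = 0.1575*(s-6),
        # peak F(12) = 0.945, so 63% of peak is crossed at 6 + 0.63*6 = 9.78
        tr, f = hysteretic_fixture(init=6.0, s63=10.0)
        io = an.build_io_curve(tr, f, "somatic")
        rep = an.compute_indices(io)
        assert rep.dci == pytest.approx(0.63 * 6.0, abs=0.15)

    def test_dfg_zero_when_onset_at_recruitment(self):
        tr, f = hysteretic_fixture()
        io = an.build_io_curve(tr, f, "somatic")
        # force an acceleration exactly at recruitment
        s = np.linspace(io.recruitment, 12.0, 40)
        io.rate_points_asc = np.column_stack(
            [s, 10 + 2 * (s - s[0]) + 8 * np.clip(s - s[0], 0, None)])
        rep = an.compute_indices(io)
        assert rep.dfg == 0.0

    def test_dfg_positive_with_late_onset(self):
        tr, f = hysteretic_fixture()
        io = an.build_io_curve(tr, f, "somatic")
        s = np.linspace(io.recruitment, 12.0, 60)
        r = 10 + 2 * (s - s[0]) + np.where(s > 9.0, 8 * (s - 9.0), 0.0)
        io.rate_points_asc = np.column_stack([s, r])
        rep = an.compute_indices(io)
        # detection resolution is the 0.5 nA sustain window
        assert rep.pic_onset == pytest.approx(9.0, abs=0.5)
        assert rep.dfg > 0.0

    def test_dct_matches_recruitment_hysteresis_when_force_tracks_firing(self):
        """When force switches exactly with firing, force DCT equals the
        recruitment-derecruitment difference to within one grid step."""
        tr, f = hysteretic_fixture(init=6.0, cess=2.0)
        io = an.build_io_curve(tr, f, "somatic")
        rep = an.compute_indices(io)
        firing_dct = io.recruitment - io.derecruitment
        assert abs(rep.dct - firing_dct) <= 2 * an.STIM_GRID_NA + 0.1


class TestClassify:
    def _rep(self, dct, onset, recruitment):
        return an.IndexReport(recruitment=recruitment, derecruitment=None,
                              pic_onset=onset, force_initiation=None,
                              force_cessation=None, dct=dct, dci=1.0, dfg=0.0)

    def test_type_i(self):
        io = an.IOCurve(np.array([0.0]), np.zeros(1), np.zeros(1),
                        np.empty((0, 2)), np.empty((0, 2)), 1.0, 5.0, 5.0)
        assert an.classify_firing_type(io, self._rep(0.0, None, 5.0)) == "I"

    def test_type_iv(self):
        io = an.IOCurve(np.array([0.0]), np.zeros(1), np.zeros(1),
                        np.empty((0, 2)), np.empty((0, 2)), 1.0, 5.0, 2.0)
        assert an.classify_firing_type(io, self._rep(3.0, 8.0, 5.0)) == "IV"

    def test_type_iii(self):
        io = an.IOCurve(np.array([0.0]), np.zeros(1), np.zeros(1),
                        np.empty((0, 2)), np.empty((0, 2)), 1.0, 5.0, 1.0)
        assert an.classify_firing_type(io, self._rep(4.0, 5.2, 5.0)) == "III"


class TestWarmupMetrics:
    def _trials(self, rate_peaks):
        out = []
        for rp in rate_peaks:
            n = 100
            ch = {"v_soma": np.full(n, -65.0), "v_band": np.full(n, -60.0)}
            tr = TraceSet(dt=1.0, channels=ch)
            if rp > 0:
                isi = 1000.0 / rp
                tr.spikes = np.arange(0.0, 99.0 * isi / 10, isi)[:5]
            else:
                tr.spikes = np.empty(0)
            out.append(tr)
        return out

    def test_constant_peaks_no_warmup(self):
        rep = an.warmup_metrics(self._trials([10.0, 10.0, 10.0, 10.0]))
        assert not rep.warmup

    def test_increasing_peaks_warmup(self):
        rep = an.warmup_metrics(self._trials([10.0, 10.3, 10.7, 11.1]))
        assert rep.warmup

    def test_rise_then_fall_no_warmup(self):
        rep = an.warmup_metrics(self._trials([10.0, 12.0, 11.0, 13.0]))
        assert not rep.warmup

    def test_needs_three_trials(self):
        with pytest.raises(ParameterError):
            an.warmup_metrics(self._trials([10.0, 11.0]))
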