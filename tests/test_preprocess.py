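"""Tests for filtering, epoching, matching, rejection and interpolation."""

import numpy as np
import pytest

from enigo import preprocess as pp
from enigo.containers import EpochSet, Erp, n_window_samples
from enigo.headmodel import standard_64_montage


# ---------------------------------------------------------------------------
# filtering


def test_filter_kills_dc():
    fs = 512.0
    x = np.full((2, int(fs * 4)), 10.0)
    y = pp.filter_continuous(x, fs)
    assert np.abs(y[:, int(fs) : -int(fs)]).max() < 0.1


def test_lowpass_cutoff_single_pass_half_power():
    fs = 1024.0
    t = np.arange(int(fs * 8)) / fs
    x = np.sin(2 * np.pi * 40.0 * t)
    y = pp.filter_continuous(
        x, fs, hp=0.0, lp=40.0, notch=None, zero_phase=False
    )
    steady = y[int(fs * 2) :]
    ratio = np.abs(steady).max()
    assert ratio == pytest.approx(1 / np.sqrt(2), abs=0.02)
    # forward-backward squares the magnitude response -> 1/2
    y2 = pp.filter_continuous(x, fs, hp=0.0, lp=40.0, notch=None, zero_phase=True)
    mid = y2[int(fs * 2) : -int(fs * 2)]
    assert np.abs(mid).max() == pytest.approx(0.5, abs=0.02)


def test_notch_suppresses_line_frequency():
    # hp=0: the 0.1 Hz high-pass transient would swamp a short test signal
    fs = 1024.0
    t = np.arange(int(fs * 6)) / fs
    x = np.sin(2 * np.pi * 50.0 * t)
    y = pp.filter_continuous(x, fs, hp=0.0)
    mid = y[int(fs * 2) : -int(fs * 2)]
    assert np.abs(mid).max() < 0.05
    # frequency-response check of the band-stop section itself
    from scipy import signal as sps

    sos = sps.butter(2, (48.0, 52.0), btype="bandstop", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[50.0], fs=fs)
    assert np.abs(h)[0] < 0.01


def test_filter_rejects_low_fs():
    with pytest.raises(ValueError):
        pp.filter_continuous(np.zeros(100), fs=60.0, lp=40.0)


def test_zero_phase_preserves_pulse_latency():
    fs = 512.0
    x = np.zeros(int(fs * 4))
    x[int(fs * 2)] = 1.0
    y = pp.filter_continuous(x, fs, hp=0.1, lp=40.0, notch=None, zero_phase=True)
    assert abs(int(np.argmax(np.abs(y))) - int(fs * 2)) <= 1


def test_filter_commutes_with_averaging(rng):
    fs = 256.0
    epochs = rng.standard_normal((4, int(fs * 2), 6))
    filt_then_avg = np.mean(
        [pp.filter_continuous(epochs[:, :, i], fs) for i in range(6)], axis=0
    )
    avg_then_filt = pp.filter_continuous(epochs.mean(axis=2), fs)
    assert np.allclose(filt_then_avg, avg_then_filt, rtol=1e-8, atol=1e-10)


# ---------------------------------------------------------------------------
# events and epoching


def test_relabel_events():
    import pandas as pd

    log = pd.DataFrame(
        {
            "stim": ["GO", "GO", "NOGO", "NOGO"],
            "response": [1, 0, 1, 0],
        }
    )
    out = pp.relabel_events(log)
    assert list(out["condition"]) == ["HIT", "CR"]
    assert list(out["stim"]) == ["GO", "NOGO"]


def test_epoch_sample_counts():
    assert n_window_samples((-100, 500), 1024.0) == 614
    assert n_window_samples((-100, 500), 1000.0) == 600
    x = np.zeros((3, 5000))
    es = pp.epoch(x, [1000, 2000], fs=1024.0)
    assert es.data.shape == (3, 614, 2)


def test_epoch_zero_events():
    es = pp.epoch(np.zeros((2, 1000)), [], fs=1000.0)
    assert es.n_epochs == 0


def test_epoch_edge_events_dropped():
    with pytest.warns(UserWarning):
        es = pp.epoch(np.zeros((1, 2000)), [50, 1000, 1950], fs=1000.0)
    assert es.n_epochs == 1


def test_epoch_time_axis_and_values():
    fs = 1000.0
    x = np.arange(3000, dtype=float)[None, :]
    es = pp.epoch(x, [1000], fs=fs, window_ms=(-100, 500))
    assert es.times[0] == -100.0
    assert es.data[0, 0, 0] == 900.0  # sample at onset-100ms
    assert es.data[0, 100, 0] == 1000.0  # onset sample at t=0


def test_baseline_subtracts_prestim_mean(rng):
    data = rng.standard_normal((2, 60, 3)) + 5.0
    es = EpochSet(data, fs=100.0, window_ms=(-100.0, 500.0))
    out = pp.baseline_correct(es)
    pre = out.times < 0
    assert np.allclose(out.data[:, pre, :].mean(axis=1), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# matching and rejection


def make_epochs(n, block=1, amp=1.0, fs=100.0):
    n_samp = n_window_samples((-100.0, 500.0), fs)
    data = amp * np.ones((2, n_samp, n))
    return EpochSet(
        data, fs=fs, window_ms=(-100.0, 500.0),
        blocks=np.full(n, block), labels=np.array(["X"] * n),
    )


def test_match_trial_counts_truncates_to_smaller():
    hit = make_epochs(28)
    hit.data *= np.arange(28)[None, None, :]  # mark presentation order
    cr = make_epochs(25)
    h2, c2 = pp.match_trial_counts(hit, cr)
    assert h2.n_epochs == 25 and c2.n_epochs == 25
    assert np.allclose(h2.data[0, 0, :], np.arange(25))  # first 25 kept


def test_match_trial_counts_equal_unchanged():
    hit, cr = make_epochs(10), make_epochs(10)
    h2, c2 = pp.match_trial_counts(hit, cr)
    assert h2.n_epochs == 10 and c2.n_epochs == 10


def test_match_trial_counts_zero_block():
    hit = make_epochs(5)
    cr = make_epochs(0)
    with pytest.warns(UserWarning):
        h2, c2 = pp.match_trial_counts(hit, cr)
    assert h2.n_epochs == 0 and c2.n_epochs == 0


def test_match_trial_counts_per_block_invariant(rng):
    n_samp = n_window_samples((-100.0, 500.0), 100.0)
    blocks_h = rng.integers(1, 5, 40)
    blocks_c = rng.integers(1, 5, 35)
    hit = EpochSet(
        np.zeros((2, n_samp, 40)), fs=100.0, window_ms=(-100.0, 500.0),
        blocks=blocks_h,
    )
    cr = EpochSet(
        np.zeros((2, n_samp, 35)), fs=100.0, window_ms=(-100.0, 500.0),
        blocks=blocks_c,
    )
    h2, c2 = pp.match_trial_counts(hit, cr)
    for b in range(1, 5):
        nh = int((h2.blocks == b).sum())
        nc = int((c2.blocks == b).sum())
        assert nh == nc == min((blocks_h == b).sum(), (blocks_c == b).sum())


def test_reject_artifacts_boundary():
    es = make_epochs(3, amp=0.0)
    es.data[0, 5, 0] = 81.0
    es.data[1, 9, 1] = 80.0  # exactly at threshold: kept (strict rule)
    out = pp.reject_artifacts(es, threshold=80.0)
    assert out.n_epochs == 2
    assert np.max(np.abs(out.data)) <= 80.0


def test_reject_artifacts_all_zero_kept():
    es = make_epochs(4, amp=0.0)
    assert pp.reject_artifacts(es).n_epochs == 4


def test_reject_artifacts_survivors_under_threshold(rng):
    n_samp = n_window_samples((-100.0, 500.0), 100.0)
    data = rng.normal(0, 25, size=(4, n_samp, 50))
    es = EpochSet(data, fs=100.0, window_ms=(-100.0, 500.0))
    out = pp.reject_artifacts(es, threshold=80.0)
    assert out.n_epochs == int((np.abs(data).max(axis=(0, 1)) <= 80.0).sum())
    assert 0 < out.n_epochs
    assert np.max(np.abs(out.data)) <= 80.0


# ---------------------------------------------------------------------------
# averaging and interpolation


def test_average_single_epoch_identity(rng):
    n_samp = n_window_samples((-100.0, 500.0), 100.0)
    data = rng.standard_normal((3, n_samp, 1))
    es = EpochSet(data, fs=100.0, window_ms=(-100.0, 500.0))
    erp = pp.average_erp(es)
    assert np.array_equal(erp.data, data[:, :, 0])
    assert erp.n_epochs == 1


def test_average_symmetric_epochs_cancel(rng):
    n_samp = n_window_samples((-100.0, 500.0), 100.0)
    v = rng.standard_normal((3, n_samp))
    es = EpochSet(
        np.stack([v, -v], axis=2), fs=100.0, window_ms=(-100.0, 500.0)
    )
    assert np.allclose(pp.average_erp(es).data, 0.0, atol=1e-14)


def test_average_empty_errors():
    es = make_epochs(0)
    with pytest.raises(ValueError):
        pp.average_erp(es)


def _erp_from_field(values, fs=100.0):
    n_samp = n_window_samples((-100.0, 500.0), fs)
    data = np.tile(np.asarray(values)[:, None], (1, n_samp))
    return Erp(data, fs=fs, window_ms=(-100.0, 500.0), n_epochs=10)


def test_interpolation_empty_bad_is_identity(rng):
    montage = standard_64_montage()
    erp = _erp_from_field(rng.standard_normal(64))
    out = pp.interpolate_bad_channels(erp, montage, [])
    assert out is erp


def test_interpolation_reproduces_constant_field():
    montage = standard_64_montage()
    erp = _erp_from_field(np.full(64, 3.7))
    out = pp.interpolate_bad_channels(erp, montage, [10])
    assert np.allclose(out.data[10], 3.7, atol=1e-8)


def test_interpolation_smooth_field_accuracy():
    montage = standard_64_montage()
    pos = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    # smooth low-degree field: combination of degree-1 and degree-2 harmonics
    field = 1.5 * pos[:, 2] + 0.8 * pos[:, 0] * pos[:, 1] + 0.5 * (
        3 * pos[:, 2] ** 2 - 1
    )
    scale = field.max() - field.min()
    errs = []
    for bad in (5, 20, 40):  # non-edge channels
        erp = _erp_from_field(field)
        out = pp.interpolate_bad_channels(erp, montage, [bad])
        errs.append(abs(out.data[bad, 0] - field[bad]) / scale)
    assert max(errs) < 0.05


def test_interpolation_rejects_large_bad_sets():
    montage = standard_64_montage()
    erp = _erp_from_field(np.zeros(64))
    with pytest.raises(ValueError):
        pp.interpolate_bad_channels(erp, montage, list(range(7)))


def test_interpolation_accepts_labels():
    montage = standard_64_montage()
    erp = _erp_from_field(np.full(64, 1.0))
    out = pp.interpolate_bad_channels(erp, montage, ["Cz"])
    idx = montage.labels.index("Cz")
    assert np.allclose(out.data[idx], 1.0, atol=1e-8)
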