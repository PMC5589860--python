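"""Continuous-signal filtering, epoching, relabeling, artifact rejection,
trial-count matching, averaging and bad-channel interpolation.

Filtering uses second-order Butterworth sections applied zero-phase
(forward-backward) by default, which doubles the effective attenuation at
the cutoffs.  Epochs follow the half-open window convention of
:mod:`enigo.containers`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import eval_legendre

from .containers import EpochSet, Erp, Montage, n_window_samples

__all__ = [
    "filter_continuous",
    "relabel_events",
    "epoch",
    "match_trial_counts",
    "reject_artifacts",
    "average_erp",
    "interpolate_bad_channels",
    "baseline_correct",
]


def filter_continuous(
    data: np.ndarray,
    fs: float,
    hp: float = 0.1,
    lp: float = 40.0,
    notch: float | None = 50.0,
    notch_half_width: float = 2.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Band-limit continuous data with 2nd-order Butterworth filters.

    High-pass at ``hp``, low-pass at ``lp`` and a band-stop of
    ``notch +/- notch_half_width`` Hz, each a second-order Butterworth
    design.  ``zero_phase=True`` applies each filter forward-backward
    (no group delay, squared magnitude response).
    """
    if fs <= 2.0 * lp:
        raise ValueError(f"fs={fs} must exceed twice the low-pass cutoff {lp}")
    x = np.asarray(data, dtype=float)

    sos_list = []
    if hp and hp > 0:
        sos_list.append(sps.butter(2, hp, btype="highpass", fs=fs, output="sos"))
    if lp and lp > 0:
        sos_list.append(sps.butter(2, lp, btype="lowpass", fs=fs, output="sos"))
    if notch is not None and notch > 0:
        band = (notch - notch_half_width, notch + notch_half_width)
        sos_list.append(sps.butter(2, band, btype="bandstop", fs=fs, output="sos"))

    for sos in sos_list:
        if zero_phase:
            x = sps.sosfiltfilt(sos, x, axis=-1)
        else:
            x = sps.sosfilt(sos, x, axis=-1)
    return x


def relabel_events(log: pd.DataFrame) -> pd.DataFrame:
    """Tag trials with their ERP condition; keep only correct outcomes.

    Responded Go trials become HIT, withheld NoGo trials CR; misses and
    false alarms are excluded from ERP processing.
    """
    required = {"stim", "response"}
    if not required.issubset(log.columns):
        raise ValueError(f"log must contain columns {sorted(required)}")
    events = log.copy()
    is_hit = (events["stim"] == "GO") & (events["response"] == 1)
    is_cr = (events["stim"] == "NOGO") & (events["response"] == 0)
    events["condition"] = np.where(is_hit, "HIT", np.where(is_cr, "CR", ""))
    return events[events["condition"] != ""].reset_index(drop=True)


def epoch(
    data: np.ndarray,
    events: np.ndarray,
    fs: float,
    window_ms: tuple[float, float] = (-100.0, 500.0),
    baseline: bool = False,
    blocks: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> EpochSet:
    """Cut a continuous record into peri-event epochs.

    ``events`` are onset sample indices.  Each epoch spans the half-open
    window ``[t0 + w0, t0 + w1)``: at 1024 Hz and (-100, 500) ms this yields
    614 samples.  Events whose window falls outside the recording are
    dropped with a warning.  ``baseline=True`` subtracts the pre-onset mean.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n_total = x.shape[1]
    n_samp = n_window_samples(window_ms, fs)
    offset = int(np.round(window_ms[0] * fs / 1000.0))

    events = np.asarray(events, dtype=int)
    starts = events + offset
    ok = (starts >= 0) & (starts + n_samp <= n_total)
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} event(s) too close to the recording edge"
        )
    starts = starts[ok]
    if blocks is not None:
        blocks = np.asarray(blocks)[ok]
    if labels is not None:
        labels = np.asarray(labels)[ok]

    out = np.empty((x.shape[0], n_samp, starts.size))
    for i, s in enumerate(starts):
        out[:, :, i] = x[:, s : s + n_samp]
    es = EpochSet(out, fs=fs, window_ms=window_ms, blocks=blocks, labels=labels)
    if baseline:
        es = baseline_correct(es)
    return es


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the mean of the pre-onset (t < 0) samples per channel/epoch."""
    pre = epochs.times < 0.0
    if not pre.any():
        raise ValueError("no pre-onset samples to use as baseline")
    base = epochs.data[:, pre, :].mean(axis=1, keepdims=True)
    out = epochs.select(np.arange(epochs.n_epochs))
    out.data = epochs.data - base
    return out


def match_trial_counts(
    hit: EpochSet, cr: EpochSet
) -> tuple[EpochSet, EpochSet]:
    """Equalize per-block trial counts between two conditions.

    Within each block both conditions are truncated to the smaller count,
    keeping the first n epochs in presentation order.  Blocks where either
    condition has zero trials contribute nothing (with a warning).
    """
    if hit.blocks is None or cr.blocks is None:
        raise ValueError("both epoch sets need block labels")
    blocks = sorted(set(hit.blocks.tolist()) | set(cr.blocks.tolist()))
    keep_hit: list[int] = []
    keep_cr: list[int] = []
    for b in blocks:
        ih = np.flatnonzero(hit.blocks == b)
        ic = np.flatnonzero(cr.blocks == b)
        n = min(ih.size, ic.size)
        if n == 0 and (ih.size or ic.size):
            warnings.warn(f"block {b}: one condition empty, block dropped")
        keep_hit.extend(ih[:n].tolist())
        keep_cr.extend(ic[:n].tolist())
    return hit.select(np.asarray(keep_hit, int)), cr.select(np.asarray(keep_cr, int))


def reject_artifacts(epochs: EpochSet, threshold: float = 80.0) -> EpochSet:
    """Drop epochs containing any sample with |voltage| strictly above
    ``threshold`` microvolts, at any channel."""
    peak = np.max(np.abs(epochs.data), axis=(0, 1))
    keep = np.flatnonzero(peak <= threshold)
    if keep.size == 0 and epochs.n_epochs > 0:
        warnings.warn("artifact rejection removed every epoch")
    return epochs.select(keep)


def average_erp(epochs: EpochSet, condition: str = "") -> Erp:
    """Channel- and time-wise mean across epochs; records the epoch count."""
    if epochs.n_epochs < 1:
        raise ValueError("cannot average an empty epoch set")
    return Erp(
        data=epochs.data.mean(axis=2),
        fs=epochs.fs,
        window_ms=epochs.window_ms,
        n_epochs=epochs.n_epochs,
        condition=condition,
        meta=dict(epochs.meta),
    )


# ---------------------------------------------------------------------------
# spherical-spline channel interpolation (Perrin et al. style)


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Spherical-spline kernel g(cos angle), Legendre series of n_terms."""
    cosang = np.clip(np.asarray(cosang, dtype=float), -1.0, 1.0)
    n = np.arange(1, n_terms + 1, dtype=float)
    coef = (2 * n + 1) / (n**m * (n + 1) ** m) / (4 * np.pi)
    pn = np.stack([eval_legendre(int(k), cosang) for k in n])
    return np.tensordot(coef, pn, axes=(0, 0))


def interpolate_bad_channels(
    erp: Erp,
    montage: Montage,
    bad: list[int] | list[str],
    m: int = 4,
    n_terms: int = 7,
    ridge: float = 1e-5,
) -> Erp:
    """Replace bad channels by a spherical-spline estimate from the others.

    Spline order ``m=4`` with the Legendre expansion truncated at
    ``n_terms`` terms; the interpolant reproduces constant fields exactly.
    ``ridge`` regularizes the (near-singular) spline system so that rough
    inputs do not produce runaway coefficients.  At most 10% of channels
    may be interpolated.
    """
    if len(bad) == 0:
        return erp
    bad_idx = np.asarray(
        [montage.labels.index(b) if isinstance(b, str) else int(b) for b in bad]
    )
    n_ch = montage.n_channels
    if bad_idx.size >= 0.10 * n_ch:
        raise ValueError("too many bad channels to interpolate (>= 10%)")
    if erp.n_channels != n_ch:
        raise ValueError("ERP channel count does not match montage")

    good = np.setdiff1d(np.arange(n_ch), bad_idx)
    pos = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)

    g_gg = _spline_g(pos[good] @ pos[good].T, m=m, n_terms=n_terms)
    g_bg = _spline_g(pos[bad_idx] @ pos[good].T, m=m, n_terms=n_terms)

    n_good = good.size
    lhs = np.zeros((n_good + 1, n_good + 1))
    lhs[:n_good, :n_good] = g_gg + ridge * np.eye(n_good)
    lhs[:n_good, n_good] = 1.0
    lhs[n_good, :n_good] = 1.0

    rhs = np.zeros((n_good + 1, erp.data.shape[1]))
    rhs[:n_good] = erp.data[good]
    sol = np.linalg.solve(lhs, rhs)
    coefs, const = sol[:n_good], sol[n_good]

    out = erp.data.copy()
    out[bad_idx] = g_bg @ coefs + const
    return Erp(
        data=out,
        fs=erp.fs,
        window_ms=erp.window_ms,
        n_epochs=erp.n_epochs,
        condition=erp.condition,
        meta=dict(erp.meta),
    )
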