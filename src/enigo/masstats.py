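"""Mass-univariate electrode x time mixed ANOVAs and sustained-period
detection with permutation-calibrated duration criteria.

At every (electrode, sample) the 2x2 mixed-ANOVA interaction is evaluated
(delegating to the vectorized core in :mod:`enigo.behavior`).  A sustained
period is a maximal run of samples where at least a fraction of electrodes
is significant, lasting at least a minimum number of contiguous frames
(defaults: 10% of electrodes, 11 frames, alpha 0.05).  The duration
criterion can instead be calibrated by permuting group labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import mixed_anova_2x2_vectorized

__all__ = [
    "StatMap",
    "SustainedPeriod",
    "pointwise_interaction",
    "electrode_count_threshold",
    "find_sustained_periods",
    "permutation_duration_threshold",
]


@dataclass
class StatMap:
    """Electrode x time F/p maps for a 2x2 interaction."""

    f_map: np.ndarray
    p_map: np.ndarray
    times: np.ndarray
    design: str = "GroupXStimulus"
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f_map = np.asarray(self.f_map, dtype=float)
        self.p_map = np.asarray(self.p_map, dtype=float)
        if self.f_map.shape != self.p_map.shape:
            raise ValueError("F and p maps must share a shape")
        if ((self.p_map < 0) | (self.p_map > 1)).any():
            raise ValueError("p values outside [0, 1]")

    @property
    def n_electrodes(self) -> int:
        return self.f_map.shape[0]


@dataclass
class SustainedPeriod:
    start_ms: float
    end_ms: float
    frames: int
    peak_electrode_fraction: float
    start_frame: int = 0
    end_frame: int = 0


def pointwise_interaction(
    data: np.ndarray,
    groups: np.ndarray,
    times: np.ndarray,
    design: str = "GroupXStimulus",
    alpha: float = 0.05,
) -> StatMap:
    """Interaction F/p at every electrode and sample.

    ``data`` is (n_subjects, 2, n_electrodes, n_samples): each subject's two
    within-condition ERPs (HIT/CR or BEG/END).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError("data must be (n_subjects, 2, n_electrodes, n_samples)")
    if data.shape[3] != np.asarray(times).size:
        raise ValueError("times length must match the sample axis")
    res = mixed_anova_2x2_vectorized(data, groups)["interaction"]
    return StatMap(
        f_map=res["F"],
        p_map=res["p"],
        times=np.asarray(times, dtype=float),
        design=design,
        alpha=alpha,
    )


def electrode_count_threshold(n_electrodes: int, electrode_frac: float) -> int:
    """Minimum significant-electrode count: ceil(frac x n); 64 at 10% -> 7."""
    return int(np.ceil(electrode_frac * n_electrodes))


def _marked_samples(p_map: np.ndarray, alpha: float, n_required: int) -> np.ndarray:
    counts = (p_map < alpha).sum(axis=0)
    return counts >= n_required


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(int))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def find_sustained_periods(
    stat_map: StatMap,
    electrode_frac: float = 0.10,
    min_frames: int = 11,
    alpha: float | None = None,
) -> list[SustainedPeriod]:
    """Maximal runs of samples meeting the electrode-fraction criterion and
    lasting at least ``min_frames`` contiguous frames."""
    alpha = stat_map.alpha if alpha is None else alpha
    n_req = electrode_count_threshold(stat_map.n_electrodes, electrode_frac)
    marked = _marked_samples(stat_map.p_map, alpha, n_req)
    sig_frac = (stat_map.p_map < alpha).mean(axis=0)
    periods = []
    for start, stop in _runs(marked):
        if stop - start >= min_frames:
            periods.append(
                SustainedPeriod(
                    start_ms=float(stat_map.times[start]),
                    end_ms=float(stat_map.times[stop - 1]),
                    frames=stop - start,
                    peak_electrode_fraction=float(sig_frac[start:stop].max()),
                    start_frame=int(start),
                    end_frame=int(stop - 1),
                )
            )
    return periods


def permutation_duration_threshold(
    data: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    electrode_frac: float = 0.10,
    seed: int = 0,
) -> int:
    """Duration criterion calibrated by between-subject label permutation.

    For each permutation the group labels are reassigned, the
    electrode-fraction-marked sample sequence recomputed, and the maximum
    run length recorded; returns the 95th percentile (upper-rounded) of the
    null maximum run lengths, plus one.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a poorly resolved duration threshold")
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    n_subj = data.shape[0]
    n_el = data.shape[2]
    n_req = electrode_count_threshold(n_el, electrode_frac)
    rng = np.random.default_rng(seed)

    max_runs = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(n_subj)
        res = mixed_anova_2x2_vectorized(data, groups[perm])["interaction"]
        marked = _marked_samples(res["p"], alpha, n_req)
        runs = _runs(marked)
        max_runs[i] = max((stop - start for start, stop in runs), default=0)
    q = int(np.quantile(max_runs, 0.95, method="higher"))
    return q + 1
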