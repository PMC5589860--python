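"""Synthetic Go/NoGo study generator.

Produces task schedules, trial-level behavioral logs with the adaptive
response-time threshold, and multichannel EEG epochs with plantable
group/stimulus/session effects, emulating a two-group (SI vs II),
two-session (BEG vs END) design.

Reaction times follow an ex-Gaussian model (Gaussian + exponential tail)
truncated at a 100 ms floor.  EEG epochs are built from forward-projected
canonical components (an N2-like fronto-central negativity near 200 ms and
a P3-like centro-parietal positivity near 350 ms), a condition-specific
source effect, spatially correlated 1/f noise projected through the lead
field, and white sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet, n_window_samples

__all__ = [
    "TaskConfig",
    "SubjectProfile",
    "GroupProfileSpec",
    "EegSimConfig",
    "generate_schedule",
    "simulate_behavior",
    "simulate_group_study",
    "simulate_eeg",
    "default_group_profiles",
    "default_effect_nodes",
]

RT_FLOOR_MS = 100.0
FA_RT_OFFSET_MS = 30.0

NOGO_LETTERS = ("A", "E", "O")
NOGO_COLORS = ("blue", "green", "red")


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class TaskConfig:
    n_blocks: int = 12
    trials_per_block: int = 60
    go_per_block: int = 30
    nogo_per_block: int = 30
    initial_rtt: float = 380.0
    rtt_fraction: float = 0.9
    fixation_range: tuple[float, float] = (1500.0, 1900.0)
    stim_duration: float = 500.0
    blank_duration: float = 1000.0

    def __post_init__(self) -> None:
        if self.go_per_block + self.nogo_per_block != self.trials_per_block:
            raise ValueError(
                "go_per_block + nogo_per_block must equal trials_per_block"
            )
        if not 0.0 < self.rtt_fraction < 1.0:
            raise ValueError("rtt_fraction must lie in (0, 1)")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")


@dataclass
class SubjectProfile:
    """Generative behavioral parameters for a single subject.

    ``rt_mean`` is the target mean Go RT at the beginning-of-session blocks;
    the Gaussian component of the ex-Gaussian is centered so that the
    expected RT (mu + tau) equals ``rt_mean`` at the BEG block center.
    """

    group: str = "SI"
    rt_mean: float = 340.0
    rt_sd: float = 25.0
    rt_tau: float = 40.0
    fa_prob: float = 0.2
    miss_prob: float = 0.02
    practice_rt_drift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fa_prob <= 1.0:
            raise ValueError("fa_prob must lie in [0, 1]")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.rt_sd <= 0:
            raise ValueError("rt_sd must be positive")


@dataclass
class GroupProfileSpec:
    """Group-level distribution from which subject profiles are drawn."""

    group: str
    rt_mean: float
    rt_mean_sd: float
    fa_prob: float
    fa_prob_sd: float
    rt_sd: float = 25.0
    rt_tau: float = 40.0
    miss_prob: float = 0.02
    practice_rt_drift: float = 0.0

    def draw(self, rng: np.random.Generator) -> SubjectProfile:
        rt = rng.normal(self.rt_mean, self.rt_mean_sd)
        fa = float(np.clip(rng.normal(self.fa_prob, self.fa_prob_sd), 0.005, 0.95))
        return SubjectProfile(
            group=self.group,
            rt_mean=max(rt, RT_FLOOR_MS + 50.0),
            rt_sd=self.rt_sd,
            rt_tau=self.rt_tau,
            fa_prob=fa,
            miss_prob=self.miss_prob,
            practice_rt_drift=self.practice_rt_drift,
        )


def default_group_profiles() -> dict[str, GroupProfileSpec]:
    """Defaults reproducing the reference behavioral magnitudes in expectation.

    SI false-alarm rate ~23%, II ~16%; SI mean Go RT ~337 ms at BEG with a
    practice speed-up, II ~357 ms and roughly stable.  Between-subject SDs
    are set so that observed subject-level spread (including binomial noise
    on the false-alarm counts) matches the reference spread.
    """
    return {
        "SI": GroupProfileSpec(
            group="SI", rt_mean=337.1, rt_mean_sd=28.0, fa_prob=0.231,
            fa_prob_sd=0.105, practice_rt_drift=-3.5,
        ),
        "II": GroupProfileSpec(
            group="II", rt_mean=357.5, rt_mean_sd=29.0, fa_prob=0.158,
            fa_prob_sd=0.058, practice_rt_drift=-0.9,
        ),
    }


@dataclass
class EegSimConfig:
    fs: float = 1024.0
    n_channels: int = 64
    epoch_window: tuple[float, float] = (-100.0, 500.0)
    noise_sd: float = 6.0
    pink_sd: float = 6.0
    pink_exponent: float = 1.0
    n_noise_dipoles: int = 12
    effect_window: tuple[float, float] = (218.0, 245.0)
    effect_nodes: tuple[int, ...] | None = None
    effect_amplitude: float = 3.0
    effect_pattern: dict = field(
        default_factory=lambda: {("SI", "CR", "BEG"): 1.0}
    )
    artifact_prob: float = 0.02
    bad_channel_prob: float = 0.1
    subject_gain_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        w0, w1 = self.epoch_window
        e0, e1 = self.effect_window
        if not (w0 <= e0 < e1 <= w1):
            raise ValueError("effect_window must lie inside the epoch window")


# ---------------------------------------------------------------------------
# schedule


def generate_schedule(config: TaskConfig, seed: int) -> pd.DataFrame:
    """Randomized per-block Go/NoGo schedule.

    Each NoGo criterion (one of three letters or three colors) governs two
    consecutive blocks, and letter-based and color-based criteria alternate
    every two blocks; the pairing order is a seeded per-subject permutation.
    Columns: block (1-based), trial (1-based), stim (GO/NOGO),
    nogo_criterion, nogo_token.
    """
    rng = np.random.default_rng(seed)
    letters = list(NOGO_LETTERS)
    colors = list(NOGO_COLORS)
    rng.shuffle(letters)
    rng.shuffle(colors)
    letter_first = bool(rng.integers(2))

    pair_specs: list[tuple[str, str]] = []
    for i in range(max((config.n_blocks + 1) // 2, 0)):
        li, ci = i // 2, i // 2
        if (i % 2 == 0) == letter_first:
            pair_specs.append(("letter", letters[li % len(letters)]))
        else:
            pair_specs.append(("color", colors[ci % len(colors)]))

    n_b, tpb = config.n_blocks, config.trials_per_block
    base = np.array(["GO"] * config.go_per_block + ["NOGO"] * config.nogo_per_block)
    stim_cols, crits, tokens = [], [], []
    for block in range(n_b):
        crit, token = pair_specs[block // 2]
        stims = base.copy()
        rng.shuffle(stims)
        stim_cols.append(stims)
        crits.append(crit)
        tokens.append(token)
    return pd.DataFrame(
        {
            "block": np.repeat(np.arange(1, n_b + 1), tpb),
            "trial": np.tile(np.arange(1, tpb + 1), n_b),
            "stim": np.concatenate(stim_cols) if n_b else np.array([], dtype=str),
            "nogo_criterion": np.repeat(np.array(crits, dtype=object), tpb)
            if n_b
            else np.array([], dtype=object),
            "nogo_token": np.repeat(np.array(tokens, dtype=object), tpb)
            if n_b
            else np.array([], dtype=object),
        }
    )


# ---------------------------------------------------------------------------
# behavior


def _ex_gaussian(
    rng: np.random.Generator, n: int, mu: float, sd: float, tau: float
) -> np.ndarray:
    rt = rng.normal(mu, sd, size=n) + rng.exponential(tau, size=n)
    return np.maximum(rt, RT_FLOOR_MS)


def simulate_behavior(
    schedule: pd.DataFrame,
    profile: SubjectProfile,
    config: TaskConfig,
    seed: int,
) -> pd.DataFrame:
    """Trial log for one subject.

    Emits per-trial outcome labels (HIT/MISS/FA/CR), the per-block adaptive
    response-time threshold (block 1 at ``config.initial_rtt``, then
    ``rtt_fraction`` x previous-block mean Go RT) and 'too late' flags for
    Go responses slower than the block threshold.
    """
    rng = np.random.default_rng(seed)
    beg_center = 2.5  # center of the default BEG blocks 1..4
    gauss_mu0 = profile.rt_mean - profile.rt_tau

    blocks = schedule["block"].to_numpy()
    is_go = (schedule["stim"] == "GO").to_numpy()
    n = len(schedule)

    drift = profile.practice_rt_drift * (blocks - beg_center)
    rts = _ex_gaussian(rng, n, gauss_mu0, profile.rt_sd, profile.rt_tau) + drift
    rts = np.maximum(rts, RT_FLOOR_MS)
    rts[~is_go] = np.maximum(rts[~is_go] - FA_RT_OFFSET_MS, RT_FLOOR_MS)

    responded = np.empty(n, dtype=bool)
    responded[is_go] = rng.random(int(is_go.sum())) >= profile.miss_prob
    responded[~is_go] = rng.random(int((~is_go).sum())) < profile.fa_prob

    rt_col = np.where(responded, rts, np.nan)
    rtt_col = np.empty(n)
    rtt = config.initial_rtt
    for block in np.unique(blocks):
        sel = blocks == block
        rtt_col[sel] = rtt
        go_rts = rt_col[sel & is_go & responded]
        if go_rts.size:
            rtt = config.rtt_fraction * float(np.mean(go_rts))
        # if no Go response occurred the previous threshold carries over

    out = schedule.copy()
    out["response"] = responded.astype(int)
    out["rt_ms"] = rt_col
    out["outcome"] = np.where(
        is_go,
        np.where(responded, "HIT", "MISS"),
        np.where(responded, "FA", "CR"),
    )
    out["rtt_ms"] = rtt_col
    out["too_late"] = (responded & is_go & (rts > rtt_col)).astype(int)
    return out


def simulate_group_study(
    n_si: int,
    n_ii: int,
    profiles: dict[str, GroupProfileSpec] | None = None,
    config: TaskConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Study-level trial log: one simulated subject per row group.

    Subject-level parameters are drawn around the group means; the default
    profiles reproduce the reference Table-1 magnitudes in expectation.
    """
    if n_si <= 0 or n_ii <= 0:
        raise ValueError("group sizes must be positive")
    profiles = profiles or default_group_profiles()
    config = config or TaskConfig()

    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(3 * (n_si + n_ii))
    frames = []
    i_seed = 0
    for group, n in (("SI", n_si), ("II", n_ii)):
        spec = profiles[group]
        for k in range(n):
            prof_rng = np.random.default_rng(subject_seeds[i_seed])
            profile = spec.draw(prof_rng)
            sched = generate_schedule(config, seed=subject_seeds[i_seed + 1])
            log = simulate_behavior(
                sched, profile, config, seed=subject_seeds[i_seed + 2]
            )
            log.insert(0, "subject", f"{group}{k + 1:02d}")
            log.insert(1, "group", group)
            frames.append(log)
            i_seed += 3
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# EEG


def default_effect_nodes(space, n_per_site: int = 1) -> np.ndarray:
    """Stand-in effect sites on the spherical grid.

    Three superficial locations loosely mirroring a right posterior-parietal,
    a right temporo-parietal and a left temporal site.
    """
    r = 0.5 * (space.inner_radius + space.outer_radius)
    targets = np.array(
        [
            [0.15, -0.80, 0.55],
            [0.85, -0.30, 0.40],
            [-0.90, -0.20, 0.15],
        ]
    )
    targets = r * targets / np.linalg.norm(targets, axis=1, keepdims=True)
    idx = []
    for t in targets:
        d = np.linalg.norm(space.nodes - t, axis=1)
        idx.extend(np.argsort(d)[:n_per_site].tolist())
    return np.unique(np.asarray(idx, dtype=int))


def _canonical_nodes(space) -> tuple[int, int]:
    r = 0.5 * (space.inner_radius + space.outer_radius)
    front = r * np.array([0.0, 0.45, 0.90]) / np.linalg.norm([0.0, 0.45, 0.90])
    pari = r * np.array([0.0, -0.55, 0.85]) / np.linalg.norm([0.0, -0.55, 0.85])
    i_front = int(np.argmin(np.linalg.norm(space.nodes - front, axis=1)))
    i_pari = int(np.argmin(np.linalg.norm(space.nodes - pari, axis=1)))
    return i_front, i_pari


def _unit_topography(lf, node: int | np.ndarray) -> np.ndarray:
    """Scalp map of radially oriented unit sources, peak-normalized to 1."""
    nodes = np.atleast_1d(node)
    topo = np.zeros(lf.n_channels)
    for nd in nodes:
        direction = lf.space.nodes[nd] / np.linalg.norm(lf.space.nodes[nd])
        topo += lf.gain[:, nd, :] @ direction
    peak = np.max(np.abs(topo))
    return topo / peak if peak > 0 else topo


def _pink_spectrum_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, exponent: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit variance."""
    n_f = n_samples // 2 + 1
    freqs = np.arange(n_f, dtype=float)
    freqs[0] = 1.0
    amp = freqs ** (-exponent / 2.0)
    spec = (
        rng.standard_normal(shape + (n_f,)) + 1j * rng.standard_normal(shape + (n_f,))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std()  # series are iid: one global scale preserves relative levels
    return x / sd if sd > 0 else x


def simulate_eeg(
    study: pd.DataFrame,
    leadfield,
    cfg: EegSimConfig,
    beg_blocks: tuple[int, ...] = (1, 2, 3, 4),
    end_blocks: tuple[int, ...] = (9, 10, 11, 12),
) -> dict[str, EpochSet]:
    """EEG epochs for every correct trial of the analyzed blocks.

    Returns a per-subject :class:`EpochSet` labeled HIT/CR with block tags;
    ``meta`` records the group, session blocks, planted effect nodes and any
    bad channel.
    """
    if leadfield.n_channels != cfg.n_channels:
        raise ValueError("lead field electrode count does not match config")
    space = leadfield.space
    if cfg.effect_nodes is None:
        effect_nodes = default_effect_nodes(space)
    else:
        effect_nodes = np.asarray(cfg.effect_nodes, dtype=int)
        if effect_nodes.size and (
            effect_nodes.min() < 0 or effect_nodes.max() >= space.n_nodes
        ):
            raise IndexError("effect_nodes outside the source space")

    fs = cfg.fs
    n_samp = n_window_samples(cfg.epoch_window, fs)
    times = cfg.epoch_window[0] + np.arange(n_samp) * (1000.0 / fs)

    i_front, i_pari = _canonical_nodes(space)
    topo_n2 = _unit_topography(leadfield, i_front)
    topo_p3 = _unit_topography(leadfield, i_pari)
    topo_eff = _unit_topography(leadfield, effect_nodes)

    course_n2 = -np.exp(-0.5 * ((times - 200.0) / 20.0) ** 2)
    course_p3 = np.exp(-0.5 * ((times - 350.0) / 45.0) ** 2)
    # effect course: smoothed plateau covering the whole effect window
    e0, e1 = cfg.effect_window
    edge = max((e1 - e0) / 6.0, 2.0)
    course_eff = 1.0 / (1.0 + np.exp(-(times - e0) / edge))
    course_eff *= 1.0 / (1.0 + np.exp((times - e1) / edge))
    course_eff /= course_eff.max()

    blocks_used = tuple(beg_blocks) + tuple(end_blocks)
    session_of = {b: "BEG" for b in beg_blocks}
    session_of.update({b: "END" for b in end_blocks})

    ss = np.random.SeedSequence(cfg.seed)
    subjects = study["subject"].unique()
    subject_seeds = ss.spawn(len(subjects))

    out: dict[str, EpochSet] = {}
    for subj, subj_seed in zip(subjects, subject_seeds):
        rng = np.random.default_rng(subj_seed)
        sublog = study[study["subject"] == subj]
        group = str(sublog["group"].iloc[0])
        trials = sublog[
            sublog["block"].isin(blocks_used)
            & sublog["outcome"].isin(["HIT", "CR"])
        ]
        n_ep = len(trials)

        gain_n2 = 5.0 * max(rng.normal(1.0, cfg.subject_gain_sd), 0.1)
        gain_p3 = 7.0 * max(rng.normal(1.0, cfg.subject_gain_sd), 0.1)
        gain_eff = max(rng.normal(1.0, cfg.subject_gain_sd), 0.1)

        # spatially correlated noise: random fixed dipoles, pink time courses
        n_noise = cfg.n_noise_dipoles
        noise_nodes = rng.integers(0, space.n_nodes, size=n_noise)
        noise_gain = leadfield.gain[:, noise_nodes, :].reshape(
            leadfield.n_channels, 3 * n_noise
        )

        labels = trials["outcome"].to_numpy(dtype=object)
        blocks = trials["block"].to_numpy(dtype=int)
        sessions = np.array([session_of[b] for b in blocks])
        mults = np.array(
            [
                cfg.effect_pattern.get((group, lab, ses), 0.0)
                for lab, ses in zip(labels, sessions)
            ]
        )

        base = gain_n2 * np.outer(topo_n2, course_n2) + gain_p3 * np.outer(
            topo_p3, course_p3
        )
        eff = (cfg.effect_amplitude * gain_eff) * np.outer(topo_eff, course_eff)
        # (n_ep, channels, samples)
        data = np.broadcast_to(base, (n_ep,) + base.shape).copy()
        data += mults[:, None, None] * eff

        if cfg.pink_sd > 0 and n_ep:
            moments = _pink_spectrum_noise(
                rng, (n_ep, 3 * n_noise), n_samp, cfg.pink_exponent
            )
            flat = np.moveaxis(moments, 1, 0).reshape(3 * n_noise, n_ep * n_samp)
            spatial = (noise_gain @ flat).reshape(cfg.n_channels, n_ep, n_samp)
            spatial = np.moveaxis(spatial, 1, 0)
            scale = spatial.std()
            if scale > 0:
                spatial *= cfg.pink_sd / scale
            data += spatial
        if cfg.noise_sd > 0:
            data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
        artifact = rng.random(n_ep) < cfg.artifact_prob
        for i in np.flatnonzero(artifact):
            ch = rng.integers(cfg.n_channels)
            t0 = rng.integers(n_samp)
            width = max(int(0.02 * fs), 2)
            lo, hi = max(0, t0 - width), min(n_samp, t0 + width)
            data[i, ch, lo:hi] += rng.choice([-1.0, 1.0]) * 150.0
        data = np.transpose(data, (1, 2, 0))  # -> (channels, samples, epochs)

        bad_channels: list[int] = []
        if rng.random() < cfg.bad_channel_prob:
            bad = int(rng.integers(cfg.n_channels))
            bad_channels = [bad]
            drift = _pink_spectrum_noise(rng, (n_ep,), n_samp, 2.0) * 30.0
            data[bad] += drift.T

        out[str(subj)] = EpochSet(
            data=data,
            fs=fs,
            window_ms=cfg.epoch_window,
            blocks=blocks,
            labels=labels.astype(str),
            meta={
                "subject": str(subj),
                "group": group,
                "units": "uV",
                "bad_channels": bad_channels,
                "effect_nodes": [int(v) for v in np.atleast_1d(effect_nodes)],
                "beg_blocks": list(beg_blocks),
                "end_blocks": list(end_blocks),
            },
        )
    return out
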