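"""Behavioral summaries and the statistical battery applied to trial logs.

Implements per-subject response-time outlier rejection, session aggregation,
signal-detection scores (d', C), pooled and Welch two-sample t tests, the
2x2 mixed (split-plot) ANOVA used both here and point-wise on EEG data,
Levene's homogeneity test, Lilliefors-style normality testing, and
speed-accuracy-tradeoff correlations with Holm step-down correction.

The mixed ANOVA exposes a vectorized core (`mixed_anova_2x2_vectorized`)
that evaluates the same decomposition simultaneously at many measurement
points; the electrode x time and node-wise analyses delegate to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehavioralSummary",
    "TTestResult",
    "MixedAnovaResult",
    "reject_rt_outliers",
    "summarize",
    "sdt_scores",
    "pooled_t",
    "welch_t",
    "mixed_anova_2x2",
    "mixed_anova_2x2_vectorized",
    "levene_test",
    "sat_correlations",
    "holm_bonferroni",
    "ks_normality",
]

BEG_BLOCKS = (1, 2, 3, 4)
END_BLOCKS = (9, 10, 11, 12)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class BehavioralSummary:
    subject: str
    group: str
    session: str
    rt_mean: float
    fa_rate: float
    hit_rate: float
    d_prime: float
    c_criterion: float


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    variant: str

    def as_dict(self) -> dict:
        return {
            "test": f"t_{self.variant}",
            "statistic": self.t,
            "df": self.df,
            "p": self.p,
            "effect_size": self.cohens_d,
        }


@dataclass
class AnovaEffect:
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float


@dataclass
class MixedAnovaResult:
    between: AnovaEffect
    within: AnovaEffect
    interaction: AnovaEffect

    def as_dict(self) -> dict:
        out = {}
        for name in ("between", "within", "interaction"):
            e: AnovaEffect = getattr(self, name)
            out[name] = {
                "F": e.F,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "p": e.p,
                "partial_eta_sq": e.partial_eta_sq,
            }
        return out


# ---------------------------------------------------------------------------
# trial-log operations


def reject_rt_outliers(log: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop responded Go trials deviating more than 2 SD from the subject mean.

    Mean and (sample) SD are computed per subject over responded Go trials;
    removal uses a strict ``> 2 SD`` rule, so a zero-SD subject loses no
    trials.  Returns the filtered log and the fraction of responded Go
    trials removed.
    """
    log = log.copy()
    responded_go = (log["stim"] == "GO") & (log["response"] == 1)
    if int(responded_go.sum()) < 2:
        raise ValueError("need at least 2 responded trials for outlier rejection")

    drop = pd.Series(False, index=log.index)
    subjects = (
        log.loc[responded_go, "subject"].unique()
        if "subject" in log.columns
        else [None]
    )
    for subj in subjects:
        if subj is None:
            mask = responded_go
        else:
            mask = responded_go & (log["subject"] == subj)
        rts = log.loc[mask, "rt_ms"].to_numpy(dtype=float)
        if rts.size < 2:
            continue
        mean = rts.mean()
        sd = rts.std(ddof=1)
        drop.loc[mask] = np.abs(log.loc[mask, "rt_ms"] - mean) > 2.0 * sd

    n_removed = int(drop.sum())
    if n_removed == int(responded_go.sum()):
        raise ValueError("outlier rejection removed every responded trial")
    frac = n_removed / int(responded_go.sum())
    return log.loc[~drop].reset_index(drop=True), frac


def summarize(
    log: pd.DataFrame,
    session_blocks: tuple[int, ...],
    session: str = "",
    c_sign: str = "paper",
) -> BehavioralSummary:
    """Session-level behavioral summary over the given blocks.

    ``rt_mean`` averages responded Go trials (HITs); ``fa_rate`` is
    FA/(FA+CR); ``hit_rate`` HIT/(HIT+MISS), both over the selected blocks.
    """
    sel = log[log["block"].isin(session_blocks)]
    missing = set(session_blocks) - set(log["block"].unique())
    if missing:
        raise ValueError(f"blocks {sorted(missing)} absent from log")
    nogo = sel[sel["stim"] == "NOGO"]
    go = sel[sel["stim"] == "GO"]
    if len(nogo) == 0:
        raise ValueError("no NoGo trials in the selected blocks")
    n_fa = int((nogo["outcome"] == "FA").sum())
    n_cr = int((nogo["outcome"] == "CR").sum())
    n_hit = int((go["outcome"] == "HIT").sum())
    n_miss = int((go["outcome"] == "MISS").sum())
    fa_rate = n_fa / (n_fa + n_cr)
    hit_rate = n_hit / (n_hit + n_miss) if (n_hit + n_miss) else np.nan
    hits = go[go["outcome"] == "HIT"]
    rt_mean = float(hits["rt_ms"].mean()) if len(hits) else np.nan
    d_prime, c_crit = sdt_scores(
        hit_rate, fa_rate, n_go=n_hit + n_miss, n_nogo=n_fa + n_cr, c_sign=c_sign
    )
    subject = str(log["subject"].iloc[0]) if "subject" in log.columns else ""
    group = str(log["group"].iloc[0]) if "group" in log.columns else ""
    return BehavioralSummary(
        subject=subject,
        group=group,
        session=session,
        rt_mean=rt_mean,
        fa_rate=fa_rate,
        hit_rate=hit_rate,
        d_prime=d_prime,
        c_criterion=c_crit,
    )


def summarize_study(
    study: pd.DataFrame,
    beg_blocks: tuple[int, ...] = BEG_BLOCKS,
    end_blocks: tuple[int, ...] = END_BLOCKS,
    reject_outliers: bool = True,
    c_sign: str = "paper",
) -> pd.DataFrame:
    """Per-subject BEG/END summaries for a whole study log.

    Vectorized equivalent of calling :func:`reject_rt_outliers` and
    :func:`summarize` per subject (asserted by the test suite).
    """
    log = study
    if reject_outliers:
        responded_go = (log["stim"] == "GO") & (log["response"] == 1)
        rts = log["rt_ms"].where(responded_go)
        grp = rts.groupby(log["subject"])
        dev = (rts - grp.transform("mean")).abs()
        drop = responded_go & (dev > 2.0 * grp.transform("std"))
        log = log.loc[~drop]

    frames = []
    for name, blocks in (("BEG", beg_blocks), ("END", end_blocks)):
        sel = log[log["block"].isin(blocks)]
        by = sel.groupby("subject", sort=True)
        counts = (
            pd.crosstab(sel["subject"], sel["outcome"])
            .reindex(columns=["HIT", "MISS", "FA", "CR"], fill_value=0)
            .sort_index()
        )
        hits = sel[sel["outcome"] == "HIT"]
        rt_mean = hits.groupby("subject")["rt_ms"].mean().reindex(counts.index)
        group = by["group"].first().reindex(counts.index)

        n_go = counts["HIT"] + counts["MISS"]
        n_nogo = counts["FA"] + counts["CR"]
        if (n_nogo == 0).any():
            raise ValueError("a subject has no NoGo trials in the selected blocks")
        fa_rate = counts["FA"] / n_nogo
        hit_rate = counts["HIT"] / n_go.replace(0, np.nan)
        d_prime = np.empty(len(counts))
        c_crit = np.empty(len(counts))
        for i, subj in enumerate(counts.index):
            d_prime[i], c_crit[i] = sdt_scores(
                float(hit_rate.loc[subj]),
                float(fa_rate.loc[subj]),
                int(n_go.loc[subj]),
                int(n_nogo.loc[subj]),
                c_sign=c_sign,
            )
        frames.append(
            pd.DataFrame(
                {
                    "subject": counts.index,
                    "group": group.to_numpy(),
                    "session": name,
                    "rt_mean": rt_mean.to_numpy(),
                    "fa_rate": fa_rate.to_numpy(),
                    "hit_rate": hit_rate.to_numpy(),
                    "d_prime": d_prime,
                    "c_criterion": c_crit,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject", "session"], ignore_index=True)


# ---------------------------------------------------------------------------
# signal detection


def sdt_scores(
    hit_rate: float,
    fa_rate: float,
    n_go: int,
    n_nogo: int,
    c_sign: str = "paper",
) -> tuple[float, float]:
    """d' and response criterion C from hit and false-alarm rates.

    Boundary rates are corrected to 1/(2N) and 1 - 1/(2N) before the
    normal-quantile transform.  ``c_sign='paper'`` returns
    C = (z(hit) + z(fa)) / 2; ``'standard'`` negates it.
    """
    if n_go <= 0 or n_nogo <= 0:
        raise ValueError("trial counts must be positive")
    if c_sign not in ("paper", "standard"):
        raise ValueError("c_sign must be 'paper' or 'standard'")
    hit = _correct_rate(hit_rate, n_go)
    fa = _correct_rate(fa_rate, n_nogo)
    zh = stats.norm.ppf(hit)
    zf = stats.norm.ppf(fa)
    d_prime = zh - zf
    c = (zh + zf) / 2.0
    if c_sign == "standard":
        c = -c
    return float(d_prime), float(c)


def _correct_rate(rate: float, n: int) -> float:
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


# ---------------------------------------------------------------------------
# two-sample t tests


def _summary_stats(sample) -> tuple[float, float, int]:
    x = np.asarray(sample, dtype=float)
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def pooled_t(
    mean1, sd1=None, n1=None, mean2=None, sd2=None, n2=None
) -> TTestResult:
    """Classical pooled-variance unpaired t test.

    Accepts either six summary numbers or two raw samples
    (``pooled_t(sample1, sample2)``).
    """
    if np.ndim(mean1) >= 1:
        sample2 = sd1
        mean1, sd1, n1 = _summary_stats(mean1)
        mean2, sd2, n2 = _summary_stats(sample2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    d = diff / np.sqrt(sp2) if sp2 > 0 else (0.0 if diff == 0.0 else np.inf)
    return TTestResult(t=float(t), df=float(df), p=p, cohens_d=float(d), variant="pooled")


def welch_t(
    mean1, sd1=None, n1=None, mean2=None, sd2=None, n2=None
) -> TTestResult:
    """Welch unequal-variance t with Satterthwaite degrees of freedom."""
    if np.ndim(mean1) >= 1:
        sample2 = sd1
        mean1, sd1, n1 = _summary_stats(mean1)
        mean2, sd2, n2 = _summary_stats(sample2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    diff = mean1 - mean2
    if v1 + v2 == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        df = float(n1 + n2 - 2)
    else:
        t = diff / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    d = diff / np.sqrt(sp2) if sp2 > 0 else (0.0 if diff == 0.0 else np.inf)
    return TTestResult(t=float(t), df=float(df), p=p, cohens_d=float(d), variant="welch")


# ---------------------------------------------------------------------------
# 2x2 mixed (split-plot) ANOVA

# With two within-subject levels the split-plot model reduces exactly to two
# orthogonal strata: per-subject averages a_i = (y_i1 + y_i2) / 2 carry the
# between-group effect, and per-subject differences d_i = y_i2 - y_i1 carry
# the within effect (intercept of d) and the interaction (group effect on d).
# Type-III tests with unbalanced groups use unweighted group-mean contrasts.


def mixed_anova_2x2_vectorized(
    y: np.ndarray, groups: np.ndarray
) -> dict[str, dict[str, np.ndarray]]:
    """Vectorized 2 (group) x 2 (within) mixed ANOVA.

    Parameters
    ----------
    y : array, shape (n_subjects, 2, ...)
        Measurements at the two within-subject levels; trailing axes are
        independent measurement points (e.g. electrodes x samples).
    groups : array of shape (n_subjects,)
        Two distinct group labels.

    Returns
    -------
    dict with keys ``between``, ``within``, ``interaction``; each maps to
    ``{"F": ..., "p": ..., "partial_eta_sq": ..., "df": (1, N-2)}`` with
    arrays shaped like the trailing axes of ``y``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 2 or y.shape[1] != 2:
        raise ValueError("y must have shape (n_subjects, 2, ...)")
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    m1 = groups == levels[0]
    m2 = groups == levels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    n_tot = n1 + n2
    df_den = n_tot - 2

    a = y.mean(axis=1)          # subject averages  (between stratum)
    d = y[:, 1] - y[:, 0]       # subject differences (within stratum)

    out: dict[str, dict[str, np.ndarray]] = {}
    for name, z, contrast in (
        ("between", a, "group"),
        ("within", d, "mean"),
        ("interaction", d, "group"),
    ):
        g1 = z[m1].mean(axis=0)
        g2 = z[m2].mean(axis=0)
        ss_err = ((z[m1] - g1) ** 2).sum(axis=0) + ((z[m2] - g2) ** 2).sum(axis=0)
        mse = ss_err / df_den
        if contrast == "group":
            num = (g1 - g2) ** 2 / (1.0 / n1 + 1.0 / n2)
        else:  # unweighted grand mean of the two group means (Type III)
            num = ((g1 + g2) / 2.0) ** 2 / ((1.0 / n1 + 1.0 / n2) / 4.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(num == 0.0, 0.0, num / mse)
        F = np.where(np.isnan(F), 0.0, F)
        p = stats.f.sf(F, 1, df_den)
        with np.errstate(divide="ignore", invalid="ignore"):
            eta = np.where(np.isinf(F), 1.0, F / (F + df_den))
        out[name] = {
            "F": F,
            "p": p,
            "partial_eta_sq": eta,
            "df": (1.0, float(df_den)),
        }
    return out


def mixed_anova_2x2(y: np.ndarray, groups: np.ndarray) -> MixedAnovaResult:
    """Scalar 2x2 mixed ANOVA; ``y`` shaped (n_subjects, 2)."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be (n_subjects, 2)")
    if np.isnan(y).any():
        raise ValueError("missing cell in mixed ANOVA input")
    res = mixed_anova_2x2_vectorized(y[:, :, None], groups)
    effects = {}
    for name in ("between", "within", "interaction"):
        r = res[name]
        effects[name] = AnovaEffect(
            F=float(r["F"][0]),
            df_num=r["df"][0],
            df_den=r["df"][1],
            p=float(r["p"][0]),
            partial_eta_sq=float(r["partial_eta_sq"][0]),
        )
    return MixedAnovaResult(**effects)


# ---------------------------------------------------------------------------
# auxiliary tests


def levene_test(*samples) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (mean-centered variant)."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    F, p = stats.levene(*arrs, center="mean")
    return float(F), float(p)


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection decisions for a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def sat_correlations(
    summaries: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Speed-accuracy-tradeoff correlations per group x session cell.

    Pearson r between ``rt_mean`` and ``fa_rate`` across subjects within
    each (group, session) cell, with Holm step-down over the family.
    """
    rows = []
    for (group, session), cell in summaries.groupby(["group", "session"], sort=True):
        if len(cell) < 3:
            raise ValueError(f"cell ({group}, {session}) has fewer than 3 subjects")
        x = cell["rt_mean"].to_numpy(dtype=float)
        y = cell["fa_rate"].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"group": group, "session": session, "r": r, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna().to_numpy()
    sig = np.zeros(len(out), dtype=bool)
    if valid.any():
        sig[valid] = holm_bonferroni(out.loc[valid, "p"].to_numpy(), alpha=alpha)
    out["holm_significant"] = sig
    return out


def ks_normality(sample, n_mc: int = 0, seed: int = 0) -> tuple[float, float]:
    """Normality test against a normal with estimated mean/SD.

    Uses the Lilliefors correction (plain KS p-values would be
    anticonservative with estimated parameters).  With ``n_mc > 0`` the
    null distribution of D is simulated directly instead of using the
    statsmodels table approximation.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std(ddof=1) == 0.0:
        raise ValueError("constant sample")

    def _stat(v: np.ndarray) -> float:
        z = np.sort((v - v.mean()) / v.std(ddof=1))
        cdf = stats.norm.cdf(z)
        n = v.size
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(n) / n)
        return float(max(d_plus, d_minus))

    D = _stat(x)
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        null = np.array([_stat(rng.standard_normal(x.size)) for _ in range(n_mc)])
        p = float((1 + np.sum(null >= D)) / (n_mc + 1))
    else:
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(x, dist="norm")
        p = float(p)
    return D, p
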