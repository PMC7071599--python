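"""Tissue-vs-rest differential expression with empirical-Bayes moderation.

Per transcript and tissue, a two-group linear model on log2 values gives
the effect (target mean minus rest-of-samples mean) and a pooled residual
variance with n - 2 degrees of freedom. Residual variances are shrunk
toward a prior fitted by method of moments on the log variances, and the
moderated t is referred to a t distribution with the augmented degrees of
freedom. The headline filter keeps transcripts passing |fold change| >
fc_cut and p < p_cut in at least one tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist


@dataclass(frozen=True)
class EBPrior:
    """Prior degrees of freedom and prior variance for variance shrinkage."""

    d0: float  # may be math.inf for homogeneous variances
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive (possibly inf)")
        if not self.s0_sq >= 0:
            raise ValueError("s0_sq must be non-negative")
        # s0_sq == 0 is a degenerate limit: moderated_t then reports
        # infinite statistics; estimate_prior never produces it


def fit_tissue_vs_rest(
    log2_values: pd.DataFrame,
    tissue_of: Mapping[str, str],
    target_tissue: str,
) -> pd.DataFrame:
    """Two-group fit per transcript: effect, pooled residual variance, df.

    Columns of ``log2_values`` are samples; ``tissue_of`` maps each to its
    tissue. Returns a frame indexed by transcript with columns
    ``effect``, ``s2``, ``df``, ``n_target``, ``n_rest``.
    """
    samples = list(log2_values.columns)
    target = [s for s in samples if tissue_of[s] == target_tissue]
    rest = [s for s in samples if tissue_of[s] != target_tissue]
    if len(target) < 2:
        raise ValueError(f"tissue {target_tissue!r} has {len(target)} sample(s); need >= 2")
    if len(rest) < 2:
        raise ValueError(f"rest group for {target_tissue!r} has {len(rest)} sample(s); need >= 2")
    yt = log2_values[target].to_numpy(dtype=float)
    yr = log2_values[rest].to_numpy(dtype=float)
    mt, mr = yt.mean(axis=1), yr.mean(axis=1)
    rss = ((yt - mt[:, None]) ** 2).sum(axis=1) + ((yr - mr[:, None]) ** 2).sum(axis=1)
    df = len(target) + len(rest) - 2
    return pd.DataFrame(
        {
            "effect": mt - mr,
            "s2": rss / df,
            "df": float(df),
            "n_target": len(target),
            "n_rest": len(rest),
        },
        index=log2_values.index,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def estimate_prior(s2, df) -> EBPrior:
    """Method-of-moments fit of (d0, s0_sq) on the log residual variances.

    Matches the mean and variance of log(s2) to the scaled-F /
    log-chi-square theory; when the empirical spread of log variances does
    not exceed the sampling floor, the variances are homogeneous and d0 is
    +infinity with s0_sq the mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; degenerate input")
    if pos.sum() < 10:
        raise ValueError("need >= 10 transcripts with positive variance to fit the prior")
    s2p, dfp = s2[pos], df[pos]
    z = np.log(s2p)
    e = z - digamma(dfp / 2.0) + np.log(dfp / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(polygamma(1, dfp / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    else:
        d0 = math.inf
        s0_sq = float(s2p.mean())
    return EBPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(effect, s2, df, prior: EBPrior, n_target: int, n_rest: int):
    """Moderated t statistic, two-sided p, and total degrees of freedom.

    The posterior variance is ``(d0*s0_sq + df*s2) / (d0 + df)`` (s0_sq
    when d0 is infinite); the statistic is referred to a t distribution
    with ``df + d0`` degrees of freedom, which degenerates to the normal
    reference when d0 is infinite (the posterior variance is then exact,
    so a t reference would be miscalibrated). A zero posterior variance
    yields an infinite statistic with p = 0.
    """
    effect = np.asarray(effect, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), effect.shape)
    if math.isinf(prior.d0):
        s2_post = np.full_like(effect, prior.s0_sq)
        df_total = np.full_like(df, np.inf, dtype=float)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    c = 1.0 / n_target + 1.0 / n_rest
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * c)
    # zero posterior variance: t undefined -> +-inf (0 when effect is 0 too)
    t = np.where(s2_post == 0, np.where(effect == 0, 0.0, np.sign(effect) * np.inf), t)
    p = 2.0 * t_dist.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p, df_total


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def de_table(
    log2_values: pd.DataFrame,
    tissue_of: Mapping[str, str],
    tissues: Sequence[str] | None = None,
    fc_cut: float = 5.0,
    p_cut: float = 1e-6,
) -> pd.DataFrame:
    """Full DE table over all tissues (one tissue-vs-rest contrast each).

    Columns: transcript, tissue, log2_fc, t_mod, p, q (BH within tissue),
    df_total, passes_filter.
    """
    if tissues is None:
        tissues = sorted(set(tissue_of.values()))
    frames = []
    for tissue in tissues:
        fit = fit_tissue_vs_rest(log2_values, tissue_of, tissue)
        prior = estimate_prior(fit["s2"], fit["df"])
        t, p, df_total = moderated_t(
            fit["effect"], fit["s2"], fit["df"], prior,
            int(fit["n_target"].iloc[0]), int(fit["n_rest"].iloc[0]),
        )
        frames.append(
            pd.DataFrame(
                {
                    "transcript": fit.index,
                    "tissue": tissue,
                    "log2_fc": fit["effect"].to_numpy(),
                    "t_mod": t,
                    "p": p,
                    "q": _bh_adjust(np.asarray(p)),
                    "df_total": df_total,
                    "passes_filter": (np.abs(fit["effect"].to_numpy()) > np.log2(fc_cut)) & (p < p_cut),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def apply_filter(table: pd.DataFrame, fc_cut: float = 5.0, p_cut: float = 1e-6) -> set[str]:
    """Transcripts passing |fold change| > fc_cut and p < p_cut in >= 1 tissue."""
    mask = (table["log2_fc"].abs() > np.log2(fc_cut)) & (table["p"] < p_cut)
    return set(table.loc[mask, "transcript"])
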