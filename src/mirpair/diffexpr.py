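"""Two-group differential expression on log2 intensities.

The responder-vs-non-responder contrast is summarised per feature by the
log-ratio (mean log2 intensity in R minus mean in NR), the signed linear fold
change derived from it, and a two-sided test that is either the classical
pooled-variance two-sample t (equivalent to one-way two-group ANOVA, F = t²)
or an empirical-Bayes moderated t in which per-feature variances are shrunk
toward a common prior:

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),   t_g = lr_g / (s̃_g·√(1/n_R+1/n_NR))

referred to a t distribution on d0 + d_g degrees of freedom. The prior
(d0, s0²) is estimated by moment-matching the marginal distribution of
log s²_g through the digamma/trigamma relations, the standard empirical-Bayes
fit for microarray linear models.

Features are called differentially expressed when |FC| ≥ 1.2 and
p ≤ 0.05, both inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 1.2
DEFAULT_P_THRESHOLD = 0.05


@dataclasses.dataclass
class DEResult:
    """Per-feature differential-expression summary (R vs NR)."""

    feature_id: str
    logratio: float
    fc_signed: float
    mean_exp: float
    t_stat: float
    df: float
    p_value: float
    adj_p: float
    passes_filter: bool
    zero_variance: bool = False


def signed_fold_change(logratio: float) -> float:
    """Signed linear fold change from a log2 ratio.

    Up-regulation maps to 2**logratio (≥ 1); down-regulation is reported as
    the negative reciprocal fold, −2**(−logratio), so the magnitude is always
    ≥ 1 and the sign carries the direction. fc(0) = 1 exactly and
    fc(−x) = −fc(x).
    """
    lr = float(logratio)
    if not math.isfinite(lr):
        raise ValueError(f"logratio must be finite, got {lr}")
    return 2.0 ** lr if lr >= 0 else -(2.0 ** (-lr))


def group_log_ratio(expr: ExpressionMatrix, sheet: SampleSheet, feature: str) -> float:
    """Mean log2 intensity in responders minus mean in non-responders."""
    row = expr.row(feature)
    mask_r, mask_nr = sheet.masks_for(expr.sample_ids)
    if not mask_r.any() or not mask_nr.any():
        raise ValueError("both groups must contain at least one sample")
    return float(row[mask_r].mean() - row[mask_nr].mean())


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    return multipletests(p, method="fdr_bh")[1]


def _fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-matching estimate of the prior (d0, s0²) from sample variances.

    Works on z = log s² whose distribution, for s²·d/σ² ~ χ²_d scaled, has
    known digamma mean and trigamma variance; the excess variance of z over
    trigamma(d/2) identifies trigamma(d0/2), inverted by Newton iteration.
    Returns (inf, geometric-mean variance) when there is no excess variance
    (all sample variances essentially equal).
    """
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    e_mean = float(e.mean())
    n = e.size
    if n < 2:
        raise ValueError("at least 2 features with positive variance are "
                         "needed to estimate the variance prior")
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1) * n / (n - 1))
    excess = e_var - float(special.polygamma(1, df_resid / 2.0))
    if excess <= 0:
        logger.warning(
            "no excess variance across features; using infinite prior df "
            "(all variances shrunk to the common value)"
        )
        return math.inf, math.exp(e_mean)
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(e_mean + float(special.digamma(half_d0)) - math.log(half_d0))
    return d0, s0_sq


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton's method on 1/trigamma."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def two_group_test(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    method: str = "pooled",
    prior_df: float | None = None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[DEResult]:
    """Per-feature R-vs-NR test on log2 intensities.

    Parameters
    ----------
    method
        ``"pooled"`` for the classical equal-variance two-sample t
        (df = n_R + n_NR − 2, squaring to the one-way ANOVA F), or
        ``"moderated"`` for the empirical-Bayes moderated t.
    prior_df
        Override for the moderated prior degrees of freedom d0 (mainly for
        validation: d0 = 0 reduces exactly to the pooled t). ``None``
        estimates d0 from the data.
    fc_threshold, p_threshold
        Inclusive gates recorded in each result's ``passes_filter`` flag.

    Features with zero within-group variance in both groups are assigned
    t = 0, p = 1 and flagged rather than dropped, so downstream pair counts
    stay deterministic.
    """
    if method not in ("pooled", "moderated"):
        raise ValueError(f"unknown method {method!r}")
    mask_r, mask_nr = sheet.masks_for(expr.sample_ids)
    n_r, n_nr = int(mask_r.sum()), int(mask_nr.sum())
    if n_r < 2 or n_nr < 2:
        raise ValueError(f"need >= 2 samples per group, got {n_r} R / {n_nr} NR")

    x_r = expr.values[:, mask_r]
    x_nr = expr.values[:, mask_nr]
    logratio = x_r.mean(axis=1) - x_nr.mean(axis=1)
    mean_exp = expr.values.mean(axis=1)
    ss = ((x_r - x_r.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_nr - x_nr.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = n_r + n_nr - 2
    s2 = ss / df_resid
    zero_var = s2 <= 0
    if zero_var.all():
        raise ValueError("every feature has zero within-group variance")

    se_factor = math.sqrt(1.0 / n_r + 1.0 / n_nr)
    if method == "pooled" or (prior_df is not None and prior_df == 0):
        s2_used = s2
        df_total = np.full(expr.n_features, float(df_resid))
    else:
        if expr.n_features < 2:
            raise ValueError("moderated test needs >= 2 features to fit the prior")
        if prior_df is None:
            d0, s0_sq = _fit_variance_prior(s2[~zero_var], df_resid)
        else:
            d0, s0_sq = float(prior_df), float(np.exp(np.log(s2[~zero_var]).mean()))
        if math.isinf(d0):
            s2_used = np.full_like(s2, s0_sq)
            df_total = np.full(expr.n_features, np.inf)
        else:
            s2_used = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = np.full(expr.n_features, d0 + df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = logratio / (np.sqrt(s2_used) * se_factor)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    t_stat = np.where(zero_var, 0.0, t_stat)
    p = np.where(zero_var, 1.0, p)
    adj = bh_adjust(p)

    results = []
    for i, fid in enumerate(expr.feature_ids):
        fc = signed_fold_change(logratio[i])
        results.append(
            DEResult(
                feature_id=fid,
                logratio=float(logratio[i]),
                fc_signed=fc,
                mean_exp=float(mean_exp[i]),
                t_stat=float(t_stat[i]),
                df=float(df_total[i]) if not zero_var[i] else float(df_resid),
                p_value=float(p[i]),
                adj_p=float(adj[i]),
                passes_filter=bool(abs(fc) >= fc_threshold and p[i] <= p_threshold),
                zero_variance=bool(zero_var[i]),
            )
        )
    return results


def filter_de(
    results: Sequence[DEResult],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[DEResult]:
    """Rows with |FC| ≥ fc_threshold and p ≤ p_threshold (both inclusive)."""
    return [
        r
        for r in results
        if abs(r.fc_signed) >= fc_threshold and r.p_value <= p_threshold
    ]


def write_de_table(results: Sequence[DEResult], path) -> None:
    """Per-feature TSV: feature_id, logratio, FC, meanExp, t, df, p, adj p, pass."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "feature_id\tlogratio\tFC\tmeanExp\tt\tdf\tp-value\tadj.p-value\tpass\n"
        )
        for r in results:
            fh.write(
                f"{r.feature_id}\t{r.logratio:.6g}\t{r.fc_signed:.6g}\t"
                f"{r.mean_exp:.6g}\t{r.t_stat:.6g}\t{r.df:.6g}\t"
                f"{r.p_value:.6g}\t{r.adj_p:.6g}\t{int(r.passes_filter)}\n"
            )
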