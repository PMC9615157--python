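"""mRNA–miRNA anti-correlation integration.

After both modalities are reduced to their differentially expressed features,
every (mRNA, miRNA) combination is scored by the Pearson correlation of
log2 intensities across the pooled samples (both response groups together).
The working hypothesis is repression — a miRNA down-weights its target — so
the primary significance test is one-sided against ρ < 0; t = ρ√(n−2)/√(1−ρ²)
on n − 2 degrees of freedom. Each pair also carries a deregulation weight

    S = −2 · logratio_miRNA · logratio_mRNA

which is positive exactly when the miRNA and the mRNA moved in opposite
directions between responders and non-responders, and grows with the size of
both shifts.

The selection cascade mirrors the published analysis: keep pairs with
correlation-test p ≤ 0.05; restrict to mature, organism-matched miRNAs and
collapse gene isoforms/probes; screen at ρ ≤ −0.38 (the one-sided 5% critical
correlation at n = 20); tighten to ρ ≤ −0.5 with p ≤ 0.05; require S > 0; and
rank the survivors by ρ ascending, then p, then S descending.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import OrderedDict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import diffexpr
from .io import ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

DEFAULT_RHO_SCREEN = -0.38
DEFAULT_RHO_FINAL = -0.5
DEFAULT_PAIR_P = 0.05


@dataclasses.dataclass
class PairResult:
    """One candidate mRNA–miRNA pair with all reported columns."""

    mirna_id: str
    mrna_id: str
    cor: float
    p_value: float
    adj_p: float
    logratio_mirna: float
    logratio_mrna: float
    mean_exp_mirna: float
    mean_exp_mrna: float
    s_score: float
    fc_mirna: float
    fc_mrna: float


@dataclasses.dataclass
class IntegrationConfig:
    """Thresholds and method switches for the full integration run.

    Defaults are the published gates: DE at |FC| ≥ 1.2 and p ≤ 0.05, the
    ρ ≤ −0.38 anti-correlation screen, the final ρ ≤ −0.5 with pair
    p ≤ 0.05, and a strictly positive S score.
    """

    fc_threshold: float = diffexpr.DEFAULT_FC_THRESHOLD
    de_p_threshold: float = diffexpr.DEFAULT_P_THRESHOLD
    de_method: str = "pooled"
    alternative: str = "less"
    rho_screen: float = DEFAULT_RHO_SCREEN
    rho_final: float = DEFAULT_RHO_FINAL
    pair_p_threshold: float = DEFAULT_PAIR_P
    require_positive_s: bool = True
    organism: str = "hsa"

    def validate(self) -> None:
        if not 0 < self.pair_p_threshold < 1 or not 0 < self.de_p_threshold < 1:
            raise ValueError("p-value thresholds must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold is a linear fold change >= 1")
        if not -1 <= self.rho_screen <= 0 or not -1 <= self.rho_final <= 0:
            raise ValueError("rho thresholds must lie in [-1, 0]")
        if self.alternative not in ("less", "two_sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.de_method not in ("pooled", "moderated"):
            raise ValueError(f"unknown de_method {self.de_method!r}")


def s_score(logratio_mirna: float, logratio_mrna: float) -> float:
    """Deregulation weight −2·logratio_miRNA·logratio_mRNA."""
    if not (math.isfinite(logratio_mirna) and math.isfinite(logratio_mrna)):
        raise ValueError("logratios must be finite")
    return -2.0 * logratio_mirna * logratio_mrna


def pairwise_pearson(mrna: ExpressionMatrix, mirna: ExpressionMatrix) -> np.ndarray:
    """All-pairs Pearson correlation matrix, mRNA rows × miRNA columns.

    Samples are pooled across both groups and must be identical and in the
    same order in the two matrices. Zero-variance features yield NaN rows or
    columns (their pairs are undefined and excluded from testing) with a
    logged warning.
    """
    if mrna.sample_ids != mirna.sample_ids:
        only_mrna = set(mrna.sample_ids) - set(mirna.sample_ids)
        only_mirna = set(mirna.sample_ids) - set(mrna.sample_ids)
        raise ValueError(
            "sample columns differ or are not aligned: "
            f"only in mRNA matrix {sorted(only_mrna)}, "
            f"only in miRNA matrix {sorted(only_mirna)}"
        )
    n = mrna.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")

    def standardize(values: np.ndarray, label: str, ids: list[str]) -> np.ndarray:
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        flat = norms == 0
        if flat.any():
            logger.warning(
                "%d zero-variance %s feature(s) excluded from correlation: %s",
                int(flat.sum()), label,
                [ids[i] for i in np.flatnonzero(flat)[:5]],
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            out = centered / norms[:, None]
        out[flat] = np.nan
        return out

    xs = standardize(mrna.values, "mRNA", mrna.feature_ids)
    ys = standardize(mirna.values, "miRNA", mirna.feature_ids)
    return np.clip(xs @ ys.T, -1.0, 1.0)


def correlation_pvalue(cor, n: int, alternative: str = "less"):
    """P-value of the Pearson correlation t-test.

    ``less`` integrates the lower tail (the anti-correlation alternative,
    the pipeline default); ``two_sided`` doubles the smaller tail. Accepts a
    scalar or array of correlations. |ρ| = 1 returns the limiting value.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if alternative not in ("less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    r = np.asarray(cor, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    if alternative == "less":
        p = stats.t.cdf(t, df)
        p = np.where(r == -1.0, 0.0, np.where(r == 1.0, 1.0, p))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.abs(r) == 1.0, 0.0, p)
    return float(p) if p.ndim == 0 else p


def critical_r(n: int, alpha: float, alternative: str = "less") -> float:
    """|ρ| at which the correlation test's p-value equals ``alpha``.

    Exact inversion of the t relation: with t* the relevant t quantile on
    n − 2 df, |ρ| = |t*| / √(n − 2 + t*²).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 2
    if alternative == "less":
        t_crit = stats.t.ppf(alpha, df)
    elif alternative == "two_sided":
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return abs(t_crit) / math.sqrt(df + t_crit * t_crit)


def _annotation_lookup(annot: pd.DataFrame | None, column: str, features, default):
    if annot is None:
        return {f: default(f) for f in features}
    table = annot.set_index("feature_id")
    missing = [f for f in features if f not in table.index]
    if missing:
        raise ValueError(f"unannotated feature {missing[0]!r}")
    return {f: table.at[f, column] for f in features}


def dedup_pairs(
    pairs: Sequence[PairResult],
    mirna_annot: pd.DataFrame | None = None,
    mrna_annot: pd.DataFrame | None = None,
    organism: str = "hsa",
) -> list[PairResult]:
    """Restrict to mature, organism-matched miRNAs and collapse gene isoforms.

    With no annotation tables, every miRNA is assumed mature and of the right
    organism and each mRNA probe is its own gene. Otherwise pairs whose miRNA
    is not mature or belongs to another organism are dropped, and among pairs
    sharing a (gene symbol, miRNA) combination only one survives: the most
    negative correlation, ties broken by smaller p, then lexicographic ids.
    """
    mirnas = sorted({p.mirna_id for p in pairs})
    mrnas = sorted({p.mrna_id for p in pairs})
    if mirna_annot is not None:
        mature = _annotation_lookup(mirna_annot, "is_mature", mirnas, lambda f: True)
        org = _annotation_lookup(mirna_annot, "organism", mirnas, lambda f: organism)
    else:
        mature = {m: True for m in mirnas}
        org = {m: organism for m in mirnas}
    gene = _annotation_lookup(mrna_annot, "gene_symbol", mrnas, lambda f: f)

    best: dict[tuple[str, str], PairResult] = {}
    for p in pairs:
        if not bool(mature[p.mirna_id]) or org[p.mirna_id] != organism:
            continue
        key = (str(gene[p.mrna_id]), p.mirna_id)
        cur = best.get(key)
        if cur is None or _dedup_rank(p) < _dedup_rank(cur):
            best[key] = p
    kept = set(map(id, best.values()))
    return [p for p in pairs if id(p) in kept]


def _dedup_rank(p: PairResult):
    return (p.cor, p.p_value, p.mirna_id, p.mrna_id)


def _selection_rank(p: PairResult):
    return (p.cor, p.p_value, -p.s_score, p.mirna_id, p.mrna_id)


def select_pairs(
    pairs: Sequence[PairResult],
    rho_max: float = DEFAULT_RHO_FINAL,
    p_max: float = DEFAULT_PAIR_P,
    require_positive_s: bool = True,
) -> list[PairResult]:
    """Final gate and ranking.

    Retains pairs with p ≤ p_max and ρ ≤ rho_max (both inclusive) and, when
    ``require_positive_s``, a strictly positive S score; sorts by ρ ascending
    (strongest anti-correlation first), then p ascending, then S descending,
    then ids.
    """
    kept = [
        p
        for p in pairs
        if p.p_value <= p_max
        and p.cor <= rho_max
        and (not require_positive_s or p.s_score > 0)
    ]
    return sorted(kept, key=_selection_rank)


def run_integration(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    sheet: SampleSheet,
    config: IntegrationConfig | None = None,
    mrna_annot: pd.DataFrame | None = None,
    mirna_annot: pd.DataFrame | None = None,
) -> tuple[list[PairResult], "OrderedDict[str, int]", list[PairResult]]:
    """Full DE → correlation → S-score → cascade pipeline.

    Returns ``(all_tested, stage_counts, final)``: every pair actually tested
    (post zero-variance exclusion and isoform collapse, the BH adjustment
    universe), the ordered cascade cardinalities, and the ranked final list.
    """
    config = config or IntegrationConfig()
    config.validate()

    de_mrna = diffexpr.two_group_test(
        mrna, sheet, method=config.de_method,
        fc_threshold=config.fc_threshold, p_threshold=config.de_p_threshold,
    )
    de_mirna = diffexpr.two_group_test(
        mirna, sheet, method=config.de_method,
        fc_threshold=config.fc_threshold, p_threshold=config.de_p_threshold,
    )
    keep_mrna = diffexpr.filter_de(de_mrna, config.fc_threshold, config.de_p_threshold)
    keep_mirna = diffexpr.filter_de(de_mirna, config.fc_threshold, config.de_p_threshold)
    de_by_id = {r.feature_id: r for r in de_mrna}
    de_by_id.update({r.feature_id: r for r in de_mirna})

    stage_counts: "OrderedDict[str, int]" = OrderedDict()
    stage_counts["de_mrna"] = len(keep_mrna)
    stage_counts["de_mirna"] = len(keep_mirna)

    if not keep_mrna or not keep_mirna:
        stage_counts.update(
            pairs_all=0, pairs_p=0, pairs_mature_dedup_screen=0,
            pairs_final_rho_p=0, pairs_s_positive=0,
        )
        return [], stage_counts, []

    sub_mrna = mrna.subset_features([r.feature_id for r in keep_mrna])
    sub_mirna = mirna.subset_features([r.feature_id for r in keep_mirna])
    cors = pairwise_pearson(sub_mrna, sub_mirna)
    n = sub_mrna.n_samples

    pairs: list[PairResult] = []
    for i, g in enumerate(sub_mrna.feature_ids):
        for j, m in enumerate(sub_mirna.feature_ids):
            r = cors[i, j]
            if not np.isfinite(r):
                continue
            de_g, de_m = de_by_id[g], de_by_id[m]
            pairs.append(
                PairResult(
                    mirna_id=m,
                    mrna_id=g,
                    cor=float(r),
                    p_value=float(correlation_pvalue(r, n, config.alternative)),
                    adj_p=float("nan"),
                    logratio_mirna=de_m.logratio,
                    logratio_mrna=de_g.logratio,
                    mean_exp_mirna=de_m.mean_exp,
                    mean_exp_mrna=de_g.mean_exp,
                    s_score=s_score(de_m.logratio, de_g.logratio),
                    fc_mirna=de_m.fc_signed,
                    fc_mrna=de_g.fc_signed,
                )
            )

    stage_counts["pairs_all"] = len(pairs)
    sig = [p for p in pairs if p.p_value <= config.pair_p_threshold]
    stage_counts["pairs_p"] = len(sig)

    # BH universe: every pair surviving zero-variance exclusion and dedup.
    tested = dedup_pairs(pairs, mirna_annot, mrna_annot, config.organism)
    for p, adj in zip(tested, diffexpr.bh_adjust([p.p_value for p in tested])):
        p.adj_p = float(adj)

    screened = [
        p for p in tested
        if p.p_value <= config.pair_p_threshold and p.cor <= config.rho_screen
    ]
    stage_counts["pairs_mature_dedup_screen"] = len(screened)
    strong = [
        p for p in screened
        if p.cor <= config.rho_final and p.p_value <= config.pair_p_threshold
    ]
    stage_counts["pairs_final_rho_p"] = len(strong)
    final = select_pairs(
        strong, config.rho_final, config.pair_p_threshold, config.require_positive_s
    )
    stage_counts["pairs_s_positive"] = len(final)
    return tested, stage_counts, final


def write_stage_counts(stage_counts, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stage\tcount\n")
        for stage, count in stage_counts.items():
            fh.write(f"{stage}\t{count}\n")
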