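"""Expression/methylation concordance of copy-number–altered genes.

An altered region is "putative functional" when at least one of its
contained lncRNAs changes expression between tumor and normal samples in the
direction of the alteration (higher in tumor for amplifications, lower for
deletions), with two-sided Welch-test p below ``alpha``. Expression is
tested on log2(x + 1). The module also provides the companion per-gene
contrasts: amplified vs non-amplified tumors, percent of tumors
amplified/expressed, and per-CpG differential methylation on β values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifiedSCNA, GenomeAnnotation
from .models import (
    AMPLIFICATION,
    LNCRNA,
    NORMAL,
    SegmentSet,
    TUMOR,
    ValidationError,
)

logger = logging.getLogger("scnalnc.concordance")

DEFAULT_ALPHA = 0.05


class DegenerateDataError(ValidationError):
    """Too few observations or zero variance in both groups."""


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sided unpaired t test with Welch's correction.

    Returns (t, Welch–Satterthwaite df, two-sided p). Requires at least two
    observations per group and nonzero variance in at least one group.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("welch_t needs >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise DegenerateDataError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class ConcordanceVerdict:
    """Direction-consistency verdict for one gene in one altered region."""

    gene_id: str
    direction: str
    tumor_mean: float
    normal_mean: float
    welch_t: float
    welch_df: float
    p_value: float
    direction_match: bool
    putative_functional: bool


def _split_by_label(matrix: pd.DataFrame, labels: dict[str, str]):
    tumors = [c for c in matrix.columns if labels.get(c) == TUMOR]
    normals = [c for c in matrix.columns if labels.get(c) == NORMAL]
    if not tumors:
        raise ValidationError("expression matrix has no tumor-labeled samples")
    if not normals:
        raise ValidationError("expression matrix has no normal-labeled samples")
    return tumors, normals


def concordance_filter(
    classified: list[ClassifiedSCNA],
    expression: pd.DataFrame,
    labels: dict[str, str],
    annotation: GenomeAnnotation,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[ConcordanceVerdict], list[ClassifiedSCNA]]:
    """Keep altered regions whose contained lncRNAs track the alteration.

    Tests every contained lncRNA of every region on log2(x + 1) expression,
    tumor vs normal. A region survives iff ≥1 contained lncRNA is putative
    functional in the matching direction. Genes absent from the matrix are
    skipped with a warning. Returns (verdicts, surviving regions).
    """
    tumors, normals = _split_by_label(expression, labels)
    log_expr = np.log2(expression + 1.0)
    verdicts: list[ConcordanceVerdict] = []
    survivors: list[ClassifiedSCNA] = []
    for scna in classified:
        lnc = [
            g
            for g in scna.genes
            if g in annotation.by_id and annotation.by_id[g].biotype == LNCRNA
        ]
        survived = False
        for gid in lnc:
            if gid not in log_expr.index:
                logger.warning("gene %s absent from expression matrix; skipped", gid)
                continue
            x = log_expr.loc[gid, tumors].to_numpy()
            y = log_expr.loc[gid, normals].to_numpy()
            t, df, p = welch_t(x, y)
            t_mean = float(expression.loc[gid, tumors].mean())
            n_mean = float(expression.loc[gid, normals].mean())
            match = t_mean > n_mean if scna.peak.direction == AMPLIFICATION else t_mean < n_mean
            functional = bool(match and p < alpha)
            verdicts.append(
                ConcordanceVerdict(
                    gene_id=gid,
                    direction=scna.peak.direction,
                    tumor_mean=t_mean,
                    normal_mean=n_mean,
                    welch_t=t,
                    welch_df=df,
                    p_value=p,
                    direction_match=bool(match),
                    putative_functional=functional,
                )
            )
            survived = survived or functional
        if survived:
            survivors.append(scna)
    return verdicts, survivors


def focal_sample_dosage(segments: SegmentSet, scna: ClassifiedSCNA) -> pd.Series:
    """Length-weighted mean log2 ratio over the focal interval, per tumor."""
    peak = scna.peak
    f_lo, f_hi = peak.focal
    df = segments.segments
    sub = df[(df["chromosome"] == peak.chromosome)]
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    ov = np.minimum(e, f_hi) - np.maximum(s, f_lo)
    hit = ov > 0
    sub = sub[hit]
    w = ov[hit].astype(float)
    tumors = segments.tumor_samples
    num = (
        pd.Series(w * sub["log2_ratio"].to_numpy(), index=sub["sample"]).groupby(level=0).sum()
    )
    den = pd.Series(w, index=sub["sample"]).groupby(level=0).sum()
    mean = (num / den).reindex(tumors).fillna(0.0)
    return mean


def amplified_samples(
    segments: SegmentSet, scna: ClassifiedSCNA, amp_threshold: float = 0.1
) -> list[str]:
    """Tumors whose mean log2 over the focal interval exceeds the threshold.

    For deletion peaks the call is mean log2 < −``amp_threshold``.
    """
    dosage = focal_sample_dosage(segments, scna)
    if scna.peak.direction == AMPLIFICATION:
        return list(dosage.index[dosage > amp_threshold])
    return list(dosage.index[dosage < -amp_threshold])


def amplification_group_test(
    expression_row: pd.Series, amplified_ids: list[str]
) -> dict:
    """Welch test of one gene's expression in amplified vs other tumors."""
    amplified_ids = [s for s in amplified_ids if s in expression_row.index]
    other = [s for s in expression_row.index if s not in set(amplified_ids)]
    if not amplified_ids or not other:
        raise DegenerateDataError("amplified/non-amplified split is degenerate")
    x = np.log2(expression_row[amplified_ids].to_numpy(float) + 1.0)
    y = np.log2(expression_row[other].to_numpy(float) + 1.0)
    t, df, p = welch_t(x, y)
    return {
        "t": t,
        "df": df,
        "p_value": p,
        "amplified_mean": float(expression_row[amplified_ids].mean()),
        "other_mean": float(expression_row[other].mean()),
        "n_amplified": len(amplified_ids),
        "n_other": len(other),
    }


def cohort_summary(
    scna: ClassifiedSCNA,
    segments: SegmentSet,
    expression: pd.DataFrame,
    gene_id: str,
    expr_threshold: float = 0.0,
    amp_threshold: float = 0.1,
) -> dict:
    """Percent of tumors amplified, expressed (FPKM > threshold), and both."""
    tumors = segments.tumor_samples
    amp = set(amplified_samples(segments, scna, amp_threshold))
    expr_cols = [s for s in tumors if s in expression.columns]
    expressed = {
        s for s in expr_cols if float(expression.loc[gene_id, s]) > expr_threshold
    }
    n = len(tumors)
    return {
        "n_tumors": n,
        "percent_amplified": 100.0 * len(amp) / n,
        "percent_expressed": 100.0 * len(expressed) / n,
        "percent_amplified_and_expressed": 100.0 * len(amp & expressed) / n,
    }


def differential_methylation(
    beta: pd.DataFrame, labels: dict[str, str]
) -> pd.DataFrame:
    """Per-CpG tumor-vs-normal Welch tests on β values.

    Returns one row per CpG with t, df, p, group means and a
    hypomethylated-in-tumor flag; CpGs with zero variance in both groups are
    reported with NaN statistics and the run continues.
    """
    tumors, normals = _split_by_label(beta, labels)
    rows = []
    for cpg in beta.index:
        x = beta.loc[cpg, tumors].to_numpy(float)
        y = beta.loc[cpg, normals].to_numpy(float)
        try:
            t, df, p = welch_t(x, y)
        except DegenerateDataError as exc:
            logger.warning("CpG %s: %s", cpg, exc)
            t = df = p = float("nan")
        rows.append(
            {
                "cpg_id": cpg,
                "tumor_mean": x.mean(),
                "normal_mean": y.mean(),
                "t": t,
                "df": df,
                "p_value": p,
                "hypomethylated_in_tumor": bool(x.mean() < y.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("cpg_id")
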