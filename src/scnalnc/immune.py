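"""Single-sample immune-signature scores and amplification contrasts.

Per-sample signature scores use a rank-based weighted Kolmogorov–Smirnov
running-sum area (the ssGSEA family of statistics): within one sample, genes
are ranked by expression (descending, midranks for ties); walking down the
ranking, signature genes add ``rank**alpha`` (normalized to sum 1 over the
signature) and non-members subtract ``1/#misses``; the score is the mean of
the running sum over all steps. Because only ranks enter, scores are
invariant to any strictly monotone transform of a sample's expression.

Group contrasts between amplified and non-amplified tumors use the
two-sided unpaired Wilcoxon rank-sum test: exact by enumeration of rank-sum
assignments for small tie-free samples, normal approximation with tie and
continuity correction otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ValidationError

logger = logging.getLogger("scnalnc.immune")

DEFAULT_SSGSEA_ALPHA = 0.25
EXACT_WILCOXON_MAX_N = 20
DEFAULT_MIN_SIGNATURE_FRACTION = 0.5


def ss_enrichment(values: pd.Series, signature: set[str], alpha: float = DEFAULT_SSGSEA_ALPHA) -> float:
    """Weighted-KS running-sum area score of one signature in one sample.

    ``values`` maps gene id to expression. The signature must hit at least
    one but not all genes of the sample.
    """
    in_sig = np.asarray(values.index.isin(list(signature)))
    n = len(values)
    n_hit = int(in_sig.sum())
    if n_hit == 0 or n_hit == n:
        raise ValidationError(
            f"degenerate signature: {n_hit} of {n} genes in the sample"
        )
    x = values.to_numpy(float)
    # descending midranks: highest expression gets rank n
    ranks = stats.rankdata(x, method="average")
    order = np.lexsort((np.arange(n), -x))  # stable descending walk
    hit = in_sig[order]
    w = np.where(hit, ranks[order] ** alpha, 0.0)
    w_sum = w.sum()
    inc = np.where(hit, w / w_sum, -1.0 / (n - n_hit))
    running = np.cumsum(inc)
    return float(running.sum() / n)


def score_signatures(
    expression: pd.DataFrame,
    signatures: dict[str, set[str]],
    alpha: float = DEFAULT_SSGSEA_ALPHA,
    min_fraction: float = DEFAULT_MIN_SIGNATURE_FRACTION,
) -> pd.DataFrame:
    """Signatures × samples score matrix.

    Signature members absent from the matrix are dropped with a warning; a
    signature errors out when fewer than ``min_fraction`` of its members
    remain.
    """
    rows = {}
    present = set(expression.index)
    for name, members in signatures.items():
        kept = members & present
        if len(kept) < len(members):
            logger.warning(
                "signature %s: %d of %d genes absent from matrix",
                name,
                len(members) - len(kept),
                len(members),
            )
        if len(kept) < min_fraction * len(members) or not kept:
            raise ValidationError(
                f"signature {name}: only {len(kept)}/{len(members)} members present"
            )
        rows[name] = [
            ss_enrichment(expression[c], kept, alpha) for c in expression.columns
        ]
    return pd.DataFrame(rows, index=expression.columns).T


def _exact_wilcoxon_p(ranks: np.ndarray, nx: int, w_obs: float) -> float:
    """Two-sided exact p over all C(n, nx) rank assignments (midranks ok)."""
    n = len(ranks)
    mean = nx * (n + 1) / 2.0
    dev = abs(w_obs - mean)
    count = 0
    total = comb(n, nx)
    for idx in combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        if abs(w - mean) >= dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum test.

    Returns (W, p) with W the rank sum of ``x`` in the pooled midranked
    sample. ``method='auto'`` uses exact enumeration when the pooled size is
    ≤ 20 (midrank enumeration if ties occur), otherwise the normal
    approximation with tie correction and continuity correction; 'exact' and
    'asymptotic' force a branch.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("wilcoxon_rank_sum needs >= 1 observation per group")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValidationError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    n, nx, ny = len(pooled), len(x), len(y)
    ranks = stats.rankdata(pooled, method="average")
    w = float(ranks[:nx].sum())
    if method == "exact" or (method == "auto" and n <= EXACT_WILCOXON_MAX_N):
        if n > 24:
            raise ValidationError("exact enumeration limited to pooled size <= 24")
        p = _exact_wilcoxon_p(ranks, nx, w)
        return w, min(1.0, p)
    mean = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return w, 1.0
    dev = abs(w - mean)
    z = max(dev - 0.5, 0.0) / sqrt(var)  # continuity correction
    p = 2.0 * stats.norm.sf(z)
    return w, min(1.0, p)


@dataclass(frozen=True)
class SignatureContrast:
    signature: str
    median_difference: float  # amplified minus non-amplified
    w: float
    p_value: float
    q_value: float


def infiltration_contrast(
    scores: pd.DataFrame, amplified_ids: list[str]
) -> pd.DataFrame:
    """Per-signature Wilcoxon contrast of amplified vs non-amplified samples.

    Positive median difference means the signature scores higher in
    amplified samples. q values are BH across signatures.
    """
    amplified = [s for s in scores.columns if s in set(amplified_ids)]
    other = [s for s in scores.columns if s not in set(amplified_ids)]
    if not amplified or not other:
        raise ValidationError("amplified/non-amplified split is degenerate")
    rows = []
    for sig in scores.index:
        a = scores.loc[sig, amplified].to_numpy(float)
        b = scores.loc[sig, other].to_numpy(float)
        w, p = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "signature": sig,
                "median_difference": float(np.median(a) - np.median(b)),
                "w": w,
                "p_value": p,
                "n_amplified": len(a),
                "n_other": len(b),
            }
        )
    df = pd.DataFrame(rows).set_index("signature")
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
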