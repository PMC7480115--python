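"""Hypergeometric enrichment of TF binding at altered-gene promoters.

Promoter windows are TSS ± ``flank`` (default 1 kb), clipped to chromosome
bounds. A promoter is "bound" by a TF when it overlaps at least one binding
site of that TF by ≥1 bp (binary, not site-count weighted). For each TF the
upper-tail hypergeometric p-value asks whether bound promoters are
over-represented among the altered set relative to a biotype-matched
universe; q values are Benjamini–Hochberg across TFs (the q column is an
addition beyond the −log10 p ranking and is flagged as such in the output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import GeneModel, Interval, ValidationError

DEFAULT_FLANK = 1000


@dataclass(frozen=True)
class EnrichmentResult:
    """One TF's promoter-binding enrichment in the altered set."""

    tf: str
    k: int  # altered promoters bound
    n: int  # altered promoters tested
    K: int  # universe promoters bound
    N: int  # universe promoters
    p_value: float
    q_value: float = float("nan")

    @property
    def neg_log10_p(self) -> float:
        return -np.log10(self.p_value)


def promoter_windows(
    genes: list[GeneModel],
    flank: int = DEFAULT_FLANK,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, Interval]:
    """TSS ± ``flank`` windows per gene, clipped to chromosome bounds."""
    windows = {}
    for g in genes:
        lo = max(0, g.tss - flank)
        hi = g.tss + flank
        if chrom_lengths and g.chromosome in chrom_lengths:
            hi = min(hi, chrom_lengths[g.chromosome])
        windows[g.gene_id] = Interval(g.chromosome, lo, hi, name=g.gene_id)
    return windows


def bound_promoters(
    windows: dict[str, Interval], sites: dict[str, list[Interval]]
) -> dict[str, set[str]]:
    """Per-TF set of gene ids whose promoter overlaps ≥1 site of that TF."""
    gene_ids = list(windows)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {w.chromosome for w in windows.values()}:
        sub = [(windows[g].start, windows[g].end, g) for g in gene_ids if windows[g].chromosome == chrom]
        by_chrom[chrom] = (
            np.array([s for s, _, _ in sub]),
            np.array([e for _, e, _ in sub]),
            [g for _, _, g in sub],
        )
    out: dict[str, set[str]] = {}
    for tf, tf_sites in sites.items():
        bound: set[str] = set()
        for site in tf_sites:
            if site.chromosome not in by_chrom:
                continue
            starts, ends, ids = by_chrom[site.chromosome]
            hit = (starts < site.end) & (ends > site.start)
            bound.update(ids[i] for i in np.flatnonzero(hit))
        out[tf] = bound
    return out


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric bounds K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValidationError(f"k={k} outside support [{max(0, n + K - N)}, {min(n, K)}]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrichment_table(
    altered: set[str],
    universe: set[str],
    windows: dict[str, Interval],
    sites: dict[str, list[Interval]],
) -> pd.DataFrame:
    """Per-TF enrichment of binding among altered promoters vs the universe.

    ``altered`` must be a subset of ``universe``; both must have windows.
    Returns a table sorted by p with columns tf, k, n, K, N, p_value,
    neg_log10_p, q_value (BH across TFs).
    """
    altered = set(altered)
    universe = set(universe)
    if not altered <= universe:
        raise ValidationError("altered gene set must be contained in the universe")
    missing = universe - set(windows)
    if missing:
        raise ValidationError(f"universe genes without promoter windows: {sorted(missing)[:5]}")
    uni_windows = {g: windows[g] for g in universe}
    bound = bound_promoters(uni_windows, sites)
    N, n = len(universe), len(altered)
    rows = []
    for tf in sorted(sites):
        K = len(bound[tf])
        k = len(bound[tf] & altered)
        p = hypergeom_upper(k, K, n, N)
        rows.append({"tf": tf, "k": k, "n": n, "K": K, "N": N, "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["neg_log10_p"] = -np.log10(df["p_value"])
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(["p_value", "tf"], kind="mergesort").reset_index(drop=True)
    return df
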