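"""Join peaks to gene annotation, classify by contained biotypes, and
collapse peaks across cohorts into unique vs shared regions.

A peak's category is decided by the genes its focal interval overlaps
(≥1 bp gene-body overlap), with precedence: any known driver →
``contains_driver``; else any protein-coding gene → ``coding``; else all
lncRNA → ``lncRNA_only``; else → ``other_noncoding_only``; no genes at all →
``gene_desert``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    GeneModel,
    Interval,
    LNCRNA,
    Peak,
    PROTEIN_CODING,
    ValidationError,
)

logger = logging.getLogger("scnalnc.classify")

CONTAINS_DRIVER = "contains_driver"
CODING = "coding"
LNCRNA_ONLY = "lncRNA_only"
OTHER_NONCODING_ONLY = "other_noncoding_only"
GENE_DESERT = "gene_desert"
CATEGORIES = (CONTAINS_DRIVER, CODING, LNCRNA_ONLY, OTHER_NONCODING_ONLY, GENE_DESERT)

PEAK_LEVELS = ("focal", "enlarged", "region")


class GenomeAnnotation:
    """Gene models indexed by id and by chromosome for overlap queries."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise ValidationError("duplicate gene ids in annotation")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom in {g.chromosome for g in self.genes}:
            sub = sorted(
                (g for g in self.genes if g.chromosome == chrom), key=lambda g: g.start
            )
            self._by_chrom[chrom] = (
                np.array([g.start for g in sub]),
                np.array([g.end for g in sub]),
                [g.gene_id for g in sub],
            )

    def overlapping(self, interval: Interval) -> list[str]:
        """Gene ids whose body overlaps ``interval`` by ≥1 bp."""
        if interval.chromosome not in self._by_chrom:
            logger.warning("chromosome %s absent from annotation", interval.chromosome)
            return []
        starts, ends, ids = self._by_chrom[interval.chromosome]
        hit = (starts < interval.end) & (ends > interval.start)
        return [ids[i] for i in np.flatnonzero(hit)]

    def of_biotype(self, biotype: str) -> list[str]:
        return [g.gene_id for g in self.genes if g.biotype == biotype]


def genes_in_peak(peak: Peak, annotation: GenomeAnnotation, level: str = "focal") -> list[str]:
    """Gene ids overlapping the peak interval at the chosen level."""
    if level not in PEAK_LEVELS:
        raise ValidationError(f"level must be one of {PEAK_LEVELS}")
    return annotation.overlapping(peak.interval(level))


def classify(gene_ids: list[str], annotation: GenomeAnnotation) -> str:
    """Biotype category of a gene set; see module docstring for precedence."""
    genes = []
    for gid in gene_ids:
        if gid not in annotation.by_id:
            raise KeyError(f"unknown gene id {gid}")
        genes.append(annotation.by_id[gid])
    if not genes:
        return GENE_DESERT
    if any(g.driver for g in genes):
        return CONTAINS_DRIVER
    if any(g.biotype == PROTEIN_CODING for g in genes):
        return CODING
    if all(g.biotype == LNCRNA for g in genes):
        return LNCRNA_ONLY
    return OTHER_NONCODING_ONLY


@dataclass
class ClassifiedSCNA:
    """A peak joined to its contained genes and biotype category."""

    peak: Peak
    genes: list[str]
    category: str
    cohort: str | None = None
    shared_across: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        d = self.peak.to_dict()
        d.pop("samples")
        d["genes"] = ",".join(self.genes)
        d["category"] = self.category
        d["cohort"] = self.cohort or ""
        d["shared_across"] = ",".join(self.shared_across)
        return d


def classify_peaks(
    peaks: list[Peak],
    annotation: GenomeAnnotation,
    level: str = "focal",
    cohort: str | None = None,
) -> list[ClassifiedSCNA]:
    out = []
    for peak in peaks:
        gids = genes_in_peak(peak, annotation, level)
        out.append(ClassifiedSCNA(peak, gids, classify(gids, annotation), cohort))
    return out


def category_counts(classified: list[ClassifiedSCNA]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for s in classified:
        counts[s.category] += 1
    return counts


@dataclass
class CollapsedRegion:
    """A cross-cohort merge of same-direction focal peaks."""

    direction: str
    chromosome: str
    start: int
    end: int
    cohorts: list[str]
    members: list[tuple[str, Peak]]

    @property
    def shared(self) -> bool:
        return len(set(self.cohorts)) > 1


def _reciprocal_overlap(a: Peak, b: Peak) -> float:
    (s1, e1), (s2, e2) = a.focal, b.focal
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1), ov / (e2 - s2))


def cross_cohort_collapse(
    peaks_by_cohort: dict[str, list[Peak]],
    min_reciprocal_overlap: float = 0.25,
) -> list[CollapsedRegion]:
    """Single-linkage merge of same-direction focal peaks across cohorts.

    Two peaks merge when their focal intervals overlap reciprocally by at
    least ``min_reciprocal_overlap`` of each; merging is transitive. Each
    merged region spans the union of member focal intervals and lists the
    cohorts it appears in.
    """
    if not (0 < min_reciprocal_overlap <= 1):
        raise ValidationError("min_reciprocal_overlap must be in (0, 1]")
    members = [
        (cohort, peak) for cohort, peaks in peaks_by_cohort.items() for peak in peaks
    ]
    n = len(members)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = members[i][1], members[j][1]
            if a.direction != b.direction or a.chromosome != b.chromosome:
                continue
            if _reciprocal_overlap(a, b) >= min_reciprocal_overlap:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    regions = []
    for idxs in groups.values():
        mem = [members[i] for i in idxs]
        peaks = [p for _, p in mem]
        regions.append(
            CollapsedRegion(
                direction=peaks[0].direction,
                chromosome=peaks[0].chromosome,
                start=min(p.focal[0] for p in peaks),
                end=max(p.focal[1] for p in peaks),
                cohorts=sorted({c for c, _ in mem}),
                members=mem,
            )
        )
    regions.sort(key=lambda r: (r.chromosome, r.start, r.direction))
    return regions


def collapse_summary(regions: list[CollapsedRegion]) -> dict[str, int]:
    shared = sum(r.shared for r in regions)
    return {
        "unique_regions": len(regions),
        "cohort_specific": len(regions) - shared,
        "shared_across_cohorts": shared,
    }


def classified_table(classified: list[ClassifiedSCNA]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in classified])
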