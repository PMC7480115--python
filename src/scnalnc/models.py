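"""Core domain types shared across the pipeline.

All coordinates are 0-based half-open in memory. On-disk conventions
(SEG and GTF-lite 1-based inclusive, BED 0-based half-open) are handled
exclusively by :mod:`scnalnc.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
PSEUDOGENE = "pseudogene"
BIOTYPES = (PROTEIN_CODING, LNCRNA, PSEUDOGENE)

AMPLIFICATION = "amplification"
DELETION = "deletion"
DIRECTIONS = (AMPLIFICATION, DELETION)

TUMOR = "tumor"
NORMAL = "normal"

SEGMENT_COLUMNS = ["sample", "chromosome", "start", "end", "log2_ratio"]


class ValidationError(ValueError):
    """An input violated a documented invariant."""


class CapacityError(ValidationError):
    """Requested synthetic genes cannot be placed without overlap."""


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with biotype and (for protein-coding genes) a driver flag.

    ``tss`` is the strand-aware transcription start: the first covered base
    for ``+`` genes, the last covered base (``end - 1``) for ``-`` genes.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    biotype: str
    driver: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        if self.driver and self.biotype != PROTEIN_CODING:
            raise ValidationError(
                f"gene {self.gene_id}: driver flag is only valid on protein_coding genes"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeSpec:
    """A synthetic annotation universe: chromosomes plus gene models."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    seed: int | None = None

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chromosome not in lengths:
                raise ValidationError(f"gene {g.gene_id}: unknown chromosome {g.chromosome}")
            if g.end > lengths[g.chromosome]:
                raise ValidationError(f"gene {g.gene_id}: extends past chromosome end")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class PlantedAlteration:
    """Ground-truth recurrent alteration injected into a synthetic cohort.

    ``carrier_frequency`` is the per-tumor probability of carrying the event;
    ``amplitude`` is the mean |log2 ratio| shift in carriers (applied with
    negative sign for deletions).
    """

    chromosome: str
    start: int
    end: int
    direction: str
    carrier_frequency: float
    amplitude: float
    amplitude_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not (0 < self.carrier_frequency <= 1):
            raise ValidationError("carrier_frequency must be in (0, 1]")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be > 0")
        if self.amplitude_sd < 0:
            raise ValidationError("amplitude_sd must be >= 0")
        if not (0 <= self.start < self.end):
            raise ValidationError("invalid alteration interval")


@dataclass
class SegmentSet:
    """Per-sample segmented copy-number profiles with tumor/normal labels.

    ``segments`` has columns (sample, chromosome, start, end, log2_ratio);
    per sample and chromosome the segments are sorted and non-overlapping.
    """

    segments: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SEGMENT_COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValidationError(f"segment table missing columns {missing}")
        self.segments = self.segments[SEGMENT_COLUMNS].reset_index(drop=True)

    def validate(self) -> "SegmentSet":
        df = self.segments
        if not np.isfinite(df["log2_ratio"].to_numpy(float)).all():
            raise ValidationError("non-finite log2_ratio")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("segment start must be < end")
        if (df["start"] < 0).any():
            raise ValidationError("negative segment start")
        srt = df.sort_values(["sample", "chromosome", "start"], kind="mergesort")
        same = (srt["sample"].shift() == srt["sample"]) & (
            srt["chromosome"].shift() == srt["chromosome"]
        )
        overlap = same & (srt["start"] < srt["end"].shift())
        if overlap.any():
            row = srt[overlap].iloc[0]
            raise ValidationError(
                f"overlapping segments for sample {row['sample']} on {row['chromosome']}"
            )
        for s in df["sample"].unique():
            self.labels.setdefault(s, TUMOR)
        return self

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.segments["sample"]))

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels.get(s, TUMOR) == TUMOR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels.get(s) == NORMAL]

    def for_samples(self, sample_ids) -> "SegmentSet":
        keep = self.segments["sample"].isin(set(sample_ids))
        return SegmentSet(
            self.segments[keep].copy(),
            {s: l for s, l in self.labels.items() if s in set(sample_ids)},
        )


@dataclass
class Peak:
    """One significant recurrent alteration at three nested interval levels."""

    direction: str
    chromosome: str
    region: tuple[int, int]
    enlarged: tuple[int, int]
    focal: tuple[int, int]
    g_score: float
    q_value: float
    samples: list[str] = field(default_factory=list)
    rank: int = 0

    def __post_init__(self) -> None:
        r, e, f = self.region, self.enlarged, self.focal
        if not (r[0] <= e[0] <= f[0] < f[1] <= e[1] <= r[1]):
            raise ValidationError(
                f"peak nesting violated: focal {f} ⊆ enlarged {e} ⊆ region {r}"
            )

    def interval(self, level: str = "focal") -> Interval:
        if level not in ("focal", "enlarged", "region"):
            raise ValueError(f"unknown peak level {level!r}")
        s, e = getattr(self, level)
        return Interval(self.chromosome, s, e)

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "chromosome": self.chromosome,
            "region_start": self.region[0],
            "region_end": self.region[1],
            "enlarged_start": self.enlarged[0],
            "enlarged_end": self.enlarged[1],
            "focal_start": self.focal[0],
            "focal_end": self.focal[1],
            "g_score": self.g_score,
            "q_value": self.q_value,
            "n_samples": len(self.samples),
            "samples": list(self.samples),
            "rank": self.rank,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Peak":
        return cls(
            direction=d["direction"],
            chromosome=d["chromosome"],
            region=(d["region_start"], d["region_end"]),
            enlarged=(d["enlarged_start"], d["enlarged_end"]),
            focal=(d["focal_start"], d["focal_end"]),
            g_score=d["g_score"],
            q_value=d["q_value"],
            samples=list(d.get("samples", [])),
            rank=d.get("rank", 0),
        )
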