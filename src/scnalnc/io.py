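"""Readers and writers for every on-disk format the pipeline touches.

Coordinate conventions are converted exactly once, here:

========  =======================  ==================
format    on disk                  in memory
========  =======================  ==================
SEG       1-based inclusive        0-based half-open
GTF-lite  1-based inclusive        0-based half-open
BED       0-based half-open        unchanged
========  =======================  ==================

Matrices are TSV with a header row of sample ids and a second ``label``
row carrying tumor/normal labels. GMT lines are name, description, then
member gene ids.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (
    GeneModel,
    Interval,
    SegmentSet,
    ValidationError,
)

logger = logging.getLogger("scnalnc")

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


class ParseError(ValueError):
    """A malformed record, reported with its 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# SEG


def read_seg(path, labels: dict[str, str] | None = None) -> SegmentSet:
    """Read a SEG file (1-based inclusive on disk) into a SegmentSet.

    ``labels`` optionally maps sample id to tumor/normal; unlisted samples
    default to tumor. Overlapping segments within a sample raise
    :class:`~scnalnc.models.ValidationError`.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t")[:2] != ["Sample", "Chromosome"]:
            raise ParseError(path, 1, "expected SEG header starting 'Sample\\tChromosome'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ParseError(path, lineno, f"expected 6 columns, got {len(parts)}")
            try:
                sample, chrom = parts[0], parts[1]
                start, end = int(parts[2]), int(parts[3])
                value = float(parts[5])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            # 1-based inclusive -> 0-based half-open
            records.append((sample, chrom, start - 1, end, value))
    df = pd.DataFrame(records, columns=["sample", "chromosome", "start", "end", "log2_ratio"])
    return SegmentSet(df, dict(labels or {})).validate()


def write_seg(segments: SegmentSet, path) -> None:
    df = segments.segments
    out = pd.DataFrame(
        {
            "Sample": df["sample"],
            "Chromosome": df["chromosome"],
            "Start": df["start"] + 1,  # back to 1-based inclusive
            "End": df["end"],
            "Num_Probes": ((df["end"] - df["start"]) // 1000 + 1).astype(int),
            "Segment_Mean": df["log2_ratio"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame({"sample": list(labels), "label": list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GTF-lite genes

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_genes(path) -> list[GeneModel]:
    """Read GTF-lite gene records (1-based inclusive) into GeneModels.

    Recognized attribute keys: gene_id, biotype, driver.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(path, lineno, f"expected 9 GTF columns, got {len(parts)}")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature != "gene":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr:
                raise ParseError(path, lineno, "missing gene_id attribute")
            gid = attr["gene_id"]
            if gid in seen:
                raise ParseError(path, lineno, f"duplicate gene id {gid}")
            seen.add(gid)
            try:
                gene = GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
                    end=int(end),
                    strand=strand,
                    biotype=attr.get("biotype", "protein_coding"),
                    driver=attr.get("driver", "false").lower() == "true",
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            genes.append(gene)
    return genes


def write_genes(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; biotype "{g.biotype}"; '
                f'driver "{"true" if g.driver else "false"}";'
            )
            fh.write(
                f"{g.chromosome}\tscnalnc\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[Interval]:
    """Read BED (0-based half-open on disk, no conversion) into Intervals."""
    path = Path(path)
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "BED needs at least 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 else None
            if strand not in (None, "+", "-", "."):
                raise ParseError(path, lineno, f"unknown strand {strand!r}")
            try:
                out.append(Interval(chrom, start, end, name, score, strand))
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chromosome, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append("%g" % iv.score if iv.score is not None else "0")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# labeled matrices


def read_matrix(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a features × samples TSV whose second row carries sample labels.

    Returns (matrix, labels). Row and column ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    labels: dict[str, str] = {}
    if "label" in df.index:
        labels = {c: str(v) for c, v in df.loc["label"].items()}
        df = df.drop(index="label")
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate feature ids")
    return df.astype(float), labels


def write_matrix(matrix: pd.DataFrame, labels: dict[str, str], path) -> None:
    out = matrix.copy()
    if labels:
        label_row = pd.DataFrame(
            [[labels.get(c, "") for c in out.columns]], index=["label"], columns=out.columns
        )
        out = pd.concat([label_row, out])
    out.to_csv(path, sep="\t", float_format="%.8g")


# ---------------------------------------------------------------------------
# GMT signatures


def read_gmt(path) -> dict[str, set[str]]:
    path = Path(path)
    sigs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "GMT line needs name, description, >=1 member")
            name, members = parts[0], set(parts[2:]) - {""}
            if not members:
                raise ParseError(path, lineno, f"empty signature {name}")
            if name in sigs:
                raise ParseError(path, lineno, f"duplicate signature {name}")
            sigs[name] = members
    return sigs


def write_gmt(signatures: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in signatures.items():
            fh.write("\t".join([name, "scnalnc"] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# config / run report plumbing


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
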