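"""Synthetic cohorts with planted ground truth.

Every downstream stage of the screen is exercised on data produced here: a
genome of protein-coding genes, lncRNAs and pseudogenes; segmented per-sample
copy-number profiles with recurrent amplifications/deletions planted at known
frequency and amplitude over piecewise-constant background noise;
dosage-coupled expression; TF binding sites enriched at chosen promoters; and
CpG β values hypomethylated at chosen 5′ ends.

Background copy-number noise is modeled as per-sample piecewise-constant
segments with geometrically distributed lengths (mean ``segment_mean_len``)
and Normal(0, ``noise_sd``) segment means, mimicking the output of SNP-array
segmentation without modeling probes. Deletions are negative log2 shifts; no
integer copy states are modeled. All functions are deterministic for a fixed
seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import (
    AMPLIFICATION,
    CapacityError,
    GeneModel,
    GenomeSpec,
    Interval,
    LNCRNA,
    NORMAL,
    PlantedAlteration,
    PROTEIN_CODING,
    PSEUDOGENE,
    SegmentSet,
    TUMOR,
    ValidationError,
)

# Default study conditions: a compact two-chromosome genome and a cohort
# sized so the full screen runs in minutes on one CPU.
DEFAULT_N_CHROM = 2
DEFAULT_CHROM_LENGTH = 10_000_000
DEFAULT_N_TUMOR = 200
DEFAULT_N_NORMAL = 30
DEFAULT_NOISE_SD = 0.02
DEFAULT_SEGMENT_MEAN_LEN = 1_000_000
DEFAULT_DOSAGE_SLOPE = 1.0
DEFAULT_BASE_LOG_EXPR = 3.0
DEFAULT_EXPR_SD = 0.5

_GENE_LENGTH_RANGE = (5_000, 30_000)  # uniform gene-body lengths, bp


def make_genome(
    n_chrom: int = DEFAULT_N_CHROM,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    n_coding: int = 0,
    n_lnc: int = 0,
    n_driver: int = 0,
    n_pseudo: int = 0,
    seed: int = 0,
) -> GenomeSpec:
    """Place non-overlapping genes of each biotype uniformly on the genome.

    ``n_driver`` of the ``n_coding`` protein-coding genes carry the driver
    flag. Strands are assigned uniformly. Raises :class:`CapacityError` if a
    gene cannot be placed without overlap within 1,000 attempts.
    """
    if min(n_chrom, chrom_length, n_coding, n_lnc, n_driver, n_pseudo) < 0:
        raise ValidationError("counts must be >= 0")
    if n_driver > n_coding:
        raise ValidationError("n_driver cannot exceed n_coding")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]

    plan = (
        [(PROTEIN_CODING, True)] * n_driver
        + [(PROTEIN_CODING, False)] * (n_coding - n_driver)
        + [(LNCRNA, False)] * n_lnc
        + [(PSEUDOGENE, False)] * n_pseudo
    )
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in chromosomes}
    genes: list[GeneModel] = []
    counters = {PROTEIN_CODING: 0, LNCRNA: 0, PSEUDOGENE: 0}
    prefix = {PROTEIN_CODING: "PC", LNCRNA: "LNC", PSEUDOGENE: "PSE"}
    for biotype, driver in plan:
        lo, hi = _GENE_LENGTH_RANGE
        lo = max(1, min(lo, chrom_length - 1))
        hi = max(lo, min(hi, chrom_length - 1))
        for _attempt in range(1000):
            chrom = chromosomes[rng.integers(len(chromosomes))][0]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, chrom_length - length))
            end = start + length
            if all(end <= s or e <= start for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise CapacityError(
                f"could not place a {biotype} gene without overlap in 1,000 attempts"
            )
        counters[biotype] += 1
        genes.append(
            GeneModel(
                gene_id=f"{prefix[biotype]}{counters[biotype]:04d}",
                chromosome=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                biotype=biotype,
                driver=driver,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return GenomeSpec(chromosomes=chromosomes, genes=genes, seed=seed)


def _background_segments(rng, chrom_length: int, mean_len: int, noise_sd: float):
    """Piecewise-constant noise segments tiling one chromosome."""
    if mean_len <= 0:
        raise ValidationError("segment_mean_len must be > 0")
    bounds = [0]
    while bounds[-1] < chrom_length:
        step = int(rng.geometric(1.0 / mean_len))
        bounds.append(min(bounds[-1] + max(step, 1), chrom_length))
    starts = np.array(bounds[:-1])
    ends = np.array(bounds[1:])
    values = rng.normal(0.0, noise_sd, size=len(starts)) if noise_sd > 0 else np.zeros(len(starts))
    return starts, ends, values


def _apply_shift(starts, ends, values, a_start, a_end, shift):
    """Split segments at [a_start, a_end) and add ``shift`` inside it."""
    new_s, new_e, new_v = [], [], []
    for s, e, v in zip(starts, ends, values):
        if e <= a_start or s >= a_end:
            new_s.append(s)
            new_e.append(e)
            new_v.append(v)
            continue
        if s < a_start:
            new_s.append(s)
            new_e.append(a_start)
            new_v.append(v)
        ov_s, ov_e = max(s, a_start), min(e, a_end)
        new_s.append(ov_s)
        new_e.append(ov_e)
        new_v.append(v + shift)
        if e > a_end:
            new_s.append(a_end)
            new_e.append(e)
            new_v.append(v)
    return np.array(new_s), np.array(new_e), np.array(new_v)


def simulate_cohort(
    genome: GenomeSpec,
    planted: list[PlantedAlteration] | None = None,
    n_tumor: int = DEFAULT_N_TUMOR,
    n_normal: int = DEFAULT_N_NORMAL,
    noise_sd: float = DEFAULT_NOISE_SD,
    segment_mean_len: int = DEFAULT_SEGMENT_MEAN_LEN,
    seed: int = 0,
) -> tuple[SegmentSet, dict[int, list[str]]]:
    """Simulate a segmented copy-number cohort with planted alterations.

    Each tumor carries each planted alteration independently with probability
    ``carrier_frequency``; carriers get a signed Normal(amplitude,
    amplitude_sd) log2 shift over the planted interval. Normal samples carry
    only background noise. Returns the SegmentSet and, as ground truth, a map
    from the index of each planted alteration to its carrier sample ids.
    """
    if n_tumor < 1:
        raise ValidationError("n_tumor must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    planted = list(planted or [])
    lengths = genome.chrom_lengths
    for alt in planted:
        if alt.chromosome not in lengths:
            raise ValidationError(f"planted alteration on unknown chromosome {alt.chromosome}")
        if alt.end > lengths[alt.chromosome]:
            raise ValidationError("planted alteration extends past chromosome end")

    rng = np.random.default_rng(seed)
    sample_ids = [f"T{i + 1:04d}" for i in range(n_tumor)] + [
        f"N{i + 1:04d}" for i in range(n_normal)
    ]
    labels = {s: (TUMOR if s.startswith("T") else NORMAL) for s in sample_ids}

    carriers: dict[int, list[str]] = {i: [] for i in range(len(planted))}
    rows: list[tuple] = []
    for sample in sample_ids:
        per_chrom = {
            chrom: _background_segments(rng, clen, segment_mean_len, noise_sd)
            for chrom, clen in genome.chromosomes
        }
        if labels[sample] == TUMOR:
            for idx, alt in enumerate(planted):
                if rng.random() >= alt.carrier_frequency:
                    continue
                carriers[idx].append(sample)
                magnitude = (
                    alt.amplitude
                    if alt.amplitude_sd == 0
                    else rng.normal(alt.amplitude, alt.amplitude_sd)
                )
                shift = magnitude if alt.direction == AMPLIFICATION else -magnitude
                s, e, v = per_chrom[alt.chromosome]
                per_chrom[alt.chromosome] = _apply_shift(s, e, v, alt.start, alt.end, shift)
        for chrom, _ in genome.chromosomes:
            s, e, v = per_chrom[chrom]
            rows.extend(zip([sample] * len(s), [chrom] * len(s), s, e, v))

    df = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "log2_ratio"])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return SegmentSet(df, labels).validate(), carriers


def gene_dosage(genome: GenomeSpec, segments: SegmentSet) -> pd.DataFrame:
    """Length-weighted mean log2 ratio over each gene body, genes × samples."""
    df = segments.segments
    samples = segments.samples
    out = np.zeros((len(genome.genes), len(samples)))
    sample_idx = {s: j for j, s in enumerate(samples)}
    by_chrom = {c: g for c, g in df.groupby("chromosome")}
    for i, gene in enumerate(genome.genes):
        sub = by_chrom.get(gene.chromosome)
        if sub is None:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        ov = np.minimum(e, gene.end) - np.maximum(s, gene.start)
        hit = ov > 0
        if not hit.any():
            continue
        w = ov[hit].astype(float)
        v = sub["log2_ratio"].to_numpy()[hit]
        cols = sub["sample"].map(sample_idx).to_numpy()[hit]
        num = np.zeros(len(samples))
        den = np.zeros(len(samples))
        np.add.at(num, cols, w * v)
        np.add.at(den, cols, w)
        out[i] = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return pd.DataFrame(out, index=[g.gene_id for g in genome.genes], columns=samples)


def simulate_expression(
    genome: GenomeSpec,
    segments: SegmentSet,
    dosage_slope: float = DEFAULT_DOSAGE_SLOPE,
    base_log_expr: float = DEFAULT_BASE_LOG_EXPR,
    expr_sd: float = DEFAULT_EXPR_SD,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dosage-coupled expression on a linear FPKM-like scale.

    Per gene and sample, log2 expression is
    ``base_log_expr + dosage_slope × (mean log2 ratio over the gene body)``
    plus Normal(0, ``expr_sd``) noise; the returned matrix is ``2**log2``,
    hence non-negative. Returns (genes × samples matrix, labels).
    """
    if dosage_slope < 0:
        raise ValidationError("dosage_slope must be >= 0")
    rng = np.random.default_rng(seed)
    dosage = gene_dosage(genome, segments)
    log_expr = base_log_expr + dosage_slope * dosage
    if expr_sd > 0:
        log_expr = log_expr + rng.normal(0.0, expr_sd, size=dosage.shape)
    return np.power(2.0, log_expr), dict(segments.labels)


def simulate_tf_sites(
    genome: GenomeSpec,
    tf_names: list[str],
    enriched: dict[str, set[str]] | None = None,
    background_rate: float = 0.0,
    site_length: int = 200,
    flank: int = 1000,
    seed: int = 0,
) -> dict[str, list[Interval]]:
    """TF binding sites: planted promoter sites plus uniform background.

    For every (tf, gene) pair in ``enriched`` one site is placed inside the
    gene's TSS ± ``flank`` promoter window; background sites are placed
    uniformly at ``background_rate`` per Mb of genome, Poisson counts per TF.
    """
    enriched = enriched or {}
    gene_by_id = {g.gene_id: g for g in genome.genes}
    for tf, gids in enriched.items():
        if tf not in tf_names:
            raise ValidationError(f"enriched TF {tf} not in tf_names")
        for gid in gids:
            if gid not in gene_by_id:
                raise KeyError(f"unknown gene id {gid} in enriched map")
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths
    genome_mb = sum(lengths.values()) / 1e6
    chroms = list(lengths)
    cum = np.cumsum([lengths[c] for c in chroms])

    sites: dict[str, list[Interval]] = {}
    for tf in tf_names:
        tf_sites: list[Interval] = []
        for gid in sorted(enriched.get(tf, ())):
            g = gene_by_id[gid]
            clen = lengths[g.chromosome]
            win_lo = max(0, g.tss - flank)
            win_hi = min(clen, g.tss + flank)
            hi = max(win_lo + 1, win_hi - site_length)
            start = int(rng.integers(win_lo, hi))
            end = min(start + site_length, clen)
            tf_sites.append(Interval(g.chromosome, start, end, name=tf))
        n_bg = int(rng.poisson(background_rate * genome_mb)) if background_rate > 0 else 0
        for _ in range(n_bg):
            pos = int(rng.integers(0, cum[-1]))
            ci = int(np.searchsorted(cum, pos, side="right"))
            offset = pos - (0 if ci == 0 else cum[ci - 1])
            chrom = chroms[ci]
            start = min(int(offset), lengths[chrom] - site_length)
            start = max(start, 0)
            tf_sites.append(Interval(chrom, start, start + site_length, name=tf))
        sites[tf] = tf_sites
    return sites


def simulate_methylation(
    genome: GenomeSpec,
    hypo_targets: set[str] | None = None,
    beta_normal_mean: float = 0.7,
    beta_tumor_delta: float = 0.2,
    beta_sd: float = 0.05,
    n_tumor: int = 50,
    n_normal: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """CpG β values with tumor hypomethylation planted at chosen genes.

    Every gene gets two CpGs within 500 bp of its TSS. Tumor β for CpGs of
    ``hypo_targets`` genes is shifted by −``beta_tumor_delta``; all β values
    are clipped to [0, 1]. Returns (β matrix CpGs × samples, CpG→gene map
    with positions, labels).
    """
    hypo_targets = set(hypo_targets or ())
    gene_ids = {g.gene_id for g in genome.genes}
    unknown = hypo_targets - gene_ids
    if unknown:
        raise KeyError(f"unknown hypo_targets {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    samples = [f"T{i + 1:04d}" for i in range(n_tumor)] + [
        f"N{i + 1:04d}" for i in range(n_normal)
    ]
    labels = {s: (TUMOR if s.startswith("T") else NORMAL) for s in samples}
    is_tumor = np.array([labels[s] == TUMOR for s in samples])

    cpg_rows = []
    betas = []
    lengths = genome.chrom_lengths
    for g in genome.genes:
        clen = lengths[g.chromosome]
        for k in range(2):
            offset = int(rng.integers(-500, 501))
            pos = int(np.clip(g.tss + offset, 0, clen - 1))
            cpg_id = f"cg_{g.gene_id}_{k + 1}"
            cpg_rows.append((cpg_id, g.gene_id, g.chromosome, pos))
            mean = np.full(len(samples), beta_normal_mean)
            if g.gene_id in hypo_targets:
                mean[is_tumor] -= beta_tumor_delta
            noise = rng.normal(0.0, beta_sd, size=len(samples)) if beta_sd > 0 else 0.0
            betas.append(np.clip(mean + noise, 0.0, 1.0))
    beta = pd.DataFrame(
        np.array(betas) if betas else np.empty((0, len(samples))),
        index=[r[0] for r in cpg_rows],
        columns=samples,
    )
    cpg_map = pd.DataFrame(cpg_rows, columns=["cpg_id", "gene_id", "chromosome", "position"])
    return beta, cpg_map.set_index("cpg_id"), labels


def pick_isolated_lncrna(genome: GenomeSpec, margin: int = 20_000) -> GeneModel:
    """First lncRNA with no other gene within ``margin`` bp of its body.

    Used to plant alterations whose focal peak can only contain that gene.
    """
    for g in genome.genes:
        if g.biotype != LNCRNA:
            continue
        crowded = any(
            o.gene_id != g.gene_id
            and o.chromosome == g.chromosome
            and o.start < g.end + margin
            and g.start - margin < o.end
            for o in genome.genes
        )
        if not crowded:
            return g
    raise ValidationError(f"no lncRNA isolated by {margin} bp in this genome")


def make_signatures(
    genome: GenomeSpec,
    n_signatures: int = 4,
    genes_per_signature: int = 15,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Disjoint-by-draw gene-set signatures over the genome's genes."""
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    if genes_per_signature > len(gene_ids):
        raise ValidationError("signature larger than gene universe")
    return {
        f"SIG{i + 1}": set(rng.choice(gene_ids, size=genes_per_signature, replace=False))
        for i in range(n_signatures)
    }
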