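"""End-to-end orchestration: simulate → detect → classify → enrich →
concord → immune, from one declarative configuration.

Every stage persists its artifacts under the output directory so each step
is independently re-runnable and inspectable; the run report records
per-stage counts, the parameter echo, input checksums and timestamps. All
randomness flows from one root seed, split per stage, so a rerun with an
identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cl
from . import concordance as cc
from . import enrichment as en
from . import immune as im
from . import io as fio
from . import recurrence as rc
from . import synthetic as syn
from .models import (
    AMPLIFICATION,
    DELETION,
    LNCRNA,
    PlantedAlteration,
    ValidationError,
)

logger = logging.getLogger("scnalnc.pipeline")


@dataclass
class RunConfig:
    """All knobs of the screen, with documented defaults."""

    out_dir: str = "scnalnc_run"
    seed: int = 0
    # detection
    bin_size: int = rc.DEFAULT_BIN_SIZE
    amp_threshold: float = rc.DEFAULT_AMP_THRESHOLD
    n_perm: int = rc.DEFAULT_N_PERM
    q_threshold: float = rc.DEFAULT_Q_THRESHOLD
    enlarged_epsilon: float = rc.DEFAULT_ENLARGED_EPSILON
    max_peaks_per_region: int = rc.DEFAULT_MAX_PEAKS_PER_REGION
    # enrichment / concordance / immune
    flank: int = en.DEFAULT_FLANK
    alpha: float = cc.DEFAULT_ALPHA
    ssgsea_alpha: float = im.DEFAULT_SSGSEA_ALPHA
    # optional simulation stanza; when present, inputs are generated
    simulate: dict | None = None
    # existing inputs (ignored when simulate is given)
    seg: str | None = None
    labels: str | None = None
    genes: str | None = None
    sites: str | None = None
    expression: str | None = None
    methylation: str | None = None
    signatures: str | None = None

    def validate(self) -> "RunConfig":
        if self.bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        if self.amp_threshold <= 0:
            raise ValidationError("amp_threshold must be > 0")
        if not (0 < self.q_threshold < 1):
            raise ValidationError("q_threshold must be in (0, 1)")
        if not (0 <= self.enlarged_epsilon < 1):
            raise ValidationError("enlarged_epsilon must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.simulate is None and self.seg is None:
            raise ValidationError("either a simulate stanza or a seg input is required")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = fio.load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg).validate()


def _default_simulation(seed: int) -> dict:
    """Study-condition defaults: one lncRNA-only amplification planted on a
    compact two-chromosome genome."""
    return {
        "n_chrom": syn.DEFAULT_N_CHROM,
        "chrom_length": syn.DEFAULT_CHROM_LENGTH,
        "n_coding": 40,
        "n_lnc": 20,
        "n_driver": 4,
        "n_pseudo": 5,
        "n_tumor": syn.DEFAULT_N_TUMOR,
        "n_normal": syn.DEFAULT_N_NORMAL,
        "noise_sd": syn.DEFAULT_NOISE_SD,
        "segment_mean_len": syn.DEFAULT_SEGMENT_MEAN_LEN,
        "dosage_slope": syn.DEFAULT_DOSAGE_SLOPE,
        "base_log_expr": syn.DEFAULT_BASE_LOG_EXPR,
        "expr_sd": syn.DEFAULT_EXPR_SD,
        "n_tf": 10,
        "tf_background_rate": 5.0,
        "planted": [],  # filled against the generated genome
        "planted_carrier_frequency": 0.10,
        "seed": seed,
    }


def _simulate_stage(cfg: RunConfig, out: Path, seeds) -> dict:
    sim = dict(_default_simulation(cfg.seed))
    sim.update(cfg.simulate or {})
    genome = syn.make_genome(
        n_chrom=sim["n_chrom"],
        chrom_length=sim["chrom_length"],
        n_coding=sim["n_coding"],
        n_lnc=sim["n_lnc"],
        n_driver=sim["n_driver"],
        n_pseudo=sim["n_pseudo"],
        seed=int(seeds[0]),
    )
    planted_cfg = sim["planted"]
    if not planted_cfg:
        # plant an amplification tightly over an isolated lncRNA (pad smaller
        # than one marker bin so the recurrent segment localizes to the gene)
        lnc = syn.pick_isolated_lncrna(genome)
        planted_cfg = [
            {
                "chromosome": lnc.chromosome,
                "start": max(0, lnc.start - 5_000),
                "end": min(genome.chrom_lengths[lnc.chromosome], lnc.end + 5_000),
                "direction": AMPLIFICATION,
                "carrier_frequency": sim["planted_carrier_frequency"],
                "amplitude": 1.5,
                "amplitude_sd": 0.1,
            }
        ]
    planted = [PlantedAlteration(**p) for p in planted_cfg]
    segments, carriers = syn.simulate_cohort(
        genome,
        planted,
        n_tumor=sim["n_tumor"],
        n_normal=sim["n_normal"],
        noise_sd=sim["noise_sd"],
        segment_mean_len=sim["segment_mean_len"],
        seed=int(seeds[1]),
    )
    expression, expr_labels = syn.simulate_expression(
        genome,
        segments,
        dosage_slope=sim["dosage_slope"],
        base_log_expr=sim["base_log_expr"],
        expr_sd=sim["expr_sd"],
        seed=int(seeds[2]),
    )
    tf_names = [f"TF{i + 1}" for i in range(sim["n_tf"])]
    lnc_in_planted = {
        g.gene_id
        for g in genome.genes
        if g.biotype == LNCRNA
        and any(
            p.chromosome == g.chromosome and g.start < p.end and p.start < g.end
            for p in planted
        )
    }
    sites = syn.simulate_tf_sites(
        genome,
        tf_names,
        enriched={tf_names[0]: lnc_in_planted} if lnc_in_planted else {},
        background_rate=sim["tf_background_rate"],
        seed=int(seeds[3]),
    )
    beta, cpg_map, meth_labels = syn.simulate_methylation(
        genome,
        hypo_targets=lnc_in_planted,
        n_tumor=min(50, sim["n_tumor"]),
        n_normal=max(30, sim["n_normal"]),
        seed=int(seeds[4]),
    )
    signatures = syn.make_signatures(genome, seed=int(seeds[5]))

    fio.write_genes(genome.genes, out / "genes.gtf")
    fio.write_seg(segments, out / "cohort.seg")
    fio.write_labels(segments.labels, out / "labels.tsv")
    fio.write_matrix(expression, expr_labels, out / "expression.tsv")
    flat_sites = [iv for tf in tf_names for iv in sites[tf]]
    fio.write_bed(flat_sites, out / "tf_sites.bed")
    fio.write_matrix(beta, meth_labels, out / "methylation.tsv")
    cpg_map.to_csv(out / "cpg_map.tsv", sep="\t")
    fio.write_gmt(signatures, out / "signatures.gmt")
    fio.write_json(
        {str(i): c for i, c in carriers.items()}, out / "planted_carriers.json"
    )
    return {
        "genome": genome,
        "segments": segments,
        "expression": expression,
        "expr_labels": expr_labels,
        "sites": sites,
        "beta": beta,
        "meth_labels": meth_labels,
        "signatures": signatures,
        "planted": planted,
        "carriers": carriers,
    }


def _load_inputs(cfg: RunConfig) -> dict:
    labels = fio.read_labels(cfg.labels) if cfg.labels else None
    segments = fio.read_seg(cfg.seg, labels)
    genes = fio.read_genes(cfg.genes) if cfg.genes else []
    sites: dict[str, list] = {}
    if cfg.sites:
        for iv in fio.read_bed(cfg.sites):
            sites.setdefault(iv.name or "TF", []).append(iv)
    expression = expr_labels = None
    if cfg.expression:
        expression, expr_labels = fio.read_matrix(cfg.expression)
    beta = meth_labels = None
    if cfg.methylation:
        beta, meth_labels = fio.read_matrix(cfg.methylation)
    signatures = fio.read_gmt(cfg.signatures) if cfg.signatures else {}
    from .models import GenomeSpec

    chrom_max = segments.segments.groupby("chromosome")["end"].max()
    genome = GenomeSpec(
        chromosomes=[(c, int(m)) for c, m in chrom_max.items()], genes=genes
    )
    return {
        "genome": genome,
        "segments": segments,
        "expression": expression,
        "expr_labels": expr_labels,
        "sites": sites,
        "beta": beta,
        "meth_labels": meth_labels,
        "signatures": signatures,
        "planted": [],
        "carriers": {},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full screen; returns the run report dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)

    if not (config.simulate is None and config.seg):
        data = _simulate_stage(config, out, seeds)
    else:
        data = _load_inputs(config)
    if not data["segments"].tumor_samples:
        raise ValidationError("cohort has no tumor samples")

    # --- detect ---------------------------------------------------------
    tracks, peaks = rc.detect(
        data["segments"],
        bin_size=config.bin_size,
        amp_threshold=config.amp_threshold,
        n_perm=config.n_perm,
        q_threshold=config.q_threshold,
        enlarged_epsilon=config.enlarged_epsilon,
        max_peaks_per_region=config.max_peaks_per_region,
        seed=int(seeds[6]),
    )
    for direction, track in tracks.items():
        track.table.to_csv(out / f"track_{direction}.tsv", sep="\t", index=False)
    fio.write_json([p.to_dict() for p in peaks], out / "peaks.json")

    # --- classify -------------------------------------------------------
    annotation = cl.GenomeAnnotation(data["genome"].genes)
    classified = cl.classify_peaks(peaks, annotation)
    counts = cl.category_counts(classified)
    cl.classified_table(classified).to_csv(out / "classified.tsv", sep="\t", index=False)

    # --- promoter enrichment -------------------------------------------
    enrich_tables = {}
    if data["sites"]:
        windows = en.promoter_windows(
            data["genome"].genes, config.flank, data["genome"].chrom_lengths
        )
        universe = set(annotation.of_biotype(LNCRNA))
        for direction in (AMPLIFICATION, DELETION):
            altered = {
                g
                for s in classified
                if s.peak.direction == direction
                for g in s.genes
                if annotation.by_id[g].biotype == LNCRNA
            }
            if altered and universe:
                table = en.enrichment_table(altered, universe, windows, data["sites"])
                table.to_csv(out / f"enrichment_{direction}.tsv", sep="\t", index=False)
                enrich_tables[direction] = table

    # --- expression concordance ----------------------------------------
    verdicts: list = []
    survivors: list = []
    if data["expression"] is not None:
        verdicts, survivors = cc.concordance_filter(
            classified,
            data["expression"],
            data["expr_labels"],
            annotation,
            alpha=config.alpha,
        )
        pd.DataFrame([asdict(v) for v in verdicts]).to_csv(
            out / "concordance.tsv", sep="\t", index=False
        )
        cl.classified_table(survivors).to_csv(
            out / "surviving_scnas.tsv", sep="\t", index=False
        )

    # --- methylation ----------------------------------------------------
    meth = None
    if data["beta"] is not None and len(data["beta"]):
        meth = cc.differential_methylation(data["beta"], data["meth_labels"])
        meth.to_csv(out / "methylation_contrast.tsv", sep="\t")

    # --- immune signatures ---------------------------------------------
    contrast = None
    if data["signatures"] and data["expression"] is not None and survivors:
        tumor_expr = data["expression"][
            [c for c in data["expression"].columns if data["expr_labels"].get(c) == "tumor"]
        ]
        scores = im.score_signatures(
            tumor_expr, data["signatures"], alpha=config.ssgsea_alpha
        )
        fio.write_matrix(scores, {}, out / "signature_scores.tsv")
        amp_survivors = [s for s in survivors if s.peak.direction == AMPLIFICATION]
        if amp_survivors:
            amp_ids = cc.amplified_samples(
                data["segments"], amp_survivors[0], config.amp_threshold
            )
            if amp_ids and len(amp_ids) < len(tumor_expr.columns):
                contrast = im.infiltration_contrast(scores, amp_ids)
                contrast.to_csv(out / "immune_contrast.tsv", sep="\t")

    # --- report ---------------------------------------------------------
    n_lnc_only = counts[cl.LNCRNA_ONLY]
    report = {
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "n_tumors": len(data["segments"].tumor_samples),
        "n_normals": len(data["segments"].normal_samples),
        "alterations": {
            "total": len(peaks),
            AMPLIFICATION: sum(p.direction == AMPLIFICATION for p in peaks),
            DELETION: sum(p.direction == DELETION for p in peaks),
        },
        "classification": counts,
        "enriched_tfs": {
            d: int((t["q_value"] < 0.25).sum()) for d, t in enrich_tables.items()
        },
        "concordance": {
            "tested_genes": len(verdicts),
            "surviving_scnas": len(survivors),
        },
        "immune_signatures_contrasted": 0 if contrast is None else len(contrast),
        "funnel": funnel_table(peaks, classified, survivors),
        "input_checksums": {
            p.name: fio.file_checksum(p)
            for p in sorted(out.glob("*.seg")) + sorted(out.glob("*.gtf"))
        },
        "wall_seconds": round(time.time() - t0, 3),
    }
    fio.write_json(report, out / "run_report.json")
    return report


def funnel_table(peaks, classified, survivors) -> dict[str, int]:
    """Selection funnel: detected → classified → lncRNA-only → concordant.

    Counts are monotone non-increasing down the funnel.
    """
    lnc_only = [s for s in classified if s.category == cl.LNCRNA_ONLY]
    lnc_set = {id(s) for s in lnc_only}
    return {
        "detected": len(peaks),
        "classified": len(classified),
        "lncRNA_only": len(lnc_only),
        "concordant_lncRNA_only": sum(1 for s in survivors if id(s) in lnc_set),
    }
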