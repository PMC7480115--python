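# Methods

`scnalnc` implements a desk-scale reimplementation of the computational
screen used to discover copy-number–altered lncRNAs in tumor cohorts:
recurrence scoring of somatic copy-number alterations (SCNAs), biotype
classification of the altered regions, promoter transcription-factor
enrichment, dosage-concordant expression filtering, methylation contrasts,
and immune-signature contrasts by amplification status. This note describes
the models, the defaults and why they were chosen, the numerical decisions,
and the limits of what the synthetic benchmarks demonstrate.

## Recurrence model

The genome is divided into fixed-size marker bins (default **10 kb**).
Per-sample segment profiles (SEG-style mean log2 copy ratios) are rasterized
onto the bins by length-weighted averaging. For each direction d ∈
{amplification, deletion}, a tumor is *altered* at a marker when its log2
value exceeds `amp_threshold` (default **0.1**, the conventional
segmentation-amplitude cutoff) — below `-amp_threshold` for deletions. The
per-marker recurrence score is

    G = frequency × mean |log2| of altered samples
      = (Σ over altered samples |log2|) / n_tumors,

so removing a sample's contribution can never increase G — the property
that makes peel-off (below) terminate and stay monotone.

**Null model.** Rather than an analytic background, significance comes from
a permutation null: in each of `n_perm` permutations (default **200**) every
tumor's marker-value vector is circularly shifted within each chromosome by
an independent uniform offset. This preserves each sample's segment-length
and amplitude structure exactly while destroying cross-sample alignment; the
G-scores of all markers in all permutations are pooled into one empirical
null per direction. Per-marker p-values use the add-one estimator
p = (1 + #{null ≥ G}) / (1 + #null), and false-discovery control is
Benjamini–Hochberg across all markers of a direction with a discovery
threshold of **q < 0.25**.

Because the null is rebuilt from the very cohort being tested, extreme
segments populate their own null ("double dipping"), which makes the test
conservative exactly when the data are noisy — the desirable direction for
a discovery screen. Note that BH is a false-discovery-*rate* control: under
a completely signal-free genome, the probability of *any* discovery
approaches the Simes level (here 0.25) whenever a large fraction of markers
carries nonzero G. The screen is therefore only quiet on null data when
background noise rarely crosses `amp_threshold`, which is also the regime
that real segmented array data occupy (see *Synthetic data* below).

**Peaks at three nested levels.** A *region* is a maximal run of contiguous
markers with q below threshold. Within a region the *focal peak* is the
widest marker run tied at the maximal G (ties are broadened to the full
tied run — conservative localization), and the *enlarged peak* extends the
focal run contiguously while G ≥ (1 − `enlarged_epsilon`) × peak G
(default ε = 0.05). Focal ⊆ enlarged ⊆ region always holds. After a peak is
emitted, *peel-off* removes the marker values of its supporting samples
(tumors altered anywhere over the focal interval) across the enclosing
region, rescores, and re-tests against the existing null using the original
BH cutoff; iteration stops when nothing remains significant, when no sample
was removed, or after `max_peaks_per_region` (default 5) peaks. Peeling by
sample rather than by segment can over-peel a sample with two independent
events in one region; this is logged and accepted for simplicity.

## Classification

A gene is *inside* a peak when its gene body overlaps the chosen peak
interval by ≥ 1 bp (default level: focal; overlap, not containment, so a
peak landing on part of a gene still claims it). Categories, by precedence:

1. `contains_driver` — any contained gene carries the known-driver flag;
2. `coding` — any contained protein-coding gene;
3. `lncRNA_only` — all contained genes are lncRNAs;
4. `other_noncoding_only` — the rest (pseudogenes, mixed non-coding);
5. `gene_desert` — no contained gene at all.

Cross-cohort collapsing merges same-direction focal peaks whose reciprocal
overlap is ≥ 0.25 (single-linkage, hence transitive); merged regions list
their member cohorts, giving cohort-specific vs shared counts.

## Promoter TF enrichment

Promoter windows are TSS ± 1 kb (strand-aware TSS; windows clipped to
chromosome bounds). A promoter is *bound* by a TF when it overlaps at least
one of that TF's sites by ≥ 1 bp — binary per promoter, not site-count
weighted. For each TF, with N universe promoters, K of them bound, n altered
promoters and k altered-and-bound, the upper-tail hypergeometric p-value
P(X ≥ k) is reported alongside −log10 p. The universe is biotype-matched
(altered lncRNAs are tested against all annotated lncRNAs) to control for
biotype-specific promoter properties. BH q-values across TFs are an
addition beyond the −log10 p ranking and are flagged as such in the output.

## Expression concordance

Each altered region's contained lncRNAs are tested tumor-vs-normal with the
two-sided unpaired Welch t-test on log2(x + 1)-transformed FPKM-like values
(variance stabilization; the transform is a package choice). A gene is
*putative functional* when p < α (default 0.05, per gene, uncorrected — the
screen is a directional agreement filter, not a discovery procedure) **and**
the direction matches (tumor mean above normal mean for amplifications,
below for deletions). A region survives when ≥ 1 contained lncRNA is
putative functional. Under the null the survival probability is therefore
α/2 per direction, not α: the two-sided test contributes α and the
direction coin flip halves it. The calibration tests assert exactly this.

Companion contrasts: Welch test of amplified vs non-amplified tumors (a
tumor is *amplified* for a region when its length-weighted mean log2 over
the focal interval exceeds `amp_threshold`); percent of tumors amplified /
expressed (value > 0) / both; per-CpG tumor-vs-normal Welch tests on β
values with a hypomethylated-in-tumor flag. CpGs with zero variance in both
groups are reported with NaN statistics and the run continues.

## Immune signatures

Per-sample signature scores are the rank-based weighted Kolmogorov–Smirnov
running-sum area (the ssGSEA family): within a sample, genes are ranked by
expression (ascending midranks; the walk descends from the highest), hits
add rank^α normalized to sum 1 over the signature, misses subtract
1/#misses, and the score is the mean of the running sum, with exponent
**α = 0.25**. Only ranks enter, so scores are invariant to monotone
transforms of a sample's expression. The statistic is a fully specified
stand-in for kernel-based GSVA scores: numerical values differ from GSVA,
ordering behavior is preserved. Two numerical notes: (i) for α > 0 the
*unnormalized* area has a small positive mean under random signatures
(≈ +0.05 at α = 0.25, 200 genes, 20-gene signatures) because hit weights
grow with rank; the offset is identical for every sample and cancels in
between-sample contrasts, and it is exactly zero at α = 0; (ii) signature
members absent from the matrix are dropped with a warning, and a signature
errors out when fewer than half its members remain.

Group contrasts use the two-sided unpaired Wilcoxon rank-sum test: exact by
enumeration of all rank assignments when the pooled size is ≤ 20 (midranks
make the enumeration valid under ties), otherwise the normal approximation
with tie correction and a 0.5 continuity correction. BH q-values are
computed across signatures, with the sign convention that a positive median
difference means higher scores in amplified samples.

## Synthetic data: what it emulates, what it does not

The generator produces the *statistical structure* the screen consumes, not
realistic genomes:

- **Genome** — default 2 chromosomes × 10 Mb with 40 protein-coding genes
  (4 flagged as known drivers), 20 lncRNAs and 5 pseudogenes, placed
  uniformly without overlap (overlap-free placement keeps "contains only
  lncRNAs" unambiguous). Gene bodies are 5–30 kb.
- **Copy number** — per-sample piecewise-constant background segments with
  geometric lengths (mean `segment_mean_len` = **1 Mb**) and
  Normal(0, `noise_sd`) segment means, mimicking segmentation output without
  modeling probes. `noise_sd` defaults to **0.02**: the generator draws
  *segment means*, and a megabase-scale segment averages hundreds of array
  probes, putting its dispersion an order of magnitude below per-probe noise
  and safely below the 0.1 calling threshold — the regime in which the
  permutation/BH machinery is quiet on signal-free cohorts. Planted
  alterations are carried independently by each tumor with probability
  `carrier_frequency` and add a signed Normal(amplitude, amplitude_sd) log2
  shift over the planted interval; normals never carry events; carrier sets
  are returned as ground truth.
- **Cohort size** — default 200 tumors and 30 normals: large enough for the
  10%-frequency, amplitude-1.5 detection regime (echoing an 8.7%-frequency
  focal amplification) while the full pipeline runs in seconds.
- **Expression** — log2 expression = 3.0 + slope × (gene-body mean log2
  ratio) + Normal(0, 0.5), exponentiated to an FPKM-like scale; slope
  defaults to 1.0 (proportional dosage). The concordance power benchmark
  plants carrier frequency 0.5 so the tumor-mean shift (≈ 0.75 on log2) is
  resolvable at 50 tumors vs 30 normals.
- **TF sites** — one site per enriched (TF, gene) pair placed inside the
  promoter window, plus uniform background sites at a Poisson rate per Mb.
- **Methylation** — two CpGs within 500 bp of every TSS; β ~ clipped
  Normal(0.7, 0.05); hypomethylated targets shift tumor means by −0.2.

Passing benchmarks on these cohorts shows the machinery is correct and
calibrated under its stated assumptions. It does **not** show robustness to
allele-specific copy number, whole-genome doubling, purity/ploidy effects,
wavy array backgrounds, expression count noise, or annotation errors — none
of which are modeled.

## Numerical and design decisions

- Internal coordinates are uniformly 0-based half-open; SEG and GTF-lite are
  converted at the I/O boundary (1-based inclusive on disk), BED is not.
  Chromosome names are taken verbatim; mismatches surface as empty overlaps
  with warnings rather than silent renames. The strand-aware TSS of a
  minus-strand gene is its last covered base (`end − 1`).
- Focal-peak ties are compared with an absolute tolerance of 1e-12 and
  resolved to the widest tied run.
- Residual peaks found after peel-off receive a q-value by mapping their
  empirical p through the original (p, q) curve of the track.
- Amplification and deletion are scored as independent tracks; a marker may
  be significant in both.
- The Welch statistic, hypergeometric tail and BH adjustment are delegated
  to scipy/statsmodels; the test suite pins them against independent
  textbook-formula and enumeration oracles (exhaustive for all
  hypergeometric grids with N ≤ 12 and all Wilcoxon partitions with n ≤ 8).
- All randomness flows from one root seed split per stage
  (`numpy.random.SeedSequence`); identical configurations reproduce
  byte-identical artifacts.

## Benchmark problem sizes

The packaged property benchmarks use 50-seed batches (25 in the acceptance
script) of the default 200-tumor cohorts for detection, 100 seeds of
50-tumor/30-normal cohorts for concordance power, 100 label shuffles for
enrichment calibration, and single cohorts for the immune and determinism
checks — sizes chosen so the whole suite completes in a few minutes on one
CPU while keeping the binomial uncertainty of each rate a few percent.

## Known limitations

- The recurrence module is a deliberately simplified, fully specified
  GISTIC-style scorer: marker bins instead of SNP probes, a circular-shift
  permutation null instead of a semi-exact convolution background, BH on
  empirical p instead of the original q computation, and no arm-level vs
  focal decomposition. Headline counts from published tumor-atlas analyses
  are functions of those externals and are not reproduction targets.
- Per-sample amplification calls for group contrasts use the same fixed
  log2 threshold as marker scoring; no per-sample noise model is fitted.
- Cross-cohort collapsing is single-linkage on focal intervals; chained
  merges can join peaks that never overlap pairwise (by design, documented).
- The exact Wilcoxon branch enumerates all C(n, nx) assignments and is
  limited to pooled sizes ≤ 24.
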