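"""Recurrent copy-number alteration detection.

The genome is binned into fixed-size markers. For each direction
(amplification / deletion) a tumor is "altered" at a marker when its log2
ratio exceeds ``amp_threshold`` (falls below ``-amp_threshold`` for
deletions). Each marker's recurrence score is

    G = frequency × mean amplitude of altered samples,

equivalently the sum of altered |log2| values divided by the cohort size.
Significance is assessed against an empirical null built by circularly
shifting each tumor's marker-value vector within each chromosome (which
preserves per-sample segment structure while destroying cross-sample
alignment), with Benjamini–Hochberg FDR control across markers and a
q < 0.25 discovery threshold. Significant regions are reported at three
nested levels — region, enlarged peak, focal peak — and additional
independent events inside one region are recovered by peeling off the
samples supporting each called peak and re-testing the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .models import (
    AMPLIFICATION,
    DELETION,
    DIRECTIONS,
    Peak,
    SegmentSet,
    ValidationError,
)

logger = logging.getLogger("scnalnc.recurrence")

DEFAULT_BIN_SIZE = 10_000
DEFAULT_AMP_THRESHOLD = 0.1
DEFAULT_Q_THRESHOLD = 0.25
DEFAULT_ENLARGED_EPSILON = 0.05
DEFAULT_N_PERM = 200
DEFAULT_MAX_PEAKS_PER_REGION = 5


@dataclass
class MarkerTrack:
    """Per-marker recurrence statistics for one direction.

    ``table`` holds one row per marker: chromosome, start, end, frequency,
    amplitude (mean |log2| over altered samples), g_score, p_value, q_value
    (p/q are NaN until :func:`empirical_q` fills them). The per-tumor marker
    value matrices are kept privately so the permutation null and peel-off
    can reuse the rasterization.
    """

    direction: str
    bin_size: int
    amp_threshold: float
    table: pd.DataFrame
    samples: list[str]
    values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_tumors(self) -> int:
        return len(self.samples)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Row indices of ``table`` belonging to one chromosome."""
        return np.flatnonzero((self.table["chromosome"] == chrom).to_numpy())


def _rasterize(segments: SegmentSet, bin_size: int) -> tuple[dict[str, np.ndarray], list[str]]:
    """Length-weighted mean log2 per (tumor sample, marker bin), per chromosome."""
    tumors = segments.tumor_samples
    if not tumors:
        raise ValidationError("no tumor samples in segment set")
    sample_idx = {s: i for i, s in enumerate(tumors)}
    df = segments.segments[segments.segments["sample"].isin(sample_idx)]
    values: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chromosome", sort=True):
        n_bins = int(np.ceil(sub["end"].max() / bin_size))
        num = np.zeros((len(tumors), n_bins))
        den = np.zeros((len(tumors), n_bins))
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        v = sub["log2_ratio"].to_numpy(float)
        rows = sub["sample"].map(sample_idx).to_numpy()
        first = s // bin_size
        last = (e - 1) // bin_size
        counts = last - first + 1
        seg_of = np.repeat(np.arange(len(s)), counts)
        bins = np.concatenate([np.arange(f, l + 1) for f, l in zip(first, last)]) if len(s) else np.array([], int)
        ov = np.minimum(e[seg_of], (bins + 1) * bin_size) - np.maximum(s[seg_of], bins * bin_size)
        np.add.at(num, (rows[seg_of], bins), ov * v[seg_of])
        np.add.at(den, (rows[seg_of], bins), ov)
        values[chrom] = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return values, tumors


def _score(values: np.ndarray, direction: str, amp_threshold: float):
    """(frequency, amplitude, g_score) per marker for one value matrix."""
    if direction == AMPLIFICATION:
        altered = values > amp_threshold
    else:
        altered = values < -amp_threshold
    n = values.shape[0]
    k = altered.sum(axis=0)
    freq = k / n
    amp_sum = np.abs(np.where(altered, values, 0.0)).sum(axis=0)
    amplitude = np.divide(amp_sum, k, out=np.zeros_like(amp_sum), where=k > 0)
    return freq, amplitude, amp_sum / n


def build_marker_track(
    segments: SegmentSet,
    bin_size: int = DEFAULT_BIN_SIZE,
    direction: str = AMPLIFICATION,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> MarkerTrack:
    """Bin the genome and compute frequency, amplitude and G per marker."""
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    if amp_threshold <= 0:
        raise ValidationError("amp_threshold must be > 0")
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    values, tumors = _rasterize(segments, bin_size)
    frames = []
    for chrom in sorted(values):
        freq, amplitude, g = _score(values[chrom], direction, amp_threshold)
        n_bins = values[chrom].shape[1]
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start": np.arange(n_bins) * bin_size,
                    "end": (np.arange(n_bins) + 1) * bin_size,
                    "frequency": freq,
                    "amplitude": amplitude,
                    "g_score": g,
                    "p_value": np.nan,
                    "q_value": np.nan,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return MarkerTrack(
        direction=direction,
        bin_size=bin_size,
        amp_threshold=amp_threshold,
        table=table,
        samples=tumors,
        values=values,
    )


def permutation_null(
    track: MarkerTrack, n_perm: int = DEFAULT_N_PERM, seed: int | None = 0
) -> np.ndarray:
    """Pooled null G-score sample from within-sample circular shifts.

    In each permutation every tumor's per-marker value vector is circularly
    shifted by an independent uniform offset within each chromosome; G-scores
    of all markers in all permutations are pooled and returned sorted.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = track.n_tumors
    null: list[np.ndarray] = []
    for chrom in sorted(track.values):
        vals = track.values[chrom]
        n_bins = vals.shape[1]
        cols = np.arange(n_bins)
        for _ in range(n_perm):
            offsets = rng.integers(0, n_bins, size=n)
            idx = (cols[None, :] - offsets[:, None]) % n_bins
            shifted = np.take_along_axis(vals, idx, axis=1)
            _, _, g = _score(shifted, track.direction, track.amp_threshold)
            null.append(g)
    return np.sort(np.concatenate(null))


def empirical_q(track: MarkerTrack, null: np.ndarray) -> MarkerTrack:
    """Fill per-marker empirical p and Benjamini–Hochberg q values.

    p(marker) = (1 + #{null G >= observed G}) / (1 + #null); q by BH step-up
    across all markers of the track's direction.
    """
    if null is None or len(null) == 0:
        raise ValidationError("empty permutation null")
    null = np.sort(np.asarray(null))
    g = track.table["g_score"].to_numpy()
    n_ge = len(null) - np.searchsorted(null, g, side="left")
    p = (1.0 + n_ge) / (1.0 + len(null))
    q = multipletests(p, method="fdr_bh")[1]
    table = track.table.copy()
    table["p_value"] = p
    table["q_value"] = q
    return replace(track, table=table)


def _runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers, as (first, last) inclusive."""
    if len(indices) == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(indices) - 1]])
    return [(int(indices[a]), int(indices[b])) for a, b in zip(starts, ends)]


def _focal_run(g: np.ndarray, lo: int, hi: int) -> tuple[int, int, float]:
    """Widest run of markers tied at the maximum G within [lo, hi]."""
    seg = g[lo : hi + 1]
    gmax = seg.max()
    tied = np.flatnonzero(seg >= gmax - 1e-12)
    runs = _runs(tied)
    widths = [b - a for a, b in runs]
    a, b = runs[int(np.argmax(widths))]
    return lo + a, lo + b, float(gmax)


def _enlarge(g: np.ndarray, lo: int, hi: int, f_lo: int, f_hi: int, peak_g: float, eps: float):
    thr = (1.0 - eps) * peak_g
    e_lo, e_hi = f_lo, f_hi
    while e_lo > lo and g[e_lo - 1] >= thr:
        e_lo -= 1
    while e_hi < hi and g[e_hi + 1] >= thr:
        e_hi += 1
    return e_lo, e_hi


def _supporting_samples(track: MarkerTrack, vals: np.ndarray, f_lo: int, f_hi: int) -> np.ndarray:
    win = vals[:, f_lo : f_hi + 1]
    if track.direction == AMPLIFICATION:
        return np.flatnonzero((win > track.amp_threshold).any(axis=1))
    return np.flatnonzero((win < -track.amp_threshold).any(axis=1))


def _p_of(null: np.ndarray, g) -> np.ndarray:
    n_ge = len(null) - np.searchsorted(null, g, side="left")
    return (1.0 + n_ge) / (1.0 + len(null))


def call_alterations(
    track: MarkerTrack,
    null: np.ndarray | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    enlarged_epsilon: float = DEFAULT_ENLARGED_EPSILON,
    max_peaks_per_region: int = DEFAULT_MAX_PEAKS_PER_REGION,
) -> list[Peak]:
    """Call significant alterations at region/enlarged/focal levels.

    A region is a maximal run of contiguous markers with q < ``q_threshold``.
    Within a region the focal peak is the widest marker run tied at the
    maximal G; the enlarged peak extends it contiguously while
    G >= (1 − ``enlarged_epsilon``) × peak G. After each peak its supporting
    samples (altered anywhere over the focal interval) are peeled off across
    the region and the residual is re-tested against ``null``; iteration
    stops when nothing remains significant or ``max_peaks_per_region`` is
    reached. Peaks are ranked by G score.
    """
    if not (0 < q_threshold < 1):
        raise ValidationError("q_threshold must be in (0, 1)")
    tab = track.table
    if tab["q_value"].isna().all():
        raise ValidationError("track has no q values; run empirical_q first")
    sig = tab["q_value"].to_numpy() < q_threshold
    if not sig.any():
        return []
    # largest empirical p still called significant: the BH step-up cutoff,
    # reused to re-test residual tracks after peel-off
    p_cutoff = tab["p_value"].to_numpy()[sig].max()
    null_sorted = np.sort(null) if null is not None and len(null) else None

    peaks: list[Peak] = []
    bs = track.bin_size
    for chrom in sorted(track.values):
        rows = track.chrom_slice(chrom)
        chrom_sig = np.flatnonzero(sig[rows])
        g_obs = tab["g_score"].to_numpy()[rows]
        q_obs = tab["q_value"].to_numpy()[rows]
        vals = track.values[chrom].copy()
        for lo, hi in _runs(chrom_sig):
            region = (lo * bs, (hi + 1) * bs)
            g_cur = g_obs.copy()
            for it in range(max_peaks_per_region):
                f_lo, f_hi, peak_g = _focal_run(g_cur, lo, hi)
                if peak_g <= 0:
                    break
                e_lo, e_hi = _enlarge(g_cur, lo, hi, f_lo, f_hi, peak_g, enlarged_epsilon)
                support = _supporting_samples(track, vals, f_lo, f_hi)
                if it == 0:
                    q_peak = float(q_obs[f_lo : f_hi + 1].min())
                else:
                    q_peak = _residual_q(tab, null_sorted, peak_g)
                peaks.append(
                    Peak(
                        direction=track.direction,
                        chromosome=chrom,
                        region=region,
                        enlarged=(e_lo * bs, (e_hi + 1) * bs),
                        focal=(f_lo * bs, (f_hi + 1) * bs),
                        g_score=peak_g,
                        q_value=q_peak,
                        samples=[track.samples[i] for i in support],
                    )
                )
                if len(support) == 0 or null_sorted is None:
                    break
                # peel off: remove supporting samples' contributions region-wide
                vals[np.ix_(support, np.arange(lo, hi + 1))] = 0.0
                _, _, g_res = _score(vals[:, lo : hi + 1], track.direction, track.amp_threshold)
                g_cur = g_cur.copy()
                g_cur[lo : hi + 1] = g_res
                p_res = _p_of(null_sorted, g_cur[lo : hi + 1])
                if not (p_res <= p_cutoff).any():
                    break
    peaks.sort(key=lambda p: -p.g_score)
    for i, p in enumerate(peaks):
        p.rank = i + 1
    return peaks


def _residual_q(tab: pd.DataFrame, null_sorted: np.ndarray | None, g: float) -> float:
    """Map a residual peak's G to a q value via the original (p, q) curve."""
    if null_sorted is None:
        return float("nan")
    p = float(_p_of(null_sorted, np.array([g]))[0])
    pq = tab[["p_value", "q_value"]].dropna().sort_values("p_value")
    idx = np.searchsorted(pq["p_value"].to_numpy(), p, side="left")
    if idx >= len(pq):
        return 1.0
    return float(pq["q_value"].to_numpy()[idx])


def peel_off(track: MarkerTrack, peak: Peak) -> MarkerTrack:
    """Remove a peak's supporting samples over its region and rescore.

    Returns a new track in which every sample supporting the peak has its
    marker values zeroed across the enclosing region; G never increases.
    q/p values are reset to NaN (re-test with :func:`empirical_q`).
    """
    sample_idx = {s: i for i, s in enumerate(track.samples)}
    support = [sample_idx[s] for s in peak.samples if s in sample_idx]
    bs = track.bin_size
    lo, hi = peak.region[0] // bs, (peak.region[1] - 1) // bs
    values = {c: v.copy() for c, v in track.values.items()}
    if support:
        values[peak.chromosome][np.ix_(support, np.arange(lo, hi + 1))] = 0.0
    table = track.table.copy()
    rows = track.chrom_slice(peak.chromosome)
    freq, amplitude, g = _score(values[peak.chromosome], track.direction, track.amp_threshold)
    table.loc[rows, "frequency"] = freq
    table.loc[rows, "amplitude"] = amplitude
    table.loc[rows, "g_score"] = g
    table["p_value"] = np.nan
    table["q_value"] = np.nan
    return replace(track, table=table, values=values)


def detect(
    segments: SegmentSet,
    directions: tuple[str, ...] = DIRECTIONS,
    bin_size: int = DEFAULT_BIN_SIZE,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    enlarged_epsilon: float = DEFAULT_ENLARGED_EPSILON,
    max_peaks_per_region: int = DEFAULT_MAX_PEAKS_PER_REGION,
    seed: int = 0,
) -> tuple[dict[str, MarkerTrack], list[Peak]]:
    """Full detection: tracks, permutation null, q values and peaks per direction."""
    tracks: dict[str, MarkerTrack] = {}
    peaks: list[Peak] = []
    for i, direction in enumerate(directions):
        track = build_marker_track(segments, bin_size, direction, amp_threshold)
        null = permutation_null(track, n_perm=n_perm, seed=None if seed is None else seed + i)
        track = empirical_q(track, null)
        tracks[direction] = track
        found = call_alterations(
            track, null, q_threshold, enlarged_epsilon, max_peaks_per_region
        )
        logger.info("direction %s: %d peaks", direction, len(found))
        peaks.extend(found)
    peaks.sort(key=lambda p: -p.g_score)
    for i, p in enumerate(peaks):
        p.rank = i + 1
    return tracks, peaks
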