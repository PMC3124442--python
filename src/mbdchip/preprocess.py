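"""Turn duplicate M/T probe intensities into smoothed, GC-corrected log-ratios.

The key idea: in adult somatic cells methylation is confined to CpG
dinucleotides, and MBD capture does not retain fragments from CpG-poor DNA.
Probes in windows of extremely low CpG density ("null probes") therefore
cannot carry true enrichment — any signal there is a sequence artifact.
The null probes, stratified by probe G+C count, supply both the baseline
that is subtracted from every probe and the empirical null distribution
used downstream for Z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import CHANNEL_M, CHANNEL_T, IntensityTable, ProbeDesign

STAGE_LOG_RATIO = "log_ratio"
STAGE_ADJUSTED = "adjusted"
STAGE_SMOOTHED = "smoothed"
STAGE_Z = "z"


@dataclass
class SignalTrack:
    """One value per design probe at a named pipeline stage."""

    values: np.ndarray
    stage: str
    sample: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, stage: str) -> "SignalTrack":
        return SignalTrack(values=values, stage=stage, sample=self.sample)


@dataclass
class NullProbeSet:
    """Indices of probes in CpG-desert windows — the empirical null set."""

    indices: np.ndarray
    window: int
    threshold: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) == 0:
            raise ValueError("null probe set is empty")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class GCStrata:
    """Per-GC-bin location and scale of the null distribution.

    ``median``/``scale``/``count`` are indexed by raw G+C count (0..max
    probe length); sparse bins are pre-merged so every GC value maps to an
    effective bin whose statistics are stored at its index.
    """

    median: np.ndarray
    scale: np.ndarray
    count: np.ndarray
    effective_bin: np.ndarray = field(default=None)  # raw gc -> effective gc label

    def __post_init__(self) -> None:
        if self.effective_bin is None:
            self.effective_bin = np.arange(len(self.median))
        if np.any(self.scale <= 0):
            raise ValueError("GC stratum scale must be positive")

    def baseline_for(self, gc_counts: np.ndarray) -> np.ndarray:
        return self.median[np.asarray(gc_counts, dtype=np.int64)]

    def scale_for(self, gc_counts: np.ndarray) -> np.ndarray:
        return self.scale[np.asarray(gc_counts, dtype=np.int64)]


# ---------------------------------------------------------------------------
# CpG density and null-probe selection
# ---------------------------------------------------------------------------

def _cpg_starts(seq: str) -> np.ndarray:
    """0-based start positions of CG dinucleotides in *seq*."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if len(arr) < 2:
        return np.empty(0, dtype=np.int64)
    hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(hits).astype(np.int64)


def local_cpg_density(genome: dict[str, str], chrom: str, position: int,
                      window: int = 1000) -> float:
    """CpG dinucleotides per 1000 bp in a *window* centered on *position*.

    The window is truncated at chromosome ends and the density rescaled to
    the actual window length; a CG counts if the dinucleotide lies fully
    inside the window.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    if not 0 <= position < len(seq):
        raise ValueError(f"position {position} outside {chrom} (length {len(seq)})")
    lo = max(0, position - window // 2)
    hi = min(len(seq), position + (window + 1) // 2)
    count = seq.count("CG", lo, hi)  # CG fully inside: last start searched is hi-2
    return 1000.0 * count / (hi - lo)


def select_null_probes(design: ProbeDesign, genome: dict[str, str],
                       threshold: float = 4.0, window: int = 1000,
                       min_probes: int = 500) -> NullProbeSet:
    """Probes whose local CpG density (centered on the probe midpoint) is
    strictly below *threshold* CpGs per 1000 bp."""
    keep = np.zeros(len(design), dtype=bool)
    for chrom, sl in design.chrom_slices().items():
        if chrom not in genome:
            raise KeyError(f"design chromosome {chrom!r} missing from genome")
        seq = genome[chrom]
        cg = _cpg_starts(seq)
        mids = design.midpoint[sl]
        lo = np.maximum(0, mids - window // 2)
        hi = np.minimum(len(seq), mids + (window + 1) // 2)
        # count CG starts in [lo, hi-1) so the dinucleotide fits inside
        counts = np.searchsorted(cg, hi - 1) - np.searchsorted(cg, lo)
        density = 1000.0 * counts / (hi - lo)
        keep[sl] = density < threshold
    idx = np.flatnonzero(keep)
    if len(idx) < min_probes:
        raise ValueError(
            f"only {len(idx)} null probes at density < {threshold}/1000 bp "
            f"(minimum {min_probes}); relax the threshold or widen the window"
        )
    return NullProbeSet(indices=idx, window=window, threshold=threshold)


# ---------------------------------------------------------------------------
# Log-ratios
# ---------------------------------------------------------------------------

def compute_log_ratio(intensity: IntensityTable, sample: str,
                      numerator_channel: str = CHANNEL_M,
                      denominator_channel: str = CHANNEL_T,
                      numerator_replicates=None,
                      denominator_replicates=None) -> SignalTrack:
    """Replicate-mean log2 ratio between two channels of one sample.

    Per probe: mean log2 intensity over duplicates within each channel,
    then numerator minus denominator. Selecting single replicates of the
    same channel (e.g. T rep 1 vs T rep 2) yields the replicate-null
    ratio used for FDR estimation.
    """
    num = intensity.channel_mean(sample, numerator_channel, numerator_replicates)
    den = intensity.channel_mean(sample, denominator_channel, denominator_replicates)
    return SignalTrack(values=num - den, stage=STAGE_LOG_RATIO, sample=sample)


def replicate_null_log_ratio(intensity: IntensityTable, sample: str,
                             channel: str = CHANNEL_T) -> SignalTrack:
    """log2(T_rep1 / T_rep2): a track with no true signal, for FDR."""
    reps = intensity.replicates(sample, channel)
    if len(reps) < 2:
        raise ValueError(f"sample {sample!r}: need >= 2 {channel} replicates for the null ratio")
    return compute_log_ratio(
        intensity, sample, channel, channel,
        numerator_replicates=[reps[0]], denominator_replicates=[reps[1]],
    )


# ---------------------------------------------------------------------------
# GC strata
# ---------------------------------------------------------------------------

_MAD_TO_SD = 1.4826

_BASELINE_STAGES = (STAGE_LOG_RATIO, STAGE_ADJUSTED, STAGE_SMOOTHED)


def estimate_gc_baseline(track: SignalTrack, nulls: NullProbeSet,
                         design: ProbeDesign, min_bin_size: int = 200) -> GCStrata:
    """Median and robust scale of null-probe values per probe-GC stratum.

    Bins are integer G+C counts of the probe sequence. Bins holding fewer
    than *min_bin_size* null probes are merged with their nearest populated
    neighbor until every effective bin meets the floor. Scale is
    1.4826 x MAD; a zero MAD falls back to the bin SD, then to the global
    robust scale, then to the global SD.
    """
    if track.stage not in _BASELINE_STAGES:
        raise ValueError(f"cannot estimate GC strata on stage {track.stage!r}")
    vals = track.values[nulls.indices]
    gcs = design.gc_count[nulls.indices]
    ok = ~np.isnan(vals)
    vals, gcs = vals[ok], gcs[ok]
    if len(vals) == 0:
        raise ValueError("all null-probe values missing")

    n_bins = int(design.length.max()) + 1
    # groups of raw gc values, merged greedily until each meets the floor
    groups: list[list[int]] = [[g] for g in sorted(set(int(g) for g in gcs))]
    sizes = [int(np.sum(np.isin(gcs, grp))) for grp in groups]
    while len(groups) > 1 and min(sizes) < min_bin_size:
        i = int(np.argmin(sizes))
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            # nearest neighbor by gc distance between group edges; tie -> smaller side
            dl = groups[i][0] - groups[i - 1][-1]
            dr = groups[i + 1][0] - groups[i][-1]
            j = i - 1 if dl <= dr else i + 1
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        sizes[lo] = sizes[lo] + sizes[hi]
        del groups[hi], sizes[hi]

    global_mad = _MAD_TO_SD * float(np.median(np.abs(vals - np.median(vals))))
    global_sd = float(np.std(vals))
    fallback = next((s for s in (global_mad, global_sd, 1.0) if s > 0), 1.0)

    median = np.full(n_bins, np.nan)
    scale = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=np.int64)
    effective = np.arange(n_bins)
    populated_labels = []
    for grp in groups:
        mask = np.isin(gcs, grp)
        v = vals[mask]
        m = float(np.median(v))
        s = _MAD_TO_SD * float(np.median(np.abs(v - m)))
        if s == 0:
            s = float(np.std(v))
        if s == 0:
            s = fallback
        label = grp[0]
        populated_labels.append(label)
        for g in grp:
            median[g], scale[g], count[g] = m, s, len(v)
            effective[g] = label
    # gc values never seen among null probes map to the nearest populated bin
    pop = np.array(sorted(populated_labels))
    for g in range(n_bins):
        if np.isnan(median[g]):
            nearest = pop[np.argmin(np.abs(pop - g))]
            median[g], scale[g] = median[nearest], scale[nearest]
            effective[g] = effective[nearest]
    return GCStrata(median=median, scale=scale, count=count, effective_bin=effective)


def adjust_signal(track: SignalTrack, strata: GCStrata, design: ProbeDesign) -> SignalTrack:
    """Subtract the GC-stratum baseline from every probe (probe-effect removal)."""
    if track.stage != STAGE_LOG_RATIO:
        raise ValueError(f"adjust_signal expects a log_ratio track, got {track.stage!r}")
    return track.with_values(track.values - strata.baseline_for(design.gc_count), STAGE_ADJUSTED)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_running_median(track: SignalTrack, design: ProbeDesign, k: int = 7) -> SignalTrack:
    """Running median over k consecutive probes, per chromosome.

    At chromosome edges the window shrinks symmetrically to the largest odd
    size available, so the estimator stays centered and no probe is dropped.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError(f"smoothing window k must be odd and >= 1, got {k}")
    out = np.empty_like(track.values)
    half = k // 2
    for _, sl in design.chrom_slices().items():
        v = track.values[sl]
        n = len(v)
        if n == 0:
            continue
        smoothed = np.empty(n)
        if n >= k:
            windows = np.lib.stride_tricks.sliding_window_view(v, k)
            smoothed[half:n - half] = np.median(windows, axis=1)
        edge_idx = [i for i in range(min(half, n))] + [i for i in range(max(n - half, 0), n)]
        for i in edge_idx:
            h = min(i, n - 1 - i, half)
            smoothed[i] = np.median(v[i - h:i + h + 1])
        out[sl] = smoothed
    return track.with_values(out, STAGE_SMOOTHED)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def autocorrelation(track: SignalTrack, subset: NullProbeSet, design: ProbeDesign,
                    lag: int = 1) -> float:
    """Pearson correlation of (value_i, value_{i+lag}) over consecutive
    subset probes on the same chromosome."""
    idx = subset.indices
    if len(idx) < 100:
        raise ValueError("need >= 100 subset probes for autocorrelation")
    same_chrom = design.chrom[idx[:-lag]] == design.chrom[idx[lag:]]
    x = track.values[idx[:-lag]][same_chrom]
    y = track.values[idx[lag:]][same_chrom]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in autocorrelation input")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def normality_diagnostic(track: SignalTrack, subset: NullProbeSet) -> float:
    """Max |observed - theoretical| standard-normal quantile gap at deciles.

    Values are standardized (mean 0, SD 1) first, so the statistic reports
    distributional shape, not location/scale.
    """
    v = track.values[subset.indices]
    v = v[~np.isnan(v)]
    if len(v) < 1000:
        raise ValueError("need >= 1000 subset probes for the Q-Q diagnostic")
    z = (v - v.mean()) / v.std()
    probs = np.arange(0.1, 1.0, 0.1)
    observed = np.quantile(z, probs)
    theoretical = stats.norm.ppf(probs)
    return float(np.max(np.abs(observed - theoretical)))
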