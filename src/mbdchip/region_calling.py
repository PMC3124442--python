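"""Per-probe Z-scores and additive-Z region calling.

A probe's Z-score is the number of null standard deviations separating its
smoothed adjusted log2(M/T) from the median of null probes with the same
G+C count. Probes with Z above a seed threshold (default 3) are chained
when their starts are within a merge gap (default 250 bp, the modal
fragment size) and the chain's additive Z over all spanned probes must
clear a region threshold (default 4) to be called. Under a standard-normal
null the per-probe thresholds correspond to upper-tail probabilities of
1.3e-3 (Z>3) and 3.2e-5 (Z>4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import IntensityTable, ProbeDesign, Region, RegionSet
from .preprocess import (
    STAGE_SMOOTHED,
    STAGE_Z,
    GCStrata,
    NullProbeSet,
    SignalTrack,
    adjust_signal,
    estimate_gc_baseline,
    replicate_null_log_ratio,
    smooth_running_median,
)

DEFAULT_Z_PROBE = 3.0
DEFAULT_Z_REGION = 4.0
DEFAULT_MERGE_GAP = 250


def probe_z_scores(track: SignalTrack, strata: GCStrata, design: ProbeDesign) -> SignalTrack:
    """z_i = (value_i - median_g(i)) / scale_g(i), g = probe G+C count.

    Z counts how many null standard deviations (per GC stratum, estimated
    on the adjusted pre-smoothing track, where the per-bin median is zero
    by construction) separate the smoothed value from the null median.
    """
    if track.stage != STAGE_SMOOTHED:
        raise ValueError(f"probe_z_scores expects a smoothed track, got {track.stage!r}")
    z = (track.values - strata.baseline_for(design.gc_count)) / strata.scale_for(design.gc_count)
    return track.with_values(z, STAGE_Z)


def call_regions(z: SignalTrack, design: ProbeDesign,
                 z_probe: float = DEFAULT_Z_PROBE,
                 z_region: float = DEFAULT_Z_REGION,
                 merge_gap: int = DEFAULT_MERGE_GAP,
                 sum_seeds_only: bool = False) -> RegionSet:
    """Seed-and-merge region calling on a per-probe Z track.

    Seeds are probes with Z > z_probe (strict). Consecutive seeds on a
    chromosome whose start-to-start distance is < merge_gap (strict) are
    chained; a chain spans from the first seed's start to the last seed's
    end and its additive Z sums over all probes in the span (or seeds only
    with ``sum_seeds_only``). Chains with additive Z > z_region are
    returned ranked by additive Z descending, ties broken by position.
    """
    if z.stage != STAGE_Z:
        raise ValueError(f"call_regions expects a z track, got {z.stage!r}")
    regions: list[Region] = []
    for chrom, sl in design.chrom_slices().items():
        zc = z.values[sl]
        starts = design.start[sl]
        ends = design.end[sl]
        seeds = np.flatnonzero(zc > z_probe)
        if len(seeds) == 0:
            continue
        breaks = np.flatnonzero(np.diff(starts[seeds]) >= merge_gap)
        chain_bounds = np.concatenate([[0], breaks + 1, [len(seeds)]])
        for a, b in zip(chain_bounds[:-1], chain_bounds[1:]):
            chain = seeds[a:b]
            i0, i1 = chain[0], chain[-1]
            span_z = zc[chain] if sum_seeds_only else zc[i0:i1 + 1]
            additive = float(np.nansum(span_z))
            if additive > z_region:
                regions.append(
                    Region(
                        chrom=chrom,
                        start=int(starts[i0]),
                        end=int(ends[i1]),
                        additive_z=additive,
                        n_probes=int(i1 - i0 + 1),
                        max_probe_z=float(np.nanmax(zc[i0:i1 + 1])),
                    )
                )
    regions.sort(key=lambda r: (-r.additive_z, r.chrom, r.start))
    for rank, r in enumerate(regions, 1):
        r.rank = rank
    return RegionSet(
        regions=regions,
        sample=z.sample,
        params={"z_probe": z_probe, "z_region": z_region, "merge_gap": merge_gap,
                "sum_seeds_only": sum_seeds_only},
    )


# ---------------------------------------------------------------------------
# FDR from replicate total-input hybridizations
# ---------------------------------------------------------------------------

def call_from_log_ratio(track: SignalTrack, design: ProbeDesign, nulls: NullProbeSet,
                        min_bin_size: int = 200, k: int = 7,
                        z_probe: float = DEFAULT_Z_PROBE,
                        z_region: float = DEFAULT_Z_REGION,
                        merge_gap: int = DEFAULT_MERGE_GAP,
                        sum_seeds_only: bool = False):
    """Run adjust -> smooth -> Z -> call on a raw log-ratio track.

    Strata are estimated twice: on the raw log-ratio for the GC baseline
    subtraction, and again on the adjusted (pre-smoothing) track for the Z
    score, whose denominator is the *unsmoothed* per-bin null SD. The
    running median shrinks the spread of null values, so a smoothed value
    three unsmoothed-SDs out is a far stronger signal than a single noisy
    probe — this is what makes the additive-Z region test specific.
    Returns (strata_raw, adjusted, smoothed, strata_z, z, regions).
    """
    strata_raw = estimate_gc_baseline(track, nulls, design, min_bin_size=min_bin_size)
    adjusted = adjust_signal(track, strata_raw, design)
    smoothed = smooth_running_median(adjusted, design, k=k)
    strata_z = estimate_gc_baseline(adjusted, nulls, design, min_bin_size=min_bin_size)
    z = probe_z_scores(smoothed, strata_z, design)
    regions = call_regions(z, design, z_probe=z_probe, z_region=z_region,
                           merge_gap=merge_gap, sum_seeds_only=sum_seeds_only)
    return strata_raw, adjusted, smoothed, strata_z, z, regions


def estimate_fdr(intensity: IntensityTable, sample: str, design: ProbeDesign,
                 nulls: NullProbeSet, n_called: int, channel: str = "T",
                 **pipeline_kwargs) -> float:
    """FDR = regions called on log2(T_rep1/T_rep2) / regions called on log2(M/T).

    The replicate-input ratio carries no true methylation signal, so every
    region the identical pipeline calls on it is a false discovery.
    """
    if n_called <= 0:
        raise ValueError("FDR undefined: no regions called on the sample (n_called = 0)")
    null_track = replicate_null_log_ratio(intensity, sample, channel=channel)
    *_, null_regions = call_from_log_ratio(null_track, design, nulls, **pipeline_kwargs)
    return len(null_regions) / n_called


# ---------------------------------------------------------------------------
# Differential calls
# ---------------------------------------------------------------------------

@dataclass
class DifferentialCall:
    """A merged region methylated in one sample (Z>4) and not the other (Z<1)."""

    chrom: str
    start: int
    end: int
    z_high: float
    z_low: float
    direction: str  # "a" if sample A is the hypermethylated one, else "b"

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_overlapping(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    merged: list[list] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [tuple(m) for m in merged]


def _additive_z_in(z: SignalTrack, design: ProbeDesign, chrom: str, start: int, end: int) -> float:
    sl = design.chrom_slices().get(chrom)
    if sl is None:
        return 0.0
    starts = design.start[sl]
    i0 = int(np.searchsorted(starts, start, side="left"))
    i1 = int(np.searchsorted(starts, end, side="left"))
    return float(np.nansum(z.values[sl][i0:i1]))


def call_differential(regions_a: RegionSet, z_a: SignalTrack,
                      regions_b: RegionSet, z_b: SignalTrack,
                      design: ProbeDesign,
                      z_high_min: float = 4.0, z_low_max: float = 1.0,
                      min_len: int = 500) -> list[DifferentialCall]:
    """Stringent two-sample differential methylation calls.

    Regions called in either sample are union-merged; each merged interval
    is kept if its additive Z (recomputed over the spanned probes) exceeds
    z_high_min in one sample, is below z_low_max in the other, and the
    interval is longer than min_len bp (all strict).
    """
    if len(z_a) != len(design) or len(z_b) != len(design):
        raise ValueError("z tracks not aligned to the shared design")
    merged = _merge_overlapping(regions_a.intervals() + regions_b.intervals())
    calls: list[DifferentialCall] = []
    chrom_slices = design.chrom_slices()
    for chrom, s, e in merged:
        if e - s <= min_len:
            continue
        if chrom not in chrom_slices:
            continue
        za = _additive_z_in(z_a, design, chrom, s, e)
        zb = _additive_z_in(z_b, design, chrom, s, e)
        if za > z_high_min and zb < z_low_max:
            calls.append(DifferentialCall(chrom, s, e, z_high=za, z_low=zb, direction="a"))
        elif zb > z_high_min and za < z_low_max:
            calls.append(DifferentialCall(chrom, s, e, z_high=zb, z_low=za, direction="b"))
    return calls


# ---------------------------------------------------------------------------
# Threshold sensitivity
# ---------------------------------------------------------------------------

def _overlaps_any(region: Region, by_chrom: dict[str, np.ndarray]) -> bool:
    ivals = by_chrom.get(region.chrom)
    if ivals is None or len(ivals) == 0:
        return False
    starts, ends = ivals[:, 0], ivals[:, 1]
    return bool(np.any((starts < region.end) & (ends > region.start)))


def cutoff_sensitivity(z: SignalTrack, design: ProbeDesign,
                       z_probe_values: list[float],
                       z_region: float = DEFAULT_Z_REGION,
                       merge_gap: int = DEFAULT_MERGE_GAP,
                       reference_z_probe: float = DEFAULT_Z_PROBE,
                       min_report_len: int = 200) -> pd.DataFrame:
    """Region counts and novel-region counts as the seed cutoff varies.

    A region is "new" at a cutoff if it is longer than min_report_len and
    overlaps no region called at the reference cutoff.
    """
    if reference_z_probe not in z_probe_values:
        raise ValueError("reference cutoff must be among z_probe_values")
    reference = call_regions(z, design, z_probe=reference_z_probe,
                             z_region=z_region, merge_gap=merge_gap)
    ref_by_chrom: dict[str, np.ndarray] = {}
    for r in reference:
        ref_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    ref_by_chrom = {c: np.array(v) for c, v in ref_by_chrom.items()}
    rows = []
    for cutoff in z_probe_values:
        called = call_regions(z, design, z_probe=cutoff, z_region=z_region, merge_gap=merge_gap)
        n_new = sum(
            1 for r in called
            if r.length > min_report_len and not _overlaps_any(r, ref_by_chrom)
        )
        rows.append({"z_probe": cutoff, "n_regions": len(called), "n_new_regions": n_new})
    return pd.DataFrame(rows)
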