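"""Genomic-compartment annotation and matched random-region enrichment tests.

Called regions are placed into five compartments (gene upstream/downstream
windows, exon, intron, distal intergenic), scored for overlap with
annotation tracks (CpG islands, conservation, TFBS), and compared against
Q random region sets matched for length and array coverage; the empirical
enrichment p-value is N(random > observed) / Q.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, ProbeDesign, Region, RegionSet
from .preprocess import STAGE_SMOOTHED, SignalTrack

COMPARTMENTS = ("gene_upstream", "gene_downstream", "exon", "intron", "intergenic")

# Intron length classes (bp): half-open short, closed long, resolving the
# boundary duplication at 2,715 bp.
SHORT_INTRON = (842, 2715)
LONG_INTRON = (2715, 11673)


# ---------------------------------------------------------------------------
# Interval arithmetic on merged sorted arrays
# ---------------------------------------------------------------------------

def merge_intervals(intervals) -> dict[str, np.ndarray]:
    """Union-merge (chrom, start, end) triples into per-chrom sorted arrays."""
    by_chrom: dict[str, list] = {}
    for chrom, s, e in sorted(intervals):
        lst = by_chrom.setdefault(chrom, [])
        if lst and s <= lst[-1][1]:
            lst[-1][1] = max(lst[-1][1], e)
        else:
            lst.append([s, e])
    return {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in by_chrom.items()}


def interval_overlap_bp(chrom: str, start: int, end: int,
                        merged: dict[str, np.ndarray]) -> int:
    """Base pairs of [start, end) covered by the merged interval set."""
    ivals = merged.get(chrom)
    if ivals is None or len(ivals) == 0:
        return 0
    lo = np.searchsorted(ivals[:, 1], start, side="right")
    hi = np.searchsorted(ivals[:, 0], end, side="left")
    if hi <= lo:
        return 0
    clipped = np.minimum(ivals[lo:hi, 1], end) - np.maximum(ivals[lo:hi, 0], start)
    return int(np.sum(np.maximum(clipped, 0)))


# ---------------------------------------------------------------------------
# Compartment classification
# ---------------------------------------------------------------------------

@dataclass
class GenomeCompartments:
    """Pre-merged compartment intervals derived from a gene set.

    Upstream/downstream windows are strand-oriented (default 2 kbp);
    ``proximal_bp`` (default 3 kbp) separates gene-proximal from distal
    intergenic space.
    """

    genes: list[GeneModel]
    upstream_bp: int = 2000
    downstream_bp: int = 2000
    proximal_bp: int = 3000
    _merged: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        up, down, exons, introns, spans = [], [], [], [], []
        for g in self.genes:
            spans.append((g.chrom, g.start, g.end))
            if g.strand == "+":
                up.append((g.chrom, max(0, g.tss - self.upstream_bp), g.tss))
                down.append((g.chrom, g.tts, g.tts + self.downstream_bp))
            else:
                up.append((g.chrom, g.tss, g.tss + self.upstream_bp))
                down.append((g.chrom, max(0, g.tts - self.downstream_bp), g.tts))
            exons.extend((g.chrom, s, e) for s, e in g.exons)
            introns.extend((g.chrom, s, e) for s, e in g.introns)
        self._merged = {
            "gene_upstream": merge_intervals(up),
            "gene_downstream": merge_intervals(down),
            "exon": merge_intervals(exons),
            "intron": merge_intervals(introns),
            "span": merge_intervals(spans),
        }

    def overlap_bp(self, region: Region, compartment: str) -> int:
        return interval_overlap_bp(region.chrom, region.start, region.end,
                                   self._merged[compartment])

    def distance_to_nearest_gene(self, region: Region) -> tuple[float, str]:
        """(bp distance to the nearest gene span, side) — side is 'left' if
        the nearest gene lies 5'-ward of the region on the chromosome."""
        spans = self._merged["span"].get(region.chrom)
        if spans is None or len(spans) == 0:
            return float("inf"), "left"
        if interval_overlap_bp(region.chrom, region.start, region.end,
                               {region.chrom: spans}) > 0:
            return 0.0, "left"
        left_gap, right_gap = float("inf"), float("inf")
        i = np.searchsorted(spans[:, 1], region.start, side="right") - 1
        if i >= 0:
            left_gap = region.start - spans[i, 1]
        j = np.searchsorted(spans[:, 0], region.end, side="left")
        if j < len(spans):
            right_gap = spans[j, 0] - region.end
        return (left_gap, "left") if left_gap <= right_gap else (right_gap, "right")

    def nearest_side_label(self, region: Region) -> str:
        """upstream/downstream label for a gene-proximal region with no
        compartment overlap, by the strand of the nearest gene."""
        spans = self._merged["span"].get(region.chrom)
        _, side = self.distance_to_nearest_gene(region)
        if spans is None:
            return "intergenic"
        if side == "left":
            i = int(np.searchsorted(spans[:, 1], region.start, side="right")) - 1
            gene_end = spans[max(i, 0), 1]
            nearest = min(self.genes, key=lambda g: abs(g.end - gene_end)
                          if g.chrom == region.chrom else np.inf)
            return "gene_downstream" if nearest.strand == "+" else "gene_upstream"
        j = int(np.searchsorted(spans[:, 0], region.end, side="left"))
        gene_start = spans[min(j, len(spans) - 1), 0]
        nearest = min(self.genes, key=lambda g: abs(g.start - gene_start)
                      if g.chrom == region.chrom else np.inf)
        return "gene_upstream" if nearest.strand == "+" else "gene_downstream"


def classify_region(region: Region, genes, upstream_bp: int = 2000,
                    downstream_bp: int = 2000, proximal_bp: int = 3000) -> str:
    """Single compartment label by majority bp overlap.

    Precedence on ties: upstream > downstream > exon > intron. A region
    overlapping nothing is intergenic iff it lies more than proximal_bp
    from every gene; otherwise it takes the nearest-side window label.
    """
    comp = genes if isinstance(genes, GenomeCompartments) else GenomeCompartments(
        genes, upstream_bp=upstream_bp, downstream_bp=downstream_bp, proximal_bp=proximal_bp)
    overlaps = {c: comp.overlap_bp(region, c) for c in COMPARTMENTS[:4]}
    best = max(overlaps.values())
    if best > 0:
        for c in COMPARTMENTS[:4]:  # precedence order
            if overlaps[c] == best:
                return c
    dist, _ = comp.distance_to_nearest_gene(region)
    if dist > comp.proximal_bp:
        return "intergenic"
    return comp.nearest_side_label(region)


def compartment_fractions(regions: RegionSet, genes, **kwargs) -> pd.DataFrame:
    """Percentage of regions (and of region bp) per compartment.

    Also reports the total region count and summed length in kbp, echoing
    the summary table layout used for array methylation surveys.
    """
    if len(regions) == 0:
        raise ValueError("cannot summarize an empty region set")
    comp = genes if isinstance(genes, GenomeCompartments) else GenomeCompartments(genes, **kwargs)
    labels = [classify_region(r, comp) for r in regions]
    lengths = np.array([r.length for r in regions], dtype=float)
    rows = []
    total_bp = lengths.sum()
    for c in COMPARTMENTS:
        mask = np.array([lab == c for lab in labels])
        rows.append({
            "compartment": c,
            "pct_regions": 100.0 * mask.sum() / len(regions),
            "pct_bp": 100.0 * lengths[mask].sum() / total_bp,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_regions"] = len(regions)
    df.attrs["total_length_kbp"] = total_bp / 1000.0
    return df


# ---------------------------------------------------------------------------
# Overlap statistics
# ---------------------------------------------------------------------------

OVERLAP_MODES = ("bp_overlap", "count_overlapping", "cpg_per_kbp", "conserved_bp")


def overlap_stats(regions: RegionSet, track, mode: str,
                  score_threshold: float = 0.8) -> float:
    """A scalar annotation statistic over the region set.

    mode:
      bp_overlap        track = intervals (frame/triples); summed bp overlap
      count_overlapping track = intervals; regions overlapping >= 1 interval
      cpg_per_kbp       track = genome dict or CpG-site intervals; CpG
                        dinucleotides per kbp of region sequence
      conserved_bp      track = bedGraph frame; bp overlapping bases with
                        score strictly > score_threshold
    """
    if mode not in OVERLAP_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {OVERLAP_MODES}")
    if mode == "cpg_per_kbp":
        total_bp = sum(r.length for r in regions)
        if total_bp == 0:
            raise ValueError("empty region set")
        if isinstance(track, dict):  # genome sequences
            n_cpg = sum(track[r.chrom].count("CG", r.start, r.end) for r in regions
                        if r.chrom in track)
        else:
            merged = _track_to_merged(track)
            n_cpg = 0
            for r in regions:
                sites = merged.get(r.chrom)
                if sites is None:
                    continue
                n_cpg += int(np.searchsorted(sites[:, 0], r.end, "left")
                             - np.searchsorted(sites[:, 0], r.start, "left"))
        return 1000.0 * n_cpg / total_bp
    if mode == "conserved_bp":
        df = track
        sel = df[df["score"] > score_threshold]
        merged = merge_intervals(list(zip(sel["chrom"], sel["start"], sel["end"])))
    else:
        merged = _track_to_merged(track)
    if mode == "count_overlapping":
        return float(sum(
            1 for r in regions
            if interval_overlap_bp(r.chrom, r.start, r.end, merged) > 0
        ))
    return float(sum(
        interval_overlap_bp(r.chrom, r.start, r.end, merged) for r in regions
    ))


def _track_to_merged(track) -> dict[str, np.ndarray]:
    if isinstance(track, dict) and all(isinstance(v, np.ndarray) for v in track.values()):
        return track
    if isinstance(track, pd.DataFrame):
        triples = list(zip(track["chrom"], track["start"], track["end"]))
    else:
        triples = [(c, s, e) for c, s, e, *_ in track]
    return merge_intervals(triples)


# ---------------------------------------------------------------------------
# Matched random region sets
# ---------------------------------------------------------------------------

def generate_matched_random(regions: RegionSet, design: ProbeDesign,
                            q: int = 500, seed: int = 0,
                            coverage_gap: int = 250,
                            max_retries: int = 10000) -> list[list[tuple[str, int, int]]]:
    """Q random region sets matched to *regions* for length and array coverage.

    Each set reproduces the observed multiset of region lengths, placed in
    rank order. Every random region starts at a probe start, must be fully
    covered by probes with no inter-probe gap exceeding *coverage_gap*,
    and may not overlap a region already placed in the same set
    (rejection sampling with uniform probe-start proposals).
    """
    rng = np.random.default_rng(seed)
    # coverage_end[i]: genomic end of the maximal well-covered probe run from probe i
    chrom_of = np.empty(len(design), dtype=object)
    coverage_end = np.empty(len(design), dtype=np.int64)
    for chrom, sl in design.chrom_slices().items():
        starts = design.start[sl]
        ends = design.end[sl]
        gaps = np.flatnonzero(np.diff(starts) > coverage_gap)
        run_bounds = np.concatenate([[0], gaps + 1, [len(starts)]])
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            coverage_end[sl][a:b] = ends[b - 1]
        chrom_of[sl] = chrom
    all_starts = design.start

    ordered = sorted(regions.regions, key=lambda r: r.rank)
    lengths = [r.length for r in ordered]
    sets: list[list[tuple[str, int, int]]] = []
    for _ in range(q):
        placed: dict[str, list] = {}  # chrom -> sorted list of (start, end)
        out = []
        for L in lengths:
            for attempt in range(max_retries):
                u = int(rng.integers(0, len(design)))
                s = int(all_starts[u])
                e = s + L
                if e > coverage_end[u]:
                    continue
                chrom = str(chrom_of[u])
                lst = placed.setdefault(chrom, [])
                i = bisect.bisect_left(lst, (s, e))
                if i > 0 and lst[i - 1][1] > s:
                    continue
                if i < len(lst) and lst[i][0] < e:
                    continue
                lst.insert(i, (s, e))
                out.append((chrom, s, e))
                break
            else:
                raise RuntimeError(
                    f"could not place a region of length {L} bp after "
                    f"{max_retries} attempts; design too sparse for matching"
                )
        sets.append(out)
    return sets


@dataclass
class EnrichmentResult:
    """Permutation-test summary: p = N(random > observed) / Q."""

    name: str
    observed: float
    randoms: list[float]
    n_exceed: int = 0
    q_total: int = 0
    p_value: float = float("nan")


def enrichment_p(observed: float, randoms, name: str = "") -> EnrichmentResult:
    """Empirical enrichment p-value with strict 'greater than' (ties favor
    significance, matching the N/Q formulation)."""
    randoms = list(randoms)
    if not randoms:
        raise ValueError("need at least one random statistic")
    n_exceed = sum(1 for r in randoms if r > observed)
    return EnrichmentResult(
        name=name, observed=observed, randoms=randoms,
        n_exceed=n_exceed, q_total=len(randoms),
        p_value=n_exceed / len(randoms),
    )


# ---------------------------------------------------------------------------
# Intron metagene profile
# ---------------------------------------------------------------------------

@dataclass
class IntronProfile:
    """Mean smoothed signal per relative-position bin over an intron class."""

    length_class: str
    bin_means: np.ndarray  # length n_bins, NaN where no probe fell
    n_introns: int


def intron_profile(track: SignalTrack, design: ProbeDesign, genes: list[GeneModel],
                   n_bins: int = 100,
                   short_class: tuple[int, int] = SHORT_INTRON,
                   long_class: tuple[int, int] = LONG_INTRON) -> tuple[IntronProfile, IntronProfile]:
    """Average signal across introns rescaled to 0-100% of intron length.

    Probes are assigned to bins by the relative position of their midpoint,
    oriented so 0% is the intron start in the direction of transcription.
    Values are averaged per bin within each intron, then across introns —
    so long, probe-dense introns do not dominate.
    """
    if track.stage != STAGE_SMOOTHED:
        raise ValueError(f"intron_profile expects a smoothed track, got {track.stage!r}")
    chrom_slices = design.chrom_slices()
    sums = {"short": np.zeros(n_bins), "long": np.zeros(n_bins)}
    counts = {"short": np.zeros(n_bins), "long": np.zeros(n_bins)}
    n_introns = {"short": 0, "long": 0}
    for g in genes:
        sl = chrom_slices.get(g.chrom)
        if sl is None:
            continue
        mids = design.midpoint[sl]
        vals = track.values[sl]
        for s, e in g.introns:
            L = e - s
            if short_class[0] <= L < short_class[1]:
                cls = "short"
            elif long_class[0] <= L <= long_class[1]:
                cls = "long"
            else:
                continue
            i0 = np.searchsorted(mids, s, "left")
            i1 = np.searchsorted(mids, e, "left")
            if i1 <= i0:
                continue
            rel = (mids[i0:i1] - s) / L
            if g.strand == "-":
                rel = 1.0 - rel - 1e-12  # orient 0% to transcriptional intron start
            bins = np.clip((rel * n_bins).astype(int), 0, n_bins - 1)
            v = vals[i0:i1]
            bin_sum = np.bincount(bins, weights=v, minlength=n_bins)
            bin_n = np.bincount(bins, minlength=n_bins)
            with np.errstate(invalid="ignore"):
                per_intron = bin_sum / bin_n
            hit = bin_n > 0
            sums[cls][hit] += per_intron[hit]
            counts[cls][hit] += 1
            n_introns[cls] += 1
    out = []
    for cls in ("short", "long"):
        with np.errstate(invalid="ignore"):
            means = np.where(counts[cls] > 0, sums[cls] / np.maximum(counts[cls], 1), np.nan)
        out.append(IntronProfile(length_class=cls, bin_means=means, n_introns=n_introns[cls]))
    return out[0], out[1]


def junction_overlap(regions: RegionSet, genes: list[GeneModel], flank: int = 0) -> int:
    """Count regions covering >= 1 intron-exon boundary (internal exon
    start/end), each region counted once however many boundaries it spans."""
    boundaries: dict[str, list[int]] = {}
    for g in genes:
        if len(g.exons) < 2:
            continue
        pts = boundaries.setdefault(g.chrom, [])
        for i, (s, e) in enumerate(g.exons):
            if i > 0:
                pts.append(s)
            if i < len(g.exons) - 1:
                pts.append(e)
    bounds = {c: np.array(sorted(set(v)), dtype=np.int64) for c, v in boundaries.items()}
    n = 0
    for r in regions:
        pts = bounds.get(r.chrom)
        if pts is None:
            continue
        lo = np.searchsorted(pts, r.start - flank, "left")
        hi = np.searchsorted(pts, r.end + flank, "left")
        if hi > lo:
            n += 1
    return n
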