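"""Synthetic genomes, annotations, methylation truth, and M/T array intensities.

The generator emulates the artifacts the analysis must survive: a
saturating, CpG-count-dependent enrichment response; a GC-dependent probe
effect riding on slowly varying genomic GC composition (which induces
positional autocorrelation in the raw log-ratio); Gaussian log2 noise;
and duplicate hybridizations per channel. Methylation is planted on
CpG-dense intervals because CpG-affinity capture cannot see methylation
where there are no CpGs.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    IntensityTable,
    ProbeDesign,
    RegionSet,
    write_bed,
    write_bedgraph,
    write_genes_bed12,
    write_genome_fasta,
    write_intensity_table,
    write_probe_design,
)

SCENARIO_NAMES = ("null", "basic", "biased", "differential", "island_enriched")


@dataclass
class SimulationParams:
    """Knobs of the synthetic study. Defaults are the conditions under which
    the pipeline's operating characteristics (FDR, recall, enrichment p)
    are quoted; see the package methods note for rationale."""

    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    probe_spacing: int = 35
    probe_length: int = 25

    # sequence composition
    gc_mean: float = 0.40
    gc_amplitude: float = 0.06        # slow sinusoidal GC variation (+/-)
    gc_period_bp: int = 60_000
    background_cpg_per_kbp: float = 2.0
    island_cpg_per_kbp: float = 25.0
    island_gc: float = 0.55

    # annotation structure
    islands_per_chrom: int = 130
    island_length_range: tuple = (500, 1500)
    genes_per_chrom: int = 18
    exons_per_gene: tuple = (3, 8)
    exon_length_range: tuple = (120, 300)
    conserved_fraction: float = 0.05
    tfbs_per_chrom: int = 40

    # methylation truth
    n_methylated_regions: int = 200   # planted per sample, genome-wide
    n_differential: int = 30

    # array physics
    fragment_modal_bp: int = 250
    enr_floor: float = 0.0
    enr_ceiling: float = 2.0
    enr_halfsat_cpg: float = 4.0
    enr_hill: float = 2.0
    gc_bias_coef: float = 0.04        # log2 per GC count above the mean (M channel)
    baseline_intensity: float = 10.0
    probe_affinity_sd: float = 0.5
    noise_sd: float = 0.3             # per replicate per channel, log2 scale

    seed: int = 0


@dataclass
class MethylationTruth:
    """Ground truth: per-sample methylated intervals and methylated CpG sites."""

    intervals: dict = field(default_factory=dict)        # sample -> [(chrom, s, e)]
    methylated_cpgs: dict = field(default_factory=dict)  # sample -> {chrom: sorted positions}
    differential: list = field(default_factory=list)     # intervals methylated in A only

    def to_json(self) -> str:
        return json.dumps(
            {
                "intervals": {s: [list(t) for t in v] for s, v in self.intervals.items()},
                "differential": [list(t) for t in self.differential],
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Enrichment response
# ---------------------------------------------------------------------------

def enrichment_response(n_meth_cpg, params: SimulationParams):
    """Expected log2 enrichment as a saturating (Hill) function of the
    number of methylated CpGs in the captured fragment.

    Zero methylated CpGs give the floor (not detectable); the response
    rises through a half-saturation CpG count and plateaus at the ceiling.
    """
    n = np.asarray(n_meth_cpg, dtype=float)
    if np.any(n < 0):
        raise ValueError("CpG count must be non-negative")
    h = params.enr_hill
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n > 0, n**h / (n**h + params.enr_halfsat_cpg**h), 0.0)
    out = params.enr_floor + (params.enr_ceiling - params.enr_floor) * frac
    return float(out) if np.isscalar(n_meth_cpg) else out


def sample_fragment_lengths(params: SimulationParams, n: int, rng) -> np.ndarray:
    """Random-fragmentation lengths: gamma with mode at the modal length.

    Models pooled frequent-cutter digestion as i.i.d. fragment sizes; with
    shape k the mode is (k-1)*scale, so scale = modal/(k-1) for k = 4.
    """
    shape = 4.0
    scale = params.fragment_modal_bp / (shape - 1.0)
    return rng.gamma(shape, scale, size=n)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

_BASES_GC = np.frombuffer(b"GC", dtype=np.uint8)
_BASES_AT = np.frombuffer(b"AT", dtype=np.uint8)


def _draw_sequence(n: int, p_gc: np.ndarray, rng) -> np.ndarray:
    """Per-base draw: G/C with probability p_gc[i], A/T otherwise."""
    is_gc = rng.random(n) < p_gc
    pick = rng.integers(0, 2, n)
    seq = np.where(is_gc, _BASES_GC[pick], _BASES_AT[pick])
    return seq.astype(np.uint8)


def _thin_cpgs(seq: np.ndarray, keep_prob: np.ndarray, rng) -> None:
    """Break CG dinucleotides in place (C -> T) so the survival probability
    of each CG is keep_prob at its position. Breaking a CG cannot create
    a new one, so a single pass suffices."""
    cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
    kill = rng.random(len(cg)) >= keep_prob[cg]
    seq[cg[kill]] = ord("T")


def _place_intervals(n: int, length_range: tuple, chrom_len: int, rng,
                     occupied: list, margin: int = 2000,
                     max_tries: int = 20000) -> list[tuple[int, int]]:
    """Place n non-overlapping intervals, avoiding *occupied* and edges."""
    placed = []
    taken = sorted(occupied)
    for _ in range(n):
        for attempt in range(max_tries):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            if chrom_len - margin - L <= margin:
                raise ValueError("chromosome too short for requested features")
            s = int(rng.integers(margin, chrom_len - margin - L))
            e = s + L
            i = bisect_left(taken, (s, e))
            if i > 0 and taken[i - 1][1] + 50 > s:
                continue
            if i < len(taken) and taken[i][0] < e + 50:
                continue
            taken.insert(i, (s, e))
            placed.append((s, e))
            break
        else:
            raise ValueError(f"could not pack {n} features of {length_range} bp "
                             f"into {chrom_len} bp")
    return placed


def simulate_genome(params: SimulationParams, rng=None):
    """Two-chromosome genome with CpG islands, gene models, conservation
    and TFBS tracks.

    Background sequence has slowly varying GC content and CpG density
    thinned below the null-probe threshold; islands are CpG-dense
    (> 20/kbp regime) intervals, about half of them placed at gene
    promoters. Returns (genome, islands, genes, conservation, tfbs).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    genome: dict[str, str] = {}
    islands: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []
    conservation_rows = []
    tfbs: list[tuple[str, int, int]] = []
    for ci, (chrom, n) in enumerate(params.chrom_lengths.items()):
        phase = rng.uniform(0, 2 * np.pi)
        x = np.arange(n)
        p_gc = params.gc_mean + params.gc_amplitude * np.sin(
            2 * np.pi * x / params.gc_period_bp + phase)
        seq = _draw_sequence(n, p_gc, rng)

        # gene models first (coordinate structure only)
        gene_spans = []
        chrom_genes = []
        for gi in range(params.genes_per_chrom):
            n_ex = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
            exon_lens = rng.integers(params.exon_length_range[0],
                                     params.exon_length_range[1] + 1, n_ex)
            exon_lens[-1] = int(rng.integers(500, 900))  # a long terminal exon
            intron_lens = []
            for _ in range(n_ex - 1):
                if rng.random() < 0.5:
                    intron_lens.append(int(rng.integers(900, 2600)))
                else:
                    intron_lens.append(int(rng.integers(2800, 11000)))
            span = int(exon_lens.sum() + sum(intron_lens))
            for attempt in range(20000):
                s = int(rng.integers(3000, n - 3000 - span))
                if all(e0 + 4000 <= s or s + span + 4000 <= s0 for s0, e0 in gene_spans):
                    break
            else:
                raise ValueError("could not pack gene models; reduce genes_per_chrom")
            gene_spans.append((s, s + span))
            exons = []
            pos = s
            for k, L in enumerate(exon_lens):
                exons.append((pos, pos + int(L)))
                pos += int(L)
                if k < n_ex - 1:
                    pos += intron_lens[k]
            strand = "+" if rng.random() < 0.5 else "-"
            chrom_genes.append(GeneModel(f"{chrom}_gene{gi}", chrom, s, s + span, strand, exons))
        genes.extend(chrom_genes)

        # islands: ~half at promoters, the rest anywhere free
        occupied: list[tuple[int, int]] = []
        n_promoter = min(params.islands_per_chrom // 2, len(chrom_genes))
        promo_genes = list(rng.choice(len(chrom_genes), size=n_promoter, replace=False))
        chrom_islands = []
        for gidx in promo_genes:
            g = chrom_genes[gidx]
            L = int(rng.integers(*params.island_length_range))
            s = g.tss - L // 2 if g.strand == "+" else g.tss - L // 2
            s = max(100, min(s, n - L - 100))
            if all(e0 <= s or s + L <= s0 for s0, e0 in occupied):
                occupied.append((s, s + L))
                chrom_islands.append((s, s + L))
        extra = _place_intervals(params.islands_per_chrom - len(chrom_islands),
                                 params.island_length_range, n, rng, occupied)
        chrom_islands.extend(extra)
        chrom_islands.sort()

        # carve island sequence: higher GC, CpG-dense
        for s, e in chrom_islands:
            seq[s:e] = _draw_sequence(e - s, np.full(e - s, params.island_gc), rng)

        # thin CpGs: background to low density, islands to the island density
        raw_rate = (np.clip(p_gc, 0.2, 0.8) / 2.0) ** 2  # expected CG per bp before thinning
        keep = np.clip((params.background_cpg_per_kbp / 1000.0) / raw_rate, 0.0, 1.0)
        island_raw = (params.island_gc / 2.0) ** 2
        island_keep = min(1.0, (params.island_cpg_per_kbp / 1000.0) / island_raw)
        for s, e in chrom_islands:
            keep[s:e] = island_keep
        _thin_cpgs(seq, keep, rng)

        genome[chrom] = seq.tobytes().decode("ascii")
        islands.extend((chrom, s, e) for s, e in chrom_islands)

        # conservation: elevated blocks over a fraction of intergenic space
        n_cons = max(1, int(params.conserved_fraction * n / 800))
        cons = _place_intervals(n_cons, (400, 1200), n, rng,
                                occupied=gene_spans + chrom_islands)
        for s, e in sorted(cons):
            conservation_rows.append((chrom, s, e, round(float(rng.uniform(0.85, 1.0)), 3)))
            if rng.random() < 0.5 and len(tfbs) < (ci + 1) * params.tfbs_per_chrom:
                ts = int(rng.integers(s, e - 15))
                tfbs.append((chrom, ts, ts + 12))
    conservation = pd.DataFrame(conservation_rows, columns=["chrom", "start", "end", "score"])
    return genome, islands, genes, conservation, tfbs


def make_design(genome: dict[str, str], spacing: int = 35, length: int = 25) -> ProbeDesign:
    """Tile every chromosome end to end at fixed spacing; GC counts are
    computed from the underlying sequence."""
    ids, chroms, starts, gcs = [], [], [], []
    for chrom in sorted(genome):
        seq = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        pos = np.arange(0, len(seq) - length + 1, spacing)
        is_gc = (seq == ord("G")) | (seq == ord("C"))
        cum = np.concatenate([[0], np.cumsum(is_gc)])
        gc = cum[pos + length] - cum[pos]
        ids.extend(f"{chrom}:{p:08d}" for p in pos)
        chroms.extend([chrom] * len(pos))
        starts.append(pos)
        gcs.append(gc)
    return ProbeDesign(
        probe_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        start=np.concatenate(starts).astype(np.int64),
        length=np.full(sum(map(len, starts)), length, dtype=np.int64),
        gc_count=np.concatenate(gcs).astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Methylation truth and array intensities
# ---------------------------------------------------------------------------

def _cpg_positions(genome: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out[chrom] = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
    return out


def build_truth(genome, islands, samples_intervals: dict) -> MethylationTruth:
    """Resolve per-sample methylated intervals to methylated CpG positions."""
    cpgs = _cpg_positions(genome)
    truth = MethylationTruth(intervals={s: sorted(v) for s, v in samples_intervals.items()})
    for sample, ivals in truth.intervals.items():
        per_chrom: dict[str, list] = {c: [] for c in genome}
        for chrom, s, e in ivals:
            sites = cpgs[chrom]
            lo, hi = np.searchsorted(sites, [s, e])
            per_chrom[chrom].append(sites[lo:hi])
        truth.methylated_cpgs[sample] = {
            c: (np.unique(np.concatenate(v)) if v else np.empty(0, dtype=np.int64))
            for c, v in per_chrom.items()
        }
    return truth


def simulate_arrays(design: ProbeDesign, truth: MethylationTruth,
                    params: SimulationParams, seed: int,
                    samples=None) -> IntensityTable:
    """Duplicate M and T log2 intensities per sample.

    T = shared probe affinity + noise. M adds a GC-dependent probe effect
    (autocorrelated along the chromosome because genomic GC varies
    smoothly) and the saturating enrichment response to the number of
    methylated CpGs in a modal-length fragment window centered on the
    probe. Fully determined by (design, truth, params, seed).
    """
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = sorted(truth.intervals) or ["A"]
    n = len(design)
    affinity = params.baseline_intensity + rng.normal(0, params.probe_affinity_sd, n)
    gc_bias = params.gc_bias_coef * (design.gc_count - float(np.mean(design.gc_count)))
    mids = design.midpoint
    table = IntensityTable(design)
    half = params.fragment_modal_bp // 2
    for sample in samples:
        meth = truth.methylated_cpgs.get(sample, {})
        n_cpg = np.zeros(n)
        for chrom, sl in design.chrom_slices().items():
            sites = meth.get(chrom, np.empty(0, dtype=np.int64))
            lo = np.searchsorted(sites, mids[sl] - half)
            hi = np.searchsorted(sites, mids[sl] + half)
            n_cpg[sl] = hi - lo
        enr = enrichment_response(n_cpg, params)
        for rep in (1, 2):
            table.data[(sample, "T", rep)] = affinity + rng.normal(0, params.noise_sd, n)
            table.data[(sample, "M", rep)] = (
                affinity + gc_bias + enr + rng.normal(0, params.noise_sd, n)
            )
    return table


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Everything one scenario produces, in memory."""

    name: str
    params: SimulationParams
    genome: dict
    islands: list
    genes: list
    conservation: pd.DataFrame
    tfbs: list
    design: ProbeDesign
    truth: MethylationTruth
    intensity: IntensityTable


def _scenario_params(name: str, seed: int, **overrides) -> SimulationParams:
    base = dict(seed=seed)
    if name == "null":
        base.update(n_methylated_regions=0)
    elif name == "biased":
        # strong GC probe effect riding on short-scale, locally correlated
        # GC composition: the raw log-ratio is visibly autocorrelated
        base.update(gc_bias_coef=0.16, gc_amplitude=0.15, gc_period_bp=5000)
    elif name == "island_enriched":
        base.update(n_methylated_regions=160)
    base.update(overrides)
    return SimulationParams(**base)


def make_scenario(name: str, seed: int, out_dir=None, **param_overrides) -> ScenarioBundle:
    """Build a named, fully seeded fixture bundle.

    null             no methylation anywhere
    basic            planted methylated regions on CpG islands, one sample
    biased           basic plus strong GC bias / autocorrelation
    differential     two samples; an A-only methylated subset across compartments
    island_enriched  methylation concentrated (~90%) in CpG islands
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid: {SCENARIO_NAMES}")
    params = _scenario_params(name, seed, **param_overrides)
    rng = np.random.default_rng(seed)
    genome, islands, genes, conservation, tfbs = simulate_genome(params, rng)
    design = make_design(genome, params.probe_spacing, params.probe_length)

    island_arr = sorted(islands)
    n_avail = len(island_arr)
    samples_intervals: dict[str, list] = {}
    differential: list = []
    if name == "null":
        samples_intervals["A"] = []
    elif name in ("basic", "biased"):
        k = min(params.n_methylated_regions, n_avail)
        pick = rng.choice(n_avail, size=k, replace=False)
        samples_intervals["A"] = [island_arr[i] for i in sorted(pick)]
    elif name == "island_enriched":
        k = min(params.n_methylated_regions, n_avail)
        pick = rng.choice(n_avail, size=k, replace=False)
        ivals = [island_arr[i] for i in sorted(pick)]
        # a small CpG-poor minority, to keep the island concentration ~90%
        n_off = max(1, k // 9)
        for chrom in list(params.chrom_lengths)[:1]:
            off = _place_intervals(n_off, (500, 1000), params.chrom_lengths[chrom],
                                   rng, occupied=[(s, e) for c, s, e in island_arr if c == chrom])
            ivals.extend((chrom, s, e) for s, e in off)
        samples_intervals["A"] = ivals
    elif name == "differential":
        k = min(params.n_methylated_regions, n_avail)
        pick = sorted(rng.choice(n_avail, size=k, replace=False))
        chosen = [island_arr[i] for i in pick]
        n_diff = min(params.n_differential, len(chosen))
        diff_idx = set(rng.choice(len(chosen), size=n_diff, replace=False).tolist())
        a_only = [chosen[i] for i in sorted(diff_idx)]
        shared = [chosen[i] for i in range(len(chosen)) if i not in diff_idx]
        samples_intervals["A"] = shared + a_only
        samples_intervals["B"] = shared
        differential = sorted(a_only)

    truth = build_truth(genome, islands, samples_intervals)
    truth.differential = differential
    intensity = simulate_arrays(design, truth, params, seed=seed + 1,
                                samples=sorted(samples_intervals))
    bundle = ScenarioBundle(name, params, genome, islands, genes, conservation,
                            tfbs, design, truth, intensity)
    if out_dir is not None:
        write_scenario(bundle, out_dir)
    return bundle


def write_scenario(bundle: ScenarioBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome_fasta(bundle.genome, out / "genome.fa")
    write_bed([(c, s, e, f"island{i}") for i, (c, s, e) in enumerate(bundle.islands)],
              out / "cpg_islands.bed")
    write_genes_bed12(bundle.genes, out / "genes.bed12")
    write_bedgraph(bundle.conservation, out / "conservation.bedgraph")
    write_bed([(c, s, e, f"tfbs{i}") for i, (c, s, e) in enumerate(bundle.tfbs)],
              out / "tfbs.bed")
    write_probe_design(bundle.design, out / "design.tsv")
    write_intensity_table(bundle.intensity, out / "intensity.tsv")
    (out / "truth.json").write_text(bundle.truth.to_json())
    p = asdict(bundle.params)
    p["chrom_lengths"] = dict(p["chrom_lengths"])
    (out / "params.json").write_text(json.dumps(p, indent=1, default=list))


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def recall_precision(called: RegionSet, truth_intervals) -> tuple[float, float]:
    """Interval-level recall (truth overlapped by >= 1 call) and precision
    (calls overlapping >= 1 truth interval)."""
    from .annotation import interval_overlap_bp, merge_intervals

    truth_merged = merge_intervals(truth_intervals)
    call_merged = merge_intervals(called.intervals())
    if truth_intervals:
        recall = sum(
            1 for c, s, e in truth_intervals
            if interval_overlap_bp(c, s, e, call_merged) > 0
        ) / len(list(truth_intervals))
    else:
        recall = float("nan")
    if len(called):
        precision = sum(
            1 for r in called
            if interval_overlap_bp(r.chrom, r.start, r.end, truth_merged) > 0
        ) / len(called)
    else:
        precision = float("nan")
    return recall, precision
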