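"""Readers and writers for tiling-array probe designs, intensity tables,
region sets and genomic annotation tracks.

All genomic coordinates are 0-based half-open, on disk and in memory.
The probe design is the coordinate skeleton of the array: every per-probe
signal track is a flat array aligned to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file or table."""


# ---------------------------------------------------------------------------
# Probe design
# ---------------------------------------------------------------------------

@dataclass
class ProbeDesign:
    """Ordered tiling probes: the array's coordinate skeleton.

    Probes are sorted by (chrom, start) with strictly increasing starts
    within a chromosome; ``gc_count`` is the G+C count of the probe
    sequence (0..length).
    """

    probe_id: np.ndarray      # object (str)
    chrom: np.ndarray         # object (str)
    start: np.ndarray         # int64, 0-based
    length: np.ndarray        # int64, bp
    gc_count: np.ndarray      # int64

    def __post_init__(self) -> None:
        n = len(self.probe_id)
        if not (len(self.chrom) == len(self.start) == len(self.length) == len(self.gc_count) == n):
            raise ValueError("ProbeDesign field lengths differ")
        ids = pd.Index(self.probe_id)
        if ids.has_duplicates:
            dups = ids[ids.duplicated()].unique()[:5].tolist()
            raise FormatError(f"duplicate probe_id(s): {dups}")
        if np.any(self.gc_count > self.length) or np.any(self.gc_count < 0):
            raise FormatError("gc_count must lie in [0, probe length]")
        order = np.lexsort((self.start, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            warnings.warn("probe design not sorted by (chrom, start); sorting", stacklevel=3)
            for f in ("probe_id", "chrom", "start", "length", "gc_count"):
                setattr(self, f, getattr(self, f)[order])
        for _, sl in self.chrom_slices().items():
            if np.any(np.diff(self.start[sl]) <= 0):
                raise FormatError("probe starts must be strictly increasing within a chromosome")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length

    @property
    def midpoint(self) -> np.ndarray:
        return self.start + self.length // 2

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous slice of the design for each chromosome, in order."""
        out: dict[str, slice] = {}
        chroms, idx = np.unique(self.chrom, return_index=True)
        bounds = np.sort(idx).tolist() + [len(self)]
        for i, b in enumerate(bounds[:-1]):
            out[str(self.chrom[b])] = slice(b, bounds[i + 1])
        return out

    def id_index(self) -> pd.Index:
        return pd.Index(self.probe_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeDesign":
        return cls(
            probe_id=df["probe_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            length=(df["end"] - df["start"]).to_numpy(dtype=np.int64),
            gc_count=df["gc_count"].to_numpy(dtype=np.int64),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "probe_id": self.probe_id,
                "gc_count": self.gc_count,
            }
        )


DESIGN_COLUMNS = ["chrom", "start", "end", "probe_id", "gc_count"]


def read_probe_design(path) -> ProbeDesign:
    """Read a BED-like TSV probe design (chrom, start, end, probe_id, gc_count)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"chrom": str, "probe_id": str})
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse probe design: {exc}") from exc
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("start", "end", "gc_count"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: non-integer {col!r} at line {line}")
        df[col] = df[col].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        line = int((df["end"] <= df["start"]).idxmax()) + 2
        raise FormatError(f"{path}: end <= start at line {line}")
    return ProbeDesign.from_frame(df)


def write_probe_design(design: ProbeDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intensity table
# ---------------------------------------------------------------------------

CHANNEL_M = "M"
CHANNEL_T = "T"


@dataclass
class IntensityTable:
    """Per-probe log2 intensities keyed to a design.

    ``data[(sample, channel, replicate)]`` is a float array aligned to the
    design. Channels M (methyl-enriched) and T (total input) must both be
    present for every sample the table claims to carry.
    """

    design: ProbeDesign
    data: dict[tuple[str, str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, arr in self.data.items():
            if len(arr) != len(self.design):
                raise FormatError(f"intensity array for {key} not aligned to design")

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _, _ in self.data})

    def channels(self, sample: str) -> list[str]:
        return sorted({c for s, c, _ in self.data if s == sample})

    def replicates(self, sample: str, channel: str) -> list[int]:
        return sorted(r for s, c, r in self.data if s == sample and c == channel)

    def validate(self, require_channels: tuple[str, ...] = (CHANNEL_M, CHANNEL_T)) -> None:
        for sample in self.samples:
            for ch in require_channels:
                if ch not in self.channels(sample):
                    raise FormatError(f"sample {sample!r}: channel {ch!r} missing")

    def values(self, sample: str, channel: str, replicate: int) -> np.ndarray:
        try:
            return self.data[(sample, channel, replicate)]
        except KeyError:
            raise FormatError(
                f"no intensities for sample={sample!r} channel={channel!r} replicate={replicate}"
            ) from None

    def channel_mean(self, sample: str, channel: str, replicates=None) -> np.ndarray:
        """Mean log2 intensity per probe over the given replicates."""
        reps = list(replicates) if replicates is not None else self.replicates(sample, channel)
        if not reps:
            raise FormatError(f"sample {sample!r}: channel {channel!r} has no replicates")
        stack = np.stack([self.values(sample, channel, r) for r in reps])
        if np.isnan(stack).any():
            raise FormatError(f"sample {sample!r} channel {channel!r}: missing probe intensities")
        return stack.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for (sample, channel, rep), arr in sorted(self.data.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": self.design.probe_id,
                        "sample": sample,
                        "channel": channel,
                        "replicate": rep,
                        "log2_intensity": arr,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def read_intensity_table(path, design: ProbeDesign) -> IntensityTable:
    """Read a long-format intensity TSV keyed to *design*.

    Columns: probe_id, sample, channel, replicate, log2_intensity.
    Probes absent from the design are rejected with the offending ids listed.
    """
    df = pd.read_csv(
        path, sep="\t", header=0,
        dtype={"probe_id": str, "sample": str, "channel": str},
    )
    required = ["probe_id", "sample", "channel", "replicate", "log2_intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    idx = design.id_index()
    pos = idx.get_indexer(df["probe_id"])
    if (pos < 0).any():
        offenders = df.loc[pos < 0, "probe_id"].unique()[:10].tolist()
        raise FormatError(f"{path}: probe_id(s) not in design: {offenders}")
    table = IntensityTable(design)
    for (sample, channel, rep), grp in df.groupby(["sample", "channel", "replicate"], sort=True):
        arr = np.full(len(design), np.nan)
        arr[pos[grp.index]] = grp["log2_intensity"].to_numpy(dtype=float)
        if np.isnan(arr).any():
            n_missing = int(np.isnan(arr).sum())
            raise FormatError(
                f"{path}: sample={sample!r} channel={channel!r} replicate={rep}: "
                f"{n_missing} probes missing"
            )
        table.data[(str(sample), str(channel), int(rep))] = arr
    table.validate()
    return table


def write_intensity_table(table: IntensityTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """A called genomic segment with its additive Z statistic."""

    chrom: str
    start: int
    end: int
    additive_z: float
    n_probes: int = 0
    max_probe_z: float = float("nan")
    rank: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Ranked, non-overlapping called regions plus calling provenance."""

    regions: list[Region] = field(default_factory=list)
    sample: str | None = None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def sorted_by_position(self) -> list[Region]:
        return sorted(self.regions, key=lambda r: (r.chrom, r.start))

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(r.chrom, r.start, r.end) for r in self.regions]


def write_regions_bed(regions: RegionSet, path) -> None:
    """Write BED6: name = rank, score = additive Z clamped to [0, 1000]."""
    with open(path, "w") as fh:
        for r in sorted(regions.regions, key=lambda r: r.rank):
            score = min(max(r.additive_z, 0.0), 1000.0)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.rank}\t{score:g}\t.\n")


def read_regions_bed(path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            rank = int(parts[3]) if len(parts) > 3 else lineno
            score = float(parts[4]) if len(parts) > 4 else float("nan")
            regions.append(Region(chrom, start, end, additive_z=score, rank=rank))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return RegionSet(regions=regions)


# ---------------------------------------------------------------------------
# Simple interval tracks (BED / bedGraph)
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a plain BED3+ file into a (chrom, start, end[, name]) frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         parts[3] if len(parts) > 3 else f"feature{lineno}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end[, name]) rows as BED."""
    with open(path, "w") as fh:
        for row in intervals if not isinstance(intervals, pd.DataFrame) else intervals.itertuples(index=False):
            row = tuple(row)
            fh.write("\t".join(str(x) for x in row[:4]) + "\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "score": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Gene models (BED12)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A transcript with strand-aware TSS/TTS and exon blocks."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.name}: strand must be + or -")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise FormatError(f"gene {self.name}: overlapping exons")

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


def read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name, strand = parts[3], parts[5]
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets) or len(sizes) != int(parts[9]):
                raise FormatError(f"{path}:{lineno}: inconsistent block fields")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return genes


def write_genes_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")
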