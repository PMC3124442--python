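"""End-to-end orchestration: intensities -> log-ratio -> GC adjustment ->
smoothing -> Z -> regions -> FDR, with one flat parameter record."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .io_formats import IntensityTable, ProbeDesign, RegionSet
from .preprocess import (
    NullProbeSet,
    SignalTrack,
    compute_log_ratio,
    select_null_probes,
)
from .region_calling import call_from_log_ratio, estimate_fdr
from . import preprocess


@dataclass
class PipelineParams:
    """Flat record of every analysis threshold (the scientific surface of
    the method); echoed into outputs for provenance."""

    null_window_bp: int = 1000
    null_density_threshold: float = 4.0
    min_null_probes: int = 500
    min_bin_size: int = 200
    smoothing_k: int = 7
    z_probe: float = 3.0
    z_region: float = 4.0
    merge_gap: int = 250
    diff_z_high: float = 4.0
    diff_z_low: float = 1.0
    diff_min_len: int = 500
    sum_seeds_only: bool = False

    def validate(self) -> None:
        if self.smoothing_k % 2 == 0 or self.smoothing_k < 1:
            raise ValueError(f"smoothing_k must be odd and >= 1, got {self.smoothing_k}")
        for name in ("null_window_bp", "min_bin_size", "merge_gap", "diff_min_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        p = cls(**known)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SampleResult:
    """All per-sample pipeline stages plus the called regions."""

    sample: str
    nulls: NullProbeSet
    log_ratio: SignalTrack
    adjusted: SignalTrack
    smoothed: SignalTrack
    z: SignalTrack
    regions: RegionSet
    strata_raw: object = None
    strata_z: object = None
    fdr: float | None = None


def run_sample(design: ProbeDesign, intensity: IntensityTable, sample: str,
               genome: dict[str, str] | None = None,
               nulls: NullProbeSet | None = None,
               params: PipelineParams | None = None,
               with_fdr: bool = False) -> SampleResult:
    """Full single-sample analysis. Either a genome (to select null probes)
    or a precomputed null set must be given."""
    params = params or PipelineParams()
    params.validate()
    if nulls is None:
        if genome is None:
            raise ValueError("need a genome or a precomputed null probe set")
        nulls = select_null_probes(
            design, genome,
            threshold=params.null_density_threshold,
            window=params.null_window_bp,
            min_probes=params.min_null_probes,
        )
    track = compute_log_ratio(intensity, sample)
    strata_raw, adjusted, smoothed, strata_z, z, regions = call_from_log_ratio(
        track, design, nulls,
        min_bin_size=params.min_bin_size, k=params.smoothing_k,
        z_probe=params.z_probe, z_region=params.z_region,
        merge_gap=params.merge_gap, sum_seeds_only=params.sum_seeds_only,
    )
    regions.sample = sample
    result = SampleResult(
        sample=sample, nulls=nulls, log_ratio=track, adjusted=adjusted,
        smoothed=smoothed, z=z, regions=regions,
        strata_raw=strata_raw, strata_z=strata_z,
    )
    if with_fdr and len(regions) > 0:
        result.fdr = estimate_fdr(
            intensity, sample, design, nulls, n_called=len(regions),
            min_bin_size=params.min_bin_size, k=params.smoothing_k,
            z_probe=params.z_probe, z_region=params.z_region,
            merge_gap=params.merge_gap, sum_seeds_only=params.sum_seeds_only,
        )
    return result
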