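"""Pipeline configuration: one plain-YAML-serialisable bundle of knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .rd_caller import CallerParams


@dataclass
class PipelineConfig:
    """Every threshold the pipeline applies, in one serialisable object.

    Defaults carry the analysis conventions this package implements:
    events must exceed 0.5 kb, a CNVR needs support from >= 4 samples of
    its group, and enrichment significance is BH-adjusted p <= 0.05.
    """

    seed: int = 0
    bin_size: int = 500
    del_thresh: float = 0.75
    dup_thresh: float = 1.25
    max_gap_bins: int = 1
    min_len_bp: int = 500
    max_segment_p: float = 2.5e-3
    min_samples: int = 4
    alpha: float = 0.05
    merge_across_groups: bool = False
    keep_intronic: bool = False
    # synthetic-cohort layout (used by the `run` demo pipeline)
    n_per_group: int = 10
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 30
    n_shared: int = 4
    n_group_a_only: int = 3
    n_intronic: int = 2
    n_intergenic: int = 1
    mean_coverage: float = 7.5
    gc_bias_strength: float = 4.0
    dispersion: float = 0.02
    # qPCR validation layout: 6 + 6 samples over 8 target regions
    qpcr_samples_per_group: int = 6
    qpcr_targets: int = 8
    qpcr_ct_noise_sd: float = 0.1

    def caller_params(self) -> CallerParams:
        return CallerParams(
            del_thresh=self.del_thresh,
            dup_thresh=self.dup_thresh,
            max_gap_bins=self.max_gap_bins,
            min_len_bp=self.min_len_bp,
            max_segment_p=self.max_segment_p,
        )

    def validate(self) -> None:
        problems = []
        if not (0 < self.del_thresh < 1 < self.dup_thresh):
            problems.append("del_thresh/dup_thresh must bracket 1")
        if self.bin_size < 1:
            problems.append("bin_size must be >= 1")
        if self.min_len_bp < 0:
            problems.append("min_len_bp must be >= 0")
        if self.min_samples < 1:
            problems.append("min_samples must be >= 1")
        if not 0 <= self.alpha <= 1:
            problems.append("alpha must be in [0, 1]")
        if self.mean_coverage <= 0:
            problems.append("mean_coverage must be positive")
        if self.dispersion < 0:
            problems.append("dispersion must be >= 0")
        if self.n_per_group < 4:
            problems.append("n_per_group must be >= 4")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
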