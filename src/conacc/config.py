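"""Pipeline configuration: every numeric threshold of the method, with the
study defaults, loadable from a single YAML file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .synthetic import DEFAULT_TARGET_BRANCHES


@dataclass
class PipelineConfig:
    # paths (set per run)
    maf: str | None = None
    gff3: str | None = None
    tree: str | None = None
    cds_dir: str | None = None
    outdir: str = "conacc_out"
    # curation
    n_run_fraction_threshold: float = 0.5
    min_species: int = 7
    total_species: int = 8
    reference: str = "A_carolinensis"
    # codon usage
    rscu_low: float = 0.6
    rscu_high: float = 1.6
    bias_rule: str = "any"          # drop family on bias in any|all species
    use_gamma: bool = False
    # windows
    window_min: int = 10
    window_max: int = 99
    split_every: int = 60
    min_tail: int = 20
    # testing and calling
    alpha: float = 0.05
    target_branches: list[str] = field(
        default_factory=lambda: list(DEFAULT_TARGET_BRANCHES)
    )
    # gene association / enrichment
    flank_distance: int = 5000
    ce_overlap_required: bool = True
    ncrna_min_frac: float = 0.8
    background_mode: str = "exclusive"
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.ncrna_min_frac <= 1):
            raise ValueError("ncrna_min_frac must be in (0, 1]")
        if self.rscu_low >= self.rscu_high:
            raise ValueError("rscu_low must be below rscu_high")
        if not (1 <= self.window_min <= self.window_max):
            raise ValueError("bad window length bounds")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
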