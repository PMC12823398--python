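"""Pipeline configuration.

All tunables of the pipeline live here with their default values, so that a run
is fully described by one YAML file plus a seed.  Defaults follow the settings
used throughout the package's statistical models: a strict UMI filter of 5,000
counts per spot, a low-signal barcode threshold of 0.05 log1p-counts per 1e4,
normal-tissue annotation at 250-700 um from the nearest tumour spot, 10,000
variational steps at learning rate 0.01 with 3 Monte-Carlo samples for the
genotype model, 2,000 steps for the genotype-to-phenotype GLMs, 5,000 posterior
genotype draws, and 3,000 retained MCMC draws for the hierarchical count model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class SimulationConfig:
    """Generative settings for the synthetic tissue generator.

    ``presence_prob`` is the marginal probability that a plasmid integrated in
    a nodule; given presence, copy number follows a truncated geometric law on
    ``{1..max_copies}`` with decay ``copy_decay``.  ``kappa_scale`` and
    ``xi_scale`` scale the exponential laws of the per-barcode expression rate
    and the additive background; the defaults describe a strong-signal tissue
    (bright barcodes over a faint background).  ``n_filler_genes`` adds
    unstructured endogenous genes so that synthetic spots have realistic total
    UMI counts.
    """

    n_spots: int = 2000
    n_nodules: int = 50
    presence_prob: float = 0.6
    copy_decay: float = 0.5
    kappa_scale: float = 5.0
    xi_scale: float = 0.05
    mu_shape: float = 3.0
    mu_rate: float = 0.3
    phi_shape: float = 1000.0
    phi_rate: float = 0.03
    tumour_fraction: float = 0.5
    spot_spacing_um: float = 100.0
    n_filler_genes: int = 50
    filler_gene_rate: float = 25.0


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline, with reproducible defaults."""

    # -- spot/barcode preprocessing
    umi_threshold: int = 5000
    low_signal_threshold: float = 0.05
    normal_min_distance: float = 500.0  # um; valid range 250-700
    # -- genotype model
    max_copies: int = 6
    normal_presence: float = 1e-3
    vi_steps: int = 10_000
    vi_learning_rate: float = 0.01
    vi_kl_samples: int = 3
    # -- genotype statistics
    n_genotype_draws: int = 5000
    or_draws: int = 2000
    null_sims: int = 5000
    # -- genotype-to-phenotype GLMs
    glm_steps: int = 2000
    glm_learning_rate: float = 0.01
    glm_kl_samples: int = 3
    intercept_scale: float = 1.0
    binary_weight_scale: float = 0.1
    expression_weight_scale: float = 1e-3
    batch_scale: float = 1.0
    # -- phenotype pipeline
    target_sum: float = 1e4
    gene_min_count: int = 10
    gene_max_count: float = 1e6
    n_hvgs_per_slide: int = 15_000
    glasso_penalty: float = 0.3
    network_min_corr: float = 0.25
    binarize_threshold: float = 0.5
    presence_annotation_power: int = 10
    # -- leave-one-out count model
    mcmc_draws: int = 3000
    mcmc_warmup: int = 1000
    # -- simulation
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.normal_presence < 1:
            raise ConfigurationError(
                f"normal_presence must be in (0,1), got {self.normal_presence}"
            )
        if self.max_copies < 1:
            raise ConfigurationError("max_copies must be >= 1")

    # -- YAML round trip -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ConfigurationError(f"unknown configuration key: {key!r}")
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            for key in sim_raw:
                if key not in sim_known:
                    raise ConfigurationError(f"unknown configuration key: sim.{key!r}")
            cfg.sim = SimulationConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
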