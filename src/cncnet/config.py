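"""Configuration objects for the simulator and the analysis pipeline.

Two dataclasses hold every tunable constant: :class:`SyntheticConfig` for the
ground-truth data generator and :class:`PipelineConfig` for the analysis
thresholds.  Both validate eagerly so that a bad value fails at construction,
not three stages into a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: proximity window (bases) for cis lncRNA-mRNA pairing
DEFAULT_PAIR_WINDOW = 300_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic annotation + expression generator.

    The defaults emulate a small two-group microarray study: two groups of
    ``n_per_group`` samples each (default 5 vs 5), tens of thousands of mRNA
    probes and thousands of lncRNA probes on a synthetic genome, per-gene
    variances drawn from an inverse-gamma law (precision ``tau ~
    Gamma(rvm_a, scale=rvm_b)``), a fraction ``frac_de`` of genes with a
    planted log2 effect, cis lncRNA-mRNA pairs planted in all four relation
    categories, and coexpression modules whose hub lncRNA is strongly
    correlated with its members in the disease group only.
    """

    n_mrna: int = 20_000
    n_lnc: int = 4_000
    n_per_group: int = 5
    n_chromosomes: int = 24
    chrom_length: int = 400_000_000
    frac_de: float = 0.05
    effect_size_log2: float = 2.5
    rvm_a: float = 2.0
    rvm_b: float = 0.5
    n_planted_pairs_per_category: int = 10
    concordance_rate: float = 0.953
    n_modules: int = 2
    module_size: int = 10
    hub_corr_disease: float = 0.99
    hub_corr_control: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_mrna": self.n_mrna,
            "n_lnc": self.n_lnc,
            "n_per_group": self.n_per_group,
            "n_chromosomes": self.n_chromosomes,
            "n_planted_pairs_per_category": self.n_planted_pairs_per_category,
            "n_modules": self.n_modules,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name, value in [("frac_de", self.frac_de),
                            ("concordance_rate", self.concordance_rate)]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be >= 0")
        if self.rvm_a <= 0 or self.rvm_b <= 0:
            raise ValueError("rvm_a and rvm_b must be > 0")
        if self.n_modules > 0 and self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if self.chrom_length <= 2 * DEFAULT_PAIR_WINDOW:
            raise ValueError(
                "chrom_length must exceed twice the 300 kb pairing window "
                "so that all four relation categories are constructible"
            )
        npp = self.n_planted_pairs_per_category
        if self.n_lnc < 4 * npp + self.n_modules:
            raise ValueError("n_lnc too small for planted pairs plus module hubs")
        if self.n_mrna < 4 * npp + self.n_modules * (self.module_size - 1):
            raise ValueError("n_mrna too small for planted pairs plus module members")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches of the analysis pipeline.

    Defaults follow the published protocol for this kind of study: raw
    ``P < 0.05`` for differential expression (no fold-change cutoff), a
    300 kb cis window, ``|r| >= 0.97`` coexpression edges, ``P < 0.01`` and
    ``FDR < 0.01`` for GO terms and ``P < 0.05`` for pathways.
    """

    de_p_threshold: float = 0.05
    de_fc_threshold: Optional[float] = None
    pair_max_distance: int = DEFAULT_PAIR_WINDOW
    corr_threshold: float = 0.97
    corr_use_absolute: bool = True
    #: 'max_degree' divides by the network's max degree, 'n_minus_1' by n-1
    k_normalization: str = "max_degree"
    #: restrict network edges to lncRNA-mRNA pairs (no same-biotype edges)
    bipartite_only: bool = False
    #: anchor upstream/downstream on the mRNA strand ('mrna') or lncRNA ('lnc')
    pair_anchor: str = "mrna"
    go_p_threshold: float = 0.01
    go_fdr_threshold: float = 0.01
    pathway_p_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_p_threshold", "go_p_threshold", "go_fdr_threshold",
                     "pathway_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.de_fc_threshold is not None and self.de_fc_threshold < 1.0:
            raise ValueError("de_fc_threshold is a linear fold change >= 1")
        if self.pair_max_distance <= 0:
            raise ValueError("pair_max_distance must be > 0")
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.k_normalization not in ("max_degree", "n_minus_1"):
            raise ValueError("k_normalization must be 'max_degree' or 'n_minus_1'")
        if self.pair_anchor not in ("mrna", "lnc"):
            raise ValueError("pair_anchor must be 'mrna' or 'lnc'")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _from_mapping(cls, mapping: dict, source: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown keys in {source}: {sorted(unknown)}")
    return cls(**mapping)


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML file of field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(SyntheticConfig, data, str(path))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file of field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(PipelineConfig, data, str(path))
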