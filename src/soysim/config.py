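"""Scenario configuration: dataclasses + YAML round-trip + grid expansion."""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = [
    "GenomeParams",
    "TraitParams",
    "ScenarioConfig",
    "load_config",
    "save_config",
    "expand_grid",
    "paper_grid",
]

MODELS = ("TBV", "Random", "Pheno", "GBLUP", "BayesA", "BayesB", "FLM", "RF")
STRATEGIES = ("AF", "WF", "WPSF")
INTENSITIES = (2.5, 5.0, 7.5, 10.0)
DESIGNS = ((300, 50), (250, 60), (200, 75), (150, 100), (100, 150))


@dataclass(frozen=True)
class GenomeParams:
    n_chr: int = 20
    sites_per_chr: int = 1000
    mean_length_cm: float = 115.0
    total_bp: int = 950_000_000
    n_markers: int = 6000
    ne: float = 100.0  # coalescent effective size behind the founders


@dataclass(frozen=True)
class TraitParams:
    prop_qtl: float = 0.70
    var_a: float = 25.0
    var_gxe: float = 49.0
    var_e: float = 121.0
    base_mean: float = 3.00


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the experiment grid.

    ``intensity`` is in percent (2.5 means the top 2.5% of candidates
    become parents). Defaults reproduce the main study design: 300
    families x 50 individuals, 200 cycles, 60 replicates.
    """

    model: str = "GBLUP"
    strategy: str = "AF"
    intensity: float = 2.5
    n_families: int = 300
    family_size: int = 50
    n_cycles: int = 200
    n_replicates: int = 60
    seed: int = 1
    n_founders: int = 200
    selfing_rounds: int = 2  # F1 -> F2 -> ... -> F(2+rounds); 2 gives F2:4
    window: int = 3
    max_training_records: int = 45_000
    wpsf_family_fraction: float = 0.30
    genome: GenomeParams = field(default_factory=GenomeParams)
    trait: TraitParams = field(default_factory=TraitParams)
    em_tol: float = 1e-8
    em_max_iter: int = 300
    rf_trees: int = 500

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.intensity <= 100:
            raise ValueError("intensity must be a percentage in (0, 100]")

    @property
    def key(self) -> str:
        return (
            f"{self.model}-{self.strategy}-i{self.intensity:g}"
            f"-p{self.n_families}x{self.family_size}"
        )

    @property
    def design(self) -> str:
        return f"{self.n_families}x{self.family_size}"

    @property
    def intensity_fraction(self) -> float:
        return self.intensity / 100.0

    @property
    def population_size(self) -> int:
        return self.n_families * self.family_size


def _to_dict(cfg: ScenarioConfig) -> dict:
    return asdict(cfg)


def _from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "genome" in d and isinstance(d["genome"], dict):
        d["genome"] = GenomeParams(**d["genome"])
    if "trait" in d and isinstance(d["trait"], dict):
        d["trait"] = TraitParams(**d["trait"])
    return ScenarioConfig(**d)


def save_config(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> "ScenarioConfig | list[ScenarioConfig]":
    """Read a YAML config; a ``grid`` block expands into a scenario list.

    The grid block may hold ``models``, ``strategies``, ``intensities``
    and ``designs`` (pairs of [n_families, family_size]); remaining keys
    are shared across all cells.
    """
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    grid = d.pop("grid", None)
    base = _from_dict(d)
    if grid is None:
        return base
    return expand_grid(
        base,
        models=grid.get("models", [base.model]),
        strategies=grid.get("strategies", [base.strategy]),
        intensities=grid.get("intensities", [base.intensity]),
        designs=grid.get("designs", [[base.n_families, base.family_size]]),
    )


def expand_grid(
    base: ScenarioConfig,
    models=("GBLUP",),
    strategies=("AF",),
    intensities=(2.5,),
    designs=((300, 50),),
) -> list[ScenarioConfig]:
    out = []
    for m, s, i, (nf, fs) in itertools.product(models, strategies, intensities, designs):
        out.append(
            replace(base, model=m, strategy=s, intensity=float(i),
                    n_families=int(nf), family_size=int(fs))
        )
    return out


def paper_grid(base: ScenarioConfig | None = None) -> list[ScenarioConfig]:
    """The main 8-model x 3-strategy x 4-intensity grid (96 scenarios)."""
    base = base or ScenarioConfig()
    return expand_grid(base, models=MODELS, strategies=STRATEGIES,
                       intensities=INTENSITIES, designs=[(base.n_families, base.family_size)])
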