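"""Run configuration: every tunable default in one serialisable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .io import PipelineError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline defaults, round-trippable through YAML.

    ``provenance`` records, per key, whether the value is the package
    default or user-set. Unknown keys in a config file are rejected.
    """

    # distance grid (nm)
    r_min: float = 1.5
    r_max: float = 8.0
    r_step: float = 0.05
    # background
    bg_dimension: float = 3.0
    fit_start: float = 1.0 / 3.0
    allow_unphysical: bool = True
    # regularisation
    alpha: float | None = None  # None -> L-curve selection
    alpha_grid_lo: float = 1e-4
    alpha_grid_hi: float = 10.0
    alpha_grid_n: int = 24
    # validation ensemble
    n_steps: int = 16
    start_lo: float = 0.05
    start_hi: float = 0.80
    trials_per_step: int = 50
    noise_scale: float = 0.5
    rmsd_cut: float = 1.15
    # validation noise reference: 'noise_sd' (fraction of the estimated
    # trace noise) or 'amplitude' (fraction of V(0))
    noise_reference: str = "noise_sd"
    # multispin
    n_spins: int = 2
    # ESEEM
    zero_fill_factor: int = 2
    detrend: bool = False
    noise_band_lo_mhz: float = 3.5
    noise_band_hi_mhz: float = 8.0
    # label modelling
    label_samples: int = 2000
    clash_cutoff: str = "tight"
    # reproducibility
    seed: int = 0

    provenance: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "provenance":
                continue
            self.provenance.setdefault(f.name, "default")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise PipelineError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)} - {"provenance"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"{path}: unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in raw:
            cfg.provenance[key] = "user-set"
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data.pop("provenance")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def replace(self, **updates) -> "RunConfig":
        data = asdict(self)
        prov = data.pop("provenance")
        data.update(updates)
        cfg = RunConfig(**data)
        cfg.provenance.update(prov)
        for key in updates:
            cfg.provenance[key] = "user-set"
        return cfg

    def r_grid(self):
        import numpy as np

        n = int(round((self.r_max - self.r_min) / self.r_step)) + 1
        return np.linspace(self.r_min, self.r_max, n)

    def alpha_grid(self):
        import numpy as np

        return np.logspace(
            np.log10(self.alpha_grid_lo), np.log10(self.alpha_grid_hi), self.alpha_grid_n
        )
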