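"""Run-time configuration blocks (geometry search, ring model, options)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

# Point-dipole ring-current defaults.  The intensity factors (relative to
# benzene) and the B constant are literature-derived model parameters, not
# outputs of this package; override them in config when a bundle ships its
# own values.
DEFAULT_RING_B = 30.42  # ppm * A^3
DEFAULT_RING_INTENSITIES = {
    "PHE": 1.00,
    "TYR": 0.81,
    "HIS": 0.69,
    "TRP5": 0.57,
    "TRP6": 1.02,
}


@dataclass(frozen=True)
class SearchConfig:
    """Hydrogen-bond geometry search windows (distances in Angstrom)."""

    amide_r_max: float = 3.0
    amide_r_min: float = 1.5
    halpha_r_max: float = 4.0
    halpha_r_min: float = 1.8
    theta_min: float = 90.0
    #: "nearest" keeps one partner per donor kind for secondary terms;
    #: "sum" keeps all in-range partners.
    secondary_mode: str = "nearest"

    def __post_init__(self):
        if self.secondary_mode not in ("nearest", "sum"):
            raise ConfigurationError(
                f"secondary_mode must be 'nearest' or 'sum', got {self.secondary_mode!r}"
            )

    def r_range(self, donor_kind: str) -> tuple[float, float]:
        if donor_kind == "alpha_H":
            return self.halpha_r_min, self.halpha_r_max
        return self.amide_r_min, self.amide_r_max


@dataclass(frozen=True)
class RingConfig:
    cutoff: float = 8.0
    B: float = DEFAULT_RING_B
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_RING_INTENSITIES))


@dataclass(frozen=True)
class RunConfig:
    """Full prediction configuration."""

    search: SearchConfig = field(default_factory=SearchConfig)
    ring: RingConfig = field(default_factory=RingConfig)
    strict: bool = True

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        cfg = RunConfig()
        if not d:
            return cfg
        search = replace(cfg.search, **d.get("search", {}))
        ring_d = dict(d.get("ring", {}))
        intens = {**DEFAULT_RING_INTENSITIES, **ring_d.pop("intensities", {})}
        ring = RingConfig(intensities=intens, **ring_d)
        return RunConfig(search=search, ring=ring,
                         strict=bool(d.get("strict", True)))
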