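"""Pipeline configuration: a flat key-value (YAML) text file.

Defaults mirror the standard analysis conditions: 1 um spherical site, the
150-bin / 7-decade lineal-energy grid starting at 0.01 keV/um, the Kase HSG
MKM parameters, RBE evaluated at 10% survival against the calculated Co-60
reference curve, and 1000 resampling replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import yaml

from . import mkm, reference
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    site_diameter: float = 1.0     # um
    y_min: float = 0.01            # keV/um
    n_decades: float = 7.0
    n_bins: int = 150
    alpha0: float = 0.13           # Gy^-1
    beta: float = 0.05             # Gy^-2
    y0: float = 150.0              # keV/um
    rd: float = 0.42               # um
    rho: float = 1.0               # g/cm^3
    reference_beam: str = "cobalt"  # or "xray-200kv"
    rbe_level: float = 0.1
    n_replicates: int = 1000
    seed: int = 12345

    @property
    def mkm_params(self) -> mkm.MKMParams:
        return mkm.MKMParams(alpha0=self.alpha0, beta=self.beta, y0=self.y0,
                             rd=self.rd, rho=self.rho)

    @property
    def reference_alpha(self) -> float:
        if self.reference_beam == "cobalt":
            return reference.ALPHA_MKM_CO
        if self.reference_beam == "xray-200kv":
            return mkm.ALPHA_200KV_XRAY
        raise ConfigurationError(
            f"unknown reference_beam '{self.reference_beam}' "
            "(expected 'cobalt' or 'xray-200kv')")

    @property
    def reference_lq(self) -> mkm.LQCoefficients:
        return mkm.LQCoefficients(alpha=self.reference_alpha, beta=self.beta)

    def config_hash(self) -> str:
        """Short stable digest of the configuration for output provenance."""
        payload = repr(sorted(dataclasses.asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | None) -> PipelineConfig:
    """Load a flat key-value config file; unknown keys are rejected by name."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a flat key-value mapping")
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in fields:
            raise ConfigurationError(f"{path}: unknown configuration key '{key}'")
        ftype = fields[key].type
        try:
            if ftype == "int":
                value = int(value)
            elif ftype == "float":
                value = float(value)
            elif ftype == "str":
                value = str(value)
        except (TypeError, ValueError):
            raise ConfigurationError(f"{path}: invalid value for '{key}': {value!r}")
        kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    cfg.reference_alpha  # validate the reference choice eagerly
    return cfg
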