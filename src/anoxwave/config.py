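"""Run configuration: flat key-value files with unit-suffixed keys.

Units live in the key names (``rho_uA_per_cm2``, not ``rho``) because unit
ambiguity in parameter tables is the classic way this kind of model gets
mis-reproduced.  An empty file means "all defaults", which reproduce the
standard experiment exactly.  Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ConfigError, InvalidParameterError
from .model import ModelParameters

__all__ = ["RunConfig", "load_config", "save_config", "save_report"]

#: config key <-> ModelParameters field
PARAM_KEYS = {
    "c_m_uF_per_cm2": "C_m",
    "g_na_mS_per_cm2": "g_Na",
    "g_nal_mS_per_cm2": "g_NaL",
    "g_k_mS_per_cm2": "g_K",
    "g_kl_mS_per_cm2": "g_KL",
    "g_cll_mS_per_cm2": "g_ClL",
    "phi_rate_scale": "phi",
    "gamma_mM_cm2_per_uC": "gamma",
    "volume_ratio_beta": "beta",
    "rho_uA_per_cm2": "rho",
    "g_glia_mM_per_s": "G_glia",
    "eps_per_s": "eps",
    "k_bath_mM": "k_bath",
    "temperature_K": "T",
}

_PROTOCOLS = ("rest", "inject", "ogd", "wave")


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    protocol: str = "ogd"
    t_end_s: float = 60.0
    rtol: float = 1e-8
    atol: float = 1e-10
    cutoff_hz: float = 0.1
    filter_order: int = 2
    jitter_width_ms: float = 300.0
    inject_amplitude_uA_per_cm2: float = 10.0
    inject_onset_s: float = 0.1
    inject_duration_s: float = 0.003
    output_dir: str = "."
    seed: int = 0  # reserved; the pipeline is fully deterministic

    def __post_init__(self) -> None:
        if self.protocol not in _PROTOCOLS:
            raise ConfigError(
                f"protocol must be one of {_PROTOCOLS}, got {self.protocol!r}"
            )
        if self.t_end_s <= 0:
            raise ConfigError(f"t_end_s must be positive, got {self.t_end_s!r}")


_RUN_KEYS = {f.name for f in fields(RunConfig)} - {"parameters"}


def load_config(path) -> RunConfig:
    """Load a flat YAML key-value config; empty file -> full defaults.

    Raises :class:`ConfigError` naming the offending key for unknown keys
    and propagating line context for malformed files.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(
            f"config must be a flat key-value mapping, got {type(data).__name__}"
        )
    params = {}
    run = {}
    for key, value in data.items():
        if key in PARAM_KEYS:
            params[PARAM_KEYS[key]] = value
        elif key in _RUN_KEYS:
            run[key] = value
        else:
            raise ConfigError(f"unknown config key: {key!r}")
    try:
        parameters = ModelParameters(**params)
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(parameters=parameters, **run)


def save_config(cfg: RunConfig, path) -> None:
    """Write a config with every key explicit; round-trips through
    :func:`load_config`."""
    inv = {v: k for k, v in PARAM_KEYS.items()}
    data = {inv[k]: v for k, v in asdict(cfg.parameters).items()}
    for key in sorted(_RUN_KEYS):
        data[key] = getattr(cfg, key)
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def save_report(report, path) -> None:
    """Serialize a :class:`~anoxwave.features.FeatureReport` to JSON."""
    report.save(path)
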