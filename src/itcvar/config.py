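"""Declarative run configuration (YAML) with validated defaults.

The default configuration mirrors the standard simulation conditions used
throughout the package: a 943 uL cell, 6:1 syringe:cell concentration
ratio, Ka = 1e5 1/M, dH = -40 kJ/mol, 25 x 10 uL injections from a 250 uL
syringe, and the NanoITC basic error parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .binding import ReactionParams, TitrationConfig
from .exceptions import ConfigError
from .measurement import AdditionalErrors, ErrorParams

__all__ = ["RunConfig", "load_config", "write_config", "config_hash", "MODES"]

MODES = ("simulate", "propagate", "compare-vf", "estimate", "validate-protocol")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate"
    titration: TitrationConfig = dataclasses.field(default_factory=TitrationConfig)
    reaction: ReactionParams = dataclasses.field(default_factory=ReactionParams)
    errors: ErrorParams = dataclasses.field(default_factory=ErrorParams)
    additional: AdditionalErrors = dataclasses.field(default_factory=AdditionalErrors)
    n_rep: int = 100_000
    n_sets: int = 2_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.n_rep < 2:
            raise ConfigError("n_rep must be >= 2")
        if self.n_sets < 100:
            raise ConfigError("n_sets must be >= 100")


_SECTION_KEYS = {
    "titration": {
        "V_cell",
        "C_syr",
        "C_cell",
        "injection_volumes",
        "injection_volume",
        "n_injections",
        "syringe_volume",
        "drop_first",
    },
    "reaction": {"Ka", "dH", "n"},
    "errors": {"sigma_b", "sigma_p", "sigma_v"},
    "additional": {"rel_sd_Csyr", "rel_sd_Ka", "rel_sd_dH"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"mode", "n_rep", "n_sets", "seed"}


def _check_keys(given: dict, allowed: set, where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build_titration(sec: dict) -> TitrationConfig:
    sec = dict(sec)
    _check_keys(sec, _SECTION_KEYS["titration"], "titration")
    if "injection_volume" in sec or "n_injections" in sec:
        if "injection_volumes" in sec:
            raise ConfigError(
                "give either injection_volumes or injection_volume/n_injections"
            )
        v = float(sec.pop("injection_volume", 10.0))
        n = int(sec.pop("n_injections", 25))
        sec["injection_volumes"] = (v,) * n
    elif "injection_volumes" in sec:
        sec["injection_volumes"] = tuple(float(x) for x in sec["injection_volumes"])
    try:
        return TitrationConfig(**sec)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid titration section: {e}") from e


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields the all-defaults configuration.  Unknown keys and
    physically invalid values raise :class:`ConfigError`.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    kwargs = {}
    if "titration" in raw:
        kwargs["titration"] = _build_titration(raw["titration"] or {})
    for sec_name, cls in (
        ("reaction", ReactionParams),
        ("errors", ErrorParams),
        ("additional", AdditionalErrors),
    ):
        if sec_name in raw:
            sec = dict(raw[sec_name] or {})
            _check_keys(sec, _SECTION_KEYS[sec_name], sec_name)
            try:
                kwargs[sec_name] = cls(**sec)
            except (TypeError, ValueError) as e:
                raise ConfigError(f"invalid {sec_name} section: {e}") from e
    for key in ("mode", "n_rep", "n_sets", "seed"):
        if key in raw and raw[key] is not None:
            kwargs[key] = raw[key]
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def _as_dict(cfg: RunConfig) -> dict:
    return {
        "mode": cfg.mode,
        "titration": {
            "V_cell": cfg.titration.V_cell,
            "C_syr": cfg.titration.C_syr,
            "C_cell": cfg.titration.C_cell,
            "injection_volumes": list(cfg.titration.injection_volumes),
            "syringe_volume": cfg.titration.syringe_volume,
            "drop_first": cfg.titration.drop_first,
        },
        "reaction": {"Ka": cfg.reaction.Ka, "dH": cfg.reaction.dH, "n": cfg.reaction.n},
        "errors": {
            "sigma_b": cfg.errors.sigma_b,
            "sigma_p": cfg.errors.sigma_p,
            "sigma_v": cfg.errors.sigma_v,
        },
        "additional": {
            "rel_sd_Csyr": cfg.additional.rel_sd_Csyr,
            "rel_sd_Ka": cfg.additional.rel_sd_Ka,
            "rel_sd_dH": cfg.additional.rel_sd_dH,
        },
        "n_rep": cfg.n_rep,
        "n_sets": cfg.n_sets,
        "seed": cfg.seed,
    }


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=False))


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration, for output provenance."""
    blob = json.dumps(_as_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
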