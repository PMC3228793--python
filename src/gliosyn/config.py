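"""Experiment configuration: strict YAML/JSON parsing and unit conversion.

A config file is a single mapping with the sections below; unknown sections
or keys are rejected so that typos fail loudly.  All rates are s^-1 except
``omega_g_per_min`` which accepts the customary min^-1 convention for the
receptor-effect decay and is converted at this boundary.  Times are seconds
and concentrations are uM throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .astrocyte import AstroParams
from .stimulus import (
    GRESchedule,
    SpikeTrain,
    gen_gre_schedule,
    gen_paired_pulses,
    gen_periodic_train,
    gen_poisson_train,
    read_times,
)
from .synapse import SynapseParams

__all__ = ["ExperimentConfig", "load_config"]

_SECTION_KEYS = {
    "synapse": {"omega_d", "omega_f", "u0_star"},
    "astro": {"alpha", "c_thr", "u_a", "omega_a", "g_scale", "omega_c", "o_g",
              "omega_g", "omega_g_per_min", "beta"},
    "stimulus": {"kind", "rate_hz", "duration_s", "freq_hz", "n_spikes", "t0_s",
                 "isi_s", "pair_rate_hz", "n_pairs", "path"},
    "gre": {"kind", "f_c_hz", "onset_s", "times", "path"},
    "meanfield": {"f_start_hz", "f_stop_hz", "n_points", "log",
                  "fc_start_hz", "fc_stop_hz", "n_fc_points"},
    "ensemble": {"n_trials", "rate_hz", "duration_s", "fc_values_hz",
                 "include_recovery_as_ppf"},
    "bath": {"conc_uM", "t_on_s", "t_off_s"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"seed"}


def _require(section: dict, name: str, key: str) -> Any:
    if key not in section:
        raise ValueError(f"config section '{name}' is missing required key '{key}'")
    return section[key]


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment description (parameters + protocol sections)."""

    synapse: SynapseParams
    astro: AstroParams | None
    stimulus: dict | None
    gre: dict | None
    meanfield: dict | None
    ensemble: dict | None
    bath: dict | None
    seed: int = 0
    resolved: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        _check_keys(raw, _TOP_KEYS, "config root")
        if "synapse" not in raw:
            raise ValueError("config is missing required key 'synapse'")
        for name in _SECTION_KEYS:
            if name in raw:
                if not isinstance(raw[name], dict):
                    raise ValueError(f"config section '{name}' must be a mapping")
                _check_keys(raw[name], _SECTION_KEYS[name], f"section '{name}'")

        syn_raw = raw["synapse"]
        for key in ("omega_d", "omega_f", "u0_star"):
            _require(syn_raw, "synapse", key)
        syn = SynapseParams(**syn_raw)

        astro = None
        if "astro" in raw:
            a = dict(raw["astro"])
            _require(a, "astro", "alpha")
            if "omega_g_per_min" in a:
                if "omega_g" in a:
                    raise ValueError("give omega_g or omega_g_per_min, not both")
                a["omega_g"] = a.pop("omega_g_per_min") / 60.0
            astro = AstroParams(**a)

        cfg = cls(
            synapse=syn,
            astro=astro,
            stimulus=raw.get("stimulus"),
            gre=raw.get("gre"),
            meanfield=raw.get("meanfield"),
            ensemble=raw.get("ensemble"),
            bath=raw.get("bath"),
            seed=int(raw.get("seed", 0)),
        )
        object.__setattr__(cfg, "resolved", cfg._resolve())
        return cfg

    def _resolve(self) -> dict:
        """Fully-resolved config (post unit conversion) for output provenance."""
        out: dict[str, Any] = {"seed": self.seed}
        out["synapse"] = vars(self.synapse).copy()
        if self.astro is not None:
            out["astro"] = {k: getattr(self.astro, k)
                            for k in ("alpha", "c_thr", "u_a", "omega_a", "g_scale",
                                      "omega_c", "o_g", "omega_g", "beta")}
        for name in ("stimulus", "gre", "meanfield", "ensemble", "bath"):
            sec = getattr(self, name)
            if sec is not None:
                out[name] = dict(sec)
        return out

    def build_stimulus(self, seed: int | None = None) -> SpikeTrain:
        sec = self.stimulus
        if sec is None:
            raise ValueError("config has no 'stimulus' section")
        kind = _require(sec, "stimulus", "kind")
        if kind == "poisson":
            return gen_poisson_train(
                _require(sec, "stimulus", "rate_hz"),
                _require(sec, "stimulus", "duration_s"),
                self.seed if seed is None else seed,
            )
        if kind == "periodic":
            return gen_periodic_train(
                _require(sec, "stimulus", "freq_hz"),
                _require(sec, "stimulus", "n_spikes"),
                sec.get("t0_s", 0.0),
            )
        if kind == "pairs":
            return gen_paired_pulses(
                _require(sec, "stimulus", "isi_s"),
                _require(sec, "stimulus", "pair_rate_hz"),
                _require(sec, "stimulus", "n_pairs"),
            )
        if kind == "file":
            times = read_times(_require(sec, "stimulus", "path"))
            duration = sec.get("duration_s", float(times[-1]) + 1.0)
            return SpikeTrain(times, duration)
        raise ValueError(f"unknown stimulus kind {kind!r}")

    def build_gres(self, duration: float) -> GRESchedule:
        sec = self.gre
        if sec is None or sec.get("kind", "none") == "none":
            return GRESchedule(np.empty(0))
        kind = sec["kind"]
        if kind == "periodic":
            return gen_gre_schedule(
                _require(sec, "gre", "f_c_hz"), duration, sec.get("onset_s", 0.0)
            )
        if kind == "times":
            if "path" in sec:
                return GRESchedule(read_times(sec["path"]))
            return GRESchedule(np.asarray(_require(sec, "gre", "times"), dtype=float))
        raise ValueError(f"unknown gre kind {kind!r}")


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML (or JSON) experiment config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
        else json.loads(text)
    return ExperimentConfig.from_dict(raw)
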