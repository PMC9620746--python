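"""YAML run-configuration files.

A config file is a flat key/value document with one section per module::

    task:
      name: mwm            # or reversal
      episodes: 40
      trials: 1
      start: [0.0, 0.0]    # or "random"
    network:
      sigma: 0.4
      peak_rate: 400.0
      delta_u: 2.0
    plasticity:
      rule: swc            # swc | cwc | swc-online | rate-swc | rate-cwc
      ada: 1.0
      a5ht: 1.0
      eta: 0.01
      wmin: 1.0
      wmax: 3.0
      rda_amp: 1.0
      r5ht_amp: 1.0
      tau_stdp_ms: 10.0
      tau_e_da_s: 2.0
      tau_e_5ht_s: 5.0
    simulation:
      sims: 200
      seed: 1
      no_5ht: false
      opto: [[10, 20, inhibit]]

Unknown sections or keys are rejected.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .arena import make_protocol
from .network import MembraneParams
from .plasticity import PlasticityParams
from .simulation import OptoWindow, RunConfig

__all__ = ["load_config", "config_from_dict"]


class ConfigError(ValueError):
    pass


def _take(section: dict, known: dict, where: str) -> dict:
    unknown = set(section) - set(known)
    if unknown:
        raise ConfigError(f"unknown keys in [{where}]: {sorted(unknown)}")
    return {known[k]: v for k, v in section.items()}


def config_from_dict(doc: dict) -> RunConfig:
    doc = dict(doc or {})
    task = doc.pop("task", {}) or {}
    network = doc.pop("network", {}) or {}
    plast = doc.pop("plasticity", {}) or {}
    sim = doc.pop("simulation", {}) or {}
    if doc:
        raise ConfigError(f"unknown sections: {sorted(doc)}")

    t = _take(
        task,
        {"name": "name", "episodes": "episodes", "trials": "trials",
         "start": "start", "t_max": "t_max"},
        "task",
    )
    name = t.pop("name", "mwm")
    overrides = {}
    if "episodes" in t:
        overrides["episodes_per_trial"] = int(t.pop("episodes"))
    if "trials" in t:
        overrides["trials"] = int(t.pop("trials"))
    if "start" in t:
        start = t.pop("start")
        overrides["start_position"] = "random" if start == "random" else tuple(start)
    if "t_max" in t:
        overrides["t_max"] = float(t.pop("t_max"))
    protocol = make_protocol(name, **overrides)

    n = _take(
        network,
        {"sigma": "sigma", "peak_rate": "peak_rate", "delta_u": "delta_u",
         "dt": "dt", "dt_move": "dt_move"},
        "network",
    )
    membrane = MembraneParams(delta_u=float(n.pop("delta_u", 2.0)))

    p = _take(
        plast,
        {"rule": "rule", "ada": "a_da", "a5ht": "a_5ht", "eta": "eta",
         "eta_da": "eta_da", "eta_5ht": "eta_5ht",
         "wmin": "w_min", "wmax": "w_max", "rda_amp": "rda_amp",
         "r5ht_amp": "r5ht_amp", "tau_stdp_ms": "tau_stdp",
         "tau_e_da_s": "tau_e_da_s", "tau_e_5ht_s": "tau_e_5ht_s"},
        "plasticity",
    )
    rule = p.pop("rule", "swc")
    cfg = RunConfig(protocol=protocol, rule=rule, membrane=membrane, **{
        k: float(v) for k, v in n.items()
    })
    pl = cfg.plasticity
    if "eta" in p:
        eta = float(p.pop("eta"))
        pl = replace(pl, eta_da=eta, eta_5ht=eta)
    pl_keys = {k: float(v) for k, v in p.items() if k in PlasticityParams.__dataclass_fields__}
    if pl_keys:
        pl = replace(pl, **pl_keys)
    cfg_keys = {k: float(v) for k, v in p.items() if k in ("a_da", "a_5ht", "tau_stdp",
                                                           "tau_e_da_s", "tau_e_5ht_s")}
    cfg = replace(cfg, plasticity=pl, **cfg_keys)

    s = _take(
        sim,
        {"sims": "n_simulations", "seed": "seed", "no_5ht": "no_5ht",
         "opto": "opto", "record_trajectories": "record_trajectories",
         "stop_after_first_reward": "stop_after_first_reward",
         "snapshot_episodes": "snapshot_episodes"},
        "simulation",
    )
    if "opto" in s:
        s["opto"] = tuple(
            OptoWindow(int(a), int(b), str(mode)) for a, b, mode in s["opto"]
        )
    if "snapshot_episodes" in s:
        s["snapshot_episodes"] = tuple(int(e) for e in s["snapshot_episodes"])
    for key in ("n_simulations", "seed"):
        if key in s:
            s[key] = int(s[key])
    return replace(cfg, **s)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is not None and not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(doc or {})
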