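"""YAML configuration loading.

A config file holds optional sections ``traits``, ``gasx``, ``soil``,
``veg``, ``damage``, ``solver`` and ``experiment``; any omitted key falls
back to the package defaults (the default warm-and-sunny high-capacitance
scenario). Example::

    traits:
      kxmax: 1.2e-7
      h: 25.0
    soil:
      retention:
        model: van_genuchten
        alpha: 2.0
        n: 1.6
      layers:
        - {depth: 0.3, w: 0.5}
        - {depth: 0.3, w: 0.3}
        - {depth: 0.4, w: 0.2}
    gasx:
      Vcmax25: 60.0
      fl_anchors: [[1.0, 0.5], [0.2, 0.1]]
    experiment:
      scenario: e1a
      n_days: 250
      variants: [baseline, H, HC]
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .experiments import DamageConfig, ExperimentConfig, ModelConfig
from .gasx import GasExchangeParams, calibrate_fl
from .hydro import PlantTraits, conductance_scaling
from .soil import RETENTION_MODELS, SoilColumn, SoilLayer
from .veg import CarbonPools

__all__ = ["load_config", "build_experiment"]


def _build_traits(section: dict) -> PlantTraits:
    section = dict(section)
    if "kx_tissue" in section:
        kxt = section.pop("kx_tissue")
        h = section.get("h", PlantTraits.h)
        ax = section.get("Ax", PlantTraits.Ax)
        section["kxmax"] = conductance_scaling(kxt, h, ax)
    return PlantTraits(**section)


def _build_gasx(section: dict) -> GasExchangeParams:
    section = dict(section)
    anchors = section.pop("fl_anchors", None)
    if anchors is not None:
        al, gl = calibrate_fl(tuple(anchors[0]), tuple(anchors[1]))
        section.setdefault("al", al)
        section.setdefault("gl", gl)
    return GasExchangeParams(**section)


def _build_soil(section: dict) -> SoilColumn:
    section = dict(section)
    ret_sec = dict(section.pop("retention", {}))
    model = ret_sec.pop("model", "van_genuchten")
    if model not in RETENTION_MODELS:
        raise ValueError(f"unknown retention model {model!r}")
    retention = RETENTION_MODELS[model](**ret_sec)
    layer_specs = section.pop(
        "layers", [{"depth": 0.3, "w": 0.5}, {"depth": 0.3, "w": 0.3}, {"depth": 0.4, "w": 0.2}]
    )
    theta0 = section.pop("theta0", retention.theta_s)
    layers = tuple(
        SoilLayer(theta=ls.get("theta", theta0), depth=ls["depth"], w=ls["w"])
        for ls in layer_specs
    )
    return SoilColumn(layers=layers, retention=retention, **section)


def load_config(path: str | Path | None) -> dict:
    """Read the YAML file (empty dict if ``path`` is None)."""
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def build_model(raw: dict, variant: str | None = None, seed: int | None = None) -> ModelConfig:
    """Assemble a :class:`ModelConfig` from a raw config dict."""
    solver = dict(raw.get("solver", {}))
    kwargs = dict(
        traits=_build_traits(raw.get("traits", {})),
        gasx=_build_gasx(raw.get("gasx", {})),
        soil=_build_soil(raw.get("soil", {})),
        pools=CarbonPools(**raw.get("veg", {})),
        damage=DamageConfig(**raw.get("damage", {})),
        **solver,
    )
    if variant is not None:
        kwargs["variant"] = variant
    if seed is not None:
        kwargs["seed"] = seed
    return ModelConfig(**kwargs)


def build_experiment(
    raw: dict, variant: str | None = None, seed: int | None = None
) -> ExperimentConfig:
    """Assemble an :class:`ExperimentConfig` (model + scenario) from raw config."""
    exp = dict(raw.get("experiment", {}))
    if "variants" in exp:
        exp["variants"] = tuple(exp["variants"])
    if variant is not None:
        exp["variants"] = (variant,)
    if "months" in exp:
        exp["months"] = tuple(exp["months"])
    model = build_model(raw, seed=seed)
    cfg = ExperimentConfig(model=model, **exp)
    if seed is not None:
        cfg = replace(cfg, seed=seed, model=replace(model, seed=seed))
    return cfg
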