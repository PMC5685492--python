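"""YAML configuration mapped onto the pipeline's parameter dataclasses.

Every default named across the modules is reachable from one YAML file, e.g.::

    preprocess:
      ggmrf: {alpha: 2.0, beta: 1.01, rho: 1.0, n_iters: 1}
    shape_prior: {tau: 10, cube_init: 3, cube_step: 2, cube_max: 11}
    lcdg: {k_dominant: 4, max_subordinate: 4, tol: 1.0e-4, max_iters: 100}
    registration: {bins: 64, levels: 3, max_iters: 4}
    icm: {max_sweeps: 10, stop_fraction: 1.0e-4, reestimate_potentials: false}
    segmenter: {k_prototypes: 3, mgrf_order: 4, skip_ggmrf: false}
"""

from __future__ import annotations

import dataclasses

import yaml

from .lcdg import LCDGFitOptions
from .preprocess import GGMRFParams
from .registration import RegistrationOptions
from .segmenter import ICMOptions, SegmenterParams
from .shape_prior import PriorSearchParams


def _apply(obj, overrides: dict):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        if key not in names:
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        setattr(obj, key, value)
    if hasattr(obj, "__post_init__"):
        obj.__post_init__()
    return obj


def params_from_dict(cfg: dict) -> SegmenterParams:
    params = SegmenterParams()
    cfg = cfg or {}
    pre = cfg.get("preprocess", {})
    if "ggmrf" in pre:
        params.ggmrf = _apply(GGMRFParams(), pre["ggmrf"])
    if "skip_ggmrf" in pre:
        params.skip_ggmrf = bool(pre["skip_ggmrf"])
    if "shape_prior" in cfg:
        params.prior = _apply(PriorSearchParams(), cfg["shape_prior"])
    if "lcdg" in cfg:
        lcdg_cfg = dict(cfg["lcdg"])
        params.lcdg_k = int(lcdg_cfg.pop("k_dominant", params.lcdg_k))
        params.lcdg = _apply(LCDGFitOptions(), lcdg_cfg)
    if "registration" in cfg:
        params.registration = _apply(RegistrationOptions(), cfg["registration"])
    if "icm" in cfg:
        params.icm = _apply(ICMOptions(), cfg["icm"])
    for key, value in cfg.get("segmenter", {}).items():
        _apply(params, {key: value})
    return params


def load_config(path) -> SegmenterParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh) or {})
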