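"""Run-configuration files (YAML or JSON) shared by the CLI subcommands.

Recognized keys, all optional::

    k_rule: {mode: variance|fixed, value: 0.95}
    delta_threshold_rel: 1.0e-3      # or delta_threshold_abs for an override
    sigma: 3.0
    temporal_scale: 10.0
    spatial_scale: 1.0
    window: 400
    stride: 400                      # defaults to window (non-overlapping)
    baseline_k: 8
"""

from __future__ import annotations

import json

import yaml

from .evaluation import EvalSettings
from .lwpca_regression import TaperConfig
from .subspace import KRule
from .wpca_regression import DeltaThreshold

__all__ = ["load_settings"]


def load_settings(path: str | None) -> EvalSettings:
    """Build :class:`EvalSettings` from a YAML/JSON config file (or defaults)."""
    if path is None:
        return EvalSettings()
    with open(path) as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    doc = doc or {}
    kr = doc.get("k_rule", {})
    k_rule = KRule(mode=kr.get("mode", "variance"), value=kr.get("value", 0.95))
    threshold = DeltaThreshold(
        relative=float(doc.get("delta_threshold_rel", 1e-3)),
        absolute=doc.get("delta_threshold_abs"),
    )
    taper = TaperConfig(
        sigma=float(doc.get("sigma", 3.0)),
        temporal_scale=float(doc.get("temporal_scale", 10.0)),
        spatial_scale=float(doc.get("spatial_scale", 1.0)),
    )
    window = int(doc.get("window", 400))
    return EvalSettings(
        k_rule=k_rule,
        taper=taper,
        threshold=threshold,
        window=window,
        baseline_k=int(doc.get("baseline_k", 8)),
    )
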