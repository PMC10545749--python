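"""YAML configuration loading for the pipeline.

The file mirrors the dataclass structure; every key is optional and falls
back to the documented default.  Example::

    mode: proposed
    filter:   {left_fraction: 0.40, right_fraction: 0.60, enabled: true}
    geometry: {center_deviation_fraction: 0.05}
    numbering:
      halve_iou_threshold: 0.5
      bridge_ratio: [33, 30, 33]
    prior:
      kappa: 0.0
      d_variant: as_printed      # or quartile
      mandible_center_halving: true
      molar_e_factor: 1.5
    weights:  {omega_p: 0.8, omega_c: 0.2}
    optimizer:
      max_sweeps: 10
      enable_round_robin: true
      enable_isolation_exception: true
      round_robin_budget: 3125
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .occlusal_geometry import GeometryConfig
from .optimizer import OptimizerConfig
from .pipeline import PipelineConfig
from .prior_knowledge import ObjectiveWeights, PriorConfig
from .prosthesis_numbering import NumberingConfig
from .tooth_filter import FilterConfig

__all__ = ["load_config", "config_from_dict"]


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    numbering = dict(data.get("numbering", {}))
    if "bridge_ratio" in numbering:
        numbering["bridge_ratio"] = tuple(numbering["bridge_ratio"])
    if "classes_enabled" in numbering:
        from .candidate_model import ProsthesisClass

        numbering["classes_enabled"] = frozenset(
            ProsthesisClass(c) for c in numbering["classes_enabled"]
        )
    return PipelineConfig(
        mode=data.get("mode", "proposed"),
        filter=FilterConfig(**data.get("filter", {})),
        geometry=GeometryConfig(**data.get("geometry", {})),
        numbering=NumberingConfig(**numbering),
        prior=PriorConfig(**data.get("prior", {})),
        weights=ObjectiveWeights(**data.get("weights", {})),
        optimizer=OptimizerConfig(**data.get("optimizer", {})),
    )


def load_config(path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()) or {})
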