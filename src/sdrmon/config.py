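"""Run configuration: YAML files with the published defaults baked in."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .extraction import PROFILES, TransducerProfile
from .sdr import AlgorithmParams
from .synthetic import BackgroundModel, DefectSpec, FixtureLayout

__all__ = ["RunConfig", "load_config", "algorithm_params_from_dict"]


def algorithm_params_from_dict(data: dict | None, seed: int | None = None
                               ) -> AlgorithmParams:
    """Build AlgorithmParams from a config mapping; unset keys keep defaults."""
    data = dict(data or {})
    if seed is not None:
        data["seed"] = seed
    return AlgorithmParams(**data)


@dataclass
class RunConfig:
    """Everything one monitoring run needs, resolvable from YAML + flags."""

    station: str = "SIM-STATION"
    transducer: str = "ML 6-15"
    params: AlgorithmParams = field(default_factory=AlgorithmParams)
    profile: TransducerProfile | None = None
    background: BackgroundModel = field(default_factory=BackgroundModel)
    layout: FixtureLayout = field(default_factory=FixtureLayout)
    defects: list[DefectSpec] = field(default_factory=list)
    threshold: float = 0.75
    seed: int = 0
    max_single_image_cols: int = 1024
    n_images: int = 150
    n_zoomed: int = 0
    n_doppler: int = 0
    bmode_size: tuple[int, int] = (500, 560)  # stored-frame B-mode rows, cols

    def resolve_profile(self) -> TransducerProfile:
        if self.profile is not None:
            return self.profile
        try:
            return PROFILES[self.transducer]
        except KeyError:
            raise KeyError(
                f"unknown transducer {self.transducer!r}; shipped profiles: "
                f"{sorted(PROFILES)}") from None


def _tuplify(value):
    return tuple(value) if isinstance(value, (list, tuple)) else value


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config; keyword overrides (e.g. CLI flags) win over the file."""
    doc = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    for key in ("station", "transducer", "threshold", "seed",
                "max_single_image_cols", "n_images", "n_zoomed", "n_doppler"):
        if key in doc:
            setattr(cfg, key, doc[key])
    if "bmode_size" in doc:
        cfg.bmode_size = tuple(doc["bmode_size"])
    if "profile" in doc:
        p = dict(doc["profile"])
        if "accepted_width_mm" in p:
            p["accepted_width_mm"] = tuple(p["accepted_width_mm"])
        cfg.profile = TransducerProfile(**p)
    if "background" in doc:
        cfg.background = BackgroundModel(**doc["background"])
    if "layout" in doc:
        lay = {k: _tuplify(v) for k, v in dict(doc["layout"]).items()}
        if "logotype_boxes" in lay:
            lay["logotype_boxes"] = tuple(tuple(b) for b in lay["logotype_boxes"])
        cfg.layout = FixtureLayout(**lay)
    if "defects" in doc:
        cfg.defects = [DefectSpec(**d) for d in doc["defects"]]
    seed_override = overrides.pop("seed", None)
    if seed_override is not None:
        cfg.seed = seed_override
    for key, value in overrides.items():
        if value is not None:
            setattr(cfg, key, value)
    cfg.params = algorithm_params_from_dict(doc.get("algorithm"), seed=cfg.seed)
    return cfg
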