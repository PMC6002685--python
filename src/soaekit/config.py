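"""Pipeline configuration: one YAML file covering every stage.

Sections (all optional; omitted keys take the documented defaults):

.. code-block:: yaml

    seed: 1
    generator:            # CohortConfig fields
      n_mono: 11
      n_trials: 240
    stft:                 # STFTParams fields
      n_fft: 22050
    detection:            # DetectionSettings fields
      snr_threshold_db: 6.0
    loadings:             # composite loadings override
      control: {flanker: 0.922}

A run's effective configuration is persisted next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .pipeline import DetectionSettings
from .synth import CohortConfig
from .types import STFTParams

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: CohortConfig = field(default_factory=CohortConfig)
    stft: STFTParams = field(default_factory=STFTParams)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    loadings: dict | None = None
    log_level: str = "INFO"


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (or pure defaults)."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"seed", "generator", "stft", "detection", "loadings",
                          "log_level"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
    gen = dict(raw.get("generator") or {})
    gen["seed"] = cfg_seed
    return PipelineConfig(
        seed=cfg_seed,
        generator=CohortConfig(**gen),
        stft=STFTParams(**(raw.get("stft") or {})),
        detection=DetectionSettings(**(raw.get("detection") or {})),
        loadings=raw.get("loadings"),
        log_level=str(raw.get("log_level", "INFO")),
    )


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    payload = {
        "seed": cfg.seed,
        "generator": asdict(cfg.generator),
        "stft": asdict(cfg.stft),
        "detection": asdict(cfg.detection),
        "loadings": cfg.loadings,
        "log_level": cfg.log_level,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
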