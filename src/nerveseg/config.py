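"""YAML run-configuration loading.

A run file has optional blocks ``data``, ``network``, ``loss``, ``train``,
``cascade`` and ``augmentation`` whose keys mirror the corresponding
dataclasses; omitted keys fall back to the dataclass defaults.
"""

from __future__ import annotations

from pathlib import Path
import yaml

from .augmentation import AugmentConfig
from .losses import LossConfig
from .network import NetworkConfig
from .pipeline import TrainConfig

_SECTION_TYPES = {
    "network": NetworkConfig,
    "loss": LossConfig,
    "train": TrainConfig,
    "augmentation": AugmentConfig,
}


def load_run_config(path) -> dict:
    """Parse a YAML run file into config objects (plus the raw ``data`` block)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {"data": raw.get("data", {}), "cascade": raw.get("cascade", {})}
    for section, cls in _SECTION_TYPES.items():
        block = dict(raw.get(section, {}))
        block.pop("name", None)
        for key in ("encoder_blocks", "decoder_blocks", "patch_size", "mirror_axes"):
            if key in block and isinstance(block[key], list):
                block[key] = tuple(block[key])
        out[section] = cls(**block)
    out["loss_name"] = (raw.get("loss", {}) or {}).get("name", "omega_double")
    return out
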