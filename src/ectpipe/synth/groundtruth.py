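"""Ground-truth record emitted next to every synthetic artifact.

Every generator returns, alongside its data, a :class:`GroundTruth` holding
the modality tag, the complete generating parameter map and the seed, so the
value each downstream stage should recover is computable in closed form (or
via a stated dense-grid oracle) from the record alone.  Identical
``(params, seed)`` always produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["GroundTruth"]

MODALITIES = frozenset(
    {
        "wire_video",
        "twitch_trace",
        "ca_trace",
        "ca_video",
        "ap_trace",
        "brightfield",
        "sarcomere_image",
        "dose_response",
        "ct_table",
    }
)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """Provenance record of one synthetic artifact."""

    modality: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.params = _jsonable(self.params)

    def to_json(self, path: str | Path) -> None:
        """Write the record as a JSON sidecar file (sorted keys, stable bytes)."""
        payload = {"modality": self.modality, "seed": self.seed, "params": self.params}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(payload["modality"], payload["params"], payload["seed"])
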