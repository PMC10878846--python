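"""Serialization: sampled stacks to multi-page TIFF + JSON sidecar, tables to CSV."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile

from .model import EmitterParams
from .optics import IlluminationSequence, OpticalConfig

__all__ = ["write_stack", "read_stack", "write_table_csv"]


def _sequence_dict(seq: IlluminationSequence) -> dict:
    return {
        "budget_scenario": seq.budget_scenario,
        "background_model": seq.background_model,
        "exposures": [asdict(e) for e in seq.exposures],
    }


def write_stack(
    path: str | Path,
    counts: np.ndarray,
    emitter: EmitterParams,
    seq: IlluminationSequence,
    config: OpticalConfig,
    seed: Optional[int] = None,
) -> Path:
    """Write a sampled K-page TIFF stack (one page per exposure) plus a JSON
    sidecar carrying the emitter, sequence, optics and seed."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(counts).astype(np.uint32), photometric="minisblack")
    sidecar = {
        "emitter": asdict(emitter),
        "sequence": _sequence_dict(seq),
        "optics": asdict(config),
        "seed": seed,
        "stack_shape": list(np.asarray(counts).shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a sampled stack and its sidecar metadata."""
    path = Path(path)
    counts = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return counts, meta


def write_table_csv(
    df: pd.DataFrame, path: str | Path, metadata: Optional[Mapping] = None
) -> Path:
    """CSV with a '#'-prefixed metadata comment block, '.' decimals, UTF-8."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
    return path
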