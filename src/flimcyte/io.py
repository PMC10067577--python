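"""On-disk formats: TIFF stacks with JSON sidecars, masks, maps, tables.

Conventions
-----------
- Decay cubes: multi-page TIFF ordered (time, y, x), one file per channel,
  with a JSON sidecar ``{bin_width_ps, n_bins, channel, excitation_nm}``
  next to it (same stem, ``.json`` suffix).
- Lifetime/fit-parameter maps: 32-bit float TIFF, NaN where unfitted.
- Label masks (including externally drawn ground truth): 16-bit unsigned
  TIFF, 0 = background.
- Tables: CSV via pandas; configs and provenance: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import FormatError, MetadataError

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_map",
    "read_map",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path, data: np.ndarray, metadata: dict) -> None:
    """Write a (time, y, x) count cube plus its JSON sidecar."""
    path = Path(path)
    data = np.asarray(data)
    required = {"bin_width_ps", "n_bins", "channel"}
    missing = required - metadata.keys()
    if missing:
        raise MetadataError(f"sidecar metadata missing keys: {sorted(missing)}")
    if int(metadata["n_bins"]) != data.shape[0]:
        raise MetadataError(
            f"n_bins={metadata['n_bins']} but cube has {data.shape[0]} time pages"
        )
    tifffile.imwrite(path, data)
    _sidecar_path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a decay cube and its sidecar; errors on missing/invalid files."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing JSON sidecar for {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    try:
        metadata = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"corrupt sidecar {sidecar}: {exc}") from exc
    if int(metadata.get("n_bins", -1)) != data.shape[0]:
        raise MetadataError(
            f"sidecar n_bins={metadata.get('n_bins')} does not match cube shape {data.shape}"
        )
    return data, metadata


def write_mask(path, mask: np.ndarray) -> None:
    """Write a label mask as 16-bit unsigned TIFF."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise FormatError("labels out of uint16 range")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    path = Path(path)
    try:
        mask = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"unreadable mask TIFF {path}: {exc}") from exc
    if not np.issubdtype(mask.dtype, np.integer):
        raise FormatError(f"mask {path} must be an integer TIFF, got {mask.dtype}")
    return mask.astype(np.int32)


def write_map(path, arr: np.ndarray) -> None:
    """Write a float parameter map (NaN = unfitted) as 32-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(arr, dtype=np.float32))


def read_map(path) -> np.ndarray:
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"unreadable map TIFF {path}: {exc}") from exc
    return np.asarray(arr, dtype=np.float32)
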