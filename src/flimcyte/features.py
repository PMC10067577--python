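"""Per-cell optical metabolic imaging (OMI) features.

Aggregates per-pixel lifetime maps into one record per labelled cell: the
ten bi-exponential components (tau1, tau2, alpha1, alpha2, tau_m for both
NAD(P)H and FAD), the optical redox ratio, and the cell size in pixels —
the twelve parameters every downstream statistic consumes — keyed by
(fov_id, cell_id) plus study metadata.

Aggregation is photon-weighted by default: a pixel contributes to a cell's
parameter mean in proportion to the photons it collected in that channel, so
bright, well-fitted pixels dominate.  The per-cell redox ratio is the ratio
of summed intensities (not the mean of per-pixel ratios), which stays stable
when individual pixels are photon-starved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DimensionError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "FeaturesConfig",
    "LIFETIME_PARAMETERS",
    "OMI_PARAMETERS",
    "FEATURE_SCHEMA",
    "extract_cell_features",
    "build_feature_table",
]

LIFETIME_PARAMETERS = (
    "nadph_tau1", "nadph_tau2", "nadph_alpha1", "nadph_alpha2", "nadph_tau_m",
    "fad_tau1", "fad_tau2", "fad_alpha1", "fad_alpha2", "fad_tau_m",
)

#: The twelve OMI parameters used for heatmaps, clustering and comparisons.
OMI_PARAMETERS = LIFETIME_PARAMETERS + ("redox_ratio", "cell_size")

META_COLUMNS = ("fov_id", "cell_id", "mouse_id", "tissue", "cell_type")
FEATURE_SCHEMA = META_COLUMNS + OMI_PARAMETERS + ("nadph_intensity", "fad_intensity")


@dataclass(frozen=True)
class FeaturesConfig:
    """Aggregation tunables.

    ``weighted`` switches between photon-weighted (default) and unweighted
    pixel means, for sensitivity checks.
    """

    weighted: bool = True


_MAP_TO_COLUMN = {
    "tau1": "tau1", "tau2": "tau2", "alpha1": "alpha1",
    "alpha2": "alpha2", "tau_m": "tau_m",
}


def _weighted_label_mean(
    values: np.ndarray, weights: np.ndarray, labels: np.ndarray, n_labels: int
) -> np.ndarray:
    """Per-label weighted mean over finite pixels; NaN when none contribute."""
    ok = np.isfinite(values) & (labels > 0) & (weights > 0)
    lab = labels[ok]
    num = np.bincount(lab, weights=(values * weights)[ok], minlength=n_labels + 1)
    den = np.bincount(lab, weights=weights[ok], minlength=n_labels + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out


def extract_cell_features(
    mask: np.ndarray,
    channel_maps: dict,
    intensity_images: dict,
    fov_id: str = "fov0",
    mouse_id: str = "m0",
    tissue: str = "tumor",
    cell_type: str = "immune",
    config: FeaturesConfig | None = None,
) -> pd.DataFrame:
    """One row of OMI parameters per labelled cell.

    Parameters
    ----------
    mask : (Y, X) int array
        Label mask, 0 = background.
    channel_maps : dict
        ``{"nadph": FitMaps-or-dict, "fad": ...}`` of per-pixel fitted maps.
    intensity_images : dict
        ``{"nadph": (Y, X) photons, "fad": ...}``; weights and redox come
        from these.

    Cells whose pixels are all unfittable in some channel are excluded and
    logged rather than reported with NaNs.
    """
    cfg = config or FeaturesConfig()
    mask = np.asarray(mask)
    n = int(mask.max())
    if n == 0:
        return pd.DataFrame(columns=list(FEATURE_SCHEMA))
    for ch, img in intensity_images.items():
        if np.asarray(img).shape != mask.shape:
            raise DimensionError(f"intensity image {ch!r} shape mismatch")

    sizes = np.bincount(mask.ravel(), minlength=n + 1)
    data: dict[str, np.ndarray] = {}
    for ch in ("nadph", "fad"):
        maps = channel_maps[ch]
        maps = maps.as_dict() if hasattr(maps, "as_dict") else maps
        intensity = np.asarray(intensity_images[ch], dtype=float)
        weights = intensity if cfg.weighted else np.ones_like(intensity)
        for map_name, col in _MAP_TO_COLUMN.items():
            vals = np.asarray(maps[map_name], dtype=float)
            if vals.shape != mask.shape:
                raise DimensionError(f"map {ch}:{map_name} shape mismatch")
            data[f"{ch}_{col}"] = _weighted_label_mean(vals, weights, mask, n)
        data[f"{ch}_intensity"] = np.bincount(
            mask.ravel(), weights=intensity.ravel(), minlength=n + 1
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        total = data["nadph_intensity"] + data["fad_intensity"]
        data["redox_ratio"] = np.where(total > 0, data["nadph_intensity"] / total, np.nan)

    records = []
    for lab in range(1, n + 1):
        row = {
            "fov_id": fov_id, "cell_id": int(lab), "mouse_id": mouse_id,
            "tissue": tissue, "cell_type": cell_type,
            "cell_size": int(sizes[lab]),
        }
        for key, arr in data.items():
            row[key] = float(arr[lab])
        if any(not np.isfinite(row[p]) for p in LIFETIME_PARAMETERS + ("redox_ratio",)):
            logger.warning(
                "cell %s/%d excluded: no fittable pixels in at least one channel",
                fov_id, lab,
            )
            continue
        records.append(row)
    return pd.DataFrame(records, columns=list(FEATURE_SCHEMA))


def build_feature_table(tables, metadata: dict | None = None) -> pd.DataFrame:
    """Concatenate per-FOV tables into one study table.

    Enforces (fov_id, cell_id) uniqueness and applies any constant
    ``metadata`` columns (e.g. mouse_id) to every row.  An empty input list
    yields an empty table with the full schema.
    """
    tables = list(tables)
    if not tables:
        return pd.DataFrame(columns=list(FEATURE_SCHEMA))
    out = pd.concat(tables, ignore_index=True)
    if metadata:
        for key, value in metadata.items():
            out[key] = value
    dup = out.duplicated(subset=["fov_id", "cell_id"])
    if dup.any():
        keys = out.loc[dup, ["fov_id", "cell_id"]].to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (fov_id, cell_id) keys: {keys[:5]}")
    return out
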