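"""Lifetime-gated ensemble segmentation of labelled immune cells.

The pipeline turns an mCherry intensity image plus a per-pixel lifetime map
into whole-cell label masks:

1. **gate** — keep only pixels whose mean lifetime falls in a fixed window
   (default 800–1500 ps, bracketing nuclear mCherry) to reject non-specific
   red autofluorescence;
2. **threshold** — foreground/background separation of the intensity image
   by one of several standard methods (otsu, yen, minimum, triangle, local)
   or a pairwise union/intersection of two of them;
3. **merge** — left-merge intersection: the thresholded foreground defines
   candidate pixels, the gate prunes them (pixelwise AND);
4. **label** — a Canny edge map splits touching blobs; connected components
   are labelled;
5. **refine** — label-aware expansion (dilate or close), border clearing,
   relabelling, a second expansion, and a small-object area filter;
6. **ensemble** — every (threshold, expansion) variant competes; the variant
   whose mask maximises the Dice coefficient against ground truth wins,
   either per image or by a single globally calibrated variant.

Everything here is deterministic given the configuration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu
from skimage import feature, filters, morphology
from skimage.measure import label as cc_label
from skimage.segmentation import clear_border, expand_labels, relabel_sequential

from .exceptions import (
    ConfigError,
    DegenerateImageError,
    DimensionError,
    EmptyEnsembleError,
    FlimcyteError,
    MissingTruthError,
    UndefinedDiceError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "EnsembleCandidate",
    "BASE_THRESHOLD_METHODS",
    "default_threshold_specs",
    "gate_lifetime",
    "threshold_intensity",
    "merge_intensity_lifetime",
    "label_rois",
    "refine_rois",
    "run_variant",
    "segment_image",
    "segment_tumor_cells",
    "ensemble_select",
    "calibrate_variant",
    "dice_coefficient",
    "dilation_sensitivity",
]

BASE_THRESHOLD_METHODS = ("otsu", "yen", "minimum", "triangle", "local")


def default_threshold_specs() -> tuple[str, ...]:
    """The five base methods plus all pairwise unions ("a|b") and
    intersections ("a&b"): 5 + 10 + 10 = 25 specs."""
    specs = list(BASE_THRESHOLD_METHODS)
    for a, b in itertools.combinations(BASE_THRESHOLD_METHODS, 2):
        specs.append(f"{a}|{b}")
    for a, b in itertools.combinations(BASE_THRESHOLD_METHODS, 2):
        specs.append(f"{a}&{b}")
    return tuple(specs)


@dataclass(frozen=True)
class SegmentationConfig:
    """Every tunable of the segmentation pipeline.

    Defaults follow the acquisition geometry of a 40x, 512x512 field of
    view: 800–1500 ps gate, 25 threshold specs, disk structuring elements of
    radius 2 then 1, and a 20 px small-object floor.
    """

    gate_low: float = 800.0
    gate_high: float = 1500.0
    threshold_methods: tuple[str, ...] = field(default_factory=default_threshold_specs)
    local_block_size: int = 35
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.9
    expansion_modes: tuple[str, ...] = ("dilate", "close")
    struct_radius_1: int = 2
    struct_radius_2: int = 1
    min_area: int = 20
    connectivity: int = 8
    voting_mode: str = "per_image_argmax"

    def __post_init__(self):
        if not self.gate_low < self.gate_high:
            raise ConfigError(
                f"gate_low ({self.gate_low}) must be < gate_high ({self.gate_high})"
            )
        if self.min_area < 1:
            raise ConfigError("min_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        for mode in self.expansion_modes:
            if mode not in ("dilate", "close"):
                raise ConfigError(f"unknown expansion mode {mode!r}")
        if self.voting_mode not in ("per_image_argmax", "global_calibration"):
            raise ConfigError(f"unknown voting mode {self.voting_mode!r}")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2

    def variants(self) -> list[tuple[str, str]]:
        return [
            (thr, exp)
            for thr in self.threshold_methods
            for exp in self.expansion_modes
        ]


@dataclass
class EnsembleCandidate:
    """One (threshold spec, expansion mode) variant's labelled mask."""

    variant_id: tuple[str, str]
    mask: np.ndarray
    dice_vs_truth: float | None = None


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def gate_lifetime(lifetime: np.ndarray, low: float, high: float) -> np.ndarray:
    """True exactly where ``low <= tau <= high`` (inclusive); NaN is False."""
    if not low < high:
        raise ConfigError(f"inverted lifetime gate [{low}, {high}]")
    lt = np.asarray(lifetime, dtype=float)
    with np.errstate(invalid="ignore"):
        return (lt >= low) & (lt <= high)


_GLOBAL_THRESHOLDS = {
    "otsu": filters.threshold_otsu,
    "yen": filters.threshold_yen,
    "minimum": filters.threshold_minimum,
    "triangle": filters.threshold_triangle,
}


def _threshold_base(img: np.ndarray, method: str, local_block_size: int) -> np.ndarray:
    if method == "local":
        block = local_block_size | 1  # must be odd
        thresh = filters.threshold_local(img.astype(float), block_size=block, method="gaussian")
        return img > thresh
    if method not in _GLOBAL_THRESHOLDS:
        raise ConfigError(f"unknown threshold method {method!r}")
    if np.ptp(img) == 0:
        raise DegenerateImageError(
            f"constant image: histogram method {method!r} undefined"
        )
    try:
        t = _GLOBAL_THRESHOLDS[method](img)
    except RuntimeError as exc:  # threshold_minimum: no two maxima
        raise DegenerateImageError(f"{method}: {exc}") from exc
    return img > t


def threshold_intensity(
    img: np.ndarray, spec: str, local_block_size: int = 35
) -> np.ndarray:
    """Foreground mask for one threshold spec.

    ``spec`` is a base method name, or ``"a|b"`` (union) / ``"a&b"``
    (intersection) of two base methods.
    """
    img = np.asarray(img)
    if "|" in spec:
        a, b = spec.split("|")
        return _threshold_base(img, a, local_block_size) | _threshold_base(img, b, local_block_size)
    if "&" in spec:
        a, b = spec.split("&")
        return _threshold_base(img, a, local_block_size) & _threshold_base(img, b, local_block_size)
    return _threshold_base(img, spec, local_block_size)


def merge_intensity_lifetime(fg: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """Left-merge intersection: intensity foreground pruned by the gate."""
    if fg.shape != gate.shape:
        raise DimensionError(f"shape mismatch {fg.shape} vs {gate.shape}")
    return fg & gate


def label_rois(mask: np.ndarray, canny_sigma: float = 1.0, connectivity: int = 8) -> np.ndarray:
    """Close region boundaries with a Canny edge map and label components.

    The Canny contour of each region closes its boundary, so any interior
    enclosed by mask + edges is filled (recovering e.g. gate-noise holes in
    a nucleus); stray edge pixels outside the mask are then discarded so
    edges never bridge nearby regions.  What remains is labelled 1..K by
    4- or 8-connected flood fill.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    conn = 1 if connectivity == 4 else 2
    edges = feature.canny(mask.astype(float), sigma=canny_sigma)
    closed = ndimage.binary_fill_holes(mask | edges)
    work = closed & ~(edges & ~mask)
    labels = cc_label(work, connectivity=conn)
    return relabel_sequential(labels)[0].astype(np.int32)


def _expand_labels_mode(labels: np.ndarray, mode: str, radius: int) -> np.ndarray:
    """Label-aware region expansion; regions never absorb each other's pixels."""
    if radius <= 0:
        return labels
    if mode == "dilate":
        return expand_labels(labels, distance=radius)
    if mode == "close":
        closed = morphology.closing(labels > 0, morphology.disk(radius))
        grown = expand_labels(labels, distance=2 * radius + 2)
        return np.where(closed, grown, 0)
    raise ConfigError(f"unknown expansion mode {mode!r}")


def _area_filter(labels: np.ndarray, min_area: int) -> np.ndarray:
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    kill = np.flatnonzero(areas < min_area)
    out = labels.copy()
    out[np.isin(out, kill[kill > 0])] = 0
    return relabel_sequential(out)[0].astype(np.int32)


def refine_rois(labels: np.ndarray, cfg: SegmentationConfig, expansion_mode: str = "dilate") -> np.ndarray:
    """Morphological refinement: expand, clear border, relabel, expand, filter.

    Stage order: round-1 expansion (``struct_radius_1``), border clearing
    (any region touching the frame is dropped in full), boundary
    recomputation/relabelling, round-2 expansion (``struct_radius_2``), then
    the small-object area filter.  Expansions are label-aware throughout.
    """
    labels = np.asarray(labels)
    out = _expand_labels_mode(labels, expansion_mode, cfg.struct_radius_1)
    out = clear_border(out)
    out = relabel_sequential(out)[0]
    out = _expand_labels_mode(out, expansion_mode, cfg.struct_radius_2)
    out = _area_filter(out.astype(np.int32), cfg.min_area)
    return out


def run_variant(
    intensity: np.ndarray,
    lifetime: np.ndarray,
    variant: tuple[str, str],
    cfg: SegmentationConfig,
    _gate: np.ndarray | None = None,
    _threshold_cache: dict | None = None,
) -> EnsembleCandidate:
    """Run gate -> threshold -> merge -> label -> refine for one variant.

    A degenerate threshold (constant image, no histogram valley) yields an
    empty candidate rather than aborting the ensemble; the event is logged.
    """
    thr_spec, expansion_mode = variant
    if intensity.shape != lifetime.shape:
        raise DimensionError("intensity and lifetime shapes differ")
    stage = "gate"
    try:
        gate = _gate if _gate is not None else gate_lifetime(lifetime, cfg.gate_low, cfg.gate_high)
        stage = "threshold"
        try:
            if _threshold_cache is not None and thr_spec in _threshold_cache:
                fg = _threshold_cache[thr_spec]
            else:
                fg = threshold_intensity(intensity, thr_spec, cfg.local_block_size)
                if _threshold_cache is not None:
                    _threshold_cache[thr_spec] = fg
        except DegenerateImageError as exc:
            logger.warning("variant %s: degenerate threshold (%s); empty foreground", variant, exc)
            fg = np.zeros(intensity.shape, dtype=bool)
        stage = "merge"
        merged = merge_intensity_lifetime(fg, gate)
        stage = "label"
        labels = label_rois(merged, cfg.canny_sigma, cfg.connectivity)
        stage = "refine"
        refined = refine_rois(labels, cfg, expansion_mode)
    except FlimcyteError:
        raise
    except Exception as exc:  # pragma: no cover - defensive stage tagging
        raise FlimcyteError(f"segmentation stage {stage!r} failed for {variant}: {exc}") from exc
    return EnsembleCandidate(variant_id=variant, mask=refined)


# ---------------------------------------------------------------------------
# mask metrics and ensemble voting
# ---------------------------------------------------------------------------

def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` of two binary masks."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise UndefinedDiceError("Dice of two empty masks is undefined")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _dice_for_selection(candidate: np.ndarray, truth: np.ndarray) -> float:
    """Dice used inside voting: agreement of two empty masks counts as 1."""
    try:
        return dice_coefficient(candidate, truth)
    except UndefinedDiceError:
        return 1.0


def ensemble_select(
    candidates: list[EnsembleCandidate],
    truth: np.ndarray | None = None,
    mode: str = "per_image_argmax",
    calibrated_variant: tuple[str, str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pick the winning candidate mask.

    ``per_image_argmax`` scores every candidate against ``truth`` and takes
    the maximiser (ties go to the earlier variant; logged).  In
    ``global_calibration`` mode a variant id previously chosen by
    :func:`calibrate_variant` is applied, so no truth is needed here.

    Returns the winning label mask and a report with one row per variant.
    """
    if not candidates:
        raise EmptyEnsembleError("no candidates to select from")
    rows = []
    if mode == "per_image_argmax":
        if truth is None:
            raise MissingTruthError("per_image_argmax voting requires a ground-truth mask")
        best_idx, best_dice = 0, -1.0
        for i, cand in enumerate(candidates):
            d = _dice_for_selection(cand.mask, truth)
            cand.dice_vs_truth = d
            rows.append({"variant_id": "/".join(cand.variant_id),
                         "variant_threshold": cand.variant_id[0],
                         "variant_expansion": cand.variant_id[1], "dice": d})
            if d > best_dice:
                best_idx, best_dice = i, d
            elif d == best_dice:
                logger.debug("dice tie at %.4f; keeping earlier variant %s",
                             d, candidates[best_idx].variant_id)
        report = pd.DataFrame(rows)
        report["selected"] = [i == best_idx for i in range(len(candidates))]
        return candidates[best_idx].mask, report
    if mode == "global_calibration":
        if calibrated_variant is None:
            raise ConfigError("global_calibration mode needs a calibrated variant id")
        chosen = None
        for cand in candidates:
            d = _dice_for_selection(cand.mask, truth) if truth is not None else np.nan
            cand.dice_vs_truth = d if truth is not None else None
            rows.append({"variant_id": "/".join(cand.variant_id),
                         "variant_threshold": cand.variant_id[0],
                         "variant_expansion": cand.variant_id[1], "dice": d})
            if tuple(cand.variant_id) == tuple(calibrated_variant):
                chosen = cand
        if chosen is None:
            raise ConfigError(f"calibrated variant {calibrated_variant} not among candidates")
        report = pd.DataFrame(rows)
        report["selected"] = [tuple(c.variant_id) == tuple(calibrated_variant) for c in candidates]
        return chosen.mask, report
    raise ConfigError(f"unknown voting mode {mode!r}")


def calibrate_variant(dice_table: pd.DataFrame) -> tuple[str, str]:
    """Pick the variant with the highest mean Dice over a calibration set.

    ``dice_table`` needs columns ``image_id``, ``variant_threshold``,
    ``variant_expansion``, ``dice``.  Ties break toward the variant that
    appears first in the table.
    """
    means = (
        dice_table.groupby(["variant_threshold", "variant_expansion"], sort=False)["dice"]
        .mean()
    )
    return tuple(means.idxmax())


def segment_image(
    intensity: np.ndarray,
    lifetime: np.ndarray,
    cfg: SegmentationConfig | None = None,
    truth: np.ndarray | None = None,
    calibrated_variant: tuple[str, str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Run the full ensemble on one image and return (best mask, report)."""
    cfg = cfg or SegmentationConfig()
    gate = gate_lifetime(lifetime, cfg.gate_low, cfg.gate_high)
    cache: dict[str, np.ndarray] = {}
    candidates = [
        run_variant(intensity, lifetime, v, cfg, _gate=gate, _threshold_cache=cache)
        for v in cfg.variants()
    ]
    return ensemble_select(
        candidates, truth=truth, mode=cfg.voting_mode, calibrated_variant=calibrated_variant
    )


def segment_tumor_cells(
    intensity: np.ndarray,
    cfg: SegmentationConfig | None = None,
    method: str = "otsu",
) -> np.ndarray:
    """Plain threshold + label path for unlabelled (NAD(P)H-bright) cells.

    Tumour cells carry no mCherry reporter and no lifetime gate applies, so
    this is a single threshold, component labelling and area filter — no
    ensemble, no voting.  Border regions are kept (tumour cells tile the
    field of view).
    """
    cfg = cfg or SegmentationConfig()
    try:
        fg = threshold_intensity(intensity, method, cfg.local_block_size)
    except DegenerateImageError:
        return np.zeros(intensity.shape, dtype=np.int32)
    labels = label_rois(fg, cfg.canny_sigma, cfg.connectivity)
    return _area_filter(labels, cfg.min_area)


# ---------------------------------------------------------------------------
# dilation-sensitivity validation
# ---------------------------------------------------------------------------

def _mw_p(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return np.nan
    if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)


def dilation_sensitivity(
    mask: np.ndarray,
    channel_maps: dict,
    intensity_images: dict,
    radii: tuple[int, ...] = (1, 2, 3),
    features_config=None,
) -> pd.DataFrame:
    """Check that cell masks are insensitive to small dilations.

    For each radius the mask is expanded (label-aware), per-cell OMI
    parameters are re-extracted from the *same* fitted maps, and each
    intensity/lifetime parameter is compared against the original masks with
    a two-sided Mann–Whitney test.  Cell size is excluded: it grows with the
    mask by construction and says nothing about parameter stability.

    Returns a tidy frame with columns ``radius``, ``parameter``, ``p_value``.
    """
    from .features import LIFETIME_PARAMETERS, extract_cell_features

    mask = np.asarray(mask)
    if mask.max() == 0:
        return pd.DataFrame(columns=["radius", "parameter", "p_value"])
    params = list(LIFETIME_PARAMETERS) + ["redox_ratio"]
    base = extract_cell_features(mask, channel_maps, intensity_images, config=features_config)
    rows = []
    for r in radii:
        dil = expand_labels(mask, distance=r) if r > 0 else mask
        tab = extract_cell_features(dil, channel_maps, intensity_images, config=features_config)
        for p in params:
            rows.append({
                "radius": r,
                "parameter": p,
                "p_value": _mw_p(base[p].to_numpy(), tab[p].to_numpy()),
            })
    return pd.DataFrame(rows)
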