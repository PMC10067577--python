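"""Synthetic multiphoton FLIM scenes with known ground truth.

The generator emulates the content of an intravital three-channel
acquisition: mCherry-labelled immune cells whose *nuclei* fluoresce in the
red channel with a near mono-exponential lifetime in the 1300–1500 ps band,
cytoplasmic NAD(P)H/FAD autofluorescence with two-component decays filling
the whole cell, non-specific red distractor blobs whose lifetimes fall
outside the 800–1500 ps segmentation gate, and a flat Poisson background.
Every photon count in every cube is a Poisson draw around the deterministic
expected decay of :func:`flimcyte.decay.biexp_forward`, so the full analysis
chain (fit → segment → features → stats) can be validated against the truth
tables the generator writes.

Cell populations are parameterised by the *drawn* quantities (per-channel
mean lifetime τm, weight α1 and short lifetime τ1; redox ratio; cell area);
the long lifetime is derived as τ2 = (τm − α1 τ1)/(1 − α1) so that
between-tissue effects can be injected directly in control-SD units of τm,
which is how the two-population dataset generator specifies its contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decay import Channel, InstrumentResponse, biexp_decay
from .exceptions import ConfigError, PackingError
from .maps import estimate_lifetime_com

__all__ = [
    "PopulationSpec",
    "SceneSpec",
    "TissueEffects",
    "DatasetSpec",
    "GroundTruth",
    "Scene",
    "generate_scene",
    "generate_dataset",
    "DEFAULT_IRF",
]

#: Default instrument response: 250 ps FWHM Gaussian, centred 488 ps into the window.
DEFAULT_IRF = InstrumentResponse(center=488.0, fwhm=250.0)

ALL_CHANNELS = ("nadph", "fad", "mcherry")


@dataclass(frozen=True)
class PopulationSpec:
    """Per-cell parameter distributions for one cell population.

    Each ``(mean, sd)`` pair is a normal distribution truncated to its
    physical domain.  Defaults describe spleen-resident mCherry+ immune
    cells: NAD(P)H τm 734 ps, FAD τm 554 ps, FAD α1 85 %, ~95 px cells.
    """

    nadph_tau_m: tuple[float, float] = (734.0, 125.0)
    nadph_alpha1: tuple[float, float] = (0.80, 0.010)
    nadph_tau1: tuple[float, float] = (380.0, 30.0)
    fad_tau_m: tuple[float, float] = (554.0, 129.0)
    fad_alpha1: tuple[float, float] = (0.85, 0.0125)
    fad_tau1: tuple[float, float] = (230.0, 15.0)
    mcherry_tau_range: tuple[float, float] = (1300.0, 1500.0)
    redox: tuple[float, float] = (0.60, 0.019)
    cell_area: tuple[float, float] = (95.0, 12.0)
    axis_ratio_max: float = 2.0
    nucleus_fraction: float = 0.65  # linear scale of the nucleus ellipse


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one field of view."""

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 10
    n_distractors: int = 5
    population: PopulationSpec = field(default_factory=PopulationSpec)
    photons_per_cell: float = 5000.0          # mCherry photons per nucleus
    autofl_photons_per_cell: float = 10_000.0  # NAD(P)H + FAD photons per cell
    distractor_photons: float = 2500.0
    distractor_area: tuple[float, float] = (30.0, 120.0)
    distractor_tau_ranges: tuple[tuple[float, float], ...] = ((300.0, 600.0), (1800.0, 2500.0))
    background_rate: dict = field(
        default_factory=lambda: {"mcherry": 2.0, "nadph": 5.0, "fad": 4.0}
    )
    background_tau: dict = field(
        default_factory=lambda: {"mcherry": 500.0, "nadph": 1500.0, "fad": 1000.0}
    )
    bin_width: float = 48.8
    n_bins: int = 256
    margin: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0 or self.n_distractors < 0:
            raise ConfigError("counts must be >= 0")
        for rate in self.background_rate.values():
            if rate < 0:
                raise ConfigError("background rates must be >= 0")


@dataclass
class GroundTruth:
    """Known answers for one scene: masks and the per-cell parameter table."""

    mask: np.ndarray               # uint16 labels for immune cells
    distractor_mask: np.ndarray    # bool
    cells: pd.DataFrame            # one row per label with the true parameters


@dataclass
class Scene:
    spec: SceneSpec
    cubes: dict                    # channel -> (T, Y, X) uint16
    intensity: dict                # channel -> (Y, X) float
    lifetime: np.ndarray           # fast mCherry mean-lifetime map (ps)
    truth: GroundTruth
    irf: InstrumentResponse


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse_pixels(shape, cy, cx, a, b, theta):
    """Row/col indices inside a rotated ellipse (axes a, b; radians theta)."""
    h, w = shape
    r = int(math.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _place_ellipses(rng, shape, n, areas, axis_ratio_max, margin, occupied, max_tries=400):
    """Rejection-sample n non-overlapping rotated ellipses.

    ``occupied`` is a bool scratch image shared across calls so distractors
    also avoid cells.  Returns a list of (cy, cx, a, b, theta).
    """
    h, w = shape
    placed = []
    for i in range(n):
        area = areas[i]
        q = rng.uniform(1.0, axis_ratio_max)
        a = math.sqrt(area * q / math.pi)
        b = math.sqrt(area / (math.pi * q))
        theta = rng.uniform(0.0, math.pi)
        rmax = max(a, b)
        lo, hi_y, hi_x = margin + rmax, h - margin - rmax, w - margin - rmax
        if hi_y <= lo or hi_x <= lo:
            raise PackingError(f"image {shape} too small for cells of radius {rmax:.1f}")
        for _ in range(max_tries):
            cy = rng.uniform(lo, hi_y)
            cx = rng.uniform(lo, hi_x)
            ys, xs = _ellipse_pixels(shape, cy, cx, a + 2.0, b + 2.0, theta)
            if not occupied[ys, xs].any():
                inner = _ellipse_pixels(shape, cy, cx, a, b, theta)
                occupied[inner] = True
                placed.append((cy, cx, a, b, theta))
                break
        else:
            raise PackingError(
                f"could not place ellipse {i + 1}/{n} after {max_tries} tries"
            )
    return placed


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _draw_cell_params(rng, pop: PopulationSpec) -> dict:
    """Draw one cell's true decay parameters; τ2 derived from (τm, α1, τ1)."""
    out = {}
    for ch, (tau_m_d, alpha1_d, tau1_d) in (
        ("nadph", (pop.nadph_tau_m, pop.nadph_alpha1, pop.nadph_tau1)),
        ("fad", (pop.fad_tau_m, pop.fad_alpha1, pop.fad_tau1)),
    ):
        a1 = float(_truncated_normal(rng, *alpha1_d, 0.02, 0.98))
        t1 = float(_truncated_normal(rng, *tau1_d, 30.0, 5000.0))
        tm = float(_truncated_normal(rng, *tau_m_d, 50.0, 8000.0))
        t2 = (tm - a1 * t1) / (1.0 - a1)
        t2 = max(t2, t1 + 100.0)  # keep ordering in pathological tails
        tm = a1 * t1 + (1.0 - a1) * t2  # re-derive if t2 was clamped
        out[f"{ch}_tau1"] = t1
        out[f"{ch}_tau2"] = t2
        out[f"{ch}_alpha1"] = a1
        out[f"{ch}_alpha2"] = 1.0 - a1
        out[f"{ch}_tau_m"] = tm
    out["mcherry_tau"] = float(rng.uniform(*pop.mcherry_tau_range))
    out["redox_ratio"] = float(_truncated_normal(rng, *pop.redox, 0.02, 0.98))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _decay_shape(t, kernel, n_bins, tau1, tau2, alpha1):
    """Unit-sum expected decay: bi-exponential convolved with the IRF kernel."""
    pure = biexp_decay(t, tau1, tau2, alpha1)
    m = np.convolve(kernel, pure)[:n_bins]
    return m / m.sum()


def generate_scene(spec: SceneSpec, channels=ALL_CHANNELS, irf: InstrumentResponse | None = None,
                   seed: int | None = None) -> Scene:
    """Render one field of view.

    Parameters
    ----------
    channels
        Which decay cubes to materialise; the truth table always carries all
        channels' parameters.  Restricting to ``("mcherry",)`` makes
        segmentation-only studies several times cheaper.
    seed
        Overrides ``spec.seed`` when given.  Identical seeds give
        bit-identical scenes.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    irf = irf or DEFAULT_IRF
    h, w = spec.shape
    n_bins, bw = spec.n_bins, spec.bin_width
    t = (np.arange(n_bins) + 0.5) * bw
    kernel = irf.kernel(bw, n_bins)
    pop = spec.population

    # --- geometry ---------------------------------------------------------
    occupied = np.zeros(spec.shape, dtype=bool)
    areas = _truncated_normal(rng, *pop.cell_area, 40.0, None, size=spec.n_cells)
    cells = _place_ellipses(rng, spec.shape, spec.n_cells, areas,
                            pop.axis_ratio_max, spec.margin, occupied)
    d_areas = rng.uniform(*spec.distractor_area, size=spec.n_distractors)
    distractors = _place_ellipses(rng, spec.shape, spec.n_distractors, d_areas,
                                  pop.axis_ratio_max, spec.margin, occupied)

    mask = np.zeros(spec.shape, dtype=np.uint16)
    nuclei: list[tuple[np.ndarray, np.ndarray]] = []
    for lab, (cy, cx, a, b, theta) in enumerate(cells, start=1):
        ys, xs = _ellipse_pixels(spec.shape, cy, cx, a, b, theta)
        mask[ys, xs] = lab
        nf = pop.nucleus_fraction
        nys, nxs = _ellipse_pixels(spec.shape, cy, cx, max(a * nf, 1.2), max(b * nf, 1.2), theta)
        nuclei.append((nys, nxs))

    distractor_mask = np.zeros(spec.shape, dtype=bool)
    d_taus = []
    for (cy, cx, a, b, theta) in distractors:
        ys, xs = _ellipse_pixels(spec.shape, cy, cx, a, b, theta)
        distractor_mask[ys, xs] = True
        lo, hi = spec.distractor_tau_ranges[rng.integers(len(spec.distractor_tau_ranges))]
        d_taus.append((ys, xs, float(rng.uniform(lo, hi))))

    # --- true parameters --------------------------------------------------
    records = []
    for lab in range(1, spec.n_cells + 1):
        p = _draw_cell_params(rng, pop)
        p["cell_id"] = lab
        p["cell_size"] = int((mask == lab).sum())
        records.append(p)
    truth_cols = (
        ["cell_id", "cell_size", "mcherry_tau", "redox_ratio"]
        + [f"{ch}_{q}" for ch in ("nadph", "fad") for q in ("tau1", "tau2", "alpha1", "alpha2", "tau_m")]
    )
    cells_df = pd.DataFrame(records)
    cells_df = cells_df[truth_cols] if len(cells_df) else pd.DataFrame(columns=truth_cols)

    # --- expected photon rates and Poisson draws --------------------------
    cubes: dict[str, np.ndarray] = {}
    for ch in channels:
        lam = np.empty((n_bins, h, w), dtype=np.float64)
        bg_rate = spec.background_rate.get(ch, 0.0)
        bg_shape = _decay_shape(t, kernel, n_bins, spec.background_tau[ch],
                                spec.background_tau[ch], 1.0)
        lam[:] = (bg_rate * bg_shape)[:, None, None]

        if ch == "mcherry":
            for (nys, nxs), rec in zip(nuclei, records):
                if nys.size == 0:
                    continue
                shape_k = _decay_shape(t, kernel, n_bins, rec["mcherry_tau"],
                                       rec["mcherry_tau"], 1.0)
                per_px = spec.photons_per_cell / nys.size
                lam[:, nys, nxs] += per_px * shape_k[:, None]
            for ys, xs, tau in d_taus:
                if ys.size == 0:
                    continue
                shape_k = _decay_shape(t, kernel, n_bins, tau, tau, 1.0)
                lam[:, ys, xs] += (spec.distractor_photons / ys.size) * shape_k[:, None]
        else:
            for lab, rec in enumerate(records, start=1):
                ys, xs = np.nonzero(mask == lab)
                if ys.size == 0:
                    continue
                r = rec["redox_ratio"]
                budget = spec.autofl_photons_per_cell * (r if ch == "nadph" else 1.0 - r)
                shape_k = _decay_shape(t, kernel, n_bins, rec[f"{ch}_tau1"],
                                       rec[f"{ch}_tau2"], rec[f"{ch}_alpha1"])
                lam[:, ys, xs] += (budget / ys.size) * shape_k[:, None]

        cubes[ch] = rng.poisson(lam).astype(np.uint16)

    intensity = {ch: cubes[ch].sum(axis=0).astype(np.float64) for ch in cubes}
    if "mcherry" in cubes:
        lifetime = estimate_lifetime_com(cubes["mcherry"], bw, irf=irf)
    else:
        lifetime = np.full(spec.shape, np.nan, dtype=np.float32)

    truth = GroundTruth(mask=mask, distractor_mask=distractor_mask, cells=cells_df)
    return Scene(spec=spec, cubes=cubes, intensity=intensity,
                 lifetime=lifetime, truth=truth, irf=irf)


# ---------------------------------------------------------------------------
# two-population datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueEffects:
    """Tumour-vs-spleen contrasts, in spleen (control) SD units.

    Defaults reproduce the reported immune-cell shifts — FAD τm down 1.5 SD
    (554 → ~361 ps), FAD α1 up 4 SD (85 → 90 %), NAD(P)H τm down 0.54 SD
    (734 → ~667 ps), cells 1.5× larger — plus coherent shifts on the
    unprinted parameters (a glycolytic increase of the free-NAD(P)H
    fraction, a bound-FAD lifetime decrease, a redox-ratio decrease) so the
    two populations are, in aggregate, as cleanly separable by tissue as
    the reported single-cell heatmaps.
    """

    fad_tau_m: float = -1.5
    fad_alpha1: float = +4.0
    fad_tau1: float = -2.0
    nadph_tau_m: float = -0.5366
    nadph_alpha1: float = +4.0
    redox: float = -4.0
    size_ratio: float = 1.5

    @classmethod
    def null(cls) -> "TissueEffects":
        """No contrast at all (for null-recovery studies)."""
        return cls(fad_tau_m=0.0, fad_alpha1=0.0, fad_tau1=0.0,
                   nadph_tau_m=0.0, nadph_alpha1=0.0, redox=0.0, size_ratio=1.0)


@dataclass(frozen=True)
class DatasetSpec:
    """Spleen-like vs tumour-like scene collections with built-in contrasts."""

    base_population: PopulationSpec = field(default_factory=PopulationSpec)
    effects: TissueEffects = field(default_factory=TissueEffects)
    n_cells_per_tissue: int = 100
    cells_per_scene: int = 10
    shape: tuple[int, int] = (256, 256)
    n_mice: int = 2
    seed: int = 0


def _shift(dist: tuple[float, float], sd_units: float) -> tuple[float, float]:
    mean, sd = dist
    return (mean + sd_units * sd, sd)


def tumor_population(base: PopulationSpec, eff: TissueEffects) -> PopulationSpec:
    """Apply the tissue contrasts to a spleen-like baseline population."""
    area_mean, area_sd = base.cell_area
    return replace(
        base,
        fad_tau_m=_shift(base.fad_tau_m, eff.fad_tau_m),
        fad_alpha1=_shift(base.fad_alpha1, eff.fad_alpha1),
        fad_tau1=_shift(base.fad_tau1, eff.fad_tau1),
        nadph_tau_m=_shift(base.nadph_tau_m, eff.nadph_tau_m),
        nadph_alpha1=_shift(base.nadph_alpha1, eff.nadph_alpha1),
        redox=_shift(base.redox, eff.redox),
        cell_area=(area_mean * eff.size_ratio, area_sd * eff.size_ratio),
    )


def generate_dataset(spec: DatasetSpec, render: bool = False, channels=ALL_CHANNELS):
    """Two labelled cell populations ("spleen" vs "tumor") with known contrasts.

    Returns ``(table, scenes)``: a feature-schema-compatible truth table with
    ``tissue``, ``mouse_id`` and ``fov_id`` metadata, and — when ``render``
    is true — the list of rendered :class:`Scene` objects (tissue recorded
    on each scene's truth table).  Without rendering, the table carries the
    *drawn* per-cell parameters, which is what the statistics-recovery
    studies consume; ``cell_size`` is then the drawn continuous area.
    """
    rng = np.random.default_rng(spec.seed)
    pops = {
        "spleen": spec.base_population,
        "tumor": tumor_population(spec.base_population, spec.effects),
    }
    rows = []
    scenes = []
    for tissue, pop in pops.items():
        n = spec.n_cells_per_tissue
        if render:
            n_scenes = math.ceil(n / spec.cells_per_scene)
            made = 0
            for s in range(n_scenes):
                n_here = min(spec.cells_per_scene, n - made)
                sc_spec = SceneSpec(shape=spec.shape, n_cells=n_here,
                                    population=pop,
                                    seed=int(rng.integers(2**31 - 1)))
                scene = generate_scene(sc_spec, channels=channels)
                df = scene.truth.cells.copy()
                df["tissue"] = tissue
                df["fov_id"] = f"{tissue}_fov{s}"
                df["mouse_id"] = f"m{s % spec.n_mice}"
                df["cell_type"] = "immune"
                scenes.append(scene)
                rows.append(df)
                made += n_here
        else:
            for s in range(math.ceil(n / spec.cells_per_scene)):
                n_here = min(spec.cells_per_scene, n - s * spec.cells_per_scene)
                for c in range(n_here):
                    p = _draw_cell_params(rng, pop)
                    p["cell_size"] = float(
                        _truncated_normal(rng, *pop.cell_area, 40.0, None)
                    )
                    p["tissue"] = tissue
                    p["fov_id"] = f"{tissue}_fov{s}"
                    p["cell_id"] = c + 1
                    p["mouse_id"] = f"m{s % spec.n_mice}"
                    p["cell_type"] = "immune"
                    rows.append(pd.DataFrame([p]))
    table = pd.concat(rows, ignore_index=True)
    return table, (scenes if render else None)
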