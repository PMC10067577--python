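"""Per-pixel lifetime maps from decay cubes.

A decay cube is a (time, y, x) array of photon counts for one channel.  Two
estimators operate on it:

``fit_cube``
    Runs the full bi-exponential fit (:mod:`flimcyte.fitting`) pixel by
    pixel, optionally after an odd-sized moving-window spatial binning that
    pools neighbouring photons into each pixel's histogram (the standard
    TCSPC trick for starved pixels).  Pixels under the photon floor become
    NaN in every output map.

``estimate_lifetime_com``
    A fast mean-arrival-time estimator (histogram centre of mass minus the
    IRF centroid).  For a near mono-exponential emitter such as nuclear
    mCherry this is an unbiased estimate of the lifetime at a tiny fraction
    of the cost of a full fit, which is why the segmentation gate uses it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .decay import Channel, DecayHistogram, InstrumentResponse
from .exceptions import DimensionError, InvalidParameterError, LowSignalError, ConvergenceError
from .fitting import BiexpDecayModel, FitConfig

__all__ = ["FitMaps", "fit_cube", "estimate_lifetime_com", "spatial_bin"]

MAP_NAMES = ("tau1", "tau2", "alpha1", "alpha2", "tau_m", "chi_sq", "photons")


@dataclass
class FitMaps:
    """Per-parameter 2-D float maps; NaN marks unfitted pixels."""

    tau1: np.ndarray
    tau2: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    tau_m: np.ndarray
    chi_sq: np.ndarray
    photons: np.ndarray
    channel: Channel | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in MAP_NAMES}


def spatial_bin(cube: np.ndarray, binning: int) -> np.ndarray:
    """Moving-window photon pooling: each pixel's histogram becomes the sum
    over its ``binning x binning`` neighbourhood (odd ``binning``; 1 = none)."""
    if binning == 1:
        return cube
    if binning < 1 or binning % 2 == 0:
        raise InvalidParameterError(f"binning must be odd and >= 1, got {binning}")
    out = uniform_filter(cube.astype(float), size=(1, binning, binning), mode="constant")
    return out * (binning * binning)


def fit_cube(
    cube: np.ndarray,
    bin_width: float,
    irf: InstrumentResponse | None = None,
    config: FitConfig | None = None,
    binning: int = 1,
    mask: np.ndarray | None = None,
    channel: Channel | None = None,
) -> FitMaps:
    """Fit every (masked) pixel of a decay cube.

    Parameters
    ----------
    cube : (T, Y, X) array
        Photon counts per time bin and pixel.
    mask : (Y, X) bool array, optional
        Restrict fitting to these pixels (e.g. a dilated union of candidate
        cells) — everything else stays NaN.  The ``photons`` map is always
        the *unbinned* per-pixel photon sum, so downstream photon-weighted
        aggregation is unaffected by binning.
    binning : int
        Odd moving-window size for photon pooling before fitting.
    """
    if cube.ndim != 3:
        raise DimensionError(f"decay cube must be (T, Y, X), got shape {cube.shape}")
    cfg = config or FitConfig()
    t_, h, w = cube.shape
    if mask is not None and mask.shape != (h, w):
        raise DimensionError("mask shape does not match cube")

    photons = cube.sum(axis=0).astype(float)
    binned = spatial_bin(cube, binning)
    maps = {name: np.full((h, w), np.nan, dtype=np.float32) for name in MAP_NAMES}
    maps["photons"] = photons.astype(np.float32)

    if irf is None:
        # estimate the IRF centre once from the brightest pixel's rising edge
        iy, ix = np.unravel_index(np.argmax(photons), photons.shape)
        ref = DecayHistogram(np.maximum(binned[:, iy, ix], 0), bin_width, channel)
        irf = InstrumentResponse(center=BiexpDecayModel(ref)._rising_edge(), fwhm=250.0)

    candidates = np.argwhere(mask) if mask is not None else np.argwhere(np.ones((h, w), bool))
    for iy, ix in candidates:
        counts = binned[:, iy, ix]
        if counts.sum() < cfg.min_photons:
            continue
        decay = DecayHistogram(np.maximum(counts, 0.0), bin_width, channel)
        try:
            res = BiexpDecayModel(decay, irf=irf, config=cfg).fit()
        except (LowSignalError, ConvergenceError):
            continue
        maps["tau1"][iy, ix] = res.tau1
        maps["tau2"][iy, ix] = res.tau2
        maps["alpha1"][iy, ix] = res.alpha1
        maps["alpha2"][iy, ix] = res.alpha2
        maps["tau_m"][iy, ix] = res.tau_m
        maps["chi_sq"][iy, ix] = res.chi_sq_reduced
    return FitMaps(channel=channel, **maps)


def estimate_lifetime_com(
    cube: np.ndarray,
    bin_width: float,
    irf: InstrumentResponse | None = None,
    min_photons: float = 20.0,
    smooth: bool = True,
) -> np.ndarray:
    """Fast per-pixel mean lifetime from the decay centre of mass.

    ``tau_hat = sum(c_k t_k)/sum(c_k) - irf_centroid``.  With ``smooth``
    (default) a photon-weighted 3x3 average is applied first, trading ~1.5 px
    of spatial resolution for a three-fold reduction in shot noise — at the
    ~100 photons/pixel typical of nuclear mCherry this keeps the estimate
    inside a 100 ps band.  Pixels with fewer than ``min_photons`` photons
    (after smoothing) are NaN.
    """
    if cube.ndim != 3:
        raise DimensionError(f"decay cube must be (T, Y, X), got shape {cube.shape}")
    n_bins = cube.shape[0]
    t = (np.arange(n_bins) + 0.5) * bin_width
    photons = cube.sum(axis=0).astype(float)
    first_moment = np.tensordot(t, cube.astype(float), axes=(0, 0))
    if smooth:
        photons_s = uniform_filter(photons, size=3, mode="constant") * 9.0
        first_moment = uniform_filter(first_moment, size=3, mode="constant") * 9.0
        photons_eff = photons_s
    else:
        photons_eff = photons
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = first_moment / photons_eff
    if irf is not None:
        tau = tau - irf.centroid(bin_width, n_bins)
    tau[photons_eff < min_photons] = np.nan
    tau[tau <= 0] = np.nan
    return tau.astype(np.float32)
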