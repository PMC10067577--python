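"""Time-domain decay model for optical metabolic imaging.

Time-correlated single photon counting (TCSPC) builds, for every pixel, a
histogram of photon arrival times.  The fluorescence of the metabolic
coenzymes NAD(P)H and FAD decays as a mixture of a short- and a long-lived
component (free vs. protein-bound states), so the measured signal is modelled
as a bi-exponential

    I(t) = alpha1 * exp(-t / tau1) + alpha2 * exp(-t / tau2) + C,

convolved with the instrument response function (IRF) of the microscope.
``tau1`` is always the short component: for NAD(P)H it is the *free*
coenzyme's lifetime, for FAD it is the *protein-bound* lifetime, and the
weights ``alpha1 + alpha2 = 1`` give the corresponding fractions.  The
intensity-weighted mean lifetime is ``tau_m = alpha1*tau1 + alpha2*tau2``.

This module holds the data containers, the deterministic forward model and
the closed-form quantities of the experiment (mean lifetime, optical redox
ratio, two-colour two-photon mixing wavelength, caliper tumour volume).
Noise is added elsewhere (:mod:`flimcyte.synthetic`), and estimation lives in
:mod:`flimcyte.fitting`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "Channel",
    "DecayHistogram",
    "InstrumentResponse",
    "biexp_decay",
    "biexp_forward",
    "mean_lifetime",
    "redox_ratio",
    "two_color_wavelength",
    "tumor_volume",
]


class Channel(str, enum.Enum):
    """Detection channel of the three-colour acquisition."""

    NADPH = "nadph"
    FAD = "fad"
    MCHERRY = "mcherry"


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per TCSPC time bin for one pixel (or summed region).

    Parameters
    ----------
    counts
        Non-negative counts per bin.  Measured data is integer; model
        (expected-value) histograms may be fractional.
    bin_width
        Width of one time bin in picoseconds.
    channel
        Which detection channel produced the histogram.
    """

    counts: np.ndarray
    bin_width: float
    channel: Channel | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 8:
            raise InvalidParameterError(
                f"decay histogram needs >= 8 bins, got shape {counts.shape}"
            )
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise InvalidParameterError("decay counts must be finite and >= 0")
        if not self.bin_width > 0:
            raise InvalidParameterError(f"bin_width must be > 0, got {self.bin_width}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())

    @property
    def times(self) -> np.ndarray:
        """Bin-centre times in picoseconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class InstrumentResponse:
    """Temporal blur of the system, as a measured histogram or Gaussian model.

    A measured IRF (e.g. second-harmonic signal from urea crystals) is given
    through ``histogram``; otherwise a Gaussian of width ``fwhm`` centred at
    ``center`` is used.  Either way the kernel is normalised to unit area
    before convolution.
    """

    histogram: DecayHistogram | None = None
    center: float = 0.0
    fwhm: float = 250.0

    def __post_init__(self):
        if self.histogram is None:
            if not self.fwhm > 0:
                raise InvalidParameterError(f"IRF fwhm must be > 0, got {self.fwhm}")
            if self.center < 0:
                raise InvalidParameterError("IRF center must be >= 0 ps")

    def kernel(self, bin_width: float, n_bins: int) -> np.ndarray:
        """Unit-area discrete kernel sampled on the acquisition time grid."""
        if self.histogram is not None:
            k = self.histogram.counts.astype(float)
            total = k.sum()
            if total <= 0:
                raise InvalidParameterError("measured IRF has zero photons")
            return k / total
        t = (np.arange(n_bins) + 0.5) * bin_width
        sigma = self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        if sigma < bin_width / 10.0:  # effectively instantaneous
            k = np.zeros(n_bins)
            k[min(int(self.center / bin_width), n_bins - 1)] = 1.0
            return k
        k = np.exp(-0.5 * ((t - self.center) / sigma) ** 2)
        # keep only the numerically relevant support to bound convolution cost
        k[k < 1e-12 * k.max()] = 0.0
        return k / k.sum()

    def centroid(self, bin_width: float, n_bins: int) -> float:
        """Mean arrival time of the kernel in ps (used by fast estimators)."""
        k = self.kernel(bin_width, n_bins)
        t = (np.arange(k.size) + 0.5) * bin_width
        return float((k * t).sum())

    @classmethod
    def delta(cls) -> "InstrumentResponse":
        """An idealised instantaneous IRF (single-bin kernel)."""
        return cls(fwhm=1e-6, center=0.0)


def biexp_decay(
    t: np.ndarray, tau1: float, tau2: float, alpha1: float
) -> np.ndarray:
    """Evaluate ``alpha1*exp(-t/tau1) + (1-alpha1)*exp(-t/tau2)`` (no offset)."""
    return alpha1 * np.exp(-t / tau1) + (1.0 - alpha1) * np.exp(-t / tau2)


def _check_biexp_params(tau1, tau2, alpha1):
    if not (tau1 > 0 and tau2 > 0):
        raise InvalidParameterError(f"lifetimes must be > 0, got tau1={tau1}, tau2={tau2}")
    if not (0.0 <= alpha1 <= 1.0):
        raise InvalidParameterError(f"alpha1 must be in [0, 1], got {alpha1}")


def biexp_forward(
    tau1: float,
    tau2: float,
    alpha1: float,
    offset_C: float = 0.0,
    irf: InstrumentResponse | None = None,
    bin_width: float = 48.8,
    n_bins: int = 256,
    total_photons: float = 10_000.0,
    channel: Channel | None = None,
) -> DecayHistogram:
    """Deterministic expected decay histogram for one emitter population.

    The pure bi-exponential is sampled at bin centres, discretely convolved
    with the unit-area IRF kernel, the constant offset ``offset_C`` is added,
    and the whole histogram is rescaled so its expected photon sum equals
    ``total_photons``.  Shot noise is applied downstream by the scene
    generator, never here.

    Parameters
    ----------
    tau1, tau2 : float
        Component lifetimes in ps (order free; the fitter, not the forward
        model, enforces the short/long convention).
    alpha1 : float
        Fractional weight of the ``tau1`` component; the other weight is
        ``1 - alpha1``.
    offset_C : float
        Constant background level per bin, in the same (pre-scaling) units as
        the unit-amplitude decay.
    irf : InstrumentResponse, optional
        Defaults to an idealised delta kernel.
    total_photons : float
        Expected photon sum of the returned histogram.

    Returns
    -------
    DecayHistogram
        Expected (fractional) counts per bin.
    """
    _check_biexp_params(tau1, tau2, alpha1)
    if offset_C < 0:
        raise InvalidParameterError(f"offset must be >= 0, got {offset_C}")
    if total_photons < 0:
        raise InvalidParameterError(f"total_photons must be >= 0, got {total_photons}")
    if irf is None:
        irf = InstrumentResponse.delta()

    t = (np.arange(n_bins) + 0.5) * bin_width
    pure = biexp_decay(t, tau1, tau2, alpha1)
    kernel = irf.kernel(bin_width, n_bins)
    model = np.convolve(kernel, pure)[:n_bins] + offset_C
    s = model.sum()
    if s > 0 and total_photons > 0:
        model = model * (total_photons / s)
    elif total_photons == 0:
        model = np.zeros_like(model)
    return DecayHistogram(counts=model, bin_width=bin_width, channel=channel)


def mean_lifetime(alpha1: float, tau1: float, alpha2: float, tau2: float) -> float:
    """Weighted mean lifetime ``tau_m = alpha1*tau1 + alpha2*tau2`` in ps.

    The weights must sum to one (tolerance 1e-9) and both lifetimes must be
    positive.
    """
    if abs(alpha1 + alpha2 - 1.0) > 1e-9:
        raise InvalidParameterError(
            f"alpha1 + alpha2 must equal 1, got {alpha1 + alpha2}"
        )
    if not (tau1 > 0 and tau2 > 0):
        raise InvalidParameterError("lifetimes must be > 0")
    return alpha1 * tau1 + alpha2 * tau2


def redox_ratio(nadph_intensity: float, fad_intensity: float) -> float:
    """Optical redox ratio N / (N + F) in [0, 1].

    N is the NAD(P)H photon intensity and F the FAD intensity.  Raises
    :class:`UndefinedRatioError` when both are zero (the cell is flagged
    rather than given an arbitrary value).
    """
    from .exceptions import UndefinedRatioError

    if nadph_intensity < 0 or fad_intensity < 0:
        raise InvalidParameterError("intensities must be >= 0")
    total = nadph_intensity + fad_intensity
    if total == 0:
        raise UndefinedRatioError("redox ratio undefined: both intensities are zero")
    return nadph_intensity / total


def two_color_wavelength(lambda1: float, lambda2: float) -> float:
    """Two-colour two-photon excitation wavelength from two laser lines.

    Simultaneous absorption of one photon from each line excites at the
    harmonic combination ``2/lambda = 1/lambda1 + 1/lambda2``, i.e.
    ``2*lambda1*lambda2 / (lambda1 + lambda2)`` (nm).  With the 750 nm
    tunable and 1041 nm fixed lines this evaluates to ~872 nm.
    """
    if not (lambda1 > 0 and lambda2 > 0):
        raise InvalidParameterError("wavelengths must be > 0")
    return 2.0 * lambda1 * lambda2 / (lambda1 + lambda2)


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumour volume approximation ``(width^2 * length) / 2`` (mm^3)."""
    if width < 0 or length < 0:
        raise InvalidParameterError("caliper measurements must be >= 0")
    return width * width * length / 2.0
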