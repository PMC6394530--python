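"""Asymmetric double sigmoidal (ADS) desirability functions.

Each physicochemical property's histogram over a set of active compounds is
fitted with the six-parameter ADS curve

    Q(x) = a + b * s((x - c + d/2)/e) * [1 - s((x - c - d/2)/f)]

where ``s`` is the logistic function. With e, f > 0 the first factor is a
rising edge at c - d/2 and the bracket a falling edge at c + d/2, giving a
unimodal, possibly skewed bump of width ~d on a baseline a. The fitted curve
divided by its maximum is the desirability function: 1 at the most typical
property value, decaying toward less typical values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.special import expit

from .errors import FitError

__all__ = [
    "ADSParams", "HistogramSpec", "DesirabilityFunction",
    "evaluate_ads", "build_histogram", "fit_ads",
    "normalize_desirability", "desirability_peak",
]


@dataclass(frozen=True)
class ADSParams:
    """The six coefficients of the ADS curve.

    ``a`` baseline offset, ``b`` amplitude, ``c`` center, ``d`` separation of
    the two logistic inflections, ``e``/``f`` left/right slope scales (both
    strictly positive so the rising edge precedes the falling one).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self):
        if not (self.e > 0 and self.f > 0):
            raise ValueError(f"slope scales must be positive: e={self.e}, f={self.f}")
        for name in ("a", "b", "c", "d", "e", "f"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


def evaluate_ads(x, params: ADSParams):
    """Evaluate the raw ADS curve at ``x`` (scalar or array), numerically stable."""
    a, b, c, d, e, f = params.as_tuple()
    rising = expit((np.asarray(x, dtype=float) - c + d / 2.0) / e)
    falling = expit((np.asarray(x, dtype=float) - c - d / 2.0) / f)
    out = a + b * rising * (1.0 - falling)
    return float(out) if np.isscalar(x) else out


def _ads_curve(x, a, b, c, d, e, f):
    # free-parameter form used by the least-squares fitter
    return a + b * expit((x - c + d / 2.0) / e) * (1.0 - expit((x - c - d / 2.0) / f))


@dataclass(frozen=True)
class HistogramSpec:
    """Binning policy for the per-property histograms.

    ``bin_rule`` is ``"auto"`` (Freedman-Diaconis with a floor of
    ``min_bins`` bins for continuous data, clipped to the
    ``clip_percentiles`` range; unit-width integer-centered bins for count
    data) or ``"fixed"`` (use ``n_bins`` over the full sample range).
    At least ``min_nonempty`` non-empty bins are required for fitting.
    """

    bin_rule: str = "auto"
    n_bins: Optional[int] = None
    min_bins: int = 20
    clip_percentiles: tuple[float, float] = (0.5, 99.5)
    min_nonempty: int = 5

    def __post_init__(self):
        if self.bin_rule not in ("auto", "fixed"):
            raise ValueError(f"unknown bin_rule {self.bin_rule!r}")
        if self.bin_rule == "fixed" and not self.n_bins:
            raise ValueError("bin_rule='fixed' requires n_bins")


def build_histogram(samples: Sequence[float], spec: HistogramSpec = HistogramSpec(),
                    integer_valued: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Histogram ``samples`` into (bin centers, raw counts) per the spec.

    Integer-valued properties get unit-width bins centered on the integers;
    continuous ones use Freedman-Diaconis widths (floored at ``min_bins``
    bins) over the clipped percentile range.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise FitError("no finite samples to histogram")

    if integer_valued and spec.bin_rule == "auto":
        lo, hi = int(np.floor(x.min())), int(np.ceil(x.max()))
        edges = np.arange(lo, hi + 2) - 0.5
    elif spec.bin_rule == "fixed":
        edges = np.histogram_bin_edges(x, bins=spec.n_bins)
    else:
        plo, phi = np.percentile(x, spec.clip_percentiles)
        if phi <= plo:
            raise FitError("degenerate sample range after percentile clipping")
        clipped = x[(x >= plo) & (x <= phi)]
        q75, q25 = np.percentile(clipped, [75, 25])
        iqr = q75 - q25
        fd_width = 2.0 * iqr / max(clipped.size, 1) ** (1.0 / 3.0)
        if fd_width > 0:
            n_bins = max(spec.min_bins, int(np.ceil((phi - plo) / fd_width)))
        else:
            n_bins = spec.min_bins
        edges = np.linspace(plo, phi, n_bins + 1)
        x = clipped
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < spec.min_nonempty:
        raise FitError(
            f"only {np.count_nonzero(counts)} non-empty bins "
            f"(need >= {spec.min_nonempty}) — distribution too narrow to fit"
        )
    return centers, counts.astype(float)


def _initial_guesses(centers: np.ndarray, counts: np.ndarray,
                     samples: np.ndarray) -> list[tuple[float, ...]]:
    # multi-start schedule: modal center, max count amplitude, IQR-scaled widths
    c0 = float(centers[int(np.argmax(counts))])
    b0 = float(counts.max())
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = float(q75 - q25)
    bin_w = float(centers[1] - centers[0]) if centers.size > 1 else 1.0
    if iqr <= 0:
        iqr = max(bin_w, 1.0)
    ef0 = max(iqr / 4.0, bin_w / 2.0, 1e-3)
    return [(0.0, b0, c0, k * iqr, ef0, ef0) for k in (0.5, 1.0, 2.0)]


_LOWER = (-np.inf, 1e-9, -np.inf, 0.0, 1e-6, 1e-6)
_UPPER = (np.inf,) * 6


def fit_ads(samples: Sequence[float], spec: HistogramSpec = HistogramSpec(),
            integer_valued: bool = False, property_name: str = "?") -> ADSParams:
    """Least-squares fit of the ADS curve to a property histogram.

    The fit target is (bin center, raw count) with uniform weights. A small
    deterministic multi-start schedule over the width parameter guards
    against the multimodal parameter surface; the converged fit with the
    lowest residual wins. Raises :class:`FitError` on degenerate samples,
    too few bins, or no convergence.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise FitError(f"{property_name}: need >= 20 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError(f"{property_name}: all samples equal ({x[0]}); cannot fit")
    centers, counts = build_histogram(x, spec, integer_valued=integer_valued)

    best: Optional[tuple[float, np.ndarray]] = None
    for p0 in _initial_guesses(centers, counts, x):
        try:
            with warnings.catch_warnings():
                # only the best-SSR point estimate is used; the parameter
                # covariance (often singular here) is discarded
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _ads_curve, centers, counts, p0=p0,
                    bounds=(_LOWER, _UPPER), method="trf", maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = _ads_curve(centers, *popt) - counts
        ssr = float(resid @ resid)
        if math.isfinite(ssr) and (best is None or ssr < best[0]):
            best = (ssr, popt)
    if best is None:
        raise FitError(f"{property_name}: ADS fit did not converge from any start")
    a, b, c, d, e, f = best[1]
    return ADSParams(a=float(a), b=float(b), c=float(c), d=float(d),
                     e=float(e), f=float(f))


# --- normalization & peak -------------------------------------------------

_COARSE_POINTS = 20001
_FINE_POINTS = 2001
_DOMAIN_PAD = 5.0  # grid extends fit_domain by this multiple of its span each side


def _grid_argmax(params: ADSParams, lo: float, hi: float) -> tuple[float, float]:
    """(argmax, max) of the raw curve over a padded coarse grid + one refinement.

    Ties at equal maxima resolve to the smallest x (first grid hit).
    """
    span = hi - lo
    if span <= 0:
        raise FitError("empty fit domain")
    xs = np.linspace(lo - _DOMAIN_PAD * span, hi + _DOMAIN_PAD * span, _COARSE_POINTS)
    ys = evaluate_ads(xs, params)
    i = int(np.argmax(ys))
    step = xs[1] - xs[0]
    fine = np.linspace(xs[i] - step, xs[i] + step, _FINE_POINTS)
    fy = evaluate_ads(fine, params)
    j = int(np.argmax(fy))
    return float(fine[j]), float(fy[j])


@dataclass(frozen=True)
class DesirabilityFunction:
    """A fitted ADS curve normalized so its maximum over the search grid is 1."""

    params: ADSParams
    norm_max: float
    property_name: str
    fit_domain: tuple[float, float]
    peak: float  # argmax of the curve; may lie outside fit_domain

    def __call__(self, x):
        """Normalized desirability at ``x``: raw curve divided by ``norm_max``."""
        return evaluate_ads(x, self.params) / self.norm_max

    def to_dict(self) -> dict:
        return {
            "a": self.params.a, "b": self.params.b, "c": self.params.c,
            "d": self.params.d, "e": self.params.e, "f": self.params.f,
            "norm_max": self.norm_max, "property": self.property_name,
            "fit_domain": list(self.fit_domain), "peak": self.peak,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesirabilityFunction":
        params = ADSParams(a=d["a"], b=d["b"], c=d["c"],
                           d=d["d"], e=d["e"], f=d["f"])
        return cls(params=params, norm_max=d["norm_max"],
                   property_name=d["property"],
                   fit_domain=tuple(d["fit_domain"]), peak=d["peak"])


def normalize_desirability(params: ADSParams, fit_domain: tuple[float, float],
                           property_name: str = "?") -> DesirabilityFunction:
    """Divide the raw fitted curve by its grid maximum so the peak value is 1.

    The search grid spans the fit domain padded by five spans on each side,
    wide enough to locate peaks well outside the data range (count-like
    properties often peak at negative abscissae).
    """
    peak, norm_max = _grid_argmax(params, *fit_domain)
    if norm_max <= 0:
        raise FitError(f"{property_name}: fitted curve never rises above zero")
    return DesirabilityFunction(params=params, norm_max=norm_max,
                                property_name=property_name,
                                fit_domain=tuple(float(v) for v in fit_domain),
                                peak=peak)


def desirability_peak(fn: DesirabilityFunction) -> float:
    """Location of the desirability maximum (argmax of the fitted curve)."""
    if abs(fn.params.b) < 1e-12:
        raise FitError(f"{fn.property_name}: flat curve (b ~ 0) has no peak")
    return fn.peak
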