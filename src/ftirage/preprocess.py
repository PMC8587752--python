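"""Spectral preprocessing: region cutting, baseline correction, area
normalization and Savitzky-Golay second differentiation.

The stages are pure per-spectrum functions; the pipeline applies them in
the fixed order cut -> baseline -> normalize -> derive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import GridError, NormalizationError, RegionError, SizeError, ValidationError
from .io_spectra import Spectrum, SpectraSet


@dataclass(frozen=True)
class RegionSpec:
    """A closed wavenumber interval [lo, hi] in cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"region {self.name!r}: need lo < hi")


#: The three analysis windows: lipid C-H stretches, the carbonyl/Amide
#: envelope, and the carbohydrate/nucleic-acid fingerprint.
CANONICAL_REGIONS = {
    "lipid": RegionSpec("lipid", 2800.0, 3050.0),
    "amide": RegionSpec("amide", 1500.0, 1800.0),
    "fingerprint": RegionSpec("fingerprint", 900.0, 1200.0),
}


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay second-derivative settings.

    ``window_points`` is the total filter window.  The default 3-point
    window with a quadratic fit is the classic central second difference;
    wider windows trade a little peak-height bias for strong noise
    suppression (white noise passes through a 3-point second difference
    amplified by sqrt(6)/h^2).
    """

    window_points: int = 3
    poly_order: int = 2
    derivative_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points < 3 or self.window_points % 2 == 0:
            raise ValidationError("window_points must be an odd integer >= 3")
        if self.poly_order < 2 or self.poly_order >= self.window_points:
            raise ValidationError("need 2 <= poly_order < window_points")
        if self.derivative_order != 2 or self.derivative_order > self.poly_order:
            raise ValidationError("derivative_order must be 2 and <= poly_order")


def cut_region(spectra_set: SpectraSet, region: RegionSpec) -> SpectraSet:
    """Restrict every spectrum to grid points with lo <= nu <= hi."""
    grid = spectra_set.grid
    if grid is None:
        raise GridError("cut_region requires a common grid")
    mask = (grid >= region.lo) & (grid <= region.hi)
    if not mask.any():
        raise RegionError(
            f"region {region.name!r} [{region.lo}, {region.hi}] does not "
            f"intersect the grid [{grid[0]}, {grid[-1]}]"
        )
    return spectra_set.map(
        lambda s: Spectrum(s.wavenumbers[mask], s.absorbance[mask], s.meta)
    )


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Piecewise-linear lower convex hull of (x, y) evaluated at x.

    Andrew's monotone chain on the lower side; x is strictly increasing
    so no sorting is needed.
    """
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j->i
            if (y[k] - y[j]) * (x[i] - x[j]) >= (y[i] - y[j]) * (x[k] - x[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def baseline_correct(spectrum: Spectrum, method: str = "rubberband") -> Spectrum:
    """Subtract a baseline estimate from one spectrum.

    ``rubberband`` subtracts the lower convex hull of the trace (the
    common choice for ATR tissue spectra); the result is >= 0 everywhere
    and exactly 0 at hull-contact points.  ``linear_endpoints`` subtracts
    the chord through the first and last points.
    """
    if len(spectrum) < 3:
        raise SizeError("baseline correction needs at least 3 points")
    x, y = spectrum.wavenumbers, spectrum.absorbance
    if method == "rubberband":
        base = _lower_hull_baseline(x, y)
    elif method == "linear_endpoints":
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    else:
        raise ValidationError(f"unknown baseline method {method!r}")
    return spectrum.with_absorbance(y - base)


def area_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale so the trapezoidal integral over the grid equals 1.

    Removes multiplicative sample-amount differences (how much tissue
    was pressed on the ATR crystal).
    """
    area = float(np.trapezoid(spectrum.absorbance, spectrum.wavenumbers))
    if not area > 0:
        raise NormalizationError(
            f"sample {spectrum.meta.sample_id!r}: non-positive area {area:g}"
        )
    return spectrum.with_absorbance(spectrum.absorbance / area)


def second_derivative_sg(spectrum: Spectrum, params: SGParams = SGParams()) -> Spectrum:
    """Savitzky-Golay estimate of d2A/dnu2 on a uniform grid.

    Output keeps physical units (absorbance * cm^2, i.e. the raw SG
    convolution divided by step^2).  Boundary points are handled by
    refitting the polynomial at the edge windows, so the trace keeps its
    length through the pipeline.
    """
    n = len(spectrum)
    if params.window_points > n:
        raise SizeError(f"window {params.window_points} exceeds length {n}")
    steps = np.diff(spectrum.wavenumbers)
    step = steps[0]
    if np.any(np.abs(steps - step) > 1e-6 * abs(step)):
        raise GridError("second derivative requires a uniform grid")
    d2 = savgol_filter(
        spectrum.absorbance,
        window_length=params.window_points,
        polyorder=params.poly_order,
        deriv=2,
        delta=step,
        mode="interp",
    )
    return spectrum.with_absorbance(d2)


def preprocess_region(
    spectra_set: SpectraSet,
    region: RegionSpec,
    baseline_method: str = "rubberband",
    sg: SGParams = SGParams(),
) -> tuple[SpectraSet, SpectraSet]:
    """Run cut -> baseline -> area-normalize -> 2nd derivative.

    Returns ``(normalized, derived)``: the baseline-corrected
    area-normalized sub-spectra (used for Amide I/II intensities) and
    their second derivatives (used for chemometrics and inverted-peak
    intensities).
    """
    cut = cut_region(spectra_set, region)
    normalized = cut.map(
        lambda s: area_normalize(baseline_correct(s, baseline_method))
    )
    derived = normalized.map(lambda s: second_derivative_sg(s, sg))
    return normalized, derived
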