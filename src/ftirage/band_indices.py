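"""Peak-intensity extraction and the nine band-ratio biomarker indices.

Sharp, overlapping bands are read off the *inverted* second-derivative
trace (band maxima become sharp second-derivative minima; multiplying by
-1 turns them back into maxima whose height tracks amplitude/sigma^2 for
a Gaussian band).  The two Amide-envelope quantities (total protein and
the fibril-formation ratio) are instead read from baseline-corrected,
area-normalized, non-derived spectra.

The nine indices:

==========================  ================================================
acyl_chain_length           (I2851 + I2922) / (I2959 + I2871)   [CH2 vs CH3]
lipid_unsaturation          I3013 / (I2851 + I2922)             [=CH vs CH2]
triglycerides               I1741                               [ester C=O]
total_protein               I_AmideI + I_AmideII                [raw spectra]
antiparallel_beta_fraction  I1693 / (I1693 + I1682 + I1628)
intermolecular_beta_fraction I1628 / (I1693 + I1682 + I1628)
fibril_formation            I_AmideII / I_AmideI                [raw spectra]
cholesterol_esters          I1169
glucose                     I1045
==========================  ================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GroupError, RatioError, WindowError
from .io_spectra import Spectrum, SpectraSet

#: Default half-width of the peak-search window, cm^-1.  Band centers in
#: tissue spectra drift by a few cm^-1 between tissues and ages, so the
#: intensity is the local maximum in a window around the nominal center.
#: +-4 cm^-1 absorbs the drift while keeping the closely spaced Amide I
#: sub-bands (1693/1682, 11 cm^-1 apart) out of each other's windows.
DEFAULT_HALFWIDTH = 4.0

#: Amide I and Amide II are located as raw-spectrum maxima within these
#: windows (the envelopes peak near 1650 and 1545 cm^-1).
AMIDE_I_WINDOW = (1600.0, 1700.0)
AMIDE_II_WINDOW = (1480.0, 1560.0)

INDEX_NAMES = [
    "acyl_chain_length",
    "lipid_unsaturation",
    "triglycerides",
    "total_protein",
    "antiparallel_beta_fraction",
    "intermolecular_beta_fraction",
    "fibril_formation",
    "cholesterol_esters",
    "glucose",
]


@dataclass(frozen=True)
class PeakQuery:
    """Where and on which trace to read a peak intensity."""

    target: float  # cm^-1
    halfwidth: float = DEFAULT_HALFWIDTH
    source: str = "second_derivative_inverted"  # or "normalized_raw"


@dataclass(frozen=True)
class PeakHit:
    intensity: float
    wavenumber: float  # argmax, for audit


def peak_intensity(spectrum: Spectrum, query: PeakQuery) -> PeakHit:
    """Maximum of the (inverted) trace in [target - hw, target + hw].

    For ``second_derivative_inverted`` the input must already be a
    second-derivative trace; the inversion (x -1) happens here.
    """
    lo, hi = query.target - query.halfwidth, query.target + query.halfwidth
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise WindowError(
            f"window [{lo}, {hi}] cm-1 contains no grid point "
            f"(sample {spectrum.meta.sample_id!r})"
        )
    trace = spectrum.absorbance[mask]
    if query.source == "second_derivative_inverted":
        trace = -trace
    elif query.source != "normalized_raw":
        raise WindowError(f"unknown peak source {query.source!r}")
    i = int(np.argmax(trace))
    return PeakHit(float(trace[i]), float(spectrum.wavenumbers[mask][i]))


def _window_max(spectrum: Spectrum, lo: float, hi: float) -> PeakHit:
    center = 0.5 * (lo + hi)
    return peak_intensity(
        spectrum, PeakQuery(center, 0.5 * (hi - lo), source="normalized_raw")
    )


def compute_panel(
    derived_lipid: SpectraSet,
    derived_amide: SpectraSet,
    derived_fingerprint: SpectraSet,
    raw_amide: SpectraSet,
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> pd.DataFrame:
    """Per-sample values of the nine indices.

    The three ``derived_*`` sets are second-derivative sub-spectra of the
    lipid (3050-2800), amide (1800-1500) and fingerprint (1200-900)
    regions; ``raw_amide`` is the baseline-corrected area-normalized
    (non-derived) amide region used for Amide I/II.  All four sets must
    contain the same samples in the same order.
    """
    n = len(derived_lipid)
    for other in (derived_amide, derived_fingerprint, raw_amide):
        if len(other) != n:
            raise GroupError("region sets differ in sample count")
        for a, b in zip(derived_lipid, other):
            if a.meta.sample_id != b.meta.sample_id:
                raise GroupError("region sets are not sample-aligned")

    def inv(spectrum: Spectrum, center: float) -> float:
        return peak_intensity(spectrum, PeakQuery(center, halfwidth)).intensity

    rows = []
    for lip, ami, fin, raw in zip(
        derived_lipid, derived_amide, derived_fingerprint, raw_amide
    ):
        sid = lip.meta.sample_id
        i2851, i2922 = inv(lip, 2851), inv(lip, 2922)
        i2959, i2871 = inv(lip, 2959), inv(lip, 2871)
        i3013 = inv(lip, 3013)
        i1741 = inv(ami, 1741)
        i1693, i1682, i1628 = inv(ami, 1693), inv(ami, 1682), inv(ami, 1628)
        i1169, i1045 = inv(fin, 1169), inv(fin, 1045)
        amide_i = _window_max(raw, *AMIDE_I_WINDOW).intensity
        amide_ii = _window_max(raw, *AMIDE_II_WINDOW).intensity

        def ratio(num: float, den: float, index: str) -> float:
            if den <= 0:
                raise RatioError(
                    f"sample {sid!r}: non-positive denominator for {index}"
                )
            return num / den

        beta_sum = i1693 + i1682 + i1628
        rows.append(
            {
                "sample_id": sid,
                "tissue": lip.meta.tissue,
                "age_months": lip.meta.age_months,
                "bio_rep": lip.meta.bio_rep,
                "tech_rep": lip.meta.tech_rep,
                "acyl_chain_length": ratio(
                    i2851 + i2922, i2959 + i2871, "acyl_chain_length"
                ),
                "lipid_unsaturation": ratio(
                    i3013, i2851 + i2922, "lipid_unsaturation"
                ),
                "triglycerides": i1741,
                "total_protein": amide_i + amide_ii,
                "antiparallel_beta_fraction": ratio(
                    i1693, beta_sum, "antiparallel_beta_fraction"
                ),
                "intermolecular_beta_fraction": ratio(
                    i1628, beta_sum, "intermolecular_beta_fraction"
                ),
                "fibril_formation": ratio(amide_ii, amide_i, "fibril_formation"),
                "cholesterol_esters": i1169,
                "glucose": i1045,
            }
        )
    return pd.DataFrame(rows)


def summarize_panel(
    panel: pd.DataFrame, by: tuple[str, ...] = ("tissue", "age_months")
) -> pd.DataFrame:
    """Mean +- sample SD (n-1 denominator) of every index per group.

    Groups of size 1 get NaN SD and are flagged in the ``sd_defined``
    column rather than raising, so a partially-filled cohort still
    summarizes.
    """
    present = [c for c in INDEX_NAMES if c in panel.columns]
    out = []
    for key, g in panel.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        row = dict(zip(by, key))
        row["n"] = len(g)
        row["sd_defined"] = len(g) >= 2
        for name in present:
            row[f"{name}_mean"] = float(g[name].mean())
            row[f"{name}_sd"] = float(g[name].std(ddof=1)) if len(g) >= 2 else float("nan")
        out.append(row)
    return pd.DataFrame(out)
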