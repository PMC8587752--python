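"""Seeded synthetic ATR-FTIR cohorts with known age and tissue effects.

The generator emulates the design of a mouse muscle aging study: two
striated-muscle tissues (cardiac, skeletal), four ages (6, 12, 17, 24
months), ten biological animals per tissue/age cell and three technical
replicates per animal.  Each spectrum is a sum of Gaussian absorption
bands at literature mid-IR assignments, plus a random quadratic baseline,
a multiplicative sample-amount scatter factor (what area normalization
must remove), and additive white noise.  Band amplitudes carry linear
age slopes and tissue offsets so that every downstream estimate has an
exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_spectra import AGES_MONTHS, TISSUES, SampleMeta, Spectrum, SpectraSet


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band and its aging behaviour.

    ``age_slope`` and ``tissue_offset`` map tissue name to absorbance
    per month and absorbance respectively; missing tissues default to 0.
    The noiseless amplitude for a tissue at a given age is

        amplitude = base_amplitude + age_slope[tissue] * age + tissue_offset[tissue]
    """

    center: float  # cm^-1
    sigma: float  # cm^-1
    base_amplitude: float
    label: str
    age_slope: Mapping[str, float] = field(default_factory=dict)
    tissue_offset: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"band {self.label!r}: sigma must be > 0")
        if self.base_amplitude < 0:
            raise ValidationError(f"band {self.label!r}: negative base amplitude")

    def slope(self, tissue: str) -> float:
        return float(self.age_slope.get(tissue, 0.0))

    def offset(self, tissue: str) -> float:
        return float(self.tissue_offset.get(tissue, 0.0))

    def amplitude(self, tissue: str, age_months: float) -> float:
        return self.base_amplitude + self.slope(tissue) * age_months + self.offset(tissue)


def default_band_catalogue() -> list[BandSpec]:
    """Band catalogue encoding the qualitative aging signature.

    Centers follow standard muscle-tissue mid-IR assignments.  Slopes
    encode the directions reported for aging striated muscle: antiparallel
    beta-sheet (1693) declines with age in both tissues; intermolecular
    beta-sheet (1628, the aggregation-prone structure) rises with age in
    cardiac muscle only; carbonyl (1741) and glucose (1045) rise in both;
    cardiac muscle carries less total protein (Amide I/II offsets) and
    more lipid unsaturation (3013 offset) than skeletal muscle.
    Amplitudes are in arbitrary absorbance units scaled so the dominant
    Amide I band is ~0.5.
    """
    c, s = "cardiac", "skeletal"
    return [
        # --- lipid C-H stretch region (3050-2800) ---
        BandSpec(3013, 6.0, 0.050, "olefinic =CH",
                 age_slope={c: 0.0008}, tissue_offset={c: 0.020}),
        BandSpec(2959, 7.0, 0.140, "CH3 asymmetric stretch",
                 age_slope={c: 0.0008, s: -0.0005}),
        BandSpec(2922, 7.0, 0.220, "CH2 asymmetric stretch",
                 age_slope={c: -0.0008, s: 0.0010}),
        BandSpec(2871, 7.0, 0.100, "CH3 symmetric stretch",
                 age_slope={c: 0.0005, s: -0.0008}),
        BandSpec(2851, 7.0, 0.160, "CH2 symmetric stretch",
                 age_slope={c: -0.0008, s: 0.0005}),
        # --- carbonyl / Amide region (1800-1500) ---
        BandSpec(1741, 6.0, 0.060, "ester carbonyl C=O",
                 age_slope={c: 0.0010, s: 0.0010}),
        BandSpec(1693, 5.0, 0.220, "antiparallel beta-sheet",
                 age_slope={c: -0.0060, s: -0.0060}),
        BandSpec(1682, 5.0, 0.220, "beta-sheet",
                 age_slope={c: 0.0014, s: 0.0014}),
        BandSpec(1662, 5.0, 0.180, "beta-turn",
                 age_slope={c: -0.0006, s: -0.0006}),
        BandSpec(1651, 6.0, 0.500, "alpha-helix (Amide I)",
                 age_slope={c: 0.0010, s: 0.0010}, tissue_offset={c: -0.060}),
        BandSpec(1628, 6.0, 0.200, "intermolecular beta-sheet",
                 age_slope={c: 0.0063, s: -0.0055}, tissue_offset={c: -0.028}),
        BandSpec(1554, 5.0, 0.120, "Amide II (high)",
                 age_slope={c: -0.0008, s: -0.0008}),
        BandSpec(1540, 6.0, 0.280, "Amide II",
                 age_slope={c: 0.0008, s: 0.0008}, tissue_offset={c: -0.030}),
        BandSpec(1512, 5.0, 0.060, "Amide II (low)",
                 age_slope={c: 0.0005, s: 0.0005}),
        # --- fingerprint region (1200-900) ---
        BandSpec(1169, 6.0, 0.050, "cholesterol esters C-O",
                 tissue_offset={c: 0.010}),
        BandSpec(1155, 6.0, 0.080, "glycogen C-O",
                 age_slope={c: -0.0004, s: -0.0010}),
        BandSpec(1081, 8.0, 0.090, "PO4- of nucleic acids",
                 age_slope={c: -0.0006, s: -0.0006}),
        BandSpec(1045, 8.0, 0.070, "glucose C-O",
                 age_slope={c: 0.0010, s: 0.0010}, tissue_offset={c: -0.010}),
    ]


def band_by_label(bands: Sequence[BandSpec], fragment: str) -> BandSpec:
    """Return the unique band whose label contains ``fragment``."""
    hits = [b for b in bands if fragment.lower() in b.label.lower()]
    if len(hits) != 1:
        raise ValidationError(
            f"label fragment {fragment!r} matches {len(hits)} bands"
        )
    return hits[0]


@dataclass
class CohortConfig:
    """Full description of one simulated cohort.

    Defaults reproduce the study design: 2 tissues x 4 ages x 10
    biological x 3 technical replicates on a 902-3998 cm^-1 grid at
    2 cm^-1 spacing.  ``baseline_coeffs_sd`` are the SDs of the constant,
    linear and quadratic coefficients of a per-spectrum baseline
    polynomial in the normalized coordinate t in [0, 1] across the grid.
    ``scale_jitter_sd`` is the log-SD of the lognormal sample-amount
    factor; ``bio_amplitude_sd`` is the log-SD of a per-animal amplitude
    factor shared by all bands and that animal's technical replicates;
    ``noise_sd`` is additive white noise (5% of the largest band
    amplitude by default).
    """

    bands: list[BandSpec] = field(default_factory=default_band_catalogue)
    grid: tuple[float, float, float] = (902.0, 3998.0, 2.0)  # (min, max, step)
    ages: tuple[int, ...] = AGES_MONTHS
    tissues: tuple[str, ...] = TISSUES
    n_bio: int = 10
    n_tech: int = 3
    baseline_coeffs_sd: tuple[float, float, float] = (0.02, 0.02, 0.02)
    scale_jitter_sd: float = 0.15
    noise_sd: float = 0.025
    bio_amplitude_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.grid
        if step <= 0 or hi <= lo:
            raise ValidationError("grid must satisfy min < max and step > 0")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValidationError("n_bio and n_tech must be >= 1")
        if self.noise_sd < 0 or self.scale_jitter_sd < 0 or self.bio_amplitude_sd < 0:
            raise ValidationError("noise/scatter SDs must be >= 0")
        for band in self.bands:
            for tissue in self.tissues:
                for age in self.ages:
                    if band.amplitude(tissue, age) < 0:
                        raise ValidationError(
                            f"band {band.label!r} amplitude negative for "
                            f"{tissue} at {age} months"
                        )

    def grid_vector(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


def null_config(**overrides) -> CohortConfig:
    """A cohort with every age slope and tissue offset removed.

    Band shapes, baselines, scatter and noise are untouched, so the null
    cohort is indistinguishable between groups except for noise — the
    right substrate for type-I-error calibration.
    """
    bands = [
        BandSpec(b.center, b.sigma, b.base_amplitude, b.label)
        for b in default_band_catalogue()
    ]
    return CohortConfig(bands=bands, **overrides)


def _noiseless_trace(
    grid: np.ndarray, bands: Sequence[BandSpec], tissue: str, age: float
) -> np.ndarray:
    out = np.zeros_like(grid)
    for b in bands:
        out += b.amplitude(tissue, age) * np.exp(
            -((grid - b.center) ** 2) / (2.0 * b.sigma**2)
        )
    return out


def generate_cohort(config: CohortConfig) -> SpectraSet:
    """Simulate the full cohort; fully reproducible from ``config.seed``.

    Each spectrum is ``scale * (sum of bands + baseline) + noise`` where
    the per-band amplitude is the noiseless ground truth times a
    per-animal lognormal factor.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid_vector()
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    centers = np.array([b.center for b in config.bands])
    sigmas = np.array([b.sigma for b in config.bands])
    # (n_points, n_bands) Gaussian profile matrix, shared by all spectra
    profiles = np.exp(-((grid[:, None] - centers[None, :]) ** 2) / (2 * sigmas**2))

    spectra = []
    for tissue in config.tissues:
        for age in config.ages:
            base_amps = np.array(
                [b.amplitude(tissue, age) for b in config.bands]
            )
            for bio in range(1, config.n_bio + 1):
                # one amplitude factor per animal, shared by all bands and
                # technical replicates: animal-level tissue amount/density
                animal_factor = (
                    float(np.exp(rng.normal(0.0, config.bio_amplitude_sd)))
                    if config.bio_amplitude_sd > 0
                    else 1.0
                )
                amps = base_amps * animal_factor
                clean = profiles @ amps
                for tech in range(1, config.n_tech + 1):
                    b0, b1, b2 = (
                        rng.normal(0.0, sd) if sd > 0 else 0.0
                        for sd in config.baseline_coeffs_sd
                    )
                    baseline = b0 + b1 * t + b2 * t**2
                    scale = (
                        np.exp(rng.normal(0.0, config.scale_jitter_sd))
                        if config.scale_jitter_sd > 0
                        else 1.0
                    )
                    noise = (
                        rng.normal(0.0, config.noise_sd, size=len(grid))
                        if config.noise_sd > 0
                        else 0.0
                    )
                    sid = f"{tissue[:4]}-{age:02d}M-b{bio:02d}-t{tech}"
                    meta = SampleMeta(sid, tissue, int(age), bio, tech)
                    spectra.append(
                        Spectrum(grid.copy(), scale * (clean + baseline) + noise, meta)
                    )
    return SpectraSet(spectra)


def ground_truth(config: CohortConfig) -> pd.DataFrame:
    """Expected noiseless band amplitudes per (tissue, age, band)."""
    rows = []
    for tissue in config.tissues:
        for age in config.ages:
            for b in config.bands:
                rows.append(
                    {
                        "tissue": tissue,
                        "age_months": int(age),
                        "center_cm1": b.center,
                        "label": b.label,
                        "amplitude": b.amplitude(tissue, age),
                    }
                )
    return pd.DataFrame(rows)


def noiseless_group_spectrum(
    config: CohortConfig, tissue: str, age: float
) -> Spectrum:
    """The exact noiseless group-mean spectrum (no baseline, no scatter)."""
    grid = config.grid_vector()
    meta = SampleMeta(f"truth-{tissue}-{int(age)}M", tissue, int(age), 1, 1)
    return Spectrum(grid, _noiseless_trace(grid, config.bands, tissue, age), meta)
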