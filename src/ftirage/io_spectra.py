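"""Spectrum containers and text-format I/O.

The canonical interchange format is a long CSV with one row per spectral
point and the header::

    sample_id,tissue,age_months,bio_rep,tech_rep,wavenumber_cm1,absorbance

Wavenumbers are stored internally in ascending order (FTIR software plots
them descending; plotting simply reverses the axis).  A read-only JCAMP-DX
importer for the ``##XYDATA=(X++(Y..Y))`` dialect is provided for
instrument exports.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicatePointError,
    FormatError,
    GridError,
    ValidationError,
)

TISSUES = ("cardiac", "skeletal")
AGES_MONTHS = (6, 12, 17, 24)

CSV_COLUMNS = [
    "sample_id",
    "tissue",
    "age_months",
    "bio_rep",
    "tech_rep",
    "wavenumber_cm1",
    "absorbance",
]


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one acquired spectrum within the cohort design.

    The study design is 2 tissues x 4 ages x 10 biological animals x 3
    technical replicates; ``bio_rep``/``tech_rep`` index within that
    design but are not capped so that smaller or larger simulated cohorts
    remain representable.
    """

    sample_id: str
    tissue: str
    age_months: int
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        if int(self.age_months) not in AGES_MONTHS:
            raise ValidationError(
                f"age_months={self.age_months} not in {AGES_MONTHS}"
            )
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValidationError("bio_rep and tech_rep must be >= 1")

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (self.tissue, self.age_months, self.bio_rep, self.tech_rep)


@dataclass
class Spectrum:
    """One absorbance trace on a strictly increasing wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValidationError("wavenumbers and absorbance must be 1-D")
        if len(self.wavenumbers) != len(self.absorbance):
            raise ValidationError("wavenumbers and absorbance differ in length")
        if len(self.wavenumbers) < 8:
            raise ValidationError("a spectrum needs at least 8 points")
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.absorbance)
        ):
            raise ValidationError("non-finite values in spectrum")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValidationError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_absorbance(self, values: np.ndarray) -> "Spectrum":
        """Return a copy with the same grid and metadata, new values."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(values, float), self.meta)


class SpectraSet:
    """An ordered cohort of spectra, normally on one shared grid.

    ``grid`` is the common wavenumber vector when every member shares it
    bitwise, else ``None`` (a ragged set fresh from disk); use
    :func:`to_common_grid` to unify.
    """

    def __init__(self, spectra: Sequence[Spectrum]):
        self.spectra: list[Spectrum] = list(spectra)
        keys = [s.meta.key for s in self.spectra]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ValidationError(f"duplicate sample design key {dup}")

    @property
    def grid(self) -> np.ndarray | None:
        if not self.spectra:
            return None
        g0 = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if len(s.wavenumbers) != len(g0) or not np.array_equal(
                s.wavenumbers, g0
            ):
                return None
        return g0

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def subset(self, keep: Iterable[bool]) -> "SpectraSet":
        keep = list(keep)
        if len(keep) != len(self.spectra):
            raise ValidationError("mask length mismatch")
        return SpectraSet([s for s, k in zip(self.spectra, keep) if k])

    def filter(self, **meta_values) -> "SpectraSet":
        """Select spectra whose metadata match all given field values."""
        out = []
        for s in self.spectra:
            if all(getattr(s.meta, k) == v for k, v in meta_values.items()):
                out.append(s)
        return SpectraSet(out)

    def map(self, fn) -> "SpectraSet":
        """Apply a per-spectrum pure function, preserving order."""
        return SpectraSet([fn(s) for s in self.spectra])

    def meta_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.meta.sample_id,
                "tissue": s.meta.tissue,
                "age_months": s.meta.age_months,
                "bio_rep": s.meta.bio_rep,
                "tech_rep": s.meta.tech_rep,
            }
            for s in self.spectra
        ]
        return pd.DataFrame(rows)

    def to_matrix(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Stack absorbances into an (n_samples, n_points) matrix.

        Requires a shared grid.
        """
        if self.grid is None:
            raise GridError("spectra are not on a common grid; interpolate first")
        X = np.vstack([s.absorbance for s in self.spectra])
        return X, self.meta_frame()


def read_spectra_csv(path: str | Path | io.TextIOBase) -> SpectraSet:
    """Read the canonical long-format CSV into a :class:`SpectraSet`.

    Rows for each sample are sorted into ascending wavenumber order
    regardless of how the file orders them.
    """
    df = pd.read_csv(path)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if df.duplicated(subset=["sample_id", "wavenumber_cm1"]).any():
        bad = df[df.duplicated(subset=["sample_id", "wavenumber_cm1"])].iloc[0]
        raise DuplicatePointError(
            f"duplicate point for sample {bad['sample_id']!r} at "
            f"{bad['wavenumber_cm1']} cm-1"
        )
    spectra = []
    for sid, g in df.groupby("sample_id", sort=False):
        metas = g[["tissue", "age_months", "bio_rep", "tech_rep"]].drop_duplicates()
        if len(metas) != 1:
            raise FormatError(f"inconsistent metadata for sample {sid!r}")
        row = metas.iloc[0]
        try:
            age = int(row["age_months"])
            bio = int(row["bio_rep"])
            tech = int(row["tech_rep"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer metadata for sample {sid!r}") from exc
        meta = SampleMeta(str(sid), str(row["tissue"]), age, bio, tech)
        g = g.sort_values("wavenumber_cm1")
        spectra.append(
            Spectrum(
                g["wavenumber_cm1"].to_numpy(float),
                g["absorbance"].to_numpy(float),
                meta,
            )
        )
    return SpectraSet(spectra)


def write_spectra_csv(spectra_set: SpectraSet, path: str | Path) -> None:
    """Write the canonical long-format CSV (12 significant digits)."""
    if len(spectra_set) == 0:
        raise ValidationError("refusing to write an empty SpectraSet")
    frames = []
    for s in spectra_set:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.meta.sample_id,
                    "tissue": s.meta.tissue,
                    "age_months": s.meta.age_months,
                    "bio_rep": s.meta.bio_rep,
                    "tech_rep": s.meta.tech_rep,
                    "wavenumber_cm1": s.wavenumbers,
                    "absorbance": s.absorbance,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.12g")


def to_common_grid(spectra_set: SpectraSet, grid: np.ndarray) -> SpectraSet:
    """Linearly interpolate every member onto ``grid``.

    ``grid`` must lie inside each member's wavenumber range; no
    extrapolation is performed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise GridError("target grid must be 1-D strictly increasing")
    out = []
    for s in spectra_set:
        if grid[0] < s.wavenumbers[0] or grid[-1] > s.wavenumbers[-1]:
            raise GridError(
                f"grid [{grid[0]}, {grid[-1]}] extends beyond sample "
                f"{s.meta.sample_id!r} range "
                f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
            )
        if len(s.wavenumbers) == len(grid) and np.array_equal(s.wavenumbers, grid):
            out.append(Spectrum(grid.copy(), s.absorbance.copy(), s.meta))
        else:
            out.append(
                Spectrum(grid.copy(), np.interp(grid, s.wavenumbers, s.absorbance), s.meta)
            )
    return SpectraSet(out)


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcampdx(
    path: str | Path, meta: SampleMeta
) -> Spectrum:
    """Read one spectrum from a JCAMP-DX file, ``(X++(Y..Y))`` dialect.

    Supports XUNITS=1/CM and YUNITS=ABSORBANCE with FIRSTX/LASTX/NPOINTS
    and XFACTOR/YFACTOR headers; metadata is supplied by the caller
    because JCAMP carries no cohort design fields.
    """
    headers: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                if "(X++(Y..Y))" not in val.replace(" ", ""):
                    raise FormatError(f"unsupported XYDATA dialect {val!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            headers[key] = val.strip()
            continue
        if in_data:
            nums = _JCAMP_NUM.findall(line)
            if nums:
                ys.extend(float(v) for v in nums[1:])  # first number is X
    for required in ("FIRSTX", "LASTX", "NPOINTS"):
        if required not in headers:
            raise FormatError(f"missing JCAMP header ##{required}")
    xunits = headers.get("XUNITS", "1/CM").upper()
    if xunits not in ("1/CM", "1/ CM"):
        raise FormatError(f"unsupported XUNITS {xunits!r}")
    npoints = int(float(headers["NPOINTS"]))
    if len(ys) != npoints:
        raise FormatError(f"expected {npoints} Y values, found {len(ys)}")
    # FIRSTX/LASTX are stored in actual units; XFACTOR scales only the
    # abscissa entries inside the data table, which we do not rely on.
    firstx = float(headers["FIRSTX"])
    lastx = float(headers["LASTX"])
    yfactor = float(headers.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ys, dtype=float) * yfactor
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return Spectrum(x.copy(), y.copy(), meta)
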