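"""Reading, validation and grid alignment of mid-infrared absorbance spectra.

A spectrum is one attenuated-total-reflectance FTIR measurement of a ground
tissue subsample: absorbance against wavenumber (cm^-1), typically recorded
over ca. 4000-700 cm^-1.  Instruments usually write descending wavenumbers;
internally every spectrum is stored in ascending order, and all region bounds
elsewhere in the package are given as (high, low) cm^-1 pairs and mapped onto
this canonical order.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_csv",
    "read_jcampdx",
    "align_to_grid",
    "write_feature_table",
    "read_feature_table",
]

#: minimum number of points for a spectrum to be usable at all
MIN_POINTS = 8


class SpectrumError(ValueError):
    """Raised for malformed or degenerate spectral input."""


@dataclass
class Spectrum:
    """One subsample's absorbance trace with its design labels.

    ``wavenumbers`` must be strictly monotonic; a descending trace (the usual
    instrument export order) is flipped to ascending on construction.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    genotype: str = ""
    sample_id: str = ""
    subsample_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise SpectrumError("wavenumber and absorbance must be equal-length 1-D vectors")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise SpectrumError("non-finite values in spectrum")
        d = np.diff(w)
        if np.all(d < 0):  # instrument order: flip to canonical ascending
            w, a = w[::-1], a[::-1]
        elif not np.all(d > 0):
            raise SpectrumError("wavenumbers must be strictly monotonic")
        self.wavenumbers = w
        self.absorbance = a

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.genotype, self.sample_id, self.subsample_id)

    def covers(self, high: float, low: float) -> bool:
        return self.wavenumbers[0] <= low and self.wavenumbers[-1] >= high

    def with_values(self, absorbance: np.ndarray) -> "Spectrum":
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))


@dataclass
class SpectrumSet:
    """A cohort of spectra grouped genotype -> sample -> subsample."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [s.key for s in self.spectra]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise SpectrumError(f"duplicate (genotype, sample, subsample) triple {dup!r}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def design(self) -> dict[str, dict[str, int]]:
        """Mapping genotype -> sample_id -> number of subsamples."""
        out: dict[str, dict[str, int]] = {}
        for s in self.spectra:
            out.setdefault(s.genotype, {}).setdefault(s.sample_id, 0)
            out[s.genotype][s.sample_id] += 1
        return out

    def shared_grid(self) -> np.ndarray | None:
        """The common wavenumber grid, or None if spectra differ."""
        if not self.spectra:
            return None
        g0 = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.size != g0.size or not np.array_equal(s.wavenumbers, g0):
                return None
        return g0


def read_spectrum_csv(path, genotype: str = "", sample_id: str = "",
                      subsample_id: str = "") -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV into a Spectrum.

    The dialect matches common spectrometer exports: comma-separated, an
    optional single header line, wavenumber first.  Row order (ascending or
    descending) does not matter; the result is always in canonical ascending
    order.
    """
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p for p in line.replace(";", ",").split(",") if p.strip() != ""]
            if len(parts) < 2:
                raise SpectrumError(f"{path}: line {lineno}: expected >=2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # optional header
                raise SpectrumError(
                    f"{path}: line {lineno}: non-numeric row {line!r}") from None
    if len(rows) < MIN_POINTS:
        raise SpectrumError(f"{path}: only {len(rows)} data points (need >= {MIN_POINTS})")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0])
    return Spectrum(arr[order, 0], arr[order, 1], genotype, sample_id, subsample_id)


def read_jcampdx(path, genotype: str = "", sample_id: str = "",
                 subsample_id: str = "") -> Spectrum:
    """Minimal JCAMP-DX reader for ``(X++(Y..Y))`` AFFN tables.

    Supports XFACTOR/YFACTOR scaling; each data line carries an abscissa
    followed by ordinates at DELTAX spacing.  Compressed (SQZ/DIF/DUP) forms
    are not supported.
    """
    xfactor = yfactor = 1.0
    deltax = None
    firstx = lastx = None
    npoints = None
    xs: list[float] = []
    ys: list[float] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.replace(" ", "").upper()
                val = val.strip()
                if key == "XFACTOR":
                    xfactor = float(val)
                elif key == "YFACTOR":
                    yfactor = float(val)
                elif key == "DELTAX":
                    deltax = float(val)
                elif key == "FIRSTX":
                    firstx = float(val)
                elif key == "LASTX":
                    lastx = float(val)
                elif key == "NPOINTS":
                    npoints = int(float(val))
                elif key == "XYDATA":
                    in_table = True
                elif key == "END":
                    in_table = False
                continue
            if in_table:
                toks = line.replace(",", " ").split()
                vals = [float(t) for t in toks]
                x0 = vals[0] * xfactor
                if deltax is None:
                    if firstx is not None and lastx is not None and npoints and npoints > 1:
                        deltax = (lastx - firstx) / (npoints - 1)
                    else:
                        raise SpectrumError(f"{path}: cannot infer DELTAX")
                for i, y in enumerate(vals[1:]):
                    xs.append(x0 + i * deltax)
                    ys.append(y * yfactor)
    if len(xs) < MIN_POINTS:
        raise SpectrumError(f"{path}: only {len(xs)} data points (need >= {MIN_POINTS})")
    order = np.argsort(xs)
    return Spectrum(np.asarray(xs)[order], np.asarray(ys)[order],
                    genotype, sample_id, subsample_id)


def align_to_grid(sset: SpectrumSet, spacing: float = 2.0,
                  high: float | None = None, low: float | None = None) -> SpectrumSet:
    """Linearly interpolate all spectra onto one shared ascending grid.

    The grid runs from ``low`` to ``high`` (defaults: the intersection of all
    spectral supports) at the given spacing.  Spectra already on the target
    grid are returned unchanged, which makes the operation idempotent.
    """
    if not sset.spectra:
        return sset
    lo = max(s.wavenumbers[0] for s in sset) if low is None else float(low)
    hi = min(s.wavenumbers[-1] for s in sset) if high is None else float(high)
    if hi <= lo:
        raise SpectrumError("spectra have no common wavenumber range")
    n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
    grid = lo + spacing * np.arange(n)
    out = []
    for s in sset:
        if not (s.wavenumbers[0] <= grid[0] and s.wavenumbers[-1] >= grid[-1]):
            raise SpectrumError(
                f"spectrum {s.key} covers {s.wavenumbers[0]:.1f}-{s.wavenumbers[-1]:.1f} "
                f"cm^-1, outside requested grid {grid[0]:.1f}-{grid[-1]:.1f}")
        if s.wavenumbers.size == grid.size and np.array_equal(s.wavenumbers, grid):
            out.append(s)
        else:
            out.append(replace(s, wavenumbers=grid,
                               absorbance=np.interp(grid, s.wavenumbers, s.absorbance)))
    return SpectrumSet(out)


ID_COLUMNS = ["genotype", "sample_id", "subsample_id"]


def write_feature_table(ft: pd.DataFrame, path, overwrite: bool = False) -> None:
    """Write a feature table as CSV, one row per (sample, subsample).

    Column order is preserved as given (the extraction stage emits columns in
    scheme declaration order).  Refuses to clobber an existing file unless
    ``overwrite`` is set.
    """
    if ft.empty:
        raise ValueError("refusing to write an empty feature table")
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    ft.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    ft = pd.read_csv(path, dtype={c: str for c in ID_COLUMNS})
    missing = [c for c in ID_COLUMNS if c not in ft.columns]
    if missing:
        raise ValueError(f"{path}: missing identifier columns {missing}")
    return ft


def spectra_from_dir(directory, pattern: str = "*.csv") -> SpectrumSet:
    """Load a directory of per-subsample CSVs named GENOTYPE_SAMPLE_SUBSAMPLE.csv."""
    import glob

    paths = sorted(glob.glob(os.path.join(directory, pattern)))
    if not paths:
        raise FileNotFoundError(f"no spectra matching {pattern!r} in {directory}")
    spectra = []
    for p in paths:
        stem = os.path.splitext(os.path.basename(p))[0]
        parts = stem.split("_")
        if len(parts) != 3:
            warnings.warn(f"{p}: name not GENOTYPE_SAMPLE_SUBSAMPLE.csv; labels left blank")
            parts = ["", "", stem]
        spectra.append(read_spectrum_csv(p, *parts))
    return SpectrumSet(spectra)
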