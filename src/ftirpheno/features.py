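"""Baseline-corrected peak heights, trapezoidal areas, splits and ratios.

Every measurement is made against a region's two-point baseline: the straight
line joining the spectrum's values at the grid nodes nearest the region's
(high, low) endpoints.  A corrected height is the spectrum minus the baseline
at the peak wavenumber; a corrected area is the trapezoidal integral of the
spectrum minus the trapezoidal integral of the baseline over the region.
Both are therefore exactly invariant to adding any straight line to the
spectrum.  Overlapped bands are located as minima of the smoothed second
derivative instead of apexes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocess import DerivativeSpectrum, PreprocessConfig, normalize, second_derivative
from .scheme import APEX, SECOND_DERIVATIVE, PeakDef, RegionDef, RegionScheme, SplitDef
from .spectra import ID_COLUMNS, Spectrum, SpectrumSet

__all__ = [
    "baseline_value", "locate_peak", "corrected_height", "corrected_area",
    "split_area", "compute_ratios", "extract_features",
]

#: denominators at or below this are treated as zero in ratios
RATIO_EPS = 1e-12


def _nearest(w: np.ndarray, at: float) -> int:
    return int(np.argmin(np.abs(w - at)))


def _region_nodes(s: Spectrum, region: RegionDef) -> tuple[int, int]:
    """Grid indices (i_low, i_high) of the nodes nearest the region endpoints.

    Endpoints are matched to the nearest node, so a region bound may fall up
    to one grid spacing outside the recorded range.
    """
    w = s.wavenumbers
    tol = float(np.median(np.diff(w)))
    if w[0] > region.low + tol or w[-1] < region.high - tol:
        raise ValueError(f"spectrum {s.key} does not cover region {region.name} "
                         f"({region.high}-{region.low} cm^-1)")
    i_lo = _nearest(w, region.low)
    i_hi = _nearest(w, region.high)
    if i_hi - i_lo < 1:
        raise ValueError(f"region {region.name} spans fewer than 2 grid nodes")
    return i_lo, i_hi


def _baseline_line(s: Spectrum, region: RegionDef):
    """Return (i_lo, i_hi, slope, intercept) of the region baseline."""
    i_lo, i_hi = _region_nodes(s, region)
    w, a = s.wavenumbers, s.absorbance
    slope = (a[i_hi] - a[i_lo]) / (w[i_hi] - w[i_lo])
    intercept = a[i_lo] - slope * w[i_lo]
    return i_lo, i_hi, slope, intercept


def baseline_value(s: Spectrum, region: RegionDef, at: float) -> float:
    """Baseline absorbance at ``at``: linear interpolation between the region endpoints."""
    i_lo, i_hi, slope, intercept = _baseline_line(s, region)
    w = s.wavenumbers
    lo = min(region.low, float(w[i_lo]))
    hi = max(region.high, float(w[i_hi]))
    if not (lo - 1e-9 <= at <= hi + 1e-9):
        raise ValueError(f"{at} cm^-1 is outside region {region.name} "
                         f"({hi:.1f}-{lo:.1f})")
    return float(slope * at + intercept)


def corrected_height(s: Spectrum, region: RegionDef, at: float) -> float:
    """Spectrum minus baseline at the node nearest ``at``; may be negative."""
    i = _nearest(s.wavenumbers, at)
    h = float(s.absorbance[i]) - baseline_value(s, region, float(s.wavenumbers[i]))
    if h < 0:
        warnings.warn(f"negative corrected height {h:.3g} at {at:.0f} cm^-1 "
                      f"in region {region.name} (spectrum {s.key})")
    return h


def corrected_area(s: Spectrum, region: RegionDef) -> float:
    """Trapezoidal integral of (spectrum - baseline) over the region.

    Negative lobes are signed, not clipped, so area additivity holds exactly.
    """
    i_lo, i_hi, slope, intercept = _baseline_line(s, region)
    w = s.wavenumbers[i_lo:i_hi + 1]
    resid = s.absorbance[i_lo:i_hi + 1] - (slope * w + intercept)
    return float(np.trapezoid(resid, w))


def split_area(s: Spectrum, split: SplitDef, region: RegionDef) -> tuple[float, float]:
    """Split a region's corrected area at the node nearest ``split_at``.

    Both parts are measured against the parent region's single baseline and
    the cut node is shared, so part_high + part_low equals the parent area
    exactly.  Returns (high-wavenumber part, low-wavenumber part), matching
    the declared part_names order.
    """
    i_lo, i_hi, slope, intercept = _baseline_line(s, region)
    w = s.wavenumbers
    i_m = _nearest(w, split.split_at)
    if not (i_lo < i_m < i_hi):
        raise ValueError(f"split point {split.split_at} not strictly inside region "
                         f"{region.name}")
    resid = s.absorbance - (slope * w + intercept)
    low_part = float(np.trapezoid(resid[i_lo:i_m + 1], w[i_lo:i_m + 1]))
    high_part = float(np.trapezoid(resid[i_m:i_hi + 1], w[i_m:i_hi + 1]))
    return high_part, low_part


def _local_extrema(v: np.ndarray, lo: int, hi: int, minima: bool) -> list[int]:
    """Indices in [lo, hi] that are local extrema of v (ties allowed)."""
    out = []
    for i in range(max(lo, 1), min(hi, v.size - 2) + 1):
        if minima:
            if v[i] <= v[i - 1] and v[i] <= v[i + 1]:
                out.append(i)
        else:
            if v[i] >= v[i - 1] and v[i] >= v[i + 1]:
                out.append(i)
    return out


def locate_peak(s: Spectrum, d2: DerivativeSpectrum | None, p: PeakDef) -> float:
    """Locate a band within ``nominal +/- search_halfwidth``.

    Apex mode finds the highest local maximum of the absorbance; second-
    derivative mode finds the deepest local minimum of the second derivative
    (where overlapped bands resolve).  Ties break toward the nominal
    position; with no interior extremum the nominal position is returned.
    """
    w = s.wavenumbers
    lo_w, hi_w = p.nominal - p.search_halfwidth, p.nominal + p.search_halfwidth
    if lo_w < w[0] or hi_w > w[-1]:
        raise ValueError(f"search window for {p.name} ({lo_w}-{hi_w}) outside grid")
    lo, hi = _nearest(w, lo_w), _nearest(w, hi_w)
    if p.mode == APEX:
        v, minima = s.absorbance, False
    elif p.mode == SECOND_DERIVATIVE:
        if d2 is None:
            raise ValueError(f"peak {p.name} needs a second derivative")
        v, minima = d2.values, True
    else:
        raise ValueError(f"unknown peak mode {p.mode!r}")
    cand = _local_extrema(v, lo, hi, minima)
    if not cand:
        return p.nominal
    best = min(v[cand]) if minima else max(v[cand])
    ties = [i for i in cand if v[i] == best]
    i_star = min(ties, key=lambda i: abs(w[i] - p.nominal))
    # a flat stretch ties everywhere; treat it as "no extremum" and keep nominal
    if len(ties) == len(cand) and len(ties) > 2:
        return p.nominal
    return float(w[i_star])


def compute_ratios(row: dict, scheme: RegionScheme) -> dict:
    """Append the scheme's ratio features to one (sub)sample's feature row.

    Ratios are computed per observation, before any averaging, so downstream
    group means are means of ratios.
    """
    out = dict(row)
    for rt in scheme.ratios:
        num, den = out.get(rt.numerator), out.get(rt.denominator)
        if num is None or den is None or not np.isfinite(num) or not np.isfinite(den):
            out[rt.name] = np.nan
            continue
        if abs(den) <= RATIO_EPS:
            warnings.warn(f"ratio {rt.name}: denominator {rt.denominator} ~ 0; set to NaN")
            out[rt.name] = np.nan
        else:
            out[rt.name] = num / den
    return out


def extract_row(s: Spectrum, scheme: RegionScheme, cfg: PreprocessConfig) -> dict:
    """All scheme features for one spectrum: normalize, differentiate, measure."""
    sn = normalize(s, cfg.normalize)
    d2 = second_derivative(sn, cfg.window, cfg.polyorder)
    regions = {r.name: r for r in scheme.regions}
    row: dict = {}
    for p in scheme.peaks:
        region = regions[p.region]
        at = locate_peak(sn, d2, p) if cfg.locate_peaks else p.nominal
        row[p.name] = corrected_height(sn, region, at)
    for r in scheme.regions:
        if r.area_name:
            row[r.area_name] = corrected_area(sn, r)
    for sp in scheme.splits:
        hi_part, lo_part = split_area(sn, sp, regions[sp.region])
        row[sp.part_names[0]] = hi_part
        row[sp.part_names[1]] = lo_part
    return compute_ratios(row, scheme)


def extract_features(sset: SpectrumSet, scheme: RegionScheme,
                     cfg: PreprocessConfig | None = None) -> pd.DataFrame:
    """Feature table for a whole cohort: one row per (genotype, sample, subsample).

    A failing spectrum is reported with its identity and skipped; the batch
    continues.  Columns follow the scheme's declaration order.
    """
    cfg = cfg or PreprocessConfig()
    rows, index = [], []
    errors = []
    for s in sset:
        try:
            rows.append(extract_row(s, scheme, cfg))
            index.append(s.key)
        except Exception as e:  # noqa: BLE001 - keep batch alive, record identity
            errors.append((s.key, e))
            warnings.warn(f"spectrum {s.key}: {e}")
    if not rows:
        raise ValueError(f"no spectrum could be processed ({len(errors)} failures)")
    ft = pd.DataFrame(rows, columns=scheme.feature_names())
    ids = pd.DataFrame(index, columns=ID_COLUMNS)
    return pd.concat([ids, ft], axis=1)
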