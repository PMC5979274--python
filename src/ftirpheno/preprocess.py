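"""Spectral preprocessing: normalization and smoothed second derivatives.

Min-max normalization removes the absorbance-scale variation caused by
uneven sample thickness on the ATR crystal; the Savitzky-Golay second
derivative sharpens overlapped bands into resolvable minima (a band riding on
a sloped baseline has the same second derivative as the isolated band, since
differentiation annihilates the linear term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumError

__all__ = ["PreprocessConfig", "DerivativeSpectrum", "normalize", "second_derivative"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs: normalization method and derivative smoothing.

    window/polyorder are the Savitzky-Golay parameters; 9 points / cubic is a
    standard choice for band resolution on a ~2 cm^-1 grid.
    """

    normalize: str = "minmax"      # "minmax", "offset" or "none"
    window: int = 9
    polyorder: int = 3
    locate_peaks: bool = True      # read heights at located peaks, not nominal positions


@dataclass
class DerivativeSpectrum:
    """Second derivative of a parent spectrum on the same grid.

    Values are in absorbance per cm^-1 squared; absorption bands appear as
    local minima.
    """

    parent: Spectrum
    wavenumbers: np.ndarray
    values: np.ndarray
    window: int
    polyorder: int


def normalize(s: Spectrum, method: str = "minmax") -> Spectrum:
    """Rescale a spectrum over its full recorded range.

    ``minmax`` maps it affinely to [0, 1]; ``offset`` only subtracts the
    minimum; ``none`` returns the input unchanged.
    """
    a = s.absorbance
    if method == "none":
        return s
    if method == "offset":
        return s.with_values(a - a.min())
    if method == "minmax":
        rng = a.max() - a.min()
        if rng <= 1e-15:
            raise SpectrumError(
                f"spectrum {s.key}: constant absorbance, min-max normalization undefined")
        return s.with_values((a - a.min()) / rng)
    raise ValueError(f"unknown normalization method {method!r}")


def _grid_spacing(w: np.ndarray) -> float:
    d = np.diff(w)
    if d.size == 0:
        raise SpectrumError("spectrum too short for differentiation")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise SpectrumError("second derivative requires a uniformly spaced grid; "
                            "align_to_grid the set first")
    return float(d[0])


def second_derivative(s: Spectrum, window: int = 9, polyorder: int = 3) -> DerivativeSpectrum:
    """Savitzky-Golay smoothed second derivative of a spectrum.

    The local polynomial fit is exact for polynomials up to ``polyorder``, so
    any straight-line baseline contributes exactly zero.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder ({polyorder}) must be < window ({window})")
    if window > len(s):
        raise ValueError(f"window ({window}) exceeds spectrum length ({len(s)})")
    if polyorder < 2:
        raise ValueError("polyorder must be >= 2 for a second derivative")
    delta = _grid_spacing(s.wavenumbers)
    d2 = savgol_filter(s.absorbance, window_length=window, polyorder=polyorder,
                       deriv=2, delta=delta)
    return DerivativeSpectrum(parent=s, wavenumbers=s.wavenumbers, values=d2,
                              window=window, polyorder=polyorder)
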