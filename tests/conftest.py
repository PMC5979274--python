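import warnings

import numpy as np
import pytest

from ftirpheno.features import extract_features
from ftirpheno.scheme import default_alfalfa_scheme
from ftirpheno.spectra import Spectrum
from ftirpheno.synthetic import default_design, simulate


def gaussian_spectrum(centers, amps, sigmas, lo=700.0, hi=4000.0, spacing=2.0,
                      baseline=0.0, slope=0.0, **labels) -> Spectrum:
    """A band-mixture spectrum on the standard grid, optionally on a sloped line."""
    w = np.arange(lo, hi + spacing / 2, spacing)
    a = np.full_like(w, float(baseline)) + slope * w
    for c, A, s in zip(np.atleast_1d(centers), np.atleast_1d(amps), np.atleast_1d(sigmas)):
        a = a + A * np.exp(-((w - c) ** 2) / (2 * s ** 2))
    return Spectrum(w, a, **labels)


@pytest.fixture(scope="session")
def scheme():
    return default_alfalfa_scheme()


@pytest.fixture(scope="session")
def cohort():
    """One synthetic cohort at the reference design (fixed seed)."""
    return simulate(default_design(), seed=1)


@pytest.fixture(scope="session")
def feature_table(cohort, scheme):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_features(cohort, scheme)
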