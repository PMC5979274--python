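"""Synthetic ATR-FTIR cohorts with the noise structure the analysis assumes.

Spectra are mixtures of Gaussian/Lorentzian bands placed at the default
scheme's nominal peak positions, plus a broad O-H stretch envelope around
3350 cm^-1 (the dominant feature of real dried-plant ATR spectra, and the
anchor that keeps min-max normalization stable across genotypes), a small
polynomial baseline, and two levels of noise mirroring the nested design:
a per-sample multiplicative random effect on each band's amplitude, and
per-subsample white noise.  Genotype effects are multiplicative on band
amplitudes; the shipped default design reproduces a published three-genotype
alfalfa experiment (wild type n=4, two RNAi-silenced lines n=5 and n=11,
five subsample spectra each) with effect sizes and noise scales read off the
experiment's printed group means and SEMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "BandSpec", "GenotypeSpec", "SyntheticDesign", "default_design", "simulate",
    "simulate_nested_observations", "PRINTED_HEIGHTS",
]

#: printed per-genotype height means, Tukey letters and SEM of the reference
#: experiment: band -> (WT mean, HB12i mean, TT8i mean, WT/HB12i/TT8i letters, SEM).
#: Rows without letter separation carry empty letter strings.
PRINTED_HEIGHTS: dict[str, tuple[float, float, float, tuple[str, str, str], float]] = {
    "TC1":        (0.646, 0.612, 0.606, ("a", "b", "b"), 0.007),
    "TC2":        (0.498, 0.550, 0.533, ("b", "a", "a"), 0.0083),
    "TC3":        (0.338, 0.381, 0.373, ("b", "a", "a"), 0.0054),
    "TC4":        (0.159, 0.152, 0.149, ("", "", ""), 0.0028),
    "CEC":        (0.078, 0.072, 0.077, ("", "", ""), 0.0029),
    "STC1":       (0.093, 0.106, 0.100, ("b", "a", "ab"), 0.0026),
    "STC2":       (0.151, 0.162, 0.152, ("b", "a", "b"), 0.0028),
    "STC3":       (0.164, 0.230, 0.187, ("c", "a", "b"), 0.0048),
    "STC4":       (0.131, 0.168, 0.143, ("b", "a", "b"), 0.0043),
    "AmideI":     (0.356, 0.341, 0.348, ("", "", ""), 0.0098),
    "AmideII":    (0.272, 0.269, 0.241, ("", "", ""), 0.0085),
    "AlphaHelix": (0.346, 0.333, 0.333, ("", "", ""), 0.0083),
    "BetaSheet":  (0.335, 0.386, 0.369, ("b", "a", "a"), 0.0071),
    "CCO":        (0.063, 0.059, 0.056, ("", "", ""), 0.0024),
    "SyCH2":      (0.101, 0.133, 0.116, ("b", "a", "b"), 0.0051),
    "SyCH3":      (0.059, 0.062, 0.060, ("", "", ""), 0.0014),
    "AsCH2":      (0.184, 0.237, 0.206, ("b", "a", "b"), 0.0084),
    "AsCH3":      (0.061, 0.066, 0.062, ("", "", ""), 0.0016),
}

#: nominal band centers (cm^-1) for the default scheme's 18 measured bands
BAND_CENTERS = {
    "TC1": 1026.0, "TC2": 1074.0, "TC3": 1104.0, "TC4": 1149.0,
    "CEC": 1237.0,
    "STC1": 1317.0, "STC2": 1370.0, "STC3": 1397.0, "STC4": 1453.0,
    "AmideI": 1649.0, "AmideII": 1540.0, "AlphaHelix": 1653.0, "BetaSheet": 1629.0,
    "CCO": 1733.0,
    "SyCH2": 2850.0, "SyCH3": 2872.0, "AsCH2": 2920.0, "AsCH3": 2955.0,
}

#: the congested carbohydrate triplet gets narrower bands so its members
#: genuinely merge and must be resolved on the second derivative
NARROW_BANDS = {"TC1", "TC2", "TC3"}


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center/width/base amplitude plus its sample-level
    relative amplitude SD (the nested random effect acts per band)."""

    name: str
    center: float
    sigma: float
    amplitude: float
    shape: str = "gaussian"  # gaussian | lorentzian
    sample_sd_rel: float = 0.0

    def profile(self, w: np.ndarray) -> np.ndarray:
        z = (w - self.center) / self.sigma
        if self.shape == "gaussian":
            return np.exp(-0.5 * z * z)
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + z * z)
        raise ValueError(f"unknown band shape {self.shape!r}")


@dataclass(frozen=True)
class GenotypeSpec:
    sample_ids: tuple[str, ...]
    multipliers: dict[str, float] = field(default_factory=dict)  # band -> amplitude factor

    def multiplier(self, band: str) -> float:
        return self.multipliers.get(band, 1.0)


@dataclass
class SyntheticDesign:
    bands: list[BandSpec]
    genotypes: dict[str, GenotypeSpec]
    subsamples: int = 5
    noise_sd: float = 5e-4            # per-point white noise (128-scan ATR scale)
    drift_sd: float = 0.2             # relative jitter of the drift amplitude per subsample
    baseline_coeffs: tuple[float, float, float] = (0.01, 0.008, -0.004)
    grid_high: float = 4000.0
    grid_low: float = 700.0
    grid_spacing: float = 2.0
    seed: int | None = None

    def validate(self) -> None:
        if self.subsamples < 1:
            raise ValueError("subsamples must be >= 1")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for b in self.bands:
            if b.sigma <= 0 or b.amplitude < 0 or b.sample_sd_rel < 0:
                raise ValueError(f"band {b.name}: invalid sigma/amplitude/SD")
        for g, spec in self.genotypes.items():
            if len(spec.sample_ids) < 1:
                raise ValueError(f"genotype {g}: needs at least one sample")
            for band, m in spec.multipliers.items():
                if m <= 0:
                    raise ValueError(f"genotype {g}, band {band}: multiplier must be > 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_spacing)) + 1
        return self.grid_low + self.grid_spacing * np.arange(n)

    def planted_directions(self) -> dict[tuple[str, str], int]:
        """(genotype, band) -> sign of the planted effect, for multipliers != 1."""
        out = {}
        for g, spec in self.genotypes.items():
            for band, m in spec.multipliers.items():
                if m != 1.0:
                    out[(g, band)] = 1 if m > 1.0 else -1
        return out


def _default_multiplier(wt: float, other: float, wt_letter: str, other_letter: str) -> float:
    """Printed-mean ratio where the genotype is letter-separated from WT, else 1."""
    if not wt_letter or not other_letter:
        return 1.0
    if set(wt_letter) & set(other_letter):
        return 1.0
    return other / wt


def default_design(seed: int | None = None) -> SyntheticDesign:
    """The reference three-genotype alfalfa design.

    Band amplitudes are the printed WT group means; per-band sample random
    effects invert the printed SEM column (SD of a sample mean = 2 * SEM,
    taking the printed SEM as the standard error of the least-replicated
    group, n=4); genotype multipliers are printed-mean ratios wherever a
    genotype does not share a Tukey letter with WT.  A broad O-H stretch
    band (amplitude 0.9 at 3350 cm^-1) dominates the spectrum so min-max
    normalization is anchored by a genotype-invariant feature.
    """
    bands = []
    hb_mult: dict[str, float] = {}
    tt_mult: dict[str, float] = {}
    for name, (wt, hb, tt, (lw, lh, lt), sem) in PRINTED_HEIGHTS.items():
        sd_rel = 2.0 * sem / wt
        bands.append(BandSpec(name=name, center=BAND_CENTERS[name],
                              sigma=8.0 if name in NARROW_BANDS else 12.0,
                              amplitude=wt, sample_sd_rel=sd_rel))
        m = _default_multiplier(wt, hb, lw, lh)
        if m != 1.0:
            hb_mult[name] = m
        m = _default_multiplier(wt, tt, lw, lt)
        if m != 1.0:
            tt_mult[name] = m
    bands.append(BandSpec(name="OH", center=3350.0, sigma=150.0, amplitude=0.9,
                          sample_sd_rel=0.01))
    # Broad carbohydrate envelope under the sharp CHO bands.  Transgenic
    # spectra carry a shared coherent elevation of this continuum (both
    # silenced lines move together), which is what lets clustering isolate
    # the wild type while leaving the two transgenic lines intermingled;
    # the sharp-band multipliers above ride on top of it.
    bands.append(BandSpec(name="CHOenv", center=1160.0, sigma=200.0, amplitude=0.35,
                          sample_sd_rel=0.015))
    hb_mult["CHOenv"] = tt_mult["CHOenv"] = 1.10
    genotypes = {
        "WT": GenotypeSpec(tuple(f"W{i}" for i in range(1, 5))),
        "HB12i": GenotypeSpec(tuple(f"H{i}" for i in range(1, 12)), hb_mult),
        "TT8i": GenotypeSpec(tuple(f"T{i}" for i in range(1, 6)), tt_mult),
    }
    return SyntheticDesign(bands=bands, genotypes=genotypes, seed=seed)


def simulate(design: SyntheticDesign, seed: int | None = None) -> SpectrumSet:
    """Draw one cohort of spectra from a design; reproducible given the seed."""
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    w = design.grid()
    x = (w - design.grid_low) / (design.grid_high - design.grid_low)
    c0, c1, c2 = design.baseline_coeffs
    drift = c0 + c1 * x + c2 * x * x
    profiles = np.stack([b.profile(w) for b in design.bands])
    amps = np.array([b.amplitude for b in design.bands])
    sds = np.array([b.sample_sd_rel for b in design.bands])
    spectra = []
    for genotype in design.genotypes:
        spec = design.genotypes[genotype]
        mult = np.array([spec.multiplier(b.name) for b in design.bands])
        for sample_id in spec.sample_ids:
            u = rng.normal(0.0, 1.0, size=len(design.bands)) * sds
            sample_amp = amps * mult * (1.0 + u)
            for k in range(1, design.subsamples + 1):
                jitter = 1.0 + rng.normal(0.0, design.drift_sd) if design.drift_sd > 0 else 1.0
                a = sample_amp @ profiles + drift * jitter
                if design.noise_sd > 0:
                    a = a + rng.normal(0.0, design.noise_sd, size=w.size)
                spectra.append(Spectrum(w, a, genotype, sample_id, str(k)))
    return SpectrumSet(spectra)


def simulate_nested_observations(means: dict[str, float], n_samples: dict[str, int],
                                 subsamples: int = 5, sigma_s: float = 0.01,
                                 sigma_e: float = 0.01,
                                 rng: np.random.Generator | None = None,
                                 feature: str = "value") -> pd.DataFrame:
    """Directly simulate the nested two-level model for one feature.

    Y_ijk = mu_i + sample effect (SD sigma_s) + subsample error (SD sigma_e);
    used for calibration studies of the univariate stage (type-I error,
    power, small-population behaviour) without going through spectra.
    """
    rng = rng or np.random.default_rng()
    rows = []
    for g, mu in means.items():
        for j in range(1, n_samples[g] + 1):
            b = rng.normal(0.0, sigma_s)
            for k in range(1, subsamples + 1):
                rows.append((g, f"{g}_{j}", str(k), mu + b + rng.normal(0.0, sigma_e)))
    return pd.DataFrame(rows, columns=["genotype", "sample_id", "subsample_id", feature])


def save_design(design: SyntheticDesign, path) -> None:
    d = asdict(design)
    d["genotypes"] = {g: {"sample_ids": list(s.sample_ids), "multipliers": s.multipliers}
                      for g, s in design.genotypes.items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def load_design(path) -> SyntheticDesign:
    with open(path) as fh:
        d = json.load(fh)
    d["bands"] = [BandSpec(**b) for b in d["bands"]]
    d["genotypes"] = {g: GenotypeSpec(tuple(s["sample_ids"]), s.get("multipliers", {}))
                      for g, s in d["genotypes"].items()}
    d["baseline_coeffs"] = tuple(d["baseline_coeffs"])
    design = SyntheticDesign(**d)
    design.validate()
    return design
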