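"""Declarative model of spectral regions, peaks, area splits and ratios.

A RegionScheme says *where* to measure: each region is a two-point baseline
(high, low endpoints in cm^-1), peaks are nominal band positions inside a
region with a localization mode, splits cut one region's area in two at a
fixed wavenumber, and ratios combine previously defined features.  The
shipped default encodes the standard forage mid-IR band assignments:
carbohydrate (CHO 1484-941 with TC/STC/CEC sub-regions), amide (1710-1484,
amide I/II and the alpha-helix/beta-sheet secondary-structure bands), and the
lipid carbonyl-ester and CH2/CH3 stretching regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = [
    "RegionDef", "PeakDef", "SplitDef", "RatioDef", "RegionScheme",
    "default_alfalfa_scheme", "load_scheme", "save_scheme", "validate_scheme",
]

APEX = "apex"
SECOND_DERIVATIVE = "second_derivative"

#: default half-width (cm^-1) of the search window around a nominal position;
#: half the typical band spacing in the congested 1026/1074/1104 triplet.
DEFAULT_HALFWIDTH = 8.0


@dataclass(frozen=True)
class RegionDef:
    """A baseline region: the straight line joining the spectrum at (high, low)."""
    name: str
    high: float
    low: float
    area_name: str | None = None  # feature name of this region's corrected area, if measured


@dataclass(frozen=True)
class PeakDef:
    """A band measured as a baseline-corrected height within one region."""
    name: str
    nominal: float
    region: str
    mode: str = APEX  # apex | second_derivative
    search_halfwidth: float = DEFAULT_HALFWIDTH


@dataclass(frozen=True)
class SplitDef:
    """Cut a region's corrected area in two at split_at (high side first)."""
    name: str
    region: str
    split_at: float
    part_names: tuple[str, str] = ()


@dataclass(frozen=True)
class RatioDef:
    name: str
    numerator: str
    denominator: str


@dataclass
class RegionScheme:
    regions: list[RegionDef] = field(default_factory=list)
    peaks: list[PeakDef] = field(default_factory=list)
    splits: list[SplitDef] = field(default_factory=list)
    ratios: list[RatioDef] = field(default_factory=list)

    def region(self, name: str) -> RegionDef:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def feature_names(self) -> list[str]:
        """All feature columns in declaration order: heights, areas, split parts, ratios."""
        names = [p.name for p in self.peaks]
        names += [r.area_name for r in self.regions if r.area_name]
        for sp in self.splits:
            names += list(sp.part_names)
        names += [rt.name for rt in self.ratios]
        return names


def validate_scheme(s: RegionScheme) -> list[str]:
    """Return a list of invariant violations (empty means the scheme is valid)."""
    v: list[str] = []
    region_names = [r.name for r in s.regions]
    if len(set(region_names)) != len(region_names):
        v.append("duplicate region names")
    for r in s.regions:
        if not r.high > r.low:
            v.append(f"region {r.name}: inverted bounds ({r.high} <= {r.low})")
    by_name = {r.name: r for r in s.regions}
    for p in s.peaks:
        r = by_name.get(p.region)
        if r is None:
            v.append(f"peak {p.name}: unresolved region {p.region!r}")
        elif not (r.low <= p.nominal <= r.high):
            v.append(f"peak {p.name}: nominal {p.nominal} outside region "
                     f"{r.name} ({r.high}-{r.low})")
        if p.mode not in (APEX, SECOND_DERIVATIVE):
            v.append(f"peak {p.name}: unknown mode {p.mode!r}")
        if p.search_halfwidth <= 0:
            v.append(f"peak {p.name}: non-positive search half-width")
    for sp in s.splits:
        r = by_name.get(sp.region)
        if r is None:
            v.append(f"split {sp.name}: unresolved region {sp.region!r}")
        elif not (r.low < sp.split_at < r.high):
            v.append(f"split {sp.name}: split point {sp.split_at} not strictly inside "
                     f"region {r.name}")
        if len(sp.part_names) != 2:
            v.append(f"split {sp.name}: needs exactly two part names")
    feat = set()
    for p in s.peaks:
        feat.add(p.name)
    for r in s.regions:
        if r.area_name:
            feat.add(r.area_name)
    for sp in s.splits:
        feat.update(sp.part_names)
    dup = len([p.name for p in s.peaks]) + len([r for r in s.regions if r.area_name]) \
        + sum(len(sp.part_names) for sp in s.splits)
    if dup != len(feat):
        v.append("duplicate feature names across peaks/areas/splits")
    for rt in s.ratios:
        for operand in (rt.numerator, rt.denominator):
            if operand not in feat:
                v.append(f"ratio {rt.name}: unresolved operand {operand!r}")
        if rt.name in feat:
            v.append(f"ratio {rt.name}: name collides with an existing feature")
    return v


def default_alfalfa_scheme() -> RegionScheme:
    """The standard forage band table used throughout this package.

    Heights for the four total-carbohydrate peaks (TC1-TC4), the cellulosic
    band (CEC), four structural-carbohydrate peaks (STC1-STC4), amide I/II
    and the alpha-helix/beta-sheet secondary-structure bands, the carbonyl
    C=O ester band and four CH2/CH3 stretching bands; corrected areas per
    sub-region; the total amide area split at 1575 cm^-1 into amide I and
    amide II areas; and the four protein-structure ratios.  Bands known to
    overlap their neighbours (TC2/TC3, amide I/II, alpha-helix/beta-sheet)
    are localized on the second derivative; isolated bands at the apex.
    """
    regions = [
        RegionDef("CHO", 1484.0, 941.0),
        RegionDef("TC", 1178.0, 941.0, area_name="TCA"),
        RegionDef("STC", 1484.0, 1178.0, area_name="STCA"),
        RegionDef("CEC", 1283.0, 1178.0, area_name="CECA"),
        RegionDef("amide", 1710.0, 1484.0, area_name="AA"),
        RegionDef("CCO", 1781.0, 1710.0, area_name="CCOA"),
        RegionDef("ASCC", 3000.0, 2761.0, area_name="ASCCA"),
        RegionDef("fingerprint", 1800.0, 800.0),
        RegionDef("whole", 4000.0, 700.0),
    ]
    peaks = [
        PeakDef("TC1", 1026.0, "TC"),
        PeakDef("TC2", 1074.0, "TC", mode=SECOND_DERIVATIVE),
        PeakDef("TC3", 1104.0, "TC", mode=SECOND_DERIVATIVE),
        PeakDef("TC4", 1149.0, "TC"),
        PeakDef("CEC", 1237.0, "CEC"),
        PeakDef("STC1", 1317.0, "STC"),
        PeakDef("STC2", 1370.0, "STC"),
        PeakDef("STC3", 1397.0, "STC"),
        PeakDef("STC4", 1453.0, "STC"),
        PeakDef("AmideI", 1649.0, "amide", mode=SECOND_DERIVATIVE),
        PeakDef("AmideII", 1540.0, "amide", mode=SECOND_DERIVATIVE),
        PeakDef("AlphaHelix", 1653.0, "amide", mode=SECOND_DERIVATIVE),
        PeakDef("BetaSheet", 1629.0, "amide", mode=SECOND_DERIVATIVE),
        PeakDef("CCO", 1733.0, "CCO"),
        PeakDef("SyCH2", 2850.0, "ASCC"),
        PeakDef("SyCH3", 2872.0, "ASCC"),
        PeakDef("AsCH2", 2920.0, "ASCC"),
        PeakDef("AsCH3", 2955.0, "ASCC"),
    ]
    splits = [SplitDef("amide_split", "amide", 1575.0, ("AIA", "AIIA"))]
    ratios = [
        RatioDef("AlphaHelix/BetaSheet", "AlphaHelix", "BetaSheet"),
        RatioDef("AmideI/AmideII", "AmideI", "AmideII"),
        RatioDef("AIA/AIIA", "AIA", "AIIA"),
        RatioDef("AIA/AA", "AIA", "AA"),
    ]
    return RegionScheme(regions, peaks, splits, ratios)


def _scheme_to_dict(s: RegionScheme) -> dict:
    d = {
        "regions": [asdict(r) for r in s.regions],
        "peaks": [asdict(p) for p in s.peaks],
        "splits": [dict(asdict(sp), part_names=list(sp.part_names)) for sp in s.splits],
        "ratios": [asdict(rt) for rt in s.ratios],
    }
    return d


def save_scheme(s: RegionScheme, path) -> None:
    with open(path, "w") as fh:
        json.dump(_scheme_to_dict(s), fh, indent=2)


def scheme_from_dict(d: dict) -> RegionScheme:
    s = RegionScheme(
        regions=[RegionDef(**r) for r in d.get("regions", [])],
        peaks=[PeakDef(**p) for p in d.get("peaks", [])],
        splits=[SplitDef(**dict(sp, part_names=tuple(sp["part_names"])))
                for sp in d.get("splits", [])],
        ratios=[RatioDef(**rt) for rt in d.get("ratios", [])],
    )
    return s


def load_scheme(path) -> RegionScheme:
    """Load a JSON scheme and raise if it violates any invariant."""
    with open(path) as fh:
        d = json.load(fh)
    s = scheme_from_dict(d)
    violations = validate_scheme(s)
    if violations:
        raise ValueError(f"{path}: invalid scheme: " + "; ".join(violations))
    return s
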