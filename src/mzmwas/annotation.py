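"""Adduct-based metabolite annotation of m/z features.

In positive-mode electrospray ionization a neutral metabolite of
monoisotopic mass M is observed at M plus a fixed adduct shift: the
protonated form M+H, the sodiated and potassiated forms M+Na and M+K,
the water-loss form M+H-H2O, and the two-water cluster M+H+2H2O.  A
feature's m/z matches a database record when the relative mass error

    ppm = 1e6 * (observed - theoretical) / theoretical

is within the search tolerance (default 10 ppm, reflecting realistic
accuracy of high-resolution FTMS surveys of plasma).

The M+H+2H2O form is interpreted as a two-water cluster on the protonated
ion (shift +1.007276 + 2*18.010565 Da), symmetric to the water-loss form.
All ions are assumed singly charged, appropriate for small molecules in
the m/z 85-850 window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .containers import MetaboliteRecord

# Monoisotopic element masses, Da (most abundant isotope).
ELEMENT_MASSES = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.9637069,
    "Cl": 34.96885271,
}

# Cation shifts are electron-corrected (proton = H minus electron mass, etc.).
PROTON = 1.007276
SODIUM_CATION = 22.989218
POTASSIUM_CATION = 38.963158
WATER = 18.010565

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported chemical formulas."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula like ``C26H43NO6`` into element counts."""
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"malformed formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"malformed formula {formula!r} near position {pos}"
            )
        elem, num = m.group(1), m.group(2)
        if elem not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element {elem!r} in {formula!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {elem} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    if pos != len(formula) or not counts:
        raise FormulaError(f"malformed formula: {formula!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a formula, in Daltons."""
    counts = parse_formula(formula)
    return float(sum(ELEMENT_MASSES[e] * n for e, n in counts.items()))


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode adduct form: observed m/z = M + mass_shift (z = 1)."""

    name: str
    mass_shift: float


M_PLUS_H = AdductSpec("M+H", PROTON)
M_PLUS_NA = AdductSpec("M+Na", SODIUM_CATION)
M_PLUS_K = AdductSpec("M+K", POTASSIUM_CATION)
M_PLUS_H_MINUS_H2O = AdductSpec("M+H-H2O", PROTON - WATER)
M_PLUS_H_PLUS_2H2O = AdductSpec("M+H+2H2O", PROTON + 2 * WATER)

#: Default search set (KEGG-style: all five forms).
DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = (
    M_PLUS_H,
    M_PLUS_NA,
    M_PLUS_K,
    M_PLUS_H_MINUS_H2O,
    M_PLUS_H_PLUS_2H2O,
)

#: Metlin-style batch preset: four forms, no potassium.
METLIN_BATCH_ADDUCTS: tuple[AdductSpec, ...] = (
    M_PLUS_H,
    M_PLUS_NA,
    M_PLUS_H_MINUS_H2O,
    M_PLUS_H_PLUS_2H2O,
)

ADDUCTS_BY_NAME = {a.name: a for a in DEFAULT_ADDUCTS}


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """Theoretical m/z of a singly charged adduct ion."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + adduct.mass_shift


@dataclass
class AnnotationConfig:
    """Search settings for database matching.

    ppm_tolerance
        Relative mass-error window. 10 ppm default; 9 and 5 are common
        stricter presets for FTMS instruments.
    adducts
        Adduct forms to search. ``DEFAULT_ADDUCTS`` or
        ``METLIN_BATCH_ADDUCTS``.
    mz_range
        Acquisition window in Daltons, used by the background-rate draw.
    """

    ppm_tolerance: float = 10.0
    adducts: Sequence[AdductSpec] = DEFAULT_ADDUCTS
    mz_range: tuple[float, float] = (85.0, 850.0)

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be > 0")
        if not self.adducts:
            raise ValueError("adduct set must be non-empty")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must be (low, high) with low < high")


@dataclass
class AnnotationHit:
    """A (feature, adduct, metabolite) match with its signed mass error."""

    feature_id: str
    record_id: str
    adduct: str
    theoretical_mz: float
    ppm_error: float  # signed: 1e6*(observed - theoretical)/theoretical


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def annotate_feature(
    mz_observed: float,
    db: Iterable[MetaboliteRecord],
    config: Optional[AnnotationConfig] = None,
    feature_id: str = "",
) -> list[AnnotationHit]:
    """All (record, adduct) matches within tolerance, best |ppm| first.

    Ties in |ppm| are broken by the adduct's position in the configured
    search order, making the result deterministic.
    """
    config = config or AnnotationConfig()
    hits: list[AnnotationHit] = []
    for rec in db:
        for k, adduct in enumerate(config.adducts):
            theo = adduct_mz(rec.monoisotopic_mass, adduct)
            err = ppm_error(mz_observed, theo)
            if abs(err) <= config.ppm_tolerance:
                hits.append(
                    AnnotationHit(feature_id, rec.record_id, adduct.name, theo, err)
                )
    order = {a.name: k for k, a in enumerate(config.adducts)}
    hits.sort(key=lambda h: (abs(h.ppm_error), order[h.adduct]))
    return hits


@dataclass
class ClusterAnnotation:
    """Batch annotation of an ion cluster: per-feature hits plus a summary."""

    cluster_id: str
    hits: dict[str, list[AnnotationHit]]
    matched_records: list[str]
    unmatched_features: list[str]


def annotate_cluster(cluster, mz, db, config=None) -> ClusterAnnotation:
    """Annotate every seed and satellite of an ion cluster as a batch.

    Parameters
    ----------
    cluster
        An ``IonCluster`` (see :mod:`mzmwas.correlation`).
    mz
        Mapping (e.g. ``pandas.Series``) from feature id to observed m/z.
    """
    config = config or AnnotationConfig()
    features = list(cluster.seed_features) + list(cluster.satellite_features)
    hits: dict[str, list[AnnotationHit]] = {}
    matched: list[str] = []
    unmatched: list[str] = []
    for fid in features:
        fh = annotate_feature(float(mz[fid]), db, config, feature_id=fid)
        hits[fid] = fh
        if fh:
            for h in fh:
                if h.record_id not in matched:
                    matched.append(h.record_id)
        else:
            unmatched.append(fid)
    return ClusterAnnotation(str(cluster.cluster_id), hits, matched, unmatched)


def background_match_rate(
    db: Sequence[MetaboliteRecord],
    config: Optional[AnnotationConfig] = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Fraction of uniform-random m/z values matching >= 1 database entry.

    Estimates the chance-match rate of the search settings: random
    high-resolution m/z values hit a metabolite database at a non-trivial
    rate, so an individual match carries limited evidence on its own.
    """
    config = config or AnnotationConfig()
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    lo, hi = config.mz_range
    draws = rng.uniform(lo, hi, size=n_draws)
    theo = np.sort(
        np.array(
            [
                adduct_mz(rec.monoisotopic_mass, adduct)
                for rec in db
                for adduct in config.adducts
            ]
        )
    )
    if theo.size == 0:
        return 0.0
    tol = config.ppm_tolerance * 1e-6
    # window half-width in Da grows with mass; bracket by searchsorted
    lo_edges = theo * (1 - tol)
    hi_edges = theo * (1 + tol)
    i_lo = np.searchsorted(hi_edges, draws, side="left")
    matched = (i_lo < theo.size) & (draws >= lo_edges[np.minimum(i_lo, theo.size - 1)])
    return float(np.mean(matched))
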