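"""Synthetic case-control LC-MS cohorts with known ground truth.

The generator emulates a positive-mode plasma profiling experiment: each
latent chemical has a per-sample log2 abundance

    a_ji = mu_j + beta_j * 1[case] + eps,   eps ~ N(0, sigma_between^2)

and emits several adduct features whose log2 intensities share that latent
abundance up to a fixed per-adduct ionization efficiency (drawn once per
chemical from a Dirichlet, giving realistic unequal ion heights) plus
per-measurement noise N(0, sigma_adduct^2).  Observed m/z is the adduct's
theoretical m/z perturbed by mass error N(0, (ppm_sd * mz / 1e6)^2).
Missingness is MNAR at low intensity (global limit-of-detection quantile
censoring) plus MCAR dropout, which exercises the presence filter the way
real peak tables do.

Every run returns the ground-truth map from chemicals to emitted features,
so detection sensitivity, false-discovery proportion, cluster recovery and
annotation accuracy are all measurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from .containers import (
    CASE,
    CONTROL,
    FeatureTable,
    MetaboliteRecord,
    ValidationError,
    make_feature_id,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Generative settings.

    Defaults mirror a 45-sample (26 case / 19 control) positive-mode ESI
    study over m/z 85-850 with ~3 correlated adduct features per chemical,
    moderate biological spread (sigma_between = 1 log2 unit), mild
    per-feature noise, and realistic missingness.
    """

    n_cases: int = 26
    n_controls: int = 19
    n_chemicals: int = 200
    adducts_per_chemical: int = 3
    differential_fraction: float = 0.10
    effect_size_log2: float = 1.0
    sigma_between: float = 1.0
    sigma_adduct: float = 0.2
    dropout_rate: float = 0.05
    lod_quantile: float = 0.05
    mz_error_ppm_sd: float = 3.0
    mz_range: tuple[float, float] = (85.0, 850.0)
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    rt_range: tuple[float, float] = (30.0, 570.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls < 4:
            raise ValidationError("need at least 4 samples")
        for name in ("sigma_between", "sigma_adduct", "mz_error_ppm_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("differential_fraction", "dropout_rate", "lod_quantile"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValidationError("mz_range must be increasing")
        if self.adducts_per_chemical < 1:
            raise ValidationError("adducts_per_chemical must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    chemical_features: dict[str, list[str]]  # chemical id -> feature ids
    chemical_effects: dict[str, tuple[bool, float]]  # id -> (differential, beta)
    feature_truth: dict[str, tuple[str, str]]  # feature -> (record id, adduct)

    @property
    def differential_chemicals(self) -> list[str]:
        return [c for c, (flag, _) in self.chemical_effects.items() if flag]

    def chemical_of(self) -> dict[str, str]:
        return {
            f: c for c, feats in self.chemical_features.items() for f in feats
        }


def simulate_dataset(
    config: SimulationConfig, db: Sequence[MetaboliteRecord]
) -> tuple[FeatureTable, pd.DataFrame, SyntheticTruth]:
    """Generate (feature table, sample metadata, ground truth).

    Chemicals are drawn without replacement from ``db``; a record whose
    perturbed adduct m/z falls outside the acquisition window is replaced
    by the next unused record (logged).  Bit-identical output under a
    fixed seed.
    """
    if len(db) < config.n_chemicals:
        raise ValidationError(
            f"db has {len(db)} records but {config.n_chemicals} chemicals requested"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    is_case = np.array([True] * config.n_cases + [False] * config.n_controls)
    samples = pd.DataFrame(
        {"group": np.where(is_case, CASE, CONTROL)}, index=pd.Index(sample_ids)
    )

    adducts = ann.DEFAULT_ADDUCTS[: config.adducts_per_chemical]
    if config.adducts_per_chemical > len(ann.DEFAULT_ADDUCTS):
        raise ValidationError(
            f"at most {len(ann.DEFAULT_ADDUCTS)} adducts per chemical supported"
        )
    pool = list(rng.permutation(len(db)))

    n_diff = round(config.differential_fraction * config.n_chemicals)
    diff_flags = np.zeros(config.n_chemicals, bool)
    diff_flags[rng.choice(config.n_chemicals, size=n_diff, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=config.n_chemicals)

    rows_log2 = []
    mz_list: list[float] = []
    rt_list: list[float] = []
    fids: list[str] = []
    chem_features: dict[str, list[str]] = {}
    chem_effects: dict[str, tuple[bool, float]] = {}
    feat_truth: dict[str, tuple[str, str]] = {}
    used_rts: set[float] = set()

    for j in range(config.n_chemicals):
        # draw a record whose perturbed adduct m/z stay inside the window
        while True:
            if not pool:
                raise ValidationError("db exhausted while resampling m/z range")
            rec = db[pool.pop(0)]
            theo = np.array([ann.adduct_mz(rec.monoisotopic_mass, a) for a in adducts])
            noise = rng.normal(0.0, config.mz_error_ppm_sd * theo / 1e6)
            mz_obs = theo + noise
            if np.all((mz_obs >= config.mz_range[0]) & (mz_obs <= config.mz_range[1])):
                break
            logger.info(
                "record %s adduct m/z outside %s; resampled", rec.record_id, config.mz_range
            )
        chem_id = f"chem{j + 1:04d}"
        beta = signs[j] * config.effect_size_log2 if diff_flags[j] else 0.0
        chem_effects[chem_id] = (bool(diff_flags[j]), float(beta))
        mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
        latent = (
            mu
            + beta * is_case.astype(float)
            + rng.normal(0.0, config.sigma_between, size=n)
        )
        eff = rng.dirichlet(np.full(len(adducts), 2.0))
        feats_j = []
        for k, adduct in enumerate(adducts):
            rt = float(rng.uniform(*config.rt_range))
            while round(rt, 2) in used_rts:  # keep (mz, rt) pairs unique
                rt = float(rng.uniform(*config.rt_range))
            used_rts.add(round(rt, 2))
            fid = make_feature_id(mz_obs[k], rt)
            log2_int = (
                latent
                + np.log2(eff[k])
                + rng.normal(0.0, config.sigma_adduct, size=n)
            )
            rows_log2.append(log2_int)
            mz_list.append(float(mz_obs[k]))
            rt_list.append(rt)
            fids.append(fid)
            feats_j.append(fid)
            feat_truth[fid] = (rec.record_id, adduct.name)
        chem_features[chem_id] = feats_j

    intens = np.power(2.0, np.array(rows_log2))
    # limit-of-detection censoring at a global intensity quantile, then MCAR
    if config.lod_quantile > 0:
        lod = np.quantile(intens, config.lod_quantile)
        intens = np.where(intens < lod, np.nan, intens)
    if config.dropout_rate > 0:
        drop = rng.random(intens.shape) < config.dropout_rate
        intens = np.where(drop, np.nan, intens)

    data = pd.DataFrame(intens, index=fids, columns=sample_ids)
    table = FeatureTable(
        data=data,
        mz=pd.Series(mz_list, index=fids),
        rt=pd.Series(rt_list, index=fids),
    )
    truth = SyntheticTruth(chem_features, chem_effects, feat_truth)
    return table, samples, truth


def truth_recovery_report(
    truth: SyntheticTruth,
    mwas_result=None,
    clusters: Optional[Sequence] = None,
    annotations: Optional[dict] = None,
    flag: str = "sig_raw",
) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    Returns a dict with (depending on which inputs are given):
    detection sensitivity and feature-level false-discovery proportion of
    the flagged significant list; adjusted Rand index between the cluster
    partition and the true chemical partition of seed features; and
    top-hit annotation accuracy.
    """
    report: dict = {}
    chem_of = truth.chemical_of()
    if mwas_result is not None:
        tab = mwas_result.table
        unknown = [f for f in tab.index if f not in chem_of]
        if unknown:
            raise ValidationError(
                f"mwas features not in truth universe: {unknown[:3]}"
            )
        sig = list(tab.index[tab[flag]])
        diff = set(truth.differential_chemicals)
        detected = {chem_of[f] for f in sig}
        n_diff = len(diff)
        report["n_significant"] = len(sig)
        report["sensitivity"] = (
            len(detected & diff) / n_diff if n_diff else float("nan")
        )
        n_false = sum(1 for f in sig if chem_of[f] not in diff)
        report["n_false_features"] = n_false
        report["fdp"] = n_false / len(sig) if sig else 0.0
    if clusters is not None:
        from sklearn.metrics import adjusted_rand_score

        seed_feats = [f for cl in clusters for f in cl.seed_features]
        if any(f not in chem_of for f in seed_feats):
            raise ValidationError("cluster features not in truth universe")
        pred = [cl.cluster_id for cl in clusters for _ in cl.seed_features]
        true = [chem_of[f] for f in seed_feats]
        report["cluster_ari"] = (
            float(adjusted_rand_score(true, pred)) if seed_feats else float("nan")
        )
    if annotations is not None:
        n_ok = n_tot = 0
        for fid, hits in annotations.items():
            if fid not in truth.feature_truth:
                raise ValidationError(f"annotated feature {fid!r} not in truth")
            if not hits:
                continue
            n_tot += 1
            if hits[0].record_id == truth.feature_truth[fid][0]:
                n_ok += 1
        report["annotation_top_hit_accuracy"] = (
            n_ok / n_tot if n_tot else float("nan")
        )
        report["n_annotated"] = n_tot
    return report


def synthetic_metabolite_db(
    n_records: int = 300,
    mz_range: tuple[float, float] = (85.0, 850.0),
    min_spacing_ppm: float = 25.0,
    seed: int = 0,
) -> list[MetaboliteRecord]:
    """A synthetic metabolite database with well-spaced neutral masses.

    Masses are drawn uniformly over the neutral-mass window implied by
    ``mz_range`` and thinned so neighbours are at least ``min_spacing_ppm``
    apart, which makes top-hit annotation unambiguous by construction.
    """
    rng = np.random.default_rng(seed)
    lo = mz_range[0] + 40.0  # headroom so all adduct forms stay in-window
    hi = mz_range[1] - 40.0
    masses = np.sort(rng.uniform(lo, hi, size=n_records * 4))
    kept: list[float] = []
    for m in masses:
        if not kept or (m - kept[-1]) / m * 1e6 >= min_spacing_ppm:
            kept.append(float(m))
        if len(kept) == n_records:
            break
    if len(kept) < n_records:
        raise ValidationError("could not place enough spaced masses")
    return [
        MetaboliteRecord(
            record_id=f"syn{i + 1:04d}",
            name=f"synthetic metabolite {i + 1}",
            monoisotopic_mass=m,
            source_tag="synthetic",
        )
        for i, m in enumerate(kept)
    ]
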