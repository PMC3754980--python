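"""Feature-wise case/control screening with dual-scale FDR control.

The screen follows the standard untargeted-metabolomics recipe: drop
features detected in fewer than half the samples, t-test every remaining
feature between groups on the raw intensity scale and again after log2
transformation, control each list with the Benjamini-Hochberg step-up
procedure (conventionally at q = 0.05 raw and q = 0.2 on the log scale),
and intersect the two significant lists.  Features significant on both
scales are robust to the transformation choice and become the focus of
downstream correlation and annotation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable, ValidationError, group_masks, validate_samples


@dataclass
class MwasConfig:
    """Screening thresholds.

    presence_threshold
        Minimum fraction of samples in which a feature must be detected.
    q_raw, q_log2
        BH FDR levels for the raw-scale and log2-scale significant lists.
    log2_offset
        Optional additive offset before log2 for data with true zeros;
        by default non-positive values simply stay missing.
    """

    presence_threshold: float = 0.50
    q_raw: float = 0.05
    q_log2: float = 0.20
    test_variant: str = "welch"
    log2_offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("presence_threshold", "q_raw", "q_log2"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.test_variant not in ("welch", "pooled"):
            raise ValidationError(f"unknown test variant {self.test_variant!r}")
        if self.log2_offset < 0:
            raise ValidationError("log2_offset must be >= 0")


@dataclass
class MwasResult:
    """Per-feature statistics and significance flags (``table`` has one row
    per tested feature; see :func:`run_mwas` for columns)."""

    table: pd.DataFrame
    config: MwasConfig

    @property
    def significant_raw(self) -> list[str]:
        return list(self.table.index[self.table["sig_raw"]])

    @property
    def significant_log2(self) -> list[str]:
        return list(self.table.index[self.table["sig_log2"]])

    @property
    def intersection(self) -> list[str]:
        return list(self.table.index[self.table["in_intersection"]])


def presence_filter(table: FeatureTable, threshold: float = 0.5) -> FeatureTable:
    """Keep features present (non-missing) in >= ``threshold`` of samples."""
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if table.n_features == 0:
        return table
    frac = table.data.notna().sum(axis=1) / table.n_samples
    keep = table.data.index[frac >= threshold]
    return table.subset(keep)


def feature_tests(
    table: FeatureTable,
    samples: pd.DataFrame,
    scale: str = "raw",
    variant: str = "welch",
) -> pd.DataFrame:
    """Two-tailed per-feature t-tests on the chosen scale.

    Returns a DataFrame indexed by feature id with columns ``t``, ``p``,
    ``n_case``, ``n_control`` and ``testable``.  Features with fewer than
    two present values in either group are flagged untestable (p = NaN) and
    are later excluded from the BH denominator.  Missing values are
    excluded pairwise, never imputed.
    """
    if scale not in ("raw", "log2"):
        raise ValidationError(f"unknown scale {scale!r}")
    validate_samples(samples)
    case_mask, ctrl_mask = group_masks(samples, table.sample_ids)
    values = table.data.to_numpy() if scale == "raw" else table.log2().to_numpy()
    xc = values[:, case_mask]
    xk = values[:, ctrl_mask]
    n_case = np.sum(~np.isnan(xc), axis=1)
    n_ctrl = np.sum(~np.isnan(xk), axis=1)
    testable = (n_case >= 2) & (n_ctrl >= 2)
    t = np.full(table.n_features, np.nan)
    p = np.full(table.n_features, np.nan)
    if testable.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                xc[testable],
                xk[testable],
                axis=1,
                nan_policy="omit",
                equal_var=(variant == "pooled"),
            )
        tt = np.asarray(res.statistic, float)
        pp = np.asarray(res.pvalue, float)
        # both groups constant: scipy yields NaN; equal means -> no evidence
        bad = np.isnan(tt)
        if bad.any():
            mc = np.nanmean(xc[testable], axis=1)
            mk = np.nanmean(xk[testable], axis=1)
            eq = np.isclose(mc, mk)
            tt[bad & eq] = 0.0
            pp[bad & eq] = 1.0
            tt[bad & ~eq] = np.sign((mc - mk)[bad & ~eq]) * np.inf
            pp[bad & ~eq] = 0.0
        t[testable] = tt
        p[testable] = pp
    return pd.DataFrame(
        {"t": t, "p": p, "n_case": n_case, "n_control": n_ctrl, "testable": testable},
        index=table.data.index,
    )


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(qvalues, reject)``: the monotone adjusted values
    min_{j>=i} p(j)*m/j capped at 1, and the step-up rejection flags
    (reject all i <= max{i : p(i) <= i*q/m}).  The flags equal
    ``qvalues <= q`` by construction.  NaN p-values are excluded from the
    denominator m and never rejected.
    """
    if not (0 < q < 1):
        raise ValidationError(f"q must be in (0, 1), got {q}")
    p = np.asarray(pvalues, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    qvals = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, bool)
    mask = ~np.isnan(p)
    m = int(mask.sum())
    if m == 0:
        return qvals, reject
    ps = p[mask]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order]
    ranks = np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate((ranked * m / ranks)[::-1])[::-1], 1.0)
    below = np.nonzero(ranked <= ranks * q / m)[0]
    k = int(below[-1]) + 1 if below.size else 0
    rej_sorted = np.zeros(m, bool)
    rej_sorted[:k] = True
    qv = np.empty(m)
    qv[order] = adj
    rj = np.empty(m, bool)
    rj[order] = rej_sorted
    qvals[mask] = qv
    reject[mask] = rj
    return qvals, reject


def run_mwas(
    table: FeatureTable,
    samples: pd.DataFrame,
    config: Optional[MwasConfig] = None,
) -> MwasResult:
    """Dual-scale screen on a presence-filtered table.

    Result columns: ``mz``, ``rt``, ``n_present``, ``t_raw``, ``p_raw``,
    ``q_raw_adj``, ``sig_raw``, ``t_log2``, ``p_log2``, ``q_log2_adj``,
    ``sig_log2``, ``in_intersection``, ``direction`` (whether the feature
    is higher or lower in cases, from raw group means).
    """
    config = config or MwasConfig()
    raw = feature_tests(table, samples, "raw", config.test_variant)
    logt = feature_tests(table, samples, "log2", config.test_variant)
    q_raw_adj, sig_raw = bh_fdr(raw["p"].to_numpy(), config.q_raw)
    q_log2_adj, sig_log2 = bh_fdr(logt["p"].to_numpy(), config.q_log2)
    case_mask, ctrl_mask = group_masks(samples, table.sample_ids)
    vals = table.data.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_case = np.nanmean(vals[:, case_mask], axis=1)
        mean_ctrl = np.nanmean(vals[:, ctrl_mask], axis=1)
    direction = np.where(mean_case > mean_ctrl, "higher", "lower")
    out = pd.DataFrame(
        {
            "mz": table.mz,
            "rt": table.rt,
            "n_present": table.data.notna().sum(axis=1),
            "t_raw": raw["t"],
            "p_raw": raw["p"],
            "q_raw_adj": q_raw_adj,
            "sig_raw": sig_raw,
            "t_log2": logt["t"],
            "p_log2": logt["p"],
            "q_log2_adj": q_log2_adj,
            "sig_log2": sig_log2,
            "in_intersection": sig_raw & sig_log2,
            "direction": direction,
        },
        index=table.data.index,
    )
    return MwasResult(table=out, config=config)


def manhattan_export(result: MwasResult, scale: str = "raw") -> pd.DataFrame:
    """Rows (mz, -log10 p, significant) ordered by increasing m/z, for a
    Manhattan plot of the screen."""
    col_p = "p_raw" if scale == "raw" else "p_log2"
    col_sig = "sig_raw" if scale == "raw" else "sig_log2"
    t = result.table
    tested = t[t[col_p].notna()]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(tested[col_p].to_numpy())
    out = pd.DataFrame(
        {"mz": tested["mz"], "neg_log10_p": neglog, "significant": tested[col_sig]},
        index=tested.index,
    )
    return out.sort_values("mz", kind="mergesort")
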