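"""Ion-correlation structure of discriminatory features.

Features deriving from the same chemical (adducts, water clusters,
isotopes) rise and fall together across samples, so their pairwise
Pearson correlation is high — empirically often above 0.81.  Given a set
of discriminatory *seed* features, this module builds the thresholded
correlation graph over the full filtered table, groups seeds into
clusters via seed-seed edges, and attaches the remaining correlated
features as satellites, reproducing the familiar
"cluster | m/z | correlated features" report layout.

Clusters are defined by seed-seed connectivity only.  Merging through a
shared satellite would conflate chemically unrelated seeds that happen to
co-correlate with one background feature, so a seed whose only links are
to non-seed features is reported as "Independent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import FeatureTable, ValidationError


@dataclass
class CorrelationConfig:
    r_threshold: float = 0.81  # strict: r must exceed this
    scale: str = "log2"
    min_overlap: int = 10  # minimum paired non-missing samples per pair

    def __post_init__(self) -> None:
        if not (0 < self.r_threshold < 1):
            raise ValidationError("r_threshold must be in (0, 1)")
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.min_overlap < 3:
            raise ValidationError("min_overlap must be >= 3")


@dataclass
class IonCluster:
    """A connected component of seed features plus its satellites.

    seed_correlates maps each seed to its full correlate list
    [(feature_id, r), ...] in rank order of r — the per-row content of the
    cluster report.
    """

    cluster_id: str
    seed_features: list[str]
    satellite_features: list[str]
    seed_edges: list[tuple[str, str, float]]
    seed_correlates: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


def correlation_matrix(
    table: FeatureTable, config: Optional[CorrelationConfig] = None
) -> pd.DataFrame:
    """Feature-feature Pearson correlations with pairwise-complete handling.

    Pairs with fewer than ``min_overlap`` shared non-missing samples, and
    pairs involving a constant feature, are NaN.  Diagonal is 1.
    """
    config = config or CorrelationConfig()
    values = table.data if config.scale == "raw" else table.log2()
    mat = values.T.corr(min_periods=config.min_overlap)
    np.fill_diagonal(mat.to_numpy(), 1.0)
    return mat


def build_clusters(
    discriminatory: Sequence[str],
    matrix: pd.DataFrame,
    full_table: FeatureTable,
    config: Optional[CorrelationConfig] = None,
) -> tuple[list[IonCluster], list[IonCluster]]:
    """Cluster discriminatory seeds by thresholded correlation.

    Returns ``(clusters, independents)``.  A seed is retained only if it
    correlates above threshold with at least one other feature in the
    matrix.  Retained seeds connected by seed-seed edges form clusters;
    retained seeds without any seed-seed edge are independent (returned as
    single-seed clusters labelled ``Independent``).  Satellites are the
    non-seed correlated features, rank-ordered by their best r against the
    cluster's seeds.
    """
    config = config or CorrelationConfig()
    missing = [f for f in discriminatory if f not in matrix.index]
    if missing:
        raise ValidationError(f"features not in correlation matrix: {missing[:3]}")
    # canonical order: by (mz, rt) so output is independent of input order
    order_key = {
        fid: (float(full_table.mz[fid]), float(full_table.rt[fid]))
        for fid in discriminatory
    }
    seeds = sorted(set(discriminatory), key=lambda f: order_key[f])
    thr = config.r_threshold

    correlates: dict[str, list[tuple[str, float]]] = {}
    for s in seeds:
        r = matrix.loc[s].drop(labels=[s])
        hit = r[r > thr].dropna()
        if len(hit):
            ranked = sorted(hit.items(), key=lambda kv: (-kv[1], kv[0]))
            correlates[s] = [(f, float(v)) for f, v in ranked]
    retained = [s for s in seeds if s in correlates]
    seed_set = set(retained)

    g = nx.Graph()
    g.add_nodes_from(retained)
    for s in retained:
        for f, r in correlates[s]:
            if f in seed_set:
                g.add_edge(s, f, r=r)

    clusters: list[IonCluster] = []
    independents: list[IonCluster] = []
    comps = [sorted(c, key=lambda f: order_key[f]) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: order_key[c[0]])
    n_cluster = 0
    for comp in comps:
        sats: dict[str, float] = {}
        for s in comp:
            for f, r in correlates[s]:
                if f not in seed_set and (f not in sats or r > sats[f]):
                    sats[f] = r
        sat_list = [f for f, _ in sorted(sats.items(), key=lambda kv: (-kv[1], kv[0]))]
        edges = [
            (u, v, float(g.edges[u, v]["r"]))
            for u, v in g.edges(comp)
            if u in comp and v in comp
        ]
        sub = {s: correlates[s] for s in comp}
        if len(comp) >= 2:
            n_cluster += 1
            clusters.append(
                IonCluster(str(n_cluster), comp, sat_list, edges, sub)
            )
        else:
            independents.append(
                IonCluster("Independent", comp, sat_list, [], sub)
            )
    return clusters, independents


def cluster_report(
    clusters: Sequence[IonCluster],
    independents: Sequence[IonCluster],
    mz: pd.Series,
    precision: int = 3,
) -> pd.DataFrame:
    """One row per seed: cluster label, seed m/z, rank-ordered correlate
    list — the printed cluster-table layout.  m/z values are formatted at
    the requested precision."""

    def fmt(fid: str) -> str:
        return f"{float(mz[fid]):.{precision}f}"

    rows = []
    for cl in list(clusters) + list(independents):
        for s in cl.seed_features:
            rows.append(
                {
                    "cluster": cl.cluster_id,
                    "mz": fmt(s),
                    "correlated_features": ", ".join(
                        fmt(f) for f, _ in cl.seed_correlates.get(s, [])
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "mz", "correlated_features"])


def render_report_rows(report: pd.DataFrame) -> list[str]:
    """Serialize report rows as tab-separated lines (header first)."""
    lines = ["cluster\tmz\tcorrelated_features"]
    for _, row in report.iterrows():
        corr = row["correlated_features"]
        if isinstance(corr, list):
            corr = ", ".join(corr)
        lines.append(f"{row['cluster']}\t{row['mz']}\t{corr}")
    return lines


def edge_list(matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """All feature pairs with r strictly above threshold (upper triangle)."""
    cols = matrix.columns
    arr = matrix.to_numpy(copy=True)
    iu = np.triu_indices(len(cols), k=1)
    r = arr[iu]
    keep = ~np.isnan(r) & (r > threshold)
    return pd.DataFrame(
        {
            "feature_a": cols[iu[0][keep]],
            "feature_b": cols[iu[1][keep]],
            "r": r[keep],
        }
    )
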