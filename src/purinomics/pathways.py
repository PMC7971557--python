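"""Pathway-impact ranking and k-NN supercluster detection.

Significant metabolites are grouped into biochemical pathways and each
pathway's impact is the sum of its members' VIP scores; pathways are
rank-ordered by that sum.  Superclusters — sets of metabolites whose
responses are coordinated regardless of pathway membership — are found by
agglomerative merging constrained to a k-nearest-neighbor graph over
metabolite z profiles, and ranked by threshold-gated summed VIP and summed
positive MDA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import kneighbors_graph

from .preprocess import ZScoreMatrix


def aggregate_pathway_vip(
    significant, vip: pd.Series, pathway_map: pd.Series,
    mean_z: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank pathways by summed VIP over their significant members.

    Returns a DataFrame (pathway, n_members, n_significant, vip_sum,
    direction, rank) sorted by descending vip_sum; ties broken by member
    count, then pathway name.  ``direction`` is computed when ``mean_z``
    is given, else "unknown".
    """
    significant = pd.Index(significant)
    missing = significant.difference(vip.index)
    if len(missing):
        raise ValueError(f"VIP missing for significant metabolite {missing[0]!r}")
    missing = significant.difference(pathway_map.index)
    if len(missing):
        raise ValueError(f"pathway missing for significant metabolite {missing[0]!r}")
    rows = []
    for pathway, members in pathway_map.groupby(pathway_map):
        sig_members = members.index.intersection(significant)
        if len(sig_members) == 0:
            continue
        if mean_z is not None:
            direction = classify_pathway_direction(mean_z.reindex(sig_members))
        else:
            direction = "unknown"
        rows.append(
            {
                "pathway": pathway,
                "n_members": int(len(members)),
                "n_significant": int(len(sig_members)),
                "vip_sum": float(vip.reindex(sig_members).sum()),
                "direction": direction,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "n_members", "n_significant", "vip_sum",
                     "direction", "rank"]
        )
    out = pd.DataFrame(rows).sort_values(
        by=["vip_sum", "n_significant", "pathway"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def classify_pathway_direction(member_mean_z: pd.Series) -> str:
    """Classify a pathway as increased, decreased or mixed.

    Increased if every significant member's mean z is positive, decreased
    if all are negative, mixed otherwise.
    """
    vals = np.asarray(member_mean_z, dtype=float)
    if vals.size == 0:
        raise ValueError("need >= 1 significant member to classify direction")
    if np.all(vals > 0):
        return "increased"
    if np.all(vals < 0):
        return "decreased"
    return "mixed"


def count_changed(n_significant: int, n_total: int) -> tuple[int, int]:
    """Count and integer percent of changed metabolites, e.g. (202, 401) -> 50%."""
    if n_total < n_significant:
        raise ValueError("total cannot be smaller than the significant count")
    if n_total <= 0:
        raise ValueError("total must be positive")
    percent = int(np.floor(100.0 * n_significant / n_total + 0.5))
    return int(n_significant), percent


def knn_superclusters(
    z, k_neighbors: int = 10, n_clusters: int = 10, seed: int = 0
) -> pd.Series:
    """Partition metabolites into superclusters of coordinated response.

    Each metabolite's profile is its z vector across samples.  A symmetric
    k-nearest-neighbor graph (Euclidean) is built over profiles and
    Ward-linkage agglomerative merging restricted to graph edges proceeds
    until exactly ``n_clusters`` remain.  Deterministic for fixed input;
    ``seed`` is accepted for interface stability but the procedure has no
    random element.
    """
    zdf = z.z if isinstance(z, ZScoreMatrix) else z
    profiles = zdf.T  # metabolites x samples
    m = profiles.shape[0]
    if n_clusters > m:
        raise ValueError(f"n_clusters = {n_clusters} exceeds {m} metabolites")
    if m == 1:
        return pd.Series([0], index=profiles.index, name="supercluster")
    X = profiles.to_numpy(dtype=float)
    k = int(min(k_neighbors, m - 1))
    graph = kneighbors_graph(X, n_neighbors=k, mode="connectivity",
                             include_self=False)
    graph = 0.5 * (graph + graph.T)  # symmetrize: union of neighbor relations
    with warnings.catch_warnings():
        # a disconnected kNN graph is completed hierarchically by sklearn
        warnings.simplefilter("ignore", UserWarning)
        model = AgglomerativeClustering(
            n_clusters=n_clusters, linkage="ward", connectivity=graph
        )
        labels = model.fit_predict(X)
    # Renumber clusters deterministically by first member in column order.
    first_seen = {}
    for lab in labels:
        if lab not in first_seen:
            first_seen[lab] = len(first_seen)
    labels = np.array([first_seen[lab] for lab in labels])
    return pd.Series(labels, index=profiles.index, name="supercluster")


@dataclass
class SuperClusterReport:
    """Ranked supercluster table plus the member partition."""

    table: pd.DataFrame
    members: dict


def rank_clusters(
    clusters: pd.Series,
    vip: pd.Series,
    mda: pd.Series,
    vip_threshold: float = 1.0,
) -> pd.DataFrame:
    """Rank superclusters by threshold-gated summed VIP, then positive MDA.

    Cluster score = sum of member VIPs that meet ``vip_threshold``;
    secondary key = sum of members' positive MDA; impact fraction = cluster
    score / total score over clusters.  If every score is zero the impact
    is spread uniformly with a warning.
    """
    missing = clusters.index.difference(vip.index)
    if len(missing):
        raise ValueError(f"VIP missing for metabolite {missing[0]!r}")
    missing = clusters.index.difference(mda.index)
    if len(missing):
        raise ValueError(f"MDA missing for metabolite {missing[0]!r}")
    rows = []
    for cid, members in clusters.groupby(clusters):
        mv = vip.reindex(members.index)
        md = mda.reindex(members.index)
        rows.append(
            {
                "cluster": cid,
                "n_members": int(len(members)),
                "n_gated": int((mv >= vip_threshold).sum()),
                "vip_sum": float(mv[mv >= vip_threshold].sum()),
                "mda_sum": float(md[md > 0].sum()),
                "first_member": str(sorted(members.index)[0]),
            }
        )
    out = pd.DataFrame(rows)
    total = out["vip_sum"].sum()
    if total == 0:
        warnings.warn("all cluster scores are zero; uniform impact fractions",
                      stacklevel=2)
        out["impact_fraction"] = 1.0 / len(out)
    else:
        out["impact_fraction"] = out["vip_sum"] / total
    out = out.sort_values(
        by=["vip_sum", "mda_sum", "first_member"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.drop(columns="first_member")


def cluster_summary(members, zmat: ZScoreMatrix) -> tuple[float, float]:
    """Mean +/- SD of member-level mean treated z for one supercluster.

    Each member metabolite contributes its mean z over treated samples;
    the summary is the mean and sample SD of those member-level means
    (SD reported as 0 for a single member).
    """
    members = pd.Index(members)
    if len(members) == 0:
        raise ValueError("empty cluster")
    member_means = zmat.mean_treated_z().reindex(members)
    if member_means.isna().any():
        bad = member_means.index[member_means.isna()][0]
        raise ValueError(f"member {bad!r} absent from the z matrix")
    mean = float(member_means.mean())
    sd = float(member_means.std(ddof=1)) if len(members) > 1 else 0.0
    return mean, sd
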