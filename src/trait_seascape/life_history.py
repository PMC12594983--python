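"""Life-history strategy classification of benthic taxa (POSE scheme).

Taxa are ordinated by fuzzy correspondence analysis of their response
traits; Ward hierarchical clustering of the taxon scores on the first two
FCA axes partitions the pool into life-history groups. Groups are then
labelled against four canonical archetypes defined by pace of life and
juvenile mortality:

* Precocial   — fast life cycle, low juvenile mortality (brooded or
  internally developing offspring, low fecundity);
* Opportunist — fast life cycle, high juvenile mortality (high fecundity,
  unprotected planktotrophic larvae);
* Survivor    — slow life cycle, low juvenile mortality;
* Episodic    — slow life cycle, high juvenile mortality (longevity buys
  repeated chances at episodic recruitment success).

Labelling matches cluster-mean fuzzy profiles to archetype template
profiles over five diagnostic traits (lifespan LS, age at maturity AM,
annual fecundity FEC, offspring protection OP, offspring development OD)
by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .ordination import OrdinationResult, fca
from .tables import FuzzyTraitTable

logger = logging.getLogger(__name__)

GROUPS = ("Precocial", "Opportunist", "Survivor", "Episodic")

# Archetype template profiles over the diagnostic response traits.
# Values are modality affinities (rows normalize to 1 internally).
ARCHETYPE_PROFILES: dict[str, dict[str, dict[str, float]]] = {
    "Precocial": {
        "LS": {"< 1": 1.0, "1-3": 1.0},
        "AM": {"< 1": 1.0},
        "FEC": {"< 1e2": 1.0, "1e2-1e3": 0.5},
        "OP": {"Bearing/Brooding": 1.0, "Capsule": 0.5},
        "OD": {"Internal": 1.0, "Lecithotrophic": 0.3},
    },
    "Opportunist": {
        "LS": {"< 1": 1.0, "1-3": 1.0},
        "AM": {"< 1": 1.0, "1-3": 0.3},
        "FEC": {"1e3-1e4": 0.5, "1e4-1e5": 1.0, "1e5-1e6": 0.5},
        "OP": {"None": 1.0},
        "OD": {"Planktotrophic": 1.0, "Mixed planktotrophic": 0.3},
    },
    "Survivor": {
        "LS": {"10-20": 1.0, "> 20": 1.0},
        "AM": {"> 3": 1.0},
        "FEC": {"< 1e2": 1.0, "1e2-1e3": 0.5},
        "OP": {"Bearing/Brooding": 0.5, "Capsule": 1.0},
        "OD": {"Lecithotrophic": 1.0, "Internal": 0.5},
    },
    "Episodic": {
        "LS": {"3-10": 1.0, "10-20": 1.0},
        "AM": {"1-3": 1.0, "> 3": 0.5},
        "FEC": {"1e5-1e6": 1.0, "> 1e6": 1.0},
        "OP": {"None": 1.0},
        "OD": {"Planktotrophic": 1.0},
    },
}

DIAGNOSTIC_TRAITS = ("LS", "AM", "FEC", "OP", "OD")


@dataclass
class LifeHistoryAssignment:
    """Cluster membership, labels and the ordination behind them."""

    labels: pd.Series            # taxon -> group label (may hold NaN if unresolved)
    clusters: pd.Series          # taxon -> integer cluster id
    fca_result: OrdinationResult
    linkage_matrix: np.ndarray
    k: int

    def write_csv(self, path) -> None:
        out = pd.DataFrame({"cluster": self.clusters, "group": self.labels})
        out = out.join(self.fca_result.row_scores.iloc[:, :2])
        out.index.name = "taxon"
        out.to_csv(path)


def ward_cluster(scores: pd.DataFrame, k: int) -> tuple[pd.Series, np.ndarray]:
    """Ward agglomeration of taxon scores; returns cluster ids and linkage.

    Deterministic for a given input order; scipy breaks merge ties by the
    lowest pair index. Merge heights are non-decreasing by construction
    of the Ward criterion on Euclidean coordinates.
    """
    n = len(scores)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} taxa available")
    Zl = linkage(scores.to_numpy(dtype=float), method="ward")
    ids = fcluster(Zl, t=k, criterion="maxclust")
    return pd.Series(ids, index=scores.index, name="cluster"), Zl


def _template_vector(group: str, columns: pd.MultiIndex) -> np.ndarray:
    vec = np.zeros(len(columns))
    prof = ARCHETYPE_PROFILES[group]
    for i, (trait, modality) in enumerate(columns):
        vec[i] = prof.get(trait, {}).get(modality, 0.0)
    # normalize each trait block to sum 1 so traits weigh equally
    for trait in {t for t, _ in columns}:
        idx = [i for i, (t, _) in enumerate(columns) if t == trait]
        s = vec[idx].sum()
        if s > 0:
            vec[idx] /= s
    return vec


def label_groups(clusters: pd.Series, Q_response: FuzzyTraitTable,
                 tie_margin: float = 1e-9) -> pd.Series:
    """Label each cluster with the best-matching POSE archetype.

    Matching uses cosine similarity between the cluster-mean fuzzy
    profile and each archetype template, restricted to the diagnostic
    traits present in the table. When two clusters claim the same
    archetype, the weaker match falls back to its next-best unused label;
    an unresolvable tie leaves the cluster unlabeled with a warning.
    """
    prof = Q_response.to_profile()
    traits = [t for t in DIAGNOSTIC_TRAITS if t in prof.traits]
    if not traits:
        raise ValueError("no diagnostic response traits available for labelling")
    sub = prof.data[[c for c in prof.data.columns if c[0] in traits]]

    cluster_ids = sorted(clusters.unique())
    sims = pd.DataFrame(index=cluster_ids, columns=list(GROUPS), dtype=float)
    for cid in cluster_ids:
        mean = sub.loc[clusters.index[clusters == cid]].mean(axis=0).to_numpy()
        for g in GROUPS:
            tv = _template_vector(g, sub.columns)
            denom = np.linalg.norm(mean) * np.linalg.norm(tv)
            sims.loc[cid, g] = float(mean @ tv / denom) if denom > 0 else 0.0

    # greedy assignment, best matches first
    assignment: dict[int, str | None] = {}
    pairs = sorted(
        ((sims.loc[c, g], c, g) for c in cluster_ids for g in GROUPS), reverse=True
    )
    used_groups: set[str] = set()
    for s, c, g in pairs:
        if c in assignment or g in used_groups:
            continue
        runner = sims.loc[c].drop(list(used_groups | {g})).max() if len(used_groups) + 1 < len(GROUPS) else -np.inf
        if np.isfinite(runner) and abs(s - runner) <= tie_margin:
            logger.warning("cluster %s: archetype tie (%.6f); left unlabeled", c, s)
            assignment[c] = None
            continue
        assignment[c] = g
        used_groups.add(g)
    return clusters.map(lambda c: assignment.get(c))


def assign_life_history(Q_response: FuzzyTraitTable, k: int = 4,
                        row_weights: pd.Series | None = None) -> LifeHistoryAssignment:
    """FCA of response traits + Ward clustering on the first two axes.

    ``k`` defaults to 4 (the full POSE scheme); if the realized pool only
    expresses fewer syndromes the labelling step simply leaves some
    archetypes unused. Taxa with missing response-trait blocks are
    excluded beforehand by the caller (``complete_taxa``).
    """
    ord_res = fca(Q_response, row_weights=row_weights)
    n_axes = min(2, ord_res.rank)
    if n_axes == 0:
        raise ValueError("zero-inertia FCA: all taxa have identical profiles")
    scores = ord_res.row_scores.iloc[:, :n_axes]
    clusters, Zl = ward_cluster(scores, k=min(k, len(scores)))
    labels = label_groups(clusters, Q_response)
    return LifeHistoryAssignment(labels=labels, clusters=clusters,
                                 fca_result=ord_res, linkage_matrix=Zl, k=k)
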