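"""Four-condition expression-pattern gene-group selection.

The procedure extracts two gene groups from a Control / Paraquat / Cdk12i /
Cdk12i+Paraquat count matrix:

* **Group A** — genes induced by paraquat in a Cdk12-dependent way.  The
  condition-mean profile must sit in a cluster with a low-high-low-low shape,
  and the gene must pass: log2FC(Paraquat/Control) > 1 with q < 0.05;
  log2FC(Cdk12i/Control) > -1; and the geometric-mean inequality
  ``mean(Cdk12i) < sqrt(mean(Control) * mean(Paraquat))``.
* **Group B** — genes whose paraquat response is suppressed by Cdk12:
  low-low-low-high cluster shape plus log2FC > 0 with q < 0.05 in both
  Cdk12i+Paraquat/Paraquat and Cdk12i+Paraquat/Cdk12i, and q < 0.05 (either
  direction) in Cdk12i/Control.

Both groups additionally require at least one read in every sample.
Profiles are row-standardized condition means clustered agglomeratively
(average linkage) under one-minus-Pearson distance; clusters are labelled
low/high per condition from the sign of the centroid, and every cluster
matching the target template is pooled before the threshold filters.  All
inequalities are strict, and a per-gene audit records every criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .destats import condition_means, cpm_normalize, differential_test
from .io import CONDITIONS

GROUP_A_PATTERN = ("low", "high", "low", "low")
GROUP_B_PATTERN = ("low", "low", "low", "high")

#: the ordered condition pairs the criteria reference
PAIR_PQ_CTRL = ("Paraquat", "Control")
PAIR_CDK_CTRL = ("Cdk12i", "Control")
PAIR_CPQ_PQ = ("Cdk12i_Paraquat", "Paraquat")
PAIR_CPQ_CDK = ("Cdk12i_Paraquat", "Cdk12i")
ALL_PAIRS = (PAIR_PQ_CTRL, PAIR_CDK_CTRL, PAIR_CPQ_PQ, PAIR_CPQ_CDK)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the two five-criteria filters (strict inequalities)."""

    min_reads_per_sample: int = 1
    # Group A
    lfc_pq_ctrl_min: float = 1.0
    q_pq_ctrl_max: float = 0.05
    lfc_cdk_ctrl_min: float = -1.0
    geometric_mean_rule: bool = True
    # Group B
    lfc_cpq_pq_min: float = 0.0
    q_cpq_pq_max: float = 0.05
    q_cdk_ctrl_max: float = 0.05
    lfc_cpq_cdk_min: float = 0.0
    q_cpq_cdk_max: float = 0.05

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
        for name in ("q_pq_ctrl_max", "q_cpq_pq_max", "q_cdk_ctrl_max", "q_cpq_cdk_max"):
            q = getattr(self, name)
            if not (0 < q <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class SelectionResult:
    """Selected gene groups plus the full per-gene audit trail."""

    group_a: list[str]
    group_b: list[str]
    audit: pd.DataFrame
    clusters: pd.DataFrame = field(default=None, repr=False)
    de: dict = field(default=None, repr=False)
    summary: pd.DataFrame = field(default=None, repr=False)
    profiles: pd.DataFrame = field(default=None, repr=False)


def filter_min_reads(counts: pd.DataFrame, min_reads: int = 1) -> pd.Index:
    """Genes whose minimum raw count over all samples is at least ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    return counts.index[counts.min(axis=1) >= min_reads]


def profile_standardize(summary: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Row-standardize condition-mean profiles to mean 0, sd 1.

    Rows with zero variance carry no shape information and Pearson
    correlation is undefined for them; they are returned separately as
    ``flat`` and excluded from the standardized output.
    """
    mu = summary.mean(axis=1)
    sd = summary.std(axis=1, ddof=0)
    flat = summary.index[sd == 0]
    keep = summary.index[sd > 0]
    z = summary.loc[keep].sub(mu.loc[keep], axis=0).div(sd.loc[keep], axis=0)
    return z, flat


def cluster_profiles(profiles: pd.DataFrame, k: int) -> pd.Series:
    """Average-linkage hierarchical clustering under 1 - Pearson distance.

    The tree is cut into ``k`` clusters; ids are dense from 0 in order of
    first appearance, so identical input yields an identical assignment.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} clusterable profiles")
    d = pdist(profiles.to_numpy(float), metric="correlation")
    labels = fcluster(linkage(d, method="average"), t=k, criterion="maxclust")
    remap, dense = {}, []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
        dense.append(remap[lab])
    return pd.Series(dense, index=profiles.index, name="cluster_id")


def cluster_centroids(profiles: pd.DataFrame, assign: pd.Series) -> pd.DataFrame:
    """Mean standardized profile per cluster, indexed by cluster id."""
    return profiles.groupby(assign).mean()


def label_cluster_pattern(centroid) -> tuple[str, ...]:
    """Label each condition high/low from the centroid sign.

    An entry above 0 (above the gene-row mean on the standardized scale) is
    ``high``; entries at exactly 0 tie-break to ``low``.
    """
    return tuple("high" if v > 0 else "low" for v in np.asarray(centroid, dtype=float))


def _require(de: dict, pairs) -> None:
    missing = [p for p in pairs if p not in de]
    if missing:
        raise ValueError(f"missing DE comparison(s): {missing}")


def apply_group_a_criteria(
    genes,
    de: dict,
    summary: pd.DataFrame,
    crit: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[str], pd.DataFrame]:
    """Threshold filters for the paraquat-induced, Cdk12-dependent group.

    ``genes`` are the pattern-cluster candidates; ``de`` maps the ordered
    condition pairs to DataFrames with ``log2fc``/``q``.  Returns the passing
    genes and an audit with the evaluated quantity and verdict per criterion.
    """
    _require(de, (PAIR_PQ_CTRL, PAIR_CDK_CTRL))
    genes = list(genes)
    pq = de[PAIR_PQ_CTRL].loc[genes]
    cdk = de[PAIR_CDK_CTRL].loc[genes]
    s = summary.loc[genes]
    geom_bound = np.sqrt(s["Control"] * s["Paraquat"])
    audit = pd.DataFrame(
        {
            "log2fc_pq_ctrl": pq["log2fc"],
            "q_pq_ctrl": pq["q"],
            "c3_pq_induced": (pq["log2fc"] > crit.lfc_pq_ctrl_min)
            & (pq["q"] < crit.q_pq_ctrl_max),
            "log2fc_cdk_ctrl": cdk["log2fc"],
            "c4_not_down_in_cdk12i": cdk["log2fc"] > crit.lfc_cdk_ctrl_min,
            "mean_cdk12i": s["Cdk12i"],
            "geom_bound": geom_bound,
            "c5_geometric_mean": (s["Cdk12i"] < geom_bound)
            if crit.geometric_mean_rule
            else True,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    audit["selected"] = (
        audit["c3_pq_induced"] & audit["c4_not_down_in_cdk12i"] & audit["c5_geometric_mean"]
    )
    return list(audit.index[audit["selected"]]), audit


def apply_group_b_criteria(
    genes,
    de: dict,
    crit: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[str], pd.DataFrame]:
    """Threshold filters for the Cdk12-suppressed-under-paraquat group."""
    _require(de, (PAIR_CPQ_PQ, PAIR_CDK_CTRL, PAIR_CPQ_CDK))
    genes = list(genes)
    cpq_pq = de[PAIR_CPQ_PQ].loc[genes]
    cdk = de[PAIR_CDK_CTRL].loc[genes]
    cpq_cdk = de[PAIR_CPQ_CDK].loc[genes]
    audit = pd.DataFrame(
        {
            "log2fc_cpq_pq": cpq_pq["log2fc"],
            "q_cpq_pq": cpq_pq["q"],
            "c3_up_cpq_vs_pq": (cpq_pq["log2fc"] > crit.lfc_cpq_pq_min)
            & (cpq_pq["q"] < crit.q_cpq_pq_max),
            "q_cdk_ctrl": cdk["q"],
            "c4_changed_cdk_vs_ctrl": cdk["q"] < crit.q_cdk_ctrl_max,
            "log2fc_cpq_cdk": cpq_cdk["log2fc"],
            "q_cpq_cdk": cpq_cdk["q"],
            "c5_up_cpq_vs_cdk": (cpq_cdk["log2fc"] > crit.lfc_cpq_cdk_min)
            & (cpq_cdk["q"] < crit.q_cpq_cdk_max),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    audit["selected"] = (
        audit["c3_up_cpq_vs_pq"] & audit["c4_changed_cdk_vs_ctrl"] & audit["c5_up_cpq_vs_cdk"]
    )
    return list(audit.index[audit["selected"]]), audit


def select_groups(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    crit: SelectionCriteria = SelectionCriteria(),
    k: int = 16,
    method: str = "moderated",
    pseudocount: float = 0.5,
) -> SelectionResult:
    """Run the full selection: read filter, clustering, pattern match, criteria.

    The audit DataFrame covers *every* input gene: the minimum-read filter
    (criterion 1), pattern-cluster membership per group (criterion 2, false
    for flat or filtered genes) and the per-group threshold criteria (3-5,
    NaN where upstream criteria already excluded the gene).
    """
    present = set(design.loc[list(counts.columns), "condition"])
    missing = [c for c in CONDITIONS if c not in present]
    if missing:
        raise ValueError(f"design lacks condition(s): {missing}")

    keep = filter_min_reads(counts, crit.min_reads_per_sample)
    norm = cpm_normalize(counts).loc[keep]
    summary = condition_means(norm, design)[list(CONDITIONS)]
    de = {
        pair: differential_test(norm, design, pair, pseudocount=pseudocount, method=method)
        for pair in ALL_PAIRS
    }

    profiles, flat = profile_standardize(summary)
    audit = pd.DataFrame(index=counts.index.rename("gene_id"))
    audit["c1_min_reads"] = audit.index.isin(keep)
    audit["c2a_pattern_cluster"] = False
    audit["c2b_pattern_cluster"] = False

    if len(profiles) >= 2:
        k_eff = min(k, len(profiles))
        assign = cluster_profiles(profiles, max(2, k_eff))
        centroids = cluster_centroids(profiles, assign)
        labels = {cid: label_cluster_pattern(row) for cid, row in centroids.iterrows()}
        clusters = pd.DataFrame(
            {
                "cluster_id": assign,
                "pattern": ["-".join(labels[c]) for c in assign],
            }
        )
        cand_a = [g for g, c in assign.items() if labels[c] == GROUP_A_PATTERN]
        cand_b = [g for g, c in assign.items() if labels[c] == GROUP_B_PATTERN]
    else:
        clusters = pd.DataFrame(columns=["cluster_id", "pattern"])
        cand_a, cand_b = [], []

    audit.loc[audit.index.isin(cand_a), "c2a_pattern_cluster"] = True
    audit.loc[audit.index.isin(cand_b), "c2b_pattern_cluster"] = True

    group_a, audit_a = ([], None)
    if cand_a:
        group_a, audit_a = apply_group_a_criteria(cand_a, de, summary, crit)
        audit = audit.join(audit_a.add_prefix("a_"))
    group_b, audit_b = ([], None)
    if cand_b:
        group_b, audit_b = apply_group_b_criteria(cand_b, de, crit)
        audit = audit.join(audit_b.add_prefix("b_"))

    return SelectionResult(
        group_a=sorted(group_a),
        group_b=sorted(group_b),
        audit=audit,
        clusters=clusters,
        de=de,
        summary=summary,
        profiles=profiles,
    )
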