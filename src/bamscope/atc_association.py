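"""Hypergeometric association of phenotype clusters with ATC categories.

For each (cluster, category) pair the upper-tail hypergeometric probability
of observing at least the realised overlap is computed: drawing ``n``
drugs (the cluster) from a population of ``N`` training drugs of which
``K`` carry the category, what is the chance of ``k`` or more carriers?
Significant overlaps define signature subgroups whose Pheno-Print centroid
anchors downstream candidate ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .consensus_clustering import ClusterAssignment

logger = logging.getLogger("bamscope.atc_association")

__all__ = ["AssociationResult", "hypergeom_overrep", "signature_centroid"]

DEFAULT_ALPHA = 0.05


@dataclass
class AssociationResult:
    """Cluster x category overlap statistics and signature subgroups."""

    table: pd.DataFrame  # columns: cluster, category, N, K, n, k, p, q, significant
    alpha: float
    subgroups: dict[tuple[int, str], list[str]] = field(default_factory=dict)
    centroids: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    @property
    def pvalues(self) -> pd.DataFrame:
        """P-value matrix, clusters as rows, categories as columns."""
        return self.table.pivot(index="cluster", columns="category", values="p")

    def significant_pairs(self) -> list[tuple[int, str]]:
        sig = self.table[self.table["significant"]]
        return [(int(r.cluster), str(r.category)) for r in sig.itertuples()]

    def associated_clusters(self) -> dict[int, str]:
        """Cluster -> its most significant associated category."""
        sig = self.table[self.table["significant"]].sort_values("p")
        out: dict[int, str] = {}
        for r in sig.itertuples():
            out.setdefault(int(r.cluster), str(r.category))
        return out


def _category_sets(table: pd.DataFrame, multi_code: str) -> pd.Series:
    """Per-drug list of level-2 ATC codes for training drugs."""
    train = table[table["set"] == "training"]
    codes = train.set_index("compound_id")["atc_codes"].fillna("")

    def split(s: str) -> list[str]:
        parts = [p.strip() for p in str(s).split(";") if p.strip()]
        if multi_code == "primary":
            return parts[:1]
        return parts

    return codes.map(split)


def hypergeom_overrep(
    assignment: ClusterAssignment,
    drug_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    phenoprints: pd.DataFrame | None = None,
    multi_code: str = "all",
) -> AssociationResult:
    """Test every (cluster, ATC category) pair for overrepresentation.

    ``p = P(X >= k)`` for X ~ Hypergeometric(N, K, n) with N the training
    population, K the category size, n the cluster size and k the overlap.
    Drugs holding several codes count once per category they hold
    (``multi_code="primary"`` restricts to the first code). Significance is
    nominal (p < alpha, no multiplicity correction, mirroring common
    practice for small association grids); a BH-adjusted column is emitted
    for reference. Empty clusters or categories yield p = 1.

    If ``phenoprints`` (indexed by compound_id) is given, signature-subgroup
    centroids are computed for every significant pair.
    """
    if multi_code not in ("all", "primary"):
        raise ValueError("multi_code must be 'all' or 'primary'")
    per_drug = _category_sets(drug_table, multi_code)
    labelled = assignment.labels
    missing = [d for d in per_drug.index if d not in labelled.index]
    if missing:
        raise ValueError(f"{len(missing)} training drug(s) lack cluster labels, e.g. {missing[:3]}")
    population = [d for d in per_drug.index]
    n_pop = len(population)
    categories = sorted({c for codes in per_drug for c in codes})
    clusters = sorted(labelled.loc[population].unique())

    rows = []
    subgroups: dict[tuple[int, str], list[str]] = {}
    for cl in clusters:
        members = [d for d in population if labelled[d] == cl]
        for cat in categories:
            carriers = [d for d in population if cat in per_drug[d]]
            overlap = [d for d in members if cat in per_drug[d]]
            big_n, big_k, n_cl, k_ov = n_pop, len(carriers), len(members), len(overlap)
            if big_k == 0 or n_cl == 0:
                logger.warning("empty category or cluster for pair (%s, %s); p = 1", cl, cat)
                p = 1.0
            else:
                p = float(hypergeom.sf(k_ov - 1, big_n, big_k, n_cl))
            rows.append(
                {
                    "cluster": int(cl),
                    "category": cat,
                    "N": big_n,
                    "K": big_k,
                    "n": n_cl,
                    "k": k_ov,
                    "p": min(p, 1.0),
                }
            )
            if p < alpha and k_ov > 0:
                subgroups[(int(cl), cat)] = overlap
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["p"] < alpha
    centroids: dict[tuple[int, str], np.ndarray] = {}
    if phenoprints is not None:
        for key, drugs in subgroups.items():
            centroids[key] = signature_centroid(drugs, phenoprints)
    return AssociationResult(table=table, alpha=alpha, subgroups=subgroups, centroids=centroids)


def signature_centroid(subgroup: list[str], phenoprints: pd.DataFrame) -> np.ndarray:
    """Componentwise mean Pheno-Print of a signature subgroup."""
    if len(subgroup) == 0:
        raise ValueError("signature subgroup is empty")
    missing = [d for d in subgroup if d not in phenoprints.index]
    if missing:
        raise ValueError(f"no Pheno-Print for subgroup member(s) {missing[:3]}")
    return phenoprints.loc[subgroup].to_numpy(dtype=float).mean(axis=0)
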