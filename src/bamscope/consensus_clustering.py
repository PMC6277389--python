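"""Consensus clustering of Pheno-Prints and cluster-coherence statistics.

Phenotype clusters are discovered by repeated hierarchical clustering
(Euclidean distance, average linkage) of resampled drug subsets; the
consensus matrix records how often each drug pair co-clusters when
co-sampled. The number of clusters is chosen where the area under the
empirical CDF of consensus values stops increasing appreciably (< 1%
relative, by default) as k grows. Per-drug coherence is quantified by
one-tailed rank tests of in-cluster vs out-of-cluster consensus scores
(and, as a second variant, Pheno-Print distances), with Benjamini-Hochberg
adjustment across drugs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, wilcoxon
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("bamscope.consensus_clustering")

__all__ = [
    "ConsensusResult",
    "ClusterAssignment",
    "consensus_cluster",
    "auc_cdf",
    "select_k",
    "cut_clusters",
    "coherence_tests",
]

DEFAULT_K_RANGE = range(2, 16)
DEFAULT_N_ITERATIONS = 1000
DEFAULT_SUBSAMPLE_FRAC = 0.8
DEFAULT_REL_INCREASE_THRESHOLD = 0.01


@dataclass
class ConsensusResult:
    """Per-k consensus matrices plus the resampling bookkeeping."""

    drug_ids: list[str]
    ks: list[int]
    consensus: dict[int, np.ndarray]  # k -> (n, n) matrix in [0, 1]
    cosample_counts: np.ndarray  # (n, n) number of iterations each pair was co-sampled
    aucs: dict[int, float]
    n_iterations: int
    subsample_frac: float
    seed: int

    def matrix(self, k: int) -> np.ndarray:
        return self.consensus[k]


@dataclass
class ClusterAssignment:
    """Final drug -> cluster labels (1..k) and representative patterns."""

    labels: pd.Series  # index: drug_id, values: int labels 1..k
    k: int
    patterns: dict[int, np.ndarray] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def _hier_labels(x: np.ndarray, ks: list[int], method: str = "average") -> np.ndarray:
    """Labels of hierarchical clustering cut at each k; shape (len(ks), n)."""
    z = linkage(x, method=method, metric="euclidean")
    cuts = cut_tree(z, n_clusters=ks)  # (n, len(ks))
    return cuts.T


def consensus_cluster(
    phenoprints: np.ndarray,
    drug_ids: list[str],
    k_range: range | list[int] = DEFAULT_K_RANGE,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    subsample_frac: float = DEFAULT_SUBSAMPLE_FRAC,
    seed: int = 0,
    linkage_method: str = "average",
    with_replacement: bool = False,
) -> ConsensusResult:
    """Consensus matrices over a range of cluster counts.

    Per iteration, ``ceil(subsample_frac * n)`` drugs are resampled (without
    replacement by default), hierarchically clustered and cut at every k in
    ``k_range``; consensus is the co-clustering frequency normalised by the
    co-sampling frequency. Pairs never co-sampled get consensus 0 with a
    warning.
    """
    x = np.asarray(phenoprints, dtype=float)
    n = x.shape[0]
    if n != len(drug_ids):
        raise ValueError("phenoprints and drug_ids disagree on library size")
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if not (0 < subsample_frac <= 1):
        raise ValueError("subsample_frac must lie in (0, 1]")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    m = int(np.ceil(subsample_frac * n))
    if max(ks) >= m:
        raise ValueError(f"largest k ({max(ks)}) must be below the subsample size ({m})")

    rng = np.random.default_rng(seed)
    cosample = np.zeros((n, n), dtype=np.int32)
    cocluster = {k: np.zeros((n, n), dtype=np.int32) for k in ks}
    for _ in range(n_iterations):
        if with_replacement:
            idx = np.unique(rng.integers(0, n, size=m))
        else:
            idx = rng.choice(n, size=m, replace=False)
        idx.sort()
        sub = x[idx]
        cosample[np.ix_(idx, idx)] += 1
        labels_per_k = _hier_labels(sub, ks, method=linkage_method)
        for k, labels in zip(ks, labels_per_k):
            same = labels[:, None] == labels[None, :]
            cocluster[k][np.ix_(idx, idx)] += same
    never = (cosample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{never.sum() // 2} drug pair(s) were never co-sampled; their consensus is 0",
            stacklevel=2,
        )
    denom = np.where(cosample == 0, 1, cosample)
    consensus = {}
    aucs = {}
    for k in ks:
        mk = cocluster[k] / denom
        np.fill_diagonal(mk, 1.0)
        mk = 0.5 * (mk + mk.T)
        consensus[k] = mk
        aucs[k] = auc_cdf(mk)
    return ConsensusResult(
        drug_ids=list(drug_ids),
        ks=ks,
        consensus=consensus,
        cosample_counts=cosample,
        aucs=aucs,
        n_iterations=n_iterations,
        subsample_frac=subsample_frac,
        seed=seed,
    )


def auc_cdf(consensus_matrix: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries.

    Computed over the upper triangle only (the diagonal is 1 by
    definition), on the interval [0, 1].
    """
    m = np.asarray(consensus_matrix)
    vals = m[np.triu_indices_from(m, k=1)]
    if vals.size == 0:
        raise ValueError("consensus matrix has no off-diagonal entries")
    xs = np.unique(np.concatenate([[0.0], np.sort(vals), [1.0]]))
    cdf = np.searchsorted(np.sort(vals), xs, side="right") / vals.size
    # exact integral of the step ECDF over [0, 1]: left endpoint of each step
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def select_k(
    result: ConsensusResult,
    rel_increase_threshold: float = DEFAULT_REL_INCREASE_THRESHOLD,
) -> int:
    """Smallest k whose AUC-CDF gain to k+1 falls below the threshold.

    Mirrors the elbow rule "stop when the area under the consensus CDF no
    longer increases substantially (< 1% relative)". If no k qualifies, the
    largest candidate is returned with a warning.
    """
    ks = result.ks
    if len(ks) < 2:
        raise ValueError("need AUCs for at least two consecutive k values")
    for a, b in zip(ks[:-1], ks[1:]):
        if b != a + 1:
            continue
        auc_a, auc_b = result.aucs[a], result.aucs[b]
        rel = (auc_b - auc_a) / auc_a if auc_a > 0 else np.inf
        if rel < rel_increase_threshold:
            return a
    logger.warning("no k met the AUC plateau rule; returning max of k_range")
    return ks[-1]


def cut_clusters(
    result: ConsensusResult,
    k: int,
    tscore_maps: dict[str, np.ndarray] | None = None,
) -> ClusterAssignment:
    """Final labels: hierarchical cut (average linkage) of 1 - consensus.

    Labels are renumbered 1..k in order of first appearance in the drug
    list. If T-score maps are supplied, each cluster's representative
    pattern is the elementwise mean over its members.
    """
    if k not in result.consensus:
        raise KeyError(f"no consensus matrix for k={k}")
    m = result.consensus[k]
    dist = 1.0 - m
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber in order of first appearance for determinism
    order: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order) + 1
        labels[i] = order[lab]
    series = pd.Series(labels, index=result.drug_ids, name="cluster")
    patterns: dict[int, np.ndarray] = {}
    if tscore_maps is not None:
        for c in range(1, labels.max() + 1):
            members = series.index[series == c]
            patterns[c] = np.mean([tscore_maps[d] for d in members], axis=0)
    return ClusterAssignment(labels=series, k=int(labels.max()), patterns=patterns)


def coherence_tests(
    result: ConsensusResult,
    assignment: ClusterAssignment,
    phenoprints: np.ndarray | None = None,
    equalize_groups: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-drug test that in-cluster coherence exceeds out-of-cluster.

    For each drug, the consensus scores pairing it with in-cluster drugs are
    compared with those pairing it with out-of-cluster drugs by a one-tailed
    rank test (Mann-Whitney; in > out). With ``equalize_groups`` the two
    score sets are subsampled to equal size and a paired one-tailed Wilcoxon
    signed-rank test is used instead. If ``phenoprints`` is given, a second
    variant tests Pheno-Print distances (in < out). P-values are BH-adjusted
    across drugs; singleton-cluster drugs get NaN.
    """
    if assignment.k < 2:
        raise ValueError("coherence tests need at least two clusters")
    if assignment.k in result.consensus:
        m = result.consensus[assignment.k]
    else:
        # labels may come from elsewhere; use the closest available k
        m = result.consensus[min(result.ks, key=lambda kk: abs(kk - assignment.k))]
    ids = result.drug_ids
    labels = assignment.labels.loc[ids].to_numpy()
    n = len(ids)
    dist = None
    if phenoprints is not None:
        dist = squareform(pdist(np.asarray(phenoprints, dtype=float)))
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        other = labels != labels[i]
        row: dict[str, object] = {"compound_id": ids[i], "cluster": int(labels[i])}
        if same.sum() == 0:
            logger.warning("drug %s is in a singleton cluster; coherence p-value missing", ids[i])
            row["p_consensus"] = np.nan
            row["p_distance"] = np.nan
        else:
            row["p_consensus"] = _one_tailed(
                m[i, same], m[i, other], larger_in=True, equalize=equalize_groups, rng=rng
            )
            if dist is not None:
                row["p_distance"] = _one_tailed(
                    dist[i, same], dist[i, other], larger_in=False, equalize=equalize_groups, rng=rng
                )
            else:
                row["p_distance"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("compound_id")
    for col in ("p_consensus", "p_distance"):
        qcol = col.replace("p_", "q_")
        mask = df[col].notna()
        df[qcol] = np.nan
        if mask.any():
            df.loc[mask, qcol] = multipletests(df.loc[mask, col], method="fdr_bh")[1]
    return df


def _one_tailed(
    in_scores: np.ndarray,
    out_scores: np.ndarray,
    larger_in: bool,
    equalize: bool,
    rng: np.random.Generator,
) -> float:
    in_scores = np.asarray(in_scores, dtype=float)
    out_scores = np.asarray(out_scores, dtype=float)
    alternative = "greater" if larger_in else "less"
    if equalize:
        m = min(in_scores.size, out_scores.size)
        a = rng.choice(in_scores, size=m, replace=False)
        b = rng.choice(out_scores, size=m, replace=False)
        d = a - b
        if np.all(d == 0):
            return 1.0
        return float(wilcoxon(a, b, alternative=alternative).pvalue)
    if np.all(in_scores[:, None] == out_scores[None, :]):
        return 1.0
    return float(
        mannwhitneyu(in_scores, out_scores, alternative=alternative, method="asymptotic").pvalue
    )
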