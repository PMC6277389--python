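"""Random-forest cluster assignment and centroid-correlation ranking.

Two-step functional prediction: (1) a random forest (100 trees by default)
trained on the training library's Pheno-Prints and cluster labels assigns
each unlabelled test compound to a phenotype cluster; (2) compounds landing
in ATC-associated clusters are ranked by the Pearson correlation between
their Pheno-Print and the signature subgroup's centroid — the
therapeutic-potential score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestClassifier

from .atc_association import AssociationResult
from .consensus_clustering import ClusterAssignment

logger = logging.getLogger("bamscope.functional_prediction")

__all__ = ["ForestModel", "train_forest", "classify", "rank_candidates"]

DEFAULT_N_TREES = 100


@dataclass
class ForestModel:
    """A fitted random-forest cluster classifier over 20-D Pheno-Prints."""

    clf: RandomForestClassifier
    classes: np.ndarray
    n_features: int
    oob_accuracy: float
    seed: int


def train_forest(
    phenoprints: pd.DataFrame,
    assignment: ClusterAssignment,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ForestModel:
    """Train the cluster classifier on training Pheno-Prints.

    Standard random forest: bootstrap per tree, sqrt(n_features) candidate
    features per split, majority vote; deterministic given the seed.
    Out-of-bag accuracy is recorded as a sanity measure.
    """
    ids = [d for d in phenoprints.index if d in assignment.labels.index]
    x = phenoprints.loc[ids].to_numpy(dtype=float)
    y = assignment.labels.loc[ids].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; nothing to classify")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    import warnings

    with warnings.catch_warnings():
        # tiny libraries can leave some samples never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        clf.fit(x, y)
        oob = float(getattr(clf, "oob_score_", np.nan))
    if oob < 1.0:
        logger.info("forest out-of-bag accuracy %.3f", oob)
    return ForestModel(
        clf=clf, classes=clf.classes_, n_features=x.shape[1], oob_accuracy=oob, seed=seed
    )


def classify(model: ForestModel, phenoprints: pd.DataFrame) -> pd.DataFrame:
    """Assign each compound to a cluster by forest majority vote.

    Returns a frame indexed by compound_id with the assigned ``cluster``
    and one ``vote_<c>`` fraction per class. Vote ties are broken toward
    the lowest cluster label (and logged).
    """
    x = phenoprints.to_numpy(dtype=float)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match the model ({model.n_features})"
        )
    proba = model.clf.predict_proba(x)
    best = proba.max(axis=1)
    ties = (np.isclose(proba, best[:, None])).sum(axis=1) > 1
    if ties.any():
        logger.info("%d compound(s) had tied forest votes; lowest label wins", int(ties.sum()))
    # argmax returns the first (lowest) class among ties; classes_ is sorted
    assigned = model.classes[np.argmax(proba, axis=1)]
    out = pd.DataFrame({"cluster": assigned.astype(int)}, index=phenoprints.index)
    for j, c in enumerate(model.classes):
        out[f"vote_{int(c)}"] = proba[:, j]
    return out


def rank_candidates(
    assignments: pd.DataFrame,
    phenoprints: pd.DataFrame,
    association: AssociationResult,
) -> pd.DataFrame:
    """Rank test compounds in ATC-associated clusters by centroid correlation.

    The therapeutic-potential score is the Pearson correlation (across the
    20 PC coefficients) between a compound's Pheno-Print and its assigned
    cluster's signature centroid. Compounds in non-associated clusters get
    no score; zero-variance Pheno-Prints yield a missing score ranked last.
    Ranks (1 = best) are assigned within each associated cluster.
    """
    assoc = association.associated_clusters()
    bad = set(assignments["cluster"].unique()) - set(
        int(c) for c in association.table["cluster"].unique()
    )
    if bad:
        raise ValueError(f"assignments refer to clusters absent from the association: {sorted(bad)}")
    rows = []
    for drug, row in assignments.iterrows():
        cl = int(row["cluster"])
        rec: dict[str, object] = {"compound_id": drug, "cluster": cl}
        if cl in assoc:
            cat = assoc[cl]
            centroid = association.centroids.get((cl, cat))
            if centroid is None:
                raise ValueError(
                    f"association result lacks the centroid for cluster {cl} / {cat}; "
                    "pass training phenoprints to hypergeom_overrep"
                )
            pp = phenoprints.loc[drug].to_numpy(dtype=float)
            if np.std(pp) == 0 or np.std(centroid) == 0:
                logger.warning("zero-variance Pheno-Print for %s; score missing", drug)
                rec["category"] = cat
                rec["r"] = np.nan
            else:
                rec["category"] = cat
                rec["r"] = float(pearsonr(pp, centroid).statistic)
        else:
            rec["category"] = ""
            rec["r"] = np.nan
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("compound_id")
    df["rank"] = np.nan
    for cl in assoc:
        in_cl = df["cluster"] == cl
        # missing scores sort last; ranks are a permutation of 1..m
        order = df.loc[in_cl, "r"].sort_values(ascending=False, na_position="last").index
        df.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return df
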