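"""Unsupervised 2-cluster severity classification and clinician agreement.

Subjects are partitioned with k-means (k = 2, Lloyd iterations, k-means++
initialisation, best of ``n_restarts`` seeded starts). The cluster with the
larger mid-forehead centroid is labelled **severe** (ties broken by the
smaller orbital centroid) — a sharper ridge with more retruded orbits is
the operative phenotype — and the other **mild**. Features are clustered in
raw m⁻¹ by default; the two features have comparable spreads, so
standardisation is optional.

Agreement maps severe ↔ operative and mild ↔ conservative and reports the
concordant fraction, the discordant subjects and the 2×2 contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateClusteringError, InputError

POOLED = ("h_mid", "h_orb")
THREE_REGION = ("h_mid", "h_orb_left", "h_orb_right")

FEATURE_SETS = {"pooled": POOLED, "three_region": THREE_REGION}


@dataclass
class ClusterResult:
    """k=2 clustering output with severity labels."""

    assignments: pd.Series  # subject_id -> {"mild", "severe"}
    centroids: pd.DataFrame  # index {mild, severe}, columns = feature names
    inertia: float
    n_mild: int
    n_severe: int
    feature_names: tuple


@dataclass
class AgreementReport:
    """Concordance between cluster severity and clinician treatment."""

    agreement_fraction: float
    n_discordant: int
    discordant_ids: list
    contingency: pd.DataFrame  # rows: cluster; cols: clinician label


def kmeans2(
    features: pd.DataFrame,
    feature_set: str = "pooled",
    seed: int = 0,
    n_restarts: int = 50,
    standardize: bool = False,
) -> ClusterResult:
    """Cluster subjects into mild/severe with k-means (k = 2).

    Deterministic given (features, seed, n_restarts); invariant to subject
    order. ``feature_set`` is ``pooled`` (h_mid, h_orb) or ``three_region``
    (h_mid and the separate left/right orbital means).
    """
    if feature_set not in FEATURE_SETS:
        raise InputError(f"feature_set must be one of {sorted(FEATURE_SETS)}")
    cols = FEATURE_SETS[feature_set]
    if features["subject_id"].duplicated().any():
        raise InputError("duplicate subject ids")
    if len(features) < 2:
        raise InputError(f"need at least 2 subjects, got {len(features)}")
    X = features.loc[:, list(cols)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputError("non-finite feature values")
    if np.allclose(X, X[0]):
        raise DegenerateClusteringError("all subjects have identical features")

    # order-invariance: cluster in a canonical row order, report in input order
    order = np.lexsort(X.T[::-1])
    Xs = X[order]
    mu, sigma = Xs.mean(axis=0), Xs.std(axis=0)
    if standardize:
        sigma = np.where(sigma == 0, 1.0, sigma)
        Xw = (Xs - mu) / sigma
    else:
        Xw = Xs

    km = KMeans(
        n_clusters=2,
        init="k-means++",
        n_init=n_restarts,
        max_iter=300,
        algorithm="lloyd",
        random_state=seed,
    ).fit(Xw)
    labels_sorted = km.labels_
    labels = np.empty(len(X), dtype=int)
    labels[order] = labels_sorted

    cent = km.cluster_centers_
    if standardize:
        cent = cent * sigma + mu
    # severe = larger h_mid centroid; ties -> smaller h_orb(-like) centroid
    h_mid_idx = cols.index("h_mid")
    orb_cent = cent[:, [i for i in range(len(cols)) if i != h_mid_idx]].mean(axis=1)
    if not np.isclose(cent[0, h_mid_idx], cent[1, h_mid_idx]):
        severe = int(np.argmax(cent[:, h_mid_idx]))
    else:
        severe = int(np.argmin(orb_cent))
    name = {severe: "severe", 1 - severe: "mild"}

    assignments = pd.Series(
        [name[l] for l in labels], index=features["subject_id"].to_numpy(), name="cluster"
    )
    centroids = pd.DataFrame(
        cent[[1 - severe, severe]], index=["mild", "severe"], columns=list(cols)
    )
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        inertia=float(km.inertia_),
        n_mild=int((assignments == "mild").sum()),
        n_severe=int((assignments == "severe").sum()),
        feature_names=tuple(cols),
    )


def agreement(result: ClusterResult, labels: pd.DataFrame) -> AgreementReport:
    """Score cluster severity against clinician treatment decisions.

    severe ↔ operative, mild ↔ conservative. Every clustered subject must
    appear in the label table.
    """
    lab = labels.set_index("subject_id")["clinician_label"]
    missing = set(result.assignments.index) - set(lab.index)
    if missing:
        raise InputError(f"unlabeled subjects: {sorted(missing)}")
    lab = lab.reindex(result.assignments.index)
    expected = result.assignments.map({"severe": "operative", "mild": "conservative"})
    discordant = result.assignments.index[(expected != lab).to_numpy()].tolist()
    n = len(result.assignments)
    contingency = pd.crosstab(result.assignments, lab)
    contingency = contingency.reindex(
        index=["mild", "severe"],
        columns=["conservative", "operative"],
        fill_value=0,
    )
    return AgreementReport(
        agreement_fraction=1.0 - len(discordant) / n,
        n_discordant=len(discordant),
        discordant_ids=discordant,
        contingency=contingency,
    )


def label_agreement(result: ClusterResult, truth: pd.Series) -> float:
    """Fraction of subjects whose cluster matches a truth series of
    {"severe", "mild"} values indexed by subject_id (for simulations)."""
    truth = truth.reindex(result.assignments.index)
    return float((result.assignments == truth).mean())
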