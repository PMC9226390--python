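"""Audiovisual-dominance pre-test analysis.

Participants classify two objects presented auditorily (Au), visually (Vi)
or audiovisually (AV); per-modality mean reaction times are clustered with
k-means (k = 2) and the cluster with relatively faster visual responses is
labelled visually dominant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .design import N_PRETEST_PRACTICE

RT_CUTOFF_MS = 1500.0

MODALITIES = ("Au", "Vi", "AV")


class DominanceError(ValueError):
    pass


@dataclass(frozen=True)
class DominanceResult:
    assignments: pd.DataFrame  # participant, label, mean_au, mean_vi, mean_av
    centroids: np.ndarray  # 2 x 3, (au, vi, av) ms
    inertia: float


def clean_pretest(records: pd.DataFrame) -> pd.DataFrame:
    """Drop practice trials, incorrect responses, and responses over 1500 ms.

    Expects columns participant, index, modality, rt_ms, correct.  Cleaning
    is idempotent.
    """
    req = {"participant", "index", "modality", "rt_ms", "correct"}
    missing = req - set(records.columns)
    if missing:
        raise DominanceError(f"pre-test log is missing columns: {sorted(missing)}")
    out = records[
        (records["index"] > N_PRETEST_PRACTICE)
        & records["correct"].astype(bool)
        & (records["rt_ms"] <= RT_CUTOFF_MS)
    ].copy()
    return out


def rt_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean RT in each modality from cleaned records.

    Participants missing any modality entirely are excluded with a warning.
    """
    means = (
        records.groupby(["participant", "modality"])["rt_ms"]
        .agg(["mean", "size"])
        .unstack("modality")
    )
    profiles = pd.DataFrame(
        {
            "mean_au": means[("mean", "Au")] if ("mean", "Au") in means else np.nan,
            "mean_vi": means[("mean", "Vi")] if ("mean", "Vi") in means else np.nan,
            "mean_av": means[("mean", "AV")] if ("mean", "AV") in means else np.nan,
        }
    )
    profiles["n_valid"] = records.groupby("participant").size()
    bad = profiles[profiles[["mean_au", "mean_vi", "mean_av"]].isna().any(axis=1)]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} participant(s) with an empty modality: "
            f"{sorted(bad.index.tolist())}"
        )
        profiles = profiles.drop(bad.index)
    return profiles.reset_index().rename(columns={"index": "participant"})


def cluster_dominance(
    profiles: pd.DataFrame, rng_seed: int = 0, n_restarts: int = 20
) -> DominanceResult:
    """2-means clustering of (mean_au, mean_vi, mean_av) into AUD/VIS labels.

    Lloyd's algorithm on raw millisecond means, best of ``n_restarts`` by
    within-cluster sum of squares.  The cluster whose centroid has the
    smaller visual-minus-auditory contrast (relatively faster visual RTs) is
    labelled VIS, the other AUD.
    """
    X = profiles[["mean_au", "mean_vi", "mean_av"]].to_numpy(float)
    if len(X) < 2 or len(np.unique(X, axis=0)) < 2:
        raise DominanceError("clustering requires at least two distinct RT profiles")
    km = KMeans(
        n_clusters=2,
        n_init=n_restarts,
        random_state=int(rng_seed) % (2**31),
        algorithm="lloyd",
    ).fit(X)
    contrast = km.cluster_centers_[:, 1] - km.cluster_centers_[:, 0]  # vi - au
    vis_cluster = int(np.argmin(contrast))
    labels = np.where(km.labels_ == vis_cluster, "VIS", "AUD")
    assignments = profiles[["participant", "mean_au", "mean_vi", "mean_av"]].copy()
    assignments.insert(1, "label", labels)
    return DominanceResult(
        assignments=assignments,
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
    )


def dominance_pipeline(
    records: pd.DataFrame, rng_seed: int = 0, n_restarts: int = 20
) -> DominanceResult:
    """clean -> profile -> cluster in one call."""
    return cluster_dominance(rt_profiles(clean_pretest(records)), rng_seed, n_restarts)
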