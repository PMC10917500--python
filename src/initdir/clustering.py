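"""k-means partitioning of multi-track IAR signal matrices.

Feature rows are the log2(x+1)-transformed, horizontally concatenated
binned tracks of each region (the displayed heatmap signal).  Clusters are
relabeled deterministically by descending size, then by descending mean
signal, so outputs are comparable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .profiles import ProfileMatrix


@dataclass
class ClusterAssignment:
    """Region -> cluster label (1..k) partition with a relabeling order.

    Labels are assigned by descending cluster size, ties broken by
    descending mean feature signal; deterministic for a fixed seed.
    """

    labels: dict[str, int]
    k: int
    seed: int
    inertia: float

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for rid, c in self.labels.items():
            out[c].append(rid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(self.labels), "cluster": list(self.labels.values())}
        )


def build_feature_matrix(
    matrices: Sequence[ProfileMatrix],
    standardize_tracks: bool = False,
    orient: str = "none",
    orient_track: int = 0,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """log2(x+1)-transform and concatenate profile matrices row-wise.

    All matrices must share region order.  Missing (NaN) bins are imputed
    as 0 before the transform.  ``orient="dominant"`` flips each region's
    rows (bin order reversed consistently within every track block) so
    that the heavier half of the ``orient_track``-th matrix lies
    downstream; this canonicalizes mirror-image unidirectional elements
    for class-recovery benchmarks.  Returns (features, region_ids,
    flipped_mask).
    """
    if not matrices:
        raise ValueError("need at least one profile matrix")
    ids = matrices[0].region_ids
    for m in matrices[1:]:
        if m.region_ids != ids:
            raise ValueError("profile matrices have mismatched region order")
    if orient not in ("none", "dominant"):
        raise ValueError(f"unknown orient mode {orient!r}")

    n = len(ids)
    flipped = np.zeros(n, dtype=bool)
    if orient == "dominant":
        ref = np.nan_to_num(matrices[orient_track].matrix, nan=0.0)
        half = ref.shape[1] // 2
        flipped = ref[:, :half].sum(axis=1) > ref[:, half:].sum(axis=1)

    blocks = []
    for m in matrices:
        x = np.nan_to_num(m.matrix, nan=0.0)
        if np.any(x < 0):
            x = np.clip(x, 0, None)
        x = np.log2(x + 1.0)
        if orient == "dominant":
            x = x.copy()
            x[flipped] = x[flipped, ::-1]
        if standardize_tracks:
            sd = x.std()
            if sd > 0:
                x = (x - x.mean()) / sd
        blocks.append(x)
    return np.hstack(blocks), list(ids), flipped


def kmeans_cluster(
    features: np.ndarray,
    region_ids: Sequence[str],
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ init, best of ``n_init`` restarts.

    Deterministic for a fixed seed.  Raises when there are fewer rows
    than clusters.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] < k:
        raise ValueError(f"{features.shape[0]} rows < k={k}")
    if features.shape[0] != len(region_ids):
        raise ValueError("region_ids length must match feature rows")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        algorithm="lloyd",
        random_state=seed,
    ).fit(features)
    raw = km.labels_
    # deterministic relabeling: by descending size, then descending mean signal
    order = sorted(
        range(k),
        key=lambda c: (
            -int(np.sum(raw == c)),
            -float(features[raw == c].mean()) if np.any(raw == c) else 0.0,
            c,
        ),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = {rid: remap[int(c)] for rid, c in zip(region_ids, raw)}
    return ClusterAssignment(labels=labels, k=k, seed=seed, inertia=float(km.inertia_))


def write_cluster_bed(
    assignment: ClusterAssignment,
    regions: dict[str, tuple[str, int, int]],
    path: str | Path,
) -> None:
    """BED6 cluster membership: name = cluster label."""
    rows = []
    for rid, label in assignment.labels.items():
        chrom, start, end = regions[rid]
        rows.append((chrom, start, end, f"C{label}", 0, "."))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def cluster_summary(
    assignment: ClusterAssignment, features: np.ndarray, region_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-cluster size and mean feature signal."""
    idx = {rid: i for i, rid in enumerate(region_ids)}
    rows = []
    for c, members in assignment.groups().items():
        sel = [idx[r] for r in members]
        rows.append(
            {
                "cluster": c,
                "n_regions": len(members),
                "mean_signal": float(features[sel].mean()) if sel else np.nan,
            }
        )
    return pd.DataFrame(rows)
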