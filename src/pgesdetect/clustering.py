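"""K-means grouping of recordings by their artifact feature maps.

Recordings whose low-frequency artifact activity shares a spatiotemporal
pattern (same channels, same post-seizure time span) end up in the same
cluster; the classifier then trains one specialist forest per cluster.
Distances are Euclidean on the flattened, per-recording-normalized maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .emd import ArtifactFeatureMap

__all__ = ["ClusterModel", "fit_kmeans", "assign", "plot_cluster_centers"]


@dataclass
class ClusterModel:
    """Fitted K-means model over artifact feature maps."""

    K: int
    centroids: np.ndarray  # (K, D), D = 18 × T
    inertia: float
    assignments: dict[str, int]  # recording_id → cluster index
    map_shape: tuple[int, int] = (18, 300)
    seed: int | None = None

    def members(self, cluster: int) -> list[str]:
        return [rid for rid, c in self.assignments.items() if c == cluster]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "K": self.K,
            "centroids": self.centroids.tolist(),
            "inertia": self.inertia,
            "assignments": self.assignments,
            "map_shape": list(self.map_shape),
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            K=payload["K"],
            centroids=np.asarray(payload["centroids"], dtype=float),
            inertia=payload["inertia"],
            assignments={k: int(v) for k, v in payload["assignments"].items()},
            map_shape=tuple(payload["map_shape"]),
            seed=payload["seed"],
        )


def fit_kmeans(
    maps: Sequence[ArtifactFeatureMap], K: int, seed: int | None = 0, n_init: int = 10
) -> ClusterModel:
    """Cluster recordings into K groups by flattened artifact maps.

    k-means++ initialization with ``n_init`` restarts, best-inertia model
    kept; deterministic given the seed.  Lloyd iterations make the
    within-cluster sum of squared distances (inertia) non-increasing.
    """
    if K > len(maps):
        raise ValueError(f"K={K} exceeds the number of recordings ({len(maps)})")
    if K < 1:
        raise ValueError("K must be ≥ 1")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"artifact maps disagree in shape: {shapes}")
    X = np.vstack([m.flatten() for m in maps])
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterModel(
        K=K,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        assignments={m.recording_id: int(l) for m, l in zip(maps, labels)},
        map_shape=maps[0].values.shape,
        seed=seed,
    )


def assign(amap: ArtifactFeatureMap, model: ClusterModel) -> int:
    """Nearest-centroid (Euclidean) cluster of an unseen recording.

    Ties break toward the lowest cluster index.
    """
    x = amap.flatten()
    if x.shape[0] != model.centroids.shape[1]:
        raise ValueError(
            f"map dimension {x.shape[0]} does not match centroids "
            f"({model.centroids.shape[1]})"
        )
    d2 = ((model.centroids - x[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))  # argmin returns the first minimum: lowest index


def plot_cluster_centers(model: ClusterModel, path: str | Path, t_max: int = 100):
    """Basic channel × time heat-map grid of the cluster centers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_ch, T = model.map_shape
    cols = min(4, model.K)
    rows = int(np.ceil(model.K / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(4 * cols, 3 * rows), squeeze=False)
    sizes = {c: len(model.members(c)) for c in range(model.K)}
    for c in range(model.K):
        ax = axes[c // cols][c % cols]
        center = model.centroids[c].reshape(n_ch, T)
        ax.imshow(center[:, :t_max], aspect="auto", origin="upper")
        ax.set_title(f"cluster {c} (n={sizes[c]})")
        ax.set_xlabel("s after seizure end")
        ax.set_ylabel("channel")
    for c in range(model.K, rows * cols):
        axes[c // cols][c % cols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
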