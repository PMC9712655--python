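"""Self-organizing-map clustering of the descriptor matrix, grid-size
scanning, and per-cluster activity-enrichment / similarity summaries.

The SOM is a rectangular, non-toroidal grid of prototype ("codebook")
vectors trained competitively: at each presentation step the best-matching
unit (BMU) of a randomly drawn chemical is found and the codebook is pulled
toward the sample with a Gaussian neighborhood around the BMU.  Learning
rate and neighborhood radius decay linearly over 10·n presentation steps.
Each grid node is one cluster; every chemical is assigned to its BMU, so the
clusters partition the library (empty clusters are allowed and reported).

Inputs should be z-scored (see :func:`steroidqsar.descriptors.standardize_matrix`)
since descriptors mix units and scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .similarity import SimilarityProfile


@dataclass
class SomModel:
    """Trained SOM: grid shape, codebook (nodes x descriptors), config."""

    grid: tuple[int, int]
    codebook: np.ndarray
    descriptor_names: list[str]
    config: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.grid[0] * self.grid[1]

    def save(self, path) -> None:
        """Persist the model (codebook + config) as JSON."""
        import json

        with open(path, "w") as handle:
            json.dump(
                {
                    "grid": list(self.grid),
                    "codebook": self.codebook.tolist(),
                    "descriptor_names": self.descriptor_names,
                    "config": self.config,
                },
                handle,
            )

    @classmethod
    def load(cls, path) -> "SomModel":
        import json

        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            grid=tuple(payload["grid"]),
            codebook=np.asarray(payload["codebook"], dtype=float),
            descriptor_names=payload["descriptor_names"],
            config=payload["config"],
        )

    def assign(self, matrix: pd.DataFrame) -> pd.Series:
        """Best-matching node (row-major cluster id) for each chemical."""
        x = matrix[self.descriptor_names].to_numpy(dtype=float)
        # squared Euclidean distance to every codebook vector
        d = ((x[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return pd.Series(d.argmin(axis=1), index=matrix.index, name="cluster")


def fit_som(
    matrix: pd.DataFrame,
    grid: tuple[int, int] = (8, 8),
    seed: int = 0,
    steps_per_chemical: int = 10,
    learning_rate: tuple[float, float] = (0.5, 0.01),
) -> SomModel:
    """Train a SOM on a (standardized) descriptor matrix.

    ``grid`` must be at least 2x2.  More nodes than chemicals is allowed
    (some clusters will stay empty).  Training is deterministic given
    ``seed``.
    """
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise InputError("SOM grid must be at least 2x2")
    x = matrix.to_numpy(dtype=float)
    n, dim = x.shape
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)

    # node coordinates on the grid, row-major
    coords = np.indices((rows, cols)).reshape(2, -1).T.astype(float)
    codebook = x[rng.integers(0, n, size=n_nodes)] + rng.normal(0, 1e-4, size=(n_nodes, dim))

    n_steps = steps_per_chemical * n
    lr0, lr1 = learning_rate
    radius0, radius1 = max(rows, cols) / 2.0, 0.5
    order = rng.integers(0, n, size=n_steps)
    for t in range(n_steps):
        frac = t / max(n_steps - 1, 1)
        lr = lr0 + (lr1 - lr0) * frac
        radius = radius0 + (radius1 - radius0) * frac
        sample = x[order[t]]
        bmu = int(((codebook - sample) ** 2).sum(axis=1).argmin())
        grid_dist2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
        influence = np.exp(-grid_dist2 / (2.0 * radius**2))
        codebook += (lr * influence)[:, None] * (sample - codebook)

    return SomModel(
        grid=grid,
        codebook=codebook,
        descriptor_names=list(matrix.columns),
        config={
            "seed": seed,
            "steps": n_steps,
            "learning_rate": learning_rate,
            "radius": (radius0, radius1),
            "topology": "rectangular",
            "neighborhood": "gaussian",
        },
    )


def scan_grid_sizes(
    matrix: pd.DataFrame,
    candidate_grids: Sequence[tuple[int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Occupancy report over candidate grid sizes.

    One row per grid: node count, empty-cluster count and min/median/max
    occupied-cluster size; sorted by node count.  Used to balance the number
    of clusters against the number of chemicals per cluster.
    """
    if len(candidate_grids) == 0:
        raise InputError("need at least one candidate grid")
    rows = []
    for grid in candidate_grids:
        model = fit_som(matrix, grid=grid, seed=seed)
        assignments = model.assign(matrix)
        sizes = assignments.value_counts().reindex(range(model.n_clusters), fill_value=0)
        occupied = sizes[sizes > 0]
        rows.append(
            {
                "grid": f"{grid[0]}x{grid[1]}",
                "n_clusters": model.n_clusters,
                "n_empty": int((sizes == 0).sum()),
                "min_size": int(occupied.min()),
                "median_size": float(occupied.median()),
                "max_size": int(occupied.max()),
            }
        )
    return pd.DataFrame(rows).sort_values("n_clusters", ignore_index=True)


def cluster_activity_enrichment(
    assignments: pd.Series,
    labels: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Per-cluster active proportions for each endpoint.

    ``labels`` maps endpoint -> (chemical id -> active/inactive/excluded).
    The proportion is actives / labeled members of the cluster; ``excluded``
    chemicals count toward cluster size but not toward any proportion.  When
    two or more endpoints are given, a ``both_active`` column reports the
    proportion of chemicals active for all endpoints.  Empty clusters get
    missing proportions.
    """
    clusters = sorted(assignments.unique())
    out = []
    endpoints = sorted(labels)
    for cluster in clusters:
        member_ids = assignments.index[assignments == cluster]
        row: dict = {"cluster": cluster, "size": len(member_ids)}
        per_endpoint_active: dict[str, set] = {}
        for endpoint in endpoints:
            mapping = labels[endpoint]
            states = [mapping[i] for i in member_ids if i in mapping and mapping[i] != "excluded"]
            active_ids = {
                i for i in member_ids if mapping.get(i) == "active"
            }
            per_endpoint_active[endpoint] = active_ids
            row[f"prop_{endpoint}"] = (
                len(active_ids) / len(states) if states else np.nan
            )
            row[f"n_labeled_{endpoint}"] = len(states)
        if len(endpoints) > 1:
            both = set.intersection(*per_endpoint_active.values())
            labeled_all = [
                i
                for i in member_ids
                if all(labels[e].get(i, "excluded") != "excluded" for e in endpoints)
            ]
            row["both_active"] = len(both) / len(labeled_all) if labeled_all else np.nan
        out.append(row)
    return pd.DataFrame(out).set_index("cluster")


def cluster_similarity_summary(
    assignments: pd.Series, profile: SimilarityProfile
) -> pd.Series:
    """Arithmetic mean reference-similarity per cluster."""
    missing = [i for i in assignments.index if i not in profile.scores]
    if missing:
        raise InputError(f"similarity profile misses assigned ids: {missing[:5]}")
    scores = pd.Series({i: profile.scores[i] for i in assignments.index})
    return scores.groupby(assignments).mean().rename("mean_similarity")
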