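"""Network-level summaries of aligned gradient embeddings.

Four metric families per subject, all in the aligned gradient space:

- within-network score: mean gradient value per network (per gradient);
- within-network dispersion: sum of squared Euclidean distances of a
  network's parcels from the network centroid in 2-D (G1, G2) space;
- between-network dispersion: Euclidean distance between network centroids
  in the same 2-D space;
- global gradient variation: standard deviation of each of the first two
  gradients across all parcels (sample sd, denominator P-1).

Centroids are unweighted means of member parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import NetworkAssignment
from .gradients import GradientEmbedding


def _components(emb: GradientEmbedding | np.ndarray) -> np.ndarray:
    if isinstance(emb, GradientEmbedding):
        if not emb.aligned:
            raise ValueError("network metrics require a template-aligned embedding")
        return emb.components
    return np.asarray(emb, dtype=float)


def within_network_score(
    emb: GradientEmbedding | np.ndarray, assign: NetworkAssignment
) -> pd.DataFrame:
    """Mean gradient value per network; rows = networks, columns = G1..Gm."""
    comp = _components(emb)
    rows = []
    for net in assign.networks:
        idx = assign.indices(net)
        rows.append(comp[idx].mean(axis=0))
    cols = [f"G{g + 1}" for g in range(comp.shape[1])]
    return pd.DataFrame(rows, index=list(assign.networks), columns=cols)


def within_network_dispersion(
    emb2d: GradientEmbedding | np.ndarray, assign: NetworkAssignment
) -> pd.Series:
    """Sum of squared distances to the network centroid in (G1, G2) space."""
    comp = _components(emb2d)[:, :2]
    values = {}
    for net in assign.networks:
        pts = comp[assign.indices(net)]
        centroid = pts.mean(axis=0)
        values[net] = float(((pts - centroid) ** 2).sum())
    return pd.Series(values, name="within_dispersion")


def between_network_dispersion(
    emb2d: GradientEmbedding | np.ndarray, assign: NetworkAssignment
) -> pd.DataFrame:
    """Pairwise Euclidean distances between network centroids in (G1, G2)."""
    comp = _components(emb2d)[:, :2]
    centroids = np.vstack([comp[assign.indices(net)].mean(axis=0) for net in assign.networks])
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return pd.DataFrame(dist, index=list(assign.networks), columns=list(assign.networks))


def global_variation(emb: GradientEmbedding | np.ndarray) -> np.ndarray:
    """Sample standard deviation of G1 and G2 across all parcels."""
    comp = _components(emb)[:, :2]
    if comp.shape[0] < 2:
        raise ValueError("global variation needs at least 2 parcels")
    return comp.std(axis=0, ddof=1)


@dataclass
class NetworkMetrics:
    """All gradient metrics for one subject."""

    subject_id: str
    within_score: pd.DataFrame  # K x m
    within_dispersion: pd.Series  # K
    between_dispersion: pd.DataFrame  # K x K
    global_var: np.ndarray  # 2

    def to_long(self) -> pd.DataFrame:
        """Long-format table: subject, metric, network(s), gradient, value."""
        records = []
        for net in self.within_score.index:
            for g in (1, 2):
                records.append((self.subject_id, "within_score", net, "", g,
                                self.within_score.loc[net, f"G{g}"]))
        for net, val in self.within_dispersion.items():
            records.append((self.subject_id, "within_dispersion", net, "", 0, val))
        nets = list(self.between_dispersion.index)
        for i, na in enumerate(nets):
            for nb in nets[i + 1:]:
                records.append((self.subject_id, "between_dispersion", na, nb, 0,
                                self.between_dispersion.loc[na, nb]))
        for g in (1, 2):
            records.append((self.subject_id, "global_variation", "", "", g,
                            self.global_var[g - 1]))
        return pd.DataFrame(
            records,
            columns=["subject_id", "metric", "network", "network_b", "gradient", "value"],
        )


def compute_network_metrics(
    emb: GradientEmbedding, assign: NetworkAssignment
) -> NetworkMetrics:
    return NetworkMetrics(
        subject_id=emb.subject_id,
        within_score=within_network_score(emb, assign),
        within_dispersion=within_network_dispersion(emb, assign),
        between_dispersion=between_network_dispersion(emb, assign),
        global_var=global_variation(emb),
    )
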