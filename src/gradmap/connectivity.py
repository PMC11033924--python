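"""Per-subject and group-average functional connectivity matrices.

The FC estimator is the pairwise Pearson correlation of parcel time-series,
Fisher r-to-z transformed before gradient estimation. The diagonal is zeroed
at the z stage (atanh(1) is undefined, and downstream row sparsification must
never select self-connections). The group template matrix is the element-wise
mean of the per-subject z matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_prep import ParcelTimeSeries

RAW_R = "raw_r"
FISHER_Z = "fisher_z"


@dataclass
class ConnectivityMatrix:
    """Symmetric P x P connectivity matrix with a processing-stage tag."""

    matrix: np.ndarray
    stage: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.stage not in (RAW_R, FISHER_Z):
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix must be symmetric to 1e-12")

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


def pearson_fc(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of all parcel rows (diagonal 1)."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = ts.matrix.std(axis=1)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size:
        raise ValueError(
            f"parcel {constant[0] + 1} has a constant time series (subject {ts.subject_id!r})"
        )
    r = np.corrcoef(ts.matrix)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(matrix=r, stage=RAW_R, subject_id=ts.subject_id)


def fisher_z(fc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z transform off-diagonal; diagonal set to exactly 0."""
    if fc.stage != RAW_R:
        raise ValueError(f"fisher_z expects stage {RAW_R!r}, got {fc.stage!r}")
    r = fc.matrix.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    saturated = off & (np.abs(r) >= 1.0)
    if saturated.any():
        i, j = np.argwhere(saturated)[0]
        raise ValueError(
            f"|r| = 1 between parcels {i + 1} and {j + 1}; duplicate parcel time series"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(matrix=z, stage=FISHER_Z, subject_id=fc.subject_id)


def group_mean_fc(fcs: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise arithmetic mean of Fisher-z matrices ("group-mean")."""
    if len(fcs) < 2:
        raise ValueError("need at least 2 matrices for a group mean")
    stages = {fc.stage for fc in fcs}
    if stages != {FISHER_Z}:
        raise ValueError(f"all matrices must share stage {FISHER_Z!r}; found {sorted(stages)}")
    shapes = {fc.n_parcels for fc in fcs}
    if len(shapes) != 1:
        raise ValueError(f"mixed parcel counts: {sorted(shapes)}")
    mean = np.mean([fc.matrix for fc in fcs], axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    return ConnectivityMatrix(matrix=mean, stage=FISHER_Z, subject_id="group-mean")
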