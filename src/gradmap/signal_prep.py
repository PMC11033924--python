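"""Subject-level time-series cleaning and cohort-level quality control.

Operations here precede functional-connectivity estimation: nuisance
(confound) regression, zero-phase band-pass filtering of the parcel
time-series, and cohort-level exclusion of subjects with excessive head
motion (mean framewise displacement) or missing parcels.

The cleaning order is regress-then-filter; both stages are individually
optional, since synthetic cohorts carry no confounds by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.signal

logger = logging.getLogger(__name__)


@dataclass
class ParcelTimeSeries:
    """One subject's parcellated BOLD signal: parcels x timepoints.

    Parameters
    ----------
    matrix : ndarray, shape (P, T)
        One row per parcel, one column per timepoint; arbitrary signal units.
    tr : float
        Sampling interval (repetition time) in seconds.
    subject_id : str
        Cohort-unique subject identifier.
    """

    matrix: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("time-series matrix must be 2-D (parcels x timepoints)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]


def _independent_columns(m: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if m.shape[1] == 0:
        return np.empty(0, dtype=int)
    r, piv = scipy.linalg.qr(m, mode="r", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0.0:
        return np.empty(0, dtype=int)
    tol = diag[0] * max(m.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    return np.sort(piv[:rank])


def regress_confounds(ts: ParcelTimeSeries, confounds: np.ndarray | pd.DataFrame | None) -> ParcelTimeSeries:
    """Replace each parcel series by its residual after projecting out confounds.

    The design is ``[intercept | confounds]``; with an empty confound set this
    reduces to row-demeaning. Linearly dependent confound columns are dropped
    via pivoted QR and logged rather than failing the solve.
    """
    if confounds is None:
        conf = np.empty((ts.n_timepoints, 0))
        names = []
    elif isinstance(confounds, pd.DataFrame):
        conf = confounds.to_numpy(dtype=float)
        names = list(confounds.columns)
    else:
        conf = np.asarray(confounds, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        names = [f"c{i}" for i in range(conf.shape[1])]
    if conf.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confound rows ({conf.shape[0]}) do not match timepoints ({ts.n_timepoints})"
        )
    design = np.column_stack([np.ones(ts.n_timepoints), conf])
    keep = _independent_columns(design)
    dropped = sorted(set(range(design.shape[1])) - set(keep.tolist()))
    if dropped:
        dropped_names = [("intercept" if j == 0 else names[j - 1]) for j in dropped]
        logger.warning(
            "subject %s: dropped %d linearly dependent confound column(s): %s",
            ts.subject_id, len(dropped), ", ".join(dropped_names),
        )
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, ts.matrix.T, rcond=None)
    resid = ts.matrix - (design @ beta).T
    return replace(ts, matrix=resid)


def bandpass(ts: ParcelTimeSeries, low: float = 0.01, high: float = 0.1) -> ParcelTimeSeries:
    """Zero-phase Butterworth band-pass of every parcel series.

    A second-order Butterworth band-pass is applied forward and backward
    (``sosfiltfilt``), so the effective magnitude response is squared and the
    phase is zero. ``high`` must lie strictly below the Nyquist frequency
    ``1/(2*tr)``.
    """
    nyq = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz is at or above Nyquist {nyq:.4g} Hz for tr={ts.tr} s"
        )
    sos = scipy.signal.butter(2, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, ts.matrix, axis=1)
    return replace(ts, matrix=np.ascontiguousarray(filtered))


def qc_filter(
    manifest: pd.DataFrame,
    timeseries: dict[str, ParcelTimeSeries],
    fd_threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, ParcelTimeSeries], pd.DataFrame]:
    """Exclude high-motion subjects and subjects with missing parcels.

    A subject is removed when mean framewise displacement is *strictly*
    greater than ``fd_threshold`` (equality retains), or when any parcel row
    is entirely zero or contains non-finite values (a missing node after
    parcellation). Retained subjects keep their manifest order.

    Returns
    -------
    (retained manifest, retained time-series, exclusion log)
        The exclusion log has columns ``subject_id`` and ``reason``.
    """
    exclusions: list[tuple[str, str]] = []
    keep_ids: list[str] = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        if float(row["mean_fd"]) > fd_threshold:
            exclusions.append((sid, f"mean FD {row['mean_fd']:.3f} > {fd_threshold} mm"))
            continue
        ts = timeseries.get(sid)
        if ts is None:
            exclusions.append((sid, "missing time-series"))
            continue
        if not np.all(np.isfinite(ts.matrix)):
            exclusions.append((sid, "non-finite values"))
            continue
        zero_rows = np.flatnonzero(np.all(ts.matrix == 0.0, axis=1))
        if zero_rows.size:
            exclusions.append((sid, f"missing parcel (all-zero row {zero_rows[0] + 1})"))
            continue
        keep_ids.append(sid)
    log = pd.DataFrame(exclusions, columns=["subject_id", "reason"])
    kept_manifest = manifest[manifest["subject_id"].astype(str).isin(keep_ids)].reset_index(drop=True)
    kept_ts = {sid: timeseries[sid] for sid in keep_ids}
    for sid, reason in exclusions:
        logger.info("excluded subject %s: %s", sid, reason)
    return kept_manifest, kept_ts, log
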