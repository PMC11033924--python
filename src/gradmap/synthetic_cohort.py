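"""Synthetic rs-fMRI cohorts with planted gradient structure.

Each subject's parcel time-series is drawn from a zero-mean Gaussian whose
correlation matrix has low-rank-plus-noise structure
``Sigma = Lambda Lambda' + band + psi I`` (rescaled to unit diagonal):

- a global factor giving the between-network baseline correlation;
- one indicator factor per network raising within-network correlation, with
  a few "bridge" parcels at each network boundary loading on both adjacent
  networks (parcellation boundaries are fuzzy in real data; these bridges
  also keep the sparsified affinity graph connected);
- two smooth latent axis columns interpolated along a canonical cortical
  ordering: axis 1 runs from visual to sensorimotor cortex, axis 2 from
  sensory to transmodal (DMN) cortex — the two-gradient geometry the
  embedding should recover;
- a short-range squared-exponential band emulating local spatial
  autocorrelation of cortical connectivity.

The canonical ordering places visual and sensorimotor cortex at opposite
ends with association cortex between them, so axis 1 is the dominant
(slowest) mode and axis 2 the secondary one. The DMN carries the largest
|axis-2| value, which anchors the template's deterministic sign convention
with the DMN at the positive end of gradient 2.

Planted effects:

- patients' sensorimotor network-factor loading is attenuated by
  ``group_effect_size`` (a within-network connectivity/coherence loss — the
  regional and network-level group effect);
- patients' axis-2 column is multiplied by ``axis2_compression`` < 1 (a
  compressed sensory-transmodal gradient);
- a per-subject latent coupling ``delta ~ N(1, delta_sd)`` scales the DMN
  entries of axis 2 and generates the cognition score
  ``sdmt = intercept + slope * (delta - 1) + noise`` (patients only), so
  cognition-score recovery through the full gradient pipeline is a genuine
  end-to-end test.

Time series are temporally white by default (the pipeline consumes only
correlations); an optional AR(1) flag adds temporal smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Cohort, NetworkAssignment
from .signal_prep import ParcelTimeSeries

#: canonical cortical ordering and 200-parcel sizes (proportions modeled on
#: the 7-network functional parcellation: DMN largest, limbic smallest);
#: visual and sensorimotor cortex sit at opposite ends of the ordering
CANONICAL_NETWORKS: tuple[str, ...] = ("VN", "DAN", "LN", "DMN", "FPN", "VAN", "SMN")
CANONICAL_SIZES: dict[str, int] = {
    "VN": 30, "DAN": 26, "LN": 12, "DMN": 44, "FPN": 30, "VAN": 24, "SMN": 34,
}
#: network anchor values for the two latent axes (interpolated per parcel)
AXIS1_ANCHORS: dict[str, float] = {
    "VN": 1.0, "DAN": 0.5, "LN": 0.2, "DMN": 0.0, "FPN": -0.2, "VAN": -0.5, "SMN": -1.0,
}
AXIS2_ANCHORS: dict[str, float] = {
    "VN": -0.6, "DAN": -0.3, "LN": 0.35, "DMN": 1.2, "FPN": 0.45, "VAN": -0.15, "SMN": -0.5,
}


def default_network_assignment(n_parcels: int = 200, n_networks: int = 7) -> NetworkAssignment:
    """Parcel-to-network lookup in the canonical ordering.

    For P = 200 / K = 7 the canonical sizes are used; otherwise parcels are
    split proportionally across the first K canonical labels.
    """
    names = CANONICAL_NETWORKS[:n_networks]
    if n_parcels == 200 and n_networks == 7:
        sizes = [CANONICAL_SIZES[n] for n in names]
    else:
        weights = np.array([CANONICAL_SIZES.get(n, 20) for n in names], dtype=float)
        sizes = np.floor(weights / weights.sum() * n_parcels).astype(int)
        sizes[-1] += n_parcels - sizes.sum()
        sizes = sizes.tolist()
    labels = np.concatenate([np.repeat(n, s) for n, s in zip(names, sizes)])
    return NetworkAssignment(labels=labels, networks=tuple(names))


@dataclass
class SimulationSpec:
    """Generator parameters; defaults define the reference study conditions."""

    n_parcels: int = 200
    n_networks: int = 7
    n_timepoints: int = 240
    tr: float = 1.5
    n_per_group: tuple[int, int] = (122, 97)  # (patients, controls), as in the study
    patient_label: str = "MS"
    control_label: str = "HC"
    within_network_corr: float = 0.35
    between_network_corr: float = 0.05
    axis_scales: tuple[float, float] = (1.0, 0.6)
    bridge_parcels: int = 4  # per side of each network boundary
    spatial_amp: float = 0.3  # squared-exponential band variance
    spatial_scale: float = 2.0  # band correlation length in parcels
    noise_variance: float = 0.5  # psi, idiosyncratic parcel variance
    group_effect_size: float = 0.45  # fractional SMN factor-loading attenuation
    axis2_compression: float = 0.7
    network_wobble_sd: float = 0.0  # per-subject, per-network coherence variability
    axis_strength_sd: float = 0.0  # per-subject global gradient-strength variability
    global_coherence_sd: float = 0.0  # per-subject overall FC-strength variability
    delta_sd: float = 0.3
    sdmt_intercept: float = 39.8
    sdmt_slope: float = 25.0
    sdmt_noise_sd: float = 2.0
    age_mean: tuple[float, float] = (37.6, 38.1)  # (patients, controls)
    age_sd: tuple[float, float] = (9.9, 12.0)
    p_female: tuple[float, float] = (0.69, 0.58)
    fd_log_median: float = 0.1  # lognormal median in mm
    fd_log_sigma: float = 0.4
    ar_coefficient: float = 0.0  # optional AR(1) temporal smoothing
    affected_network: str = "SMN"
    coupled_network: str = "DMN"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.between_network_corr < self.within_network_corr < 1.0):
            raise ValueError("need 0 <= between_network_corr < within_network_corr < 1")
        if not (0.0 < self.axis2_compression <= 1.0):
            raise ValueError("axis2_compression must lie in (0, 1]")
        if not (0.0 <= self.group_effect_size < 1.0):
            raise ValueError("group_effect_size must lie in [0, 1)")
        if min(self.n_per_group) < 1:
            raise ValueError("each group needs at least one subject")

    def assignment(self) -> NetworkAssignment:
        return default_network_assignment(self.n_parcels, self.n_networks)


def axis_loadings(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """The two latent axis columns as smooth functions of parcel index.

    Network anchor values are linearly interpolated at network centers, so
    parcels vary smoothly within and across networks instead of collapsing
    onto K points.
    """
    assign = spec.assignment()
    sizes = np.array([assign.indices(n).size for n in assign.networks], dtype=float)
    centers = np.cumsum(sizes) - sizes / 2.0
    idx = np.arange(spec.n_parcels, dtype=float)
    a1 = np.interp(idx, centers, [AXIS1_ANCHORS.get(n, 0.0) for n in assign.networks])
    a2 = np.interp(idx, centers, [AXIS2_ANCHORS.get(n, 0.0) for n in assign.networks])
    return a1, a2


def _network_factor_columns(spec: SimulationSpec) -> dict[str, np.ndarray]:
    """Per-network factor columns with boundary bridge parcels.

    ``bridge_parcels`` parcels on each side of every network boundary split
    their loading equally between the two adjacent networks.
    """
    assign = spec.assignment()
    load = np.sqrt(spec.within_network_corr - spec.between_network_corr)
    cols = {n: np.zeros(spec.n_parcels) for n in assign.networks}
    for net in assign.networks:
        cols[net][assign.indices(net)] = load
    sizes = [assign.indices(n).size for n in assign.networks]
    bounds = np.cumsum(sizes)[:-1]
    for bi, bound in enumerate(bounds):
        left, right = assign.networks[bi], assign.networks[bi + 1]
        for j in range(spec.bridge_parcels):
            for p in (bound - 1 - j, bound + j):
                if 0 <= p < spec.n_parcels:
                    cols[left][p] = load / np.sqrt(2.0)
                    cols[right][p] = load / np.sqrt(2.0)
    return cols


def build_group_covariance(
    spec: SimulationSpec,
    group: str,
    delta: float = 1.0,
    wobble: np.ndarray | None = None,
    axis_strength: float = 1.0,
    coherence: float = 1.0,
) -> np.ndarray:
    """Unit-diagonal covariance for one subject of the given group.

    Patients (``group == spec.patient_label``) receive the sensorimotor
    factor-loading attenuation and the axis-2 compression; ``delta`` scales
    the DMN entries of the axis-2 column for every subject. ``wobble``
    (length K, around 1) scales each network's factor loading, modeling
    ordinary between-subject variability in network coherence;
    ``axis_strength`` scales both axis columns, modeling between-subject
    variability in how strongly the global gradient geometry is expressed;
    ``coherence`` scales the entire structured covariance against the fixed
    idiosyncratic noise, modeling overall FC-strength differences between
    subjects (the dominant mode of real between-subject FC variability).
    """
    if group not in (spec.patient_label, spec.control_label):
        raise ValueError(f"unknown group {group!r}")
    delta_max = 1.0 + 2.5 * spec.delta_sd
    if not (0.0 < delta <= delta_max):
        raise ValueError(f"delta must lie in (0, {delta_max:.3g}] (2.5 sd around 1)")
    assign = spec.assignment()
    a1, a2 = axis_loadings(spec)
    factor_cols = _network_factor_columns(spec)
    a2 = a2.copy()
    if wobble is not None:
        factor_cols = {
            n: factor_cols[n] * w for n, w in zip(assign.networks, wobble)
        }
    if group == spec.patient_label:
        factor_cols = dict(factor_cols)
        factor_cols[spec.affected_network] = (
            factor_cols[spec.affected_network] * (1.0 - spec.group_effect_size)
        )
        a2 *= spec.axis2_compression
    # delta is a variance-neutral coupling: the coupled network's axis-2
    # loading scales with delta while its idiosyncratic variance absorbs the
    # difference, so a subject's delta changes only the coupled network's
    # correlations along axis 2, not its total variance
    s1 = spec.axis_scales[0] * axis_strength
    s2 = spec.axis_scales[1] * axis_strength
    coupled = assign.indices(spec.coupled_network)
    # delta scales the coupled network's axis-2 loading, strengthening or
    # weakening its coupling to the sensory-transmodal hierarchy
    a2[coupled] *= delta
    psi = np.full(spec.n_parcels, spec.noise_variance)

    cols = [np.full(spec.n_parcels, np.sqrt(spec.between_network_corr))]
    cols.extend(factor_cols[n] for n in assign.networks)
    cols.append(s1 * a1)
    cols.append(s2 * a2)
    lam = coherence * np.column_stack(cols)
    sigma = lam @ lam.T
    if spec.spatial_amp > 0.0:
        d2 = np.subtract.outer(np.arange(spec.n_parcels), np.arange(spec.n_parcels)) ** 2
        sigma += coherence ** 2 * spec.spatial_amp * np.exp(-d2 / (2.0 * spec.spatial_scale ** 2))
    sigma[np.diag_indices_from(sigma)] += psi
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    sigma = (sigma + sigma.T) / 2.0
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig < -1e-10:
        raise ValueError(f"constructed covariance is not PSD (min eigenvalue {min_eig:.3e})")
    return sigma


def simulate_subject(
    sigma: np.ndarray,
    n_timepoints: int,
    seed: int | np.random.Generator,
    tr: float = 1.5,
    subject_id: str = "",
    ar_coefficient: float = 0.0,
) -> ParcelTimeSeries:
    """Draw a parcels x timepoints Gaussian series with covariance ``sigma``.

    Timepoints are independent draws unless ``ar_coefficient`` > 0, in which
    case a variance-normalized AR(1) filter is applied along time.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = sigma.shape[0]
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(p))
    z = rng.standard_normal((n_timepoints, p))
    if ar_coefficient > 0.0:
        phi = ar_coefficient
        for t in range(1, n_timepoints):
            z[t] = phi * z[t - 1] + np.sqrt(1.0 - phi ** 2) * z[t]
    x = z @ chol.T  # T x P
    return ParcelTimeSeries(matrix=x.T, tr=tr, subject_id=subject_id)


def simulate_cohort(spec: SimulationSpec) -> tuple[Cohort, pd.DataFrame]:
    """Generate a full cohort plus its ground truth.

    Returns ``(cohort, ground_truth)``; the ground-truth table records each
    subject's latent coupling delta and cognition-score noise, and (in
    ``attrs``) the planted affected/coupled networks and the base group
    covariances at delta = 1.
    """
    rng = np.random.default_rng(spec.seed)
    n_pat, n_con = spec.n_per_group
    records = []
    truth = []
    timeseries: dict[str, ParcelTimeSeries] = {}
    groups = [spec.patient_label] * n_pat + [spec.control_label] * n_con
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        gi = 0 if group == spec.patient_label else 1
        delta = float(np.clip(
            1.0 + spec.delta_sd * rng.standard_normal(),
            1.0 - 2.49 * spec.delta_sd, 1.0 + 2.49 * spec.delta_sd,
        ))
        wobble = np.clip(
            1.0 + spec.network_wobble_sd * rng.standard_normal(spec.n_networks), 0.5, 1.5
        )
        axis_strength = float(np.clip(
            1.0 + spec.axis_strength_sd * rng.standard_normal(), 0.7, 1.3
        ))
        coherence = float(np.clip(
            1.0 + spec.global_coherence_sd * rng.standard_normal(), 0.4, 1.6
        ))
        sigma = build_group_covariance(
            spec, group, delta=delta, wobble=wobble,
            axis_strength=axis_strength, coherence=coherence,
        )
        timeseries[sid] = simulate_subject(
            sigma, spec.n_timepoints, rng, tr=spec.tr, subject_id=sid,
            ar_coefficient=spec.ar_coefficient,
        )
        age = spec.age_mean[gi] + spec.age_sd[gi] * rng.standard_normal()
        sex = "F" if rng.random() < spec.p_female[gi] else "M"
        mean_fd = float(np.exp(np.log(spec.fd_log_median) + spec.fd_log_sigma * rng.standard_normal()))
        noise = spec.sdmt_noise_sd * rng.standard_normal()
        sdmt = spec.sdmt_intercept + spec.sdmt_slope * (delta - 1.0) + noise
        is_patient = group == spec.patient_label
        records.append({
            "subject_id": sid, "group": group, "age": round(age, 1), "sex": sex,
            "mean_fd": round(mean_fd, 4),
            "sdmt": round(sdmt, 1) if is_patient else np.nan,
            "edss": round(float(np.clip(rng.normal(2.5, 1.5), 0, 9)), 1) if is_patient else np.nan,
            "disease_duration": round(float(np.clip(rng.normal(10.3, 8.7), 0.1, None)), 1)
            if is_patient else np.nan,
            "lesion_load": round(float(np.clip(rng.normal(4.0, 4.1), 0.05, None)), 2)
            if is_patient else np.nan,
            "bpf": round(float(np.clip(rng.normal(0.71 if gi == 0 else 0.74, 0.03), 0.5, 1.0)), 3),
        })
        truth.append({"subject_id": sid, "group": group, "delta": delta, "sdmt_noise": noise})
    manifest = pd.DataFrame(records)
    ground_truth = pd.DataFrame(truth)
    ground_truth.attrs["affected_network"] = spec.affected_network
    ground_truth.attrs["coupled_network"] = spec.coupled_network
    ground_truth.attrs["group_covariance"] = {
        spec.patient_label: build_group_covariance(spec, spec.patient_label),
        spec.control_label: build_group_covariance(spec, spec.control_label),
    }
    cohort = Cohort(manifest=manifest, timeseries=timeseries, assignment=spec.assignment())
    return cohort, ground_truth
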