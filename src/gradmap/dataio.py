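"""Tabular I/O, run configuration, and cross-file consistency checks.

Everything on disk is delimited text (TSV): the cohort manifest, per-subject
parcel-by-timepoint matrices, the parcel-to-network lookup, and all result
tables. Parcel ids are 1-based in files and 0-based in memory; the lookup's
row order defines matrix row order.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal_prep import ParcelTimeSeries

logger = logging.getLogger(__name__)

#: manifest columns that may legitimately be absent per subject
OPTIONAL_MANIFEST_COLUMNS = ("sdmt", "edss", "disease_duration", "lesion_load", "bpf")

FLOAT_FORMAT = "%.10g"


@dataclass
class NetworkAssignment:
    """Unique assignment of P parcels to K large-scale functional networks.

    ``labels[i]`` is the network of parcel i (0-based); ``networks`` holds the
    K distinct labels in first-appearance order.
    """

    labels: np.ndarray
    networks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if not self.networks:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(str(lab), None)
            self.networks = tuple(seen)

    @property
    def n_parcels(self) -> int:
        return int(self.labels.size)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def indices(self, network: str) -> np.ndarray:
        idx = np.flatnonzero(self.labels == network)
        if idx.size == 0:
            raise ValueError(f"network {network!r} has no parcels")
        return idx


@dataclass
class RunConfig:
    """Pipeline parameters with the analysis defaults.

    density : fraction of strongest connections kept per FC row (0.10).
    n_components : gradients computed per subject (10; the first 2 analyzed).
    alpha : diffusion anisotropy exponent (0.5).
    diffusion_time : 0 selects multiscale lambda/(1-lambda) scaling.
    band : band-pass edges in Hz (0.01, 0.1).
    fd_threshold : mean-FD exclusion cutoff in mm (0.5).
    """

    density: float = 0.10
    n_components: int = 10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    band: tuple[float, float] = (0.01, 0.1)
    fd_threshold: float = 0.5
    patient_label: str = "MS"
    control_label: str = "HC"
    correlation_family: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.density < 1.0):
            raise ValueError("density must lie in (0, 1)")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        low, high = self.band
        if not (0.0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)


@dataclass
class Cohort:
    """Manifest plus the per-subject parcellated time-series it indexes."""

    manifest: pd.DataFrame
    timeseries: dict[str, ParcelTimeSeries]
    assignment: NetworkAssignment | None = None
    flagged: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.manifest)

    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.manifest["subject_id"]]


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "age", "sex", "mean_fd"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing required columns: {sorted(missing)}")
    if manifest["subject_id"].duplicated().any():
        dupes = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")
    groups = manifest["group"].unique().tolist()
    if len(groups) != 2:
        raise ValueError(f"manifest must contain exactly two group labels, found {groups}")
    return manifest


def read_timeseries(path: str | Path, tr: float, subject_id: str) -> ParcelTimeSeries:
    mat = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return ParcelTimeSeries(matrix=mat, tr=tr, subject_id=subject_id)


def read_cohort(manifest_path: str | Path, timeseries_dir: str | Path, tr: float = 1.5) -> Cohort:
    """Load a manifest and one ``ts_<subject_id>.tsv`` matrix per subject.

    Subjects whose time-series file is missing are *flagged* (kept in the
    manifest, listed in ``Cohort.flagged``), never silently dropped; a
    parcel-count mismatch across subjects is a hard error naming the subject.
    """
    manifest = read_manifest(manifest_path)
    tsdir = Path(timeseries_dir)
    timeseries: dict[str, ParcelTimeSeries] = {}
    flagged: list[str] = []
    n_parcels: int | None = None
    ref_subject = ""
    for sid in manifest["subject_id"].astype(str):
        fpath = tsdir / f"ts_{sid}.tsv"
        if not fpath.exists():
            flagged.append(sid)
            logger.warning("subject %s: time-series file %s not found; flagged", sid, fpath)
            continue
        ts = read_timeseries(fpath, tr=tr, subject_id=sid)
        if n_parcels is None:
            n_parcels, ref_subject = ts.n_parcels, sid
        elif ts.n_parcels != n_parcels:
            raise ValueError(
                f"subject {sid} has {ts.n_parcels} parcels but subject "
                f"{ref_subject} has {n_parcels}"
            )
        timeseries[sid] = ts
    return Cohort(manifest=manifest, timeseries=timeseries, flagged=flagged)


def read_network_lookup(path: str | Path, n_parcels: int | None = None) -> NetworkAssignment:
    """Read a two-column (parcel_id, network) lookup into a NetworkAssignment.

    Parcel ids must be exactly 1..P with no duplicates; label levels are taken
    in first-appearance order. If fewer labels appear than the conventional 7
    a warning is logged but the assignment is still returned.
    """
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("lookup must have two columns: parcel_id, network")
    ids = table.iloc[:, 0].to_numpy(dtype=int)
    labels = table.iloc[:, 1].astype(str).to_numpy(dtype=object)
    if n_parcels is not None and ids.size != n_parcels:
        raise ValueError(f"lookup has {ids.size} rows, expected {n_parcels}")
    if np.unique(ids).size != ids.size:
        dup = int(ids[pd.Series(ids).duplicated().to_numpy()][0])
        raise ValueError(f"duplicate parcel_id {dup} in lookup")
    expected = np.arange(1, ids.size + 1)
    if not np.array_equal(np.sort(ids), expected):
        missing = sorted(set(expected.tolist()) - set(ids.tolist()))
        raise ValueError(f"lookup parcel ids are not 1..P; missing {missing[:5]}")
    order = np.argsort(ids)
    assign = NetworkAssignment(labels=labels[order])
    if assign.n_networks < 7:
        logger.warning(
            "lookup defines only %d network labels (7 expected for the canonical parcellation)",
            assign.n_networks,
        )
    return assign


def write_network_lookup(assign: NetworkAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"parcel_id": np.arange(1, assign.n_parcels + 1), "network": assign.labels}
    ).to_csv(path, sep="\t", index=False)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a bare numeric matrix as TSV (no header, no index).

    Full (17 significant digit) precision so matrices round-trip exactly.
    """
    pd.DataFrame(np.asarray(matrix)).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.17g"
    )


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write named result tables as deterministic TSVs.

    Rows are sorted by the leading identifier columns and floats serialized at
    fixed precision, so writing the same table twice yields byte-identical
    files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        sort_cols = [
            c for c in ("parcel", "network", "network_a", "network_b", "subject_id",
                        "metric", "gradient", "feature", "variable")
            if c in table.columns
        ]
        if sort_cols:
            table = table.sort_values(sort_cols, kind="stable")
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    return written


def write_run_log(path: str | Path, config: RunConfig, notes: dict[str, object] | None = None) -> None:
    """Record config, seeds, and library versions for provenance."""
    import scipy
    import sklearn
    import statsmodels
    import xgboost

    lines = ["[config]"]
    for key, val in vars(config).items():
        lines.append(f"{key} = {val!r}")
    lines.append("[versions]")
    for mod in (np, scipy, pd, sklearn, statsmodels, xgboost):
        lines.append(f"{mod.__name__} = {mod.__version__}")
    lines.append(f"python = {sys.version.split()[0]}")
    if notes:
        lines.append("[notes]")
        for key, val in notes.items():
            lines.append(f"{key} = {val!r}")
    Path(path).write_text("\n".join(lines) + "\n")
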