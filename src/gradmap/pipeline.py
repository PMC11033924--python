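"""End-to-end orchestration of the gradient analysis stages.

Glue only: every step delegates to the stage modules. The canonical order is
QC filtering -> per-subject FC -> group-mean FC -> template -> per-subject
diffusion embeddings aligned to the template -> network metrics -> group
statistics / correlations -> prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, fisher_z, group_mean_fc, pearson_fc
from .dataio import Cohort, NetworkAssignment, RunConfig
from .gradients import GradientEmbedding, GradientTemplate, align_to_template, build_template, subject_gradients
from .group_stats import correlation_screen, demographics_table, network_group_tests, regional_group_tests
from .network_metrics import NetworkMetrics, compute_network_metrics
from .prediction import PredictionConfig, PredictionResult, feature_table, run_prediction
from .signal_prep import bandpass, qc_filter, regress_confounds


@dataclass
class GradientStage:
    manifest: pd.DataFrame
    template: GradientTemplate
    embeddings: dict[str, GradientEmbedding]
    exclusions: pd.DataFrame
    assignment: NetworkAssignment

    def stacked_2d(self) -> np.ndarray:
        """Aligned (G1, G2) coordinates, shape (n_subjects, P, 2), manifest order."""
        return np.stack(
            [self.embeddings[str(s)].gradient2d() for s in self.manifest["subject_id"]]
        )


def compute_gradients(
    cohort: Cohort,
    cfg: RunConfig | None = None,
    clean: bool = False,
    confounds: dict[str, np.ndarray] | None = None,
) -> GradientStage:
    """QC filter the cohort, build the template, and align every subject.

    ``clean=True`` applies confound regression (when confounds are supplied)
    followed by band-pass filtering before FC estimation; synthetic cohorts
    are already band-limited white Gaussian draws, so cleaning defaults off.
    """
    cfg = cfg or RunConfig()
    if cohort.assignment is None:
        raise ValueError("cohort has no network assignment")
    manifest, timeseries, exclusions = qc_filter(
        cohort.manifest, cohort.timeseries, fd_threshold=cfg.fd_threshold
    )
    if clean:
        cleaned = {}
        for sid, ts in timeseries.items():
            if confounds and sid in confounds:
                ts = regress_confounds(ts, confounds[sid])
            cleaned[sid] = bandpass(ts, *cfg.band)
        timeseries = cleaned
    z_matrices: dict[str, ConnectivityMatrix] = {
        sid: fisher_z(pearson_fc(ts)) for sid, ts in timeseries.items()
    }
    template = build_template(group_mean_fc(list(z_matrices.values())), cfg)
    embeddings = {
        sid: align_to_template(subject_gradients(z, cfg), template)
        for sid, z in z_matrices.items()
    }
    return GradientStage(
        manifest=manifest,
        template=template,
        embeddings=embeddings,
        exclusions=exclusions,
        assignment=cohort.assignment,
    )


def compute_metrics(stage: GradientStage) -> list[NetworkMetrics]:
    return [
        compute_network_metrics(stage.embeddings[str(s)], stage.assignment)
        for s in stage.manifest["subject_id"]
    ]


@dataclass
class AnalysisResult:
    stage: GradientStage
    metrics: list[NetworkMetrics]
    regional: pd.DataFrame
    network: pd.DataFrame
    correlations: pd.DataFrame
    demographics: pd.DataFrame
    prediction: PredictionResult | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "regional_stats": self.regional,
            "network_stats": self.network,
            "correlations": self.correlations,
            "demographics": self.demographics,
            "exclusions": self.stage.exclusions,
        }
        if self.prediction is not None:
            out["prediction_report"] = self.prediction.to_frame()
        return out


def analyze_cohort(
    cohort: Cohort,
    cfg: RunConfig | None = None,
    prediction_cfg: PredictionConfig | None = None,
    predict: bool = False,
) -> AnalysisResult:
    """Run the full analysis; prediction is optional (it dominates runtime)."""
    cfg = cfg or RunConfig()
    stage = compute_gradients(cohort, cfg)
    metrics = compute_metrics(stage)
    regional = regional_group_tests(
        stage.stacked_2d(), stage.manifest, stage.assignment, patient_label=cfg.patient_label
    )
    network = network_group_tests(metrics, stage.manifest, patient_label=cfg.patient_label)
    correlations = correlation_screen(
        metrics, stage.manifest, patient_label=cfg.patient_label,
        family_size=cfg.correlation_family,
    )
    demographics = demographics_table(stage.manifest, patient_label=cfg.patient_label)
    prediction = None
    if predict:
        table = feature_table(metrics, stage.manifest, patient_label=cfg.patient_label)
        prediction = run_prediction(table, prediction_cfg or PredictionConfig(seed=cfg.seed))
    return AnalysisResult(
        stage=stage, metrics=metrics, regional=regional, network=network,
        correlations=correlations, demographics=demographics, prediction=prediction,
    )
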