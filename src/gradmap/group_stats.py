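"""Covariate-adjusted group comparison, correlations, and cohort description.

Group effects on the two gradients are tested with a multivariate linear
model (Hotelling's T^2 on the group coefficient, controlling for age, sex
and mean framewise displacement): with ``B = (X'X)^-1 X'Y`` and the
single-row contrast C selecting the group column,

    H = (CB)' [C (X'X)^-1 C']^-1 (CB),   E = residual cross-products,
    T^2 = nu * trace(H E^-1),            nu = n - p,

and the exact transform ``F = T^2 (nu - q + 1)/(q nu)`` is referred to an
F(q, nu - q + 1) distribution. Scalar responses (dispersion, global
variation) use ordinary least squares with a two-sided t test on the group
coefficient. Multiple comparisons are Bonferroni-corrected within each
declared family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .dataio import NetworkAssignment
from .network_metrics import NetworkMetrics

COVARIATES = ("age", "sex", "mean_fd")


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni adjustment min(1, m*p)."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m) if np.ndim(p) else min(1.0, float(p) * m)


def design_matrix(manifest: pd.DataFrame, patient_label: str) -> pd.DataFrame:
    """Design [intercept, group, age, sex, mean_fd]; group 1 = patient.

    Sex is coded 0/1 by first appearance in the manifest.
    """
    sex_levels = list(dict.fromkeys(manifest["sex"].astype(str)))
    if len(sex_levels) > 2:
        raise ValueError(f"sex must be binary, found levels {sex_levels}")
    sex = manifest["sex"].astype(str).map({lv: i for i, lv in enumerate(sex_levels)})
    x = pd.DataFrame(
        {
            "intercept": 1.0,
            "group": (manifest["group"] == patient_label).astype(float),
            "age": manifest["age"].astype(float),
            "sex": sex.astype(float),
            "mean_fd": manifest["mean_fd"].astype(float),
        }
    )
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return x


@dataclass
class HotellingResult:
    t2: float
    f: float
    df1: int
    df2: int
    p: float
    coef: np.ndarray  # group coefficient per response


def hotelling_group_test(
    y: np.ndarray, x: np.ndarray | pd.DataFrame, coef_index: int = 1
) -> HotellingResult:
    """Hotelling T^2 for the ``coef_index`` coefficient of a multivariate LS fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    q = y.shape[1]
    nu = n - p
    if nu - q + 1 < 1:
        raise ValueError(f"too few observations (n={n}) for p={p} predictors, q={q} responses")
    xtx_inv = np.linalg.inv(x.T @ x)
    b = xtx_inv @ x.T @ y
    resid = y - x @ b
    e = resid.T @ resid
    if np.linalg.matrix_rank(e) < q:
        raise ValueError("singular residual cross-product matrix (degenerate responses)")
    g = b[coef_index]  # (q,)
    h = np.outer(g, g) / xtx_inv[coef_index, coef_index]
    t2 = nu * float(np.trace(h @ np.linalg.inv(e)))
    df1, df2 = q, nu - q + 1
    f = t2 * df2 / (q * nu)
    pval = float(scipy.stats.f.sf(f, df1, df2))
    return HotellingResult(t2=t2, f=f, df1=df1, df2=df2, p=pval, coef=g)


def hotelling_batch(y: np.ndarray, x: np.ndarray, coef_index: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bivariate Hotelling T^2 over many response pairs.

    ``y`` has shape (n, B, 2) — B independent bivariate responses sharing the
    design ``x``. Returns (t2, p), each length B. Same algebra as
    :func:`hotelling_group_test`, with the 2x2 error inverse in closed form.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    nu = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    proj = xtx_inv @ x.T  # p x n
    b = np.einsum("kn,nbq->kbq", proj, y)
    resid = y - np.einsum("nk,kbq->nbq", x, b)
    e = np.einsum("nbq,nbr->bqr", resid, resid)
    g = b[coef_index]  # (B, 2)
    det = e[:, 0, 0] * e[:, 1, 1] - e[:, 0, 1] ** 2
    if np.any(det <= 0):
        raise ValueError("singular residual cross-product matrix in batch")
    # g E^-1 g' with the adjugate of the 2x2 E
    quad = (
        g[:, 0] ** 2 * e[:, 1, 1] - 2.0 * g[:, 0] * g[:, 1] * e[:, 0, 1] + g[:, 1] ** 2 * e[:, 0, 0]
    ) / det
    t2 = nu * quad / xtx_inv[coef_index, coef_index]
    f = t2 * (nu - 1) / (2.0 * nu)
    pvals = scipy.stats.f.sf(f, 2, nu - 1)
    return t2, pvals


def univariate_group_test(y: np.ndarray, x: pd.DataFrame | np.ndarray) -> tuple[float, float, float]:
    """OLS t test on the group coefficient; returns (coef, t, p)."""
    xdf = pd.DataFrame(x) if not isinstance(x, pd.DataFrame) else x
    fit = sm.OLS(np.asarray(y, dtype=float), xdf).fit()
    return float(fit.params["group"]), float(fit.tvalues["group"]), float(fit.pvalues["group"])


def regional_group_tests(
    gradients: np.ndarray, manifest: pd.DataFrame, assign: NetworkAssignment,
    patient_label: str = "MS",
) -> pd.DataFrame:
    """Per-parcel bivariate group test on (G1, G2) across subjects.

    ``gradients`` has shape (n_subjects, P, 2) in manifest row order. The
    Bonferroni family is the parcel count P.
    """
    x = design_matrix(manifest, patient_label).to_numpy()
    t2, pvals = hotelling_batch(np.asarray(gradients, dtype=float), x)
    n_parcels = gradients.shape[1]
    return pd.DataFrame(
        {
            "parcel": np.arange(1, n_parcels + 1),
            "network": assign.labels,
            "T2": t2,
            "p": pvals,
            "p_bonferroni": bonferroni(pvals, n_parcels),
        }
    )


def network_group_tests(
    metrics: list[NetworkMetrics], manifest: pd.DataFrame, patient_label: str = "MS"
) -> pd.DataFrame:
    """Network- and global-level group tests across the four metric families.

    Families and Bonferroni sizes: within-network score (bivariate T^2,
    m = K), within-network dispersion (t, m = K), between-network dispersion
    (t, m = K(K-1)/2), global gradient variation (t, m = 2).
    """
    by_id = {m.subject_id: m for m in metrics}
    ids = [str(s) for s in manifest["subject_id"]]
    missing = [s for s in ids if s not in by_id]
    if missing:
        raise ValueError(f"metrics missing for subjects {missing[:5]}")
    ordered = [by_id[s] for s in ids]
    networks = list(ordered[0].within_score.index)
    x = design_matrix(manifest, patient_label)
    xa = x.to_numpy()
    rows = []

    score_stack = np.stack(
        [m.within_score.loc[networks, ["G1", "G2"]].to_numpy() for m in ordered]
    )  # n x K x 2
    t2, pvals = hotelling_batch(score_stack, xa)
    for i, net in enumerate(networks):
        rows.append(("within_score", net, "T2", t2[i], pvals[i], len(networks), np.nan))

    for net in networks:
        yvals = np.array([m.within_dispersion[net] for m in ordered])
        coef, tstat, pval = univariate_group_test(yvals, x)
        rows.append(("within_dispersion", net, "t", tstat, pval, len(networks), coef))

    pairs = list(combinations(networks, 2))
    for na, nb in pairs:
        yvals = np.array([m.between_dispersion.loc[na, nb] for m in ordered])
        coef, tstat, pval = univariate_group_test(yvals, x)
        rows.append(("between_dispersion", f"{na}-{nb}", "t", tstat, pval, len(pairs), coef))

    for g in (1, 2):
        yvals = np.array([m.global_var[g - 1] for m in ordered])
        coef, tstat, pval = univariate_group_test(yvals, x)
        rows.append(("global_variation", f"G{g}", "t", tstat, pval, 2, coef))

    table = pd.DataFrame(
        rows, columns=["family", "unit", "stat_name", "statistic", "p", "family_size", "group_coef"]
    )
    table["p_bonferroni"] = np.minimum(1.0, table["p"] * table["family_size"])
    return table


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    ci95: tuple[float, float]
    p_bonferroni: float = np.nan


def fisher_ci(rho: float, n: int, ci_inflation: bool = False) -> tuple[float, float]:
    """Fisher-transform 95% confidence interval for a correlation.

    ``tanh(atanh(rho) +/- 1.96 * c / sqrt(n - 3))`` with c = 1 by default or
    c = 1.03 under the rank-variance inflation variant for Spearman's rho.
    """
    c = 1.03 if ci_inflation else 1.0
    halfwidth = 1.96 * c / np.sqrt(n - 3)
    return (
        float(np.tanh(np.arctanh(rho) - halfwidth)),
        float(np.tanh(np.arctanh(rho) + halfwidth)),
    )


def spearman_with_ci(x: np.ndarray, y: np.ndarray, ci_inflation: bool = False) -> CorrelationResult:
    """Spearman correlation with a Fisher-transform 95% CI.

    Missing values are removed pairwise; see :func:`fisher_ci` for the
    interval convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 complete pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in ranks")
    rho, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult(
        rho=float(rho), p=float(p), n=int(n), ci95=fisher_ci(float(rho), n, ci_inflation)
    )


def correlation_screen(
    metrics: list[NetworkMetrics],
    manifest: pd.DataFrame,
    variables: tuple[str, ...] = ("sdmt", "edss", "disease_duration", "lesion_load", "bpf"),
    patient_label: str = "MS",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Spearman screen of within-network scores vs clinical variables.

    Patients only. Features are the K x 2 within-network scores. The
    Bonferroni family defaults to features x variables but is caller-exposed
    because no single convention is canonical. The full table is returned
    regardless of significance.
    """
    by_id = {m.subject_id: m for m in metrics}
    pat = manifest[manifest["group"] == patient_label]
    networks = list(metrics[0].within_score.index)
    feature_rows = {
        f"{net}_G{g}": np.array(
            [by_id[str(s)].within_score.loc[net, f"G{g}"] for s in pat["subject_id"]]
        )
        for g in (1, 2)
        for net in networks
    }
    variables = tuple(v for v in variables if v in pat.columns)
    m = family_size if family_size is not None else len(feature_rows) * len(variables)
    rows = []
    for feat, fvals in feature_rows.items():
        for var in variables:
            vvals = pat[var].to_numpy(dtype=float)
            try:
                res = spearman_with_ci(fvals, vvals)
            except ValueError:
                continue
            rows.append(
                (feat, var, res.rho, res.p, min(1.0, res.p * m), res.n, res.ci95[0], res.ci95[1])
            )
    return pd.DataFrame(
        rows, columns=["feature", "variable", "rho", "p", "p_bonferroni", "n", "ci_low", "ci_high"]
    )


def demographics_table(manifest: pd.DataFrame, patient_label: str = "MS") -> pd.DataFrame:
    """Group-comparison summary: pooled-variance t for continuous variables,
    continuity-corrected chi-squared for sex."""
    groups = list(dict.fromkeys(manifest["group"]))
    if len(groups) != 2:
        raise ValueError("demographics table requires exactly two groups")
    pat_label = patient_label if patient_label in groups else groups[0]
    con_label = next(g for g in groups if g != pat_label)
    pat = manifest[manifest["group"] == pat_label]
    con = manifest[manifest["group"] == con_label]
    rows = []
    for var in ("age", "mean_fd", "bpf", "sdmt", "edss", "disease_duration", "lesion_load"):
        if var not in manifest.columns:
            continue
        a = pat[var].dropna().to_numpy(dtype=float)
        b = con[var].dropna().to_numpy(dtype=float)
        summary_a = f"{a.mean():.3g} ± {a.std(ddof=1):.3g}" if a.size else "N/A"
        summary_b = f"{b.mean():.3g} ± {b.std(ddof=1):.3g}" if b.size else "N/A"
        if a.size > 1 and b.size > 1:
            tstat, pval = scipy.stats.ttest_ind(a, b, equal_var=True)
            rows.append((var, summary_a, summary_b, "t", float(tstat), float(pval)))
        else:
            rows.append((var, summary_a, summary_b, "", np.nan, np.nan))
    sex_levels = list(dict.fromkeys(manifest["sex"].astype(str)))
    counts = np.array(
        [[int((g["sex"].astype(str) == lv).sum()) for lv in sex_levels] for g in (pat, con)]
    )
    if counts.shape == (2, 2) and counts.min() >= 0 and (counts.sum(axis=0) > 0).all():
        chi2, pval = sex_counts_chi2(counts)
        label_a = ":".join(str(c) for c in counts[0])
        label_b = ":".join(str(c) for c in counts[1])
        rows.append((f"sex ({':'.join(sex_levels)})", label_a, label_b, "chi2", chi2, pval))
    return pd.DataFrame(
        rows, columns=["variable", pat_label, con_label, "stat_name", "statistic", "p"]
    )


def sex_counts_chi2(counts: np.ndarray) -> tuple[float, float]:
    """2x2 chi-squared with Yates continuity correction; returns (chi2, p)."""
    counts = np.asarray(counts)
    if np.all(counts == counts[0]):
        return 0.0, 1.0
    chi2, pval, _, _ = scipy.stats.chi2_contingency(counts, correction=True)
    return float(chi2), float(pval)
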