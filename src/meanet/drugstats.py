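"""Dose-response statistics over the 10-parameter burst panel.

Per parameter, each drug concentration is compared against the vehicle
control by one-way ANOVA followed by Dunnett's many-to-one test (the
heat-map statistic). A 5-parameter subset (total spikes, NB duration,
IMFI, CV of NB duration, CV of spikes/NB) feeds a PCA; the first two
component scores per condition are compared pairwise by one-way MANOVA
(Wilks' Λ with its F approximation). A two-tailed paired t-test serves
pre/post designs such as theta-burst stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.multivariate.manova import MANOVA

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .netburst import METRIC_NAMES, BurstMetrics

__all__ = [
    "PCA5_PARAMETERS",
    "build_param_table",
    "anova_dunnett",
    "pca5",
    "PCAResult",
    "manova_pairwise",
    "paired_t",
]

#: The 5-parameter set used for PCA-based drug-effect separation.
PCA5_PARAMETERS = (
    "total_spikes",
    "mean_nb_duration_s",
    "mean_imfi_s",
    "cv_nb_duration",
    "cv_spikes_per_nb",
)

#: Seed for the multivariate-t integration inside Dunnett's test.
DUNNETT_SEED = 20221220


def build_param_table(entries, control: str) -> pd.DataFrame:
    """Tidy table of burst metrics: one row per (sample, condition, concentration).

    ``entries`` is an iterable of ``(sample_id, condition, concentration,
    BurstMetrics-or-dict)``. The designated control condition must appear.
    NaN-flagged metrics (wells without enough NBs) stay NaN and are dropped
    pairwise by the downstream tests.
    """
    rows = []
    seen = set()
    for sample_id, condition, concentration, metrics in entries:
        key = (sample_id, condition, concentration)
        if key in seen:
            raise ValidationError(f"duplicate table row {key}")
        seen.add(key)
        if condition is None or condition == "":
            raise ValidationError("every row needs a condition label")
        md = metrics.to_dict() if isinstance(metrics, BurstMetrics) else dict(metrics)
        rows.append({"sample_id": sample_id, "condition": condition,
                     "concentration": concentration, **{k: md[k] for k in METRIC_NAMES}})
    table = pd.DataFrame(rows)
    if len(table) == 0 or control not in set(table["condition"]):
        raise ValidationError(f"control condition '{control}' missing from the table")
    return table.sort_values(["condition", "concentration", "sample_id"]).reset_index(drop=True)


def _group_values(table: pd.DataFrame, parameter: str):
    if parameter not in table.columns:
        raise ValidationError(f"unknown parameter '{parameter}'")
    out = []
    for (cond, conc), g in table.groupby(["condition", "concentration"], sort=True):
        vals = g[parameter].to_numpy(float)
        n_missing = int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        out.append((cond, conc, vals, n_missing))
    return out


def anova_dunnett(table: pd.DataFrame, parameter: str, control: str) -> pd.DataFrame:
    """One heat-map row: ANOVA F plus Dunnett-adjusted p per concentration.

    The control group pools every row of the control condition. Returns a
    DataFrame with condition, concentration, direction (sign of the mean
    difference vs control), p_adj, and tier ('**' p<0.01, '*' p<0.05, '').
    """
    groups = _group_values(table, parameter)
    control_vals = np.concatenate(
        [v for c, _, v, _ in groups if c == control] or [np.empty(0)])
    tests = [(c, conc, v, m) for c, conc, v, m in groups if c != control]
    if control_vals.size < 2 or not tests:
        raise InsufficientDataError("need a control group (n >= 2) and >= 1 test group")
    for cond, conc, v, _ in tests:
        if v.size < 2:
            raise InsufficientDataError(
                f"group ({cond}, {conc}) has n < 2 non-missing values")
    all_vals = [control_vals] + [v for _, _, v, _ in tests]
    pooled = np.concatenate(all_vals)
    if np.ptp(pooled) == 0:
        f_stat, p_anova = 0.0, 1.0
        p_adj = np.ones(len(tests))
    else:
        f_stat, p_anova = stats.f_oneway(*all_vals)
        res = stats.dunnett(*[v for _, _, v, _ in tests], control=control_vals,
                            rng=DUNNETT_SEED)
        p_adj = np.asarray(res.pvalue)
    rows = []
    cmean = control_vals.mean()
    for (cond, conc, v, n_missing), p in zip(tests, p_adj):
        diff = v.mean() - cmean
        tier = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append({
            "parameter": parameter, "condition": cond, "concentration": conc,
            "direction": int(np.sign(diff)), "p_adj": float(p), "tier": tier,
            "n": int(v.size), "n_missing": n_missing,
            "F": float(f_stat), "p_anova": float(p_anova),
        })
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    """Standardized-loading PCA of the 5-parameter set."""

    loadings: np.ndarray  # (n_components, n_params) orthonormal rows
    scores: np.ndarray  # (n_rows, 2)
    explained_variance_ratio: np.ndarray
    parameters: tuple
    dropped: tuple  # zero-variance columns removed with a warning
    row_index: pd.DataFrame  # sample_id / condition / concentration per score row


def pca5(table: pd.DataFrame, parameters=PCA5_PARAMETERS) -> PCAResult:
    """PCA on z-scored columns (correlation structure); first 2 scores.

    Rows with any missing value in the parameter set are dropped;
    zero-variance columns are dropped with a warning. The sign of each
    component is fixed so its largest-|loading| element is positive.
    """
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise ValidationError(f"table lacks PCA parameters {missing}")
    sub = table.dropna(subset=list(parameters))
    if len(sub) < 3:
        raise InsufficientDataError("PCA needs at least 3 complete rows")
    x = sub[list(parameters)].to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(p for p, k in zip(parameters, keep) if not k)
    if dropped:
        warnings.warn(f"dropping zero-variance columns {dropped}", stacklevel=2)
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 parameters with non-zero variance")
    kept = tuple(p for p, k in zip(parameters, keep) if k)
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(2, z.shape[1], len(sub) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_
    # sign convention: the largest-|loading| entry of each component is positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        parameters=kept,
        dropped=dropped,
        row_index=sub[["sample_id", "condition", "concentration"]].reset_index(drop=True),
    )


def manova_pairwise(scores: np.ndarray, labels) -> pd.DataFrame:
    """Pairwise one-way MANOVA (Wilks' Λ) on 2-D PCA scores.

    Returns a symmetric DataFrame of p-values indexed by group label;
    the diagonal is NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValidationError("scores must be (n, 2)")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g in groups:
        if np.sum(labels == g) < 3:
            raise InsufficientDataError(f"group '{g}' has n < 3")
    p = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            sel = (labels == gi) | (labels == gj)
            df = pd.DataFrame({
                "PC1": scores[sel, 0],
                "PC2": scores[sel, 1],
                "group": labels[sel],
            })
            try:
                mv = MANOVA.from_formula("PC1 + PC2 ~ group", data=df).mv_test()
                stat = mv.results["group"]["stat"]
                pij = float(stat.loc["Wilks' lambda", "Pr > F"])
            except (np.linalg.LinAlgError, ValueError) as err:
                raise DegenerateInputError(
                    f"singular covariance for pair ({gi}, {gj}): {err}") from err
            p.loc[gi, gj] = p.loc[gj, gi] = pij
    return p


def paired_t(pre_values, post_values):
    """Two-tailed paired t-test; returns (t, p, mean difference post - pre).

    Identical paired samples (zero-variance differences, equal means) take
    the convention t = 0, p = 1.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValidationError("paired t-test needs equal-length 1-D samples")
    if pre.size < 2:
        raise InsufficientDataError("paired t-test needs n >= 2 pairs")
    diff = post - pre
    mean_diff = float(diff.mean())
    if np.ptp(diff) == 0:
        if mean_diff == 0:
            return 0.0, 1.0, 0.0
        return float(np.inf * np.sign(mean_diff)), 0.0, mean_diff
    t, p = stats.ttest_rel(post, pre)
    return float(t), float(p), mean_diff
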