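"""Diagnostic model construction from confirmed DMRs.

Marker CpGs are those significant after Bonferroni correction in both
validation cohorts with a concordant direction of change.  Their per-sample
methylation rates, together with clinical covariates (age, sex, APOE e4
allele count), feed elastic-net-penalized logistic regression; every
nonempty DMR subset plus a covariate-only base model is fitted, the penalty
strength is chosen on the same stratified CV folds, models are ranked by
mean CV AUC on the discovery split, and the winner is refit on the full
discovery set and evaluated on the held-out validation split with a DeLong
95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import MethylationCallMatrix
from .validation import CohortValidation

__all__ = [
    "MarkerSet",
    "select_marker_cpgs",
    "marker_feature_matrix",
    "assemble_dataset",
    "split_discovery_validation",
    "ModelResult",
    "search_models",
    "mann_whitney_auc",
    "delong_ci",
    "evaluate_auc",
    "sensitivity_analysis",
]

COVARIATE_COLUMNS = ("age", "sex_male", "apoe_e4")


@dataclass
class MarkerSet:
    """Selected marker CpGs: one row per CpG with its parent DMR and the
    concordant direction of change."""

    sites: pd.DataFrame  # columns: dmr, chrom, pos, direction

    @property
    def dmrs(self) -> list:
        return sorted(self.sites["dmr"].unique())

    def counts(self) -> pd.Series:
        return self.sites.groupby("dmr").size()

    def __len__(self) -> int:
        return len(self.sites)


def select_marker_cpgs(
    cohort2: CohortValidation, cohort3: CohortValidation, alpha: float = 0.05
) -> MarkerSet:
    """Intersect per-CpG validation results of two cohorts.

    A CpG is selected when it is Bonferroni-significant (at ``alpha`` over
    each cohort's own test count) in BOTH cohorts and its delta-beta has the
    same sign in both.  CpGs present in only one cohort are ineligible.
    """
    c2 = cohort2.per_cpg.set_index(["chrom", "pos"])
    c3 = cohort3.per_cpg.set_index(["chrom", "pos"])
    shared = c2.index.intersection(c3.index)
    only = len(c2.index.symmetric_difference(c3.index))
    if only:
        warnings.warn(f"{only} CpGs present in only one cohort are ineligible", stacklevel=2)
    rows = []
    for key in shared:
        r2, r3 = c2.loc[key], c3.loc[key]
        sig2 = r2["p_raw"] <= alpha / r2["m_tests"]
        sig3 = r3["p_raw"] <= alpha / r3["m_tests"]
        concordant = np.sign(r2["delta_beta"]) == np.sign(r3["delta_beta"]) != 0
        if sig2 and sig3 and concordant:
            rows.append(
                {
                    "dmr": r2["dmr"],
                    "chrom": key[0],
                    "pos": key[1],
                    "direction": "hypo" if r2["delta_beta"] < 0 else "hyper",
                }
            )
    sites = pd.DataFrame(rows, columns=["dmr", "chrom", "pos", "direction"])
    sites = sites[sites["dmr"].notna()].sort_values(["dmr", "chrom", "pos"]).reset_index(drop=True)
    return MarkerSet(sites)


def marker_feature_matrix(matrix: MethylationCallMatrix, marker_set: MarkerSet) -> pd.DataFrame:
    """Per-sample methylation rates at marker CpGs (one feature per CpG).

    Column names are ``dmr|chrom:pos``; missing cells are filled with the
    site mean so the model matrix is complete.
    """
    rates = matrix.rates()
    cols = {}
    site_lookup = {(c, p): i for i, (c, p) in enumerate(zip(matrix.chroms, matrix.positions))}
    for _, row in marker_set.sites.iterrows():
        i = site_lookup.get((row["chrom"], row["pos"]))
        if i is None:
            continue
        col = rates[i]
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        cols[f"{row['dmr']}|{row['chrom']}:{row['pos']}"] = col
    return pd.DataFrame(cols, index=matrix.sample_ids)


def assemble_dataset(marker_set: MarkerSet, cohorts) -> tuple[pd.DataFrame, pd.Series]:
    """Stack (matrix, sample_table) pairs into one model dataset.

    Returns ``(X, y)`` where X holds marker-CpG rate features plus the
    clinical covariates in :data:`COVARIATE_COLUMNS` and y is the binary
    AD indicator.
    """
    xs, ys = [], []
    for matrix, samples in cohorts:
        feats = marker_feature_matrix(matrix, marker_set)
        meta = samples.set_index("sample_id").loc[feats.index]
        feats["age"] = meta["age"].astype(float)
        feats["sex_male"] = meta["sex"].astype(str).str.lower().isin(["male", "m", "1"]).astype(float)
        feats["apoe_e4"] = meta["apoe_e4"].astype(float)
        xs.append(feats)
        ys.append((meta["group"] == "AD").astype(int))
    X = pd.concat(xs, axis=0)
    y = pd.concat(ys, axis=0)
    X.index = range(len(X))
    y.index = range(len(y))
    return X, y


def split_discovery_validation(features: pd.DataFrame, labels, fraction: float = 0.8, seed: int = 0):
    """Stratified random split into discovery (``fraction``) and validation."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = pd.Series(np.asarray(labels), index=features.index)
    if labels.nunique() < 2:
        raise ValueError("need both classes present")
    X_disc, X_val, y_disc, y_val = train_test_split(
        features, labels, train_size=fraction, stratify=labels, random_state=seed
    )
    return X_disc, X_val, y_disc.to_numpy(), y_val.to_numpy()


@dataclass
class ModelResult:
    dmrs: tuple
    C: float
    l1_ratio: float
    cv_folds: int
    cv_auc: float
    model: object = field(repr=False, default=None)
    feature_columns: list = field(repr=False, default_factory=list)
    val_auc: float | None = None
    val_ci: tuple | None = None

    @property
    def is_base(self) -> bool:
        return len(self.dmrs) == 0


def _make_estimator(C: float, l1_ratio: float):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=C, max_iter=5000, tol=1e-4),
    )


def _cv_auc(X: np.ndarray, y: np.ndarray, C: float, l1_ratio: float, folds: int, seed: int) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in cv.split(X, y):
        est = _make_estimator(C, l1_ratio).fit(X[train], y[train])
        scores = est.predict_proba(X[test])[:, 1]
        aucs.append(mann_whitney_auc(y[test], scores))
    return float(np.mean(aucs))


def search_models(
    marker_set: MarkerSet,
    X_disc: pd.DataFrame,
    y_disc,
    cv_folds: int = 3,
    penalty_grid=(0.1, 1.0, 10.0, 100.0),
    l1_ratio: float = 0.5,
    seed: int = 0,
    max_exhaustive: int = 20,
) -> list[ModelResult]:
    """Exhaustively rank DMR subsets (plus the covariate-only base model).

    Each candidate model uses the clinical covariates plus the marker CpGs
    of the chosen DMR subset; the penalty strength is selected on the same
    stratified folds; models are ranked by mean CV AUC and each is refit on
    the full discovery set.  Standardization is fitted within training folds
    only (no leakage into held-out folds).
    """
    dmrs = marker_set.dmrs
    if len(dmrs) > max_exhaustive:
        raise ValueError(
            f"{len(dmrs)} DMRs would need {2 ** len(dmrs) - 1} subsets; exhaustive search refused "
            "(consider a greedy search or raise max_exhaustive)"
        )
    y = np.asarray(y_disc, dtype=int)
    covar_cols = [c for c in COVARIATE_COLUMNS if c in X_disc.columns]
    subsets = [()]
    for r in range(1, len(dmrs) + 1):
        subsets.extend(combinations(dmrs, r))
    results = []
    for subset in subsets:
        feat_cols = covar_cols + [
            c for c in X_disc.columns if "|" in c and c.split("|")[0] in subset
        ]
        X = X_disc[feat_cols].to_numpy(dtype=float)
        best = None
        for C in penalty_grid:
            auc = _cv_auc(X, y, C, l1_ratio, cv_folds, seed)
            if best is None or auc > best[1]:
                best = (C, auc)
        model = _make_estimator(best[0], l1_ratio).fit(X, y)
        results.append(
            ModelResult(
                dmrs=tuple(subset),
                C=best[0],
                l1_ratio=l1_ratio,
                cv_folds=cv_folds,
                cv_auc=best[1],
                model=model,
                feature_columns=feat_cols,
            )
        )
    results.sort(key=lambda r: (-r.cv_auc, len(r.dmrs)))
    return results


def mann_whitney_auc(y_true, scores) -> float:
    """AUC as the tie-corrected Mann–Whitney U statistic / (n_pos * n_neg)."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(y_true, scores) -> tuple[float, float]:
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m    # placement of each negative among positives
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def delong_ci(y_true, scores, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong normal-approximation confidence interval."""
    auc, var = _delong_variance(y_true, scores)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def evaluate_auc(model_or_result, X_val, y_val):
    """Held-out AUC with DeLong 95% CI and ROC points.

    Accepts a fitted estimator (with ``predict_proba``) or a
    :class:`ModelResult`; in the latter case features are pulled by column
    name from ``X_val``.  Returns ``(auc, ci_low, ci_high, roc_points)``.
    """
    y = np.asarray(y_val, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("validation set must contain both classes")
    if isinstance(model_or_result, ModelResult):
        X = X_val[model_or_result.feature_columns].to_numpy(dtype=float)
        scores = model_or_result.model.predict_proba(X)[:, 1]
    else:
        X = np.asarray(X_val, dtype=float)
        scores = model_or_result.predict_proba(X)[:, 1]
    auc, lo, hi = delong_ci(y, scores)
    fpr, tpr, _ = roc_curve(y, scores)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    if isinstance(model_or_result, ModelResult):
        model_or_result.val_auc = auc
        model_or_result.val_ci = (lo, hi)
    return auc, lo, hi, roc_points


def sensitivity_analysis(
    marker_set: MarkerSet,
    X_disc: pd.DataFrame,
    y_disc,
    X_val: pd.DataFrame,
    y_val,
    fold_counts=(3, 5, 10),
    penalty_grid=(0.1, 1.0, 10.0, 100.0),
    l1_ratio: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the subset search at several CV fold counts.

    One row per fold count with the selected subset, chosen penalty, CV and
    held-out AUC; ``subset_changed`` flags a winner differing from the first
    fold count's.
    """
    rows = []
    reference = None
    for folds in fold_counts:
        ranked = search_models(
            marker_set, X_disc, y_disc, cv_folds=folds, penalty_grid=penalty_grid, l1_ratio=l1_ratio, seed=seed
        )
        winner = ranked[0]
        auc, lo, hi, _ = evaluate_auc(winner, X_val, y_val)
        if reference is None:
            reference = winner.dmrs
        rows.append(
            {
                "cv_folds": folds,
                "selected_dmrs": "+".join(winner.dmrs) if winner.dmrs else "(base)",
                "C": winner.C,
                "cv_auc": winner.cv_auc,
                "val_auc": auc,
                "val_ci_low": lo,
                "val_ci_high": hi,
                "subset_changed": winner.dmrs != reference,
            }
        )
    return pd.DataFrame(rows)
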