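"""Cohort validation of candidate DMRs.

Given amplicon-style methylation calls restricted to DMR regions in an
independent cohort, this module provides

* per-CpG two-group tests with Bonferroni control over all CpGs analyzed in
  the cohort,
* a DMR-level burden score test adjusted for covariates (sex and age by
  default): the per-sample burden is a weighted sum of CpG methylation
  rates and its association with case status is tested with a 1-df score
  test against the logistic null model ``phenotype ~ intercept + covariates``,
* BH false-discovery-rate q-values across DMRs within a cohort,
* signed Stouffer meta-analysis across cohorts, and
* the confirmation rule chain (enough Bonferroni-significant CpGs, burden
  FDR, meta-analysis significance).

The burden score statistic is Q = U^2 / Var(U) with
``U = sum_i (y_i - mu_i) B_i`` and
``Var = B'VB - B'VX (X'VX)^-1 X'VB`` (V the null binomial variances, X the
null design).  For an intercept-only null, the exact conditional null of U
given ``sum(y)`` is the permutation distribution of the case-burden sum;
when the number of case assignments is enumerable the p-value is computed
exactly from that distribution rather than from the asymptotic chi-square.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import MethylationCallMatrix, group_masks

logger = logging.getLogger(__name__)

__all__ = [
    "per_cpg_test",
    "bonferroni_flag",
    "BurdenResult",
    "burden_test",
    "bh_fdr",
    "MetaResult",
    "meta_analyze",
    "CohortValidation",
    "validate_cohort",
    "confirm_dmrs",
]


# ---------------------------------------------------------------------------
# per-CpG screen
# ---------------------------------------------------------------------------

def per_cpg_test(rates: np.ndarray, groups: np.ndarray, method: str = "welch") -> np.ndarray:
    """Two-sided per-CpG p-values on per-sample methylation rates.

    ``rates`` is (n_cpgs, n_samples) (NaN = missing); ``groups`` is a
    boolean case mask over samples.  Welch's t-test by default; zero
    variance in both groups gives p=1 for equal means and p~0 (degenerate,
    flagged via log) otherwise.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    groups = np.asarray(groups, dtype=bool)
    a = rates[:, ~groups]
    b = rates[:, groups]
    if method != "welch":
        raise ValueError(f"unknown per-CpG test {method!r}")
    if min(a.shape[1], b.shape[1]) < 2:
        raise ValueError("need at least 2 samples per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(b, a, axis=1, equal_var=False, nan_policy="omit").pvalue
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        mean_a = np.nanmean(a[degenerate], axis=1)
        mean_b = np.nanmean(b[degenerate], axis=1)
        fix = np.where(np.isclose(mean_a, mean_b), 1.0, np.nextafter(0, 1))
        logger.warning("per_cpg_test: %d zero-variance CpGs flagged as degenerate", int(degenerate.sum()))
        p[degenerate] = fix
    return p


def bonferroni_flag(p, alpha: float = 0.05, m: int = 1) -> np.ndarray:
    """Bonferroni significance: p <= alpha / m (m = CpGs analyzed in the cohort)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.asarray(p) <= alpha / m


# ---------------------------------------------------------------------------
# burden score test
# ---------------------------------------------------------------------------

@dataclass
class BurdenResult:
    dmr_id: str
    cohort: str
    statistic: float
    p_value: float
    n_cpgs_used: int
    weights: str
    fdr_q: float | None = None
    delta_beta: float | None = None
    n_samples: int | None = None
    exact: bool = False


def _fit_null_logistic(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fitted null probabilities; ridge fallback on separation/failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            mu = np.asarray(fit.mu)
            if np.all((mu > 1e-10) & (mu < 1 - 1e-10)):
                return mu
        except Exception:
            pass
    logger.warning("null logistic fit failed or separated; using penalized (ridge) fit")
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(penalty="l2", C=10.0, fit_intercept=False, max_iter=1000)
    lr.fit(X, y)
    return lr.predict_proba(X)[:, 1]


def _exact_conditional_p(b: np.ndarray, n_cases: int, u_obs: float) -> float:
    """Exact two-sided p of |sum over cases of b| under random case labels.

    ``b`` is the centered burden (sums to 0 over samples).  Enumerates all
    case subsets; the caller guarantees the count is tractable.
    """
    from itertools import chain

    n = len(b)
    tol = 1e-9 * max(1.0, float(np.abs(b).sum()))
    idx = np.fromiter(chain.from_iterable(combinations(range(n), n_cases)), dtype=np.intp)
    sums = b[idx.reshape(-1, n_cases)].sum(axis=1)
    return float(np.mean(np.abs(sums) >= abs(u_obs) - tol))


def burden_test(
    rates,
    phenotype,
    covariates: pd.DataFrame | np.ndarray | None = None,
    weights=None,
    dmr_id: str = "DMR",
    cohort: str = "cohort",
    exact_limit: int = 300_000,
) -> BurdenResult:
    """DMR-level covariate-adjusted burden score test.

    Parameters
    ----------
    rates
        (n_samples, n_cpgs) per-sample methylation rates for the DMR's CpGs.
        NaN cells are averaged out of the burden (row-wise available-case
        weighted sum).
    phenotype
        Binary case indicator (1 = AD).
    covariates
        Null-model covariates (sex, age by default in the pipeline); an
        intercept is always included.  ``None`` fits the intercept-only null.
    weights
        Per-CpG weights; ``None`` (flat), ``"beta"`` (Beta(1,25) density at
        each CpG's mean rate, rare-variant style) or an explicit vector.
        The 1-df statistic is invariant to a positive rescaling.
    """
    R = np.atleast_2d(np.asarray(rates, dtype=float))
    y = np.asarray(phenotype, dtype=float)
    n, n_cpgs = R.shape
    if n_cpgs < 1:
        raise ValueError("need at least one CpG")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if weights is None:
        w = np.ones(n_cpgs)
        wdesc = "flat"
    elif isinstance(weights, str) and weights == "beta":
        mean_rate = np.nanmean(R, axis=0)
        w = stats.beta.pdf(np.clip(mean_rate, 1e-6, 1 - 1e-6), 1, 25)
        wdesc = "beta(1,25)"
    else:
        w = np.asarray(weights, dtype=float)
        wdesc = "custom"
        if w.shape != (n_cpgs,) or (w < 0).any():
            raise ValueError("weights must be a non-negative vector, one per CpG")
    # available-case burden: weighted mean over observed CpGs
    mask = np.isfinite(R)
    wsum = (mask * w).sum(axis=1)
    if (wsum == 0).any():
        raise ValueError("a sample has no observed CpGs in this DMR")
    B = np.nansum(np.where(mask, R, 0.0) * w, axis=1)

    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        C = np.atleast_2d(C.T).T if C.ndim == 1 else C
        X = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    mu = _fit_null_logistic(y, X)
    v = mu * (1.0 - mu)
    U = float(np.sum((y - mu) * B))
    XtVB = X.T @ (v * B)
    XtVX = X.T @ (X * v[:, None])
    var = float((v * B) @ B - XtVB @ np.linalg.solve(XtVX, XtVB))
    if var <= 1e-12 * max(1.0, float(np.abs(B).max()) ** 2):
        return BurdenResult(dmr_id, cohort, 0.0, 1.0, n_cpgs, wdesc, n_samples=n)
    q = U * U / var
    n_cases = int(y.sum())
    if covariates is None and 0 < n_cases < n and comb(n, n_cases) <= exact_limit:
        p = _exact_conditional_p(B - B.mean(), n_cases, float(np.sum((y - y.mean()) * B)))
        exact = True
    else:
        p = float(stats.chi2.sf(q, df=1))
        exact = False
    return BurdenResult(dmr_id, cohort, float(q), max(p, np.nextafter(0, 1)), n_cpgs, wdesc, n_samples=n, exact=exact)


# ---------------------------------------------------------------------------
# FDR and meta-analysis
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MetaResult:
    dmr_id: str
    cohort_p: list
    meta_p: float
    meta_z: float | None
    method: str


def meta_analyze(
    p_values,
    deltas,
    ns,
    dmr_id: str = "DMR",
    method: str = "stouffer",
) -> MetaResult:
    """Combine per-cohort two-sided burden p-values across cohorts.

    Default is the signed Stouffer method: per cohort
    ``z_k = Phi^-1(1 - p_k/2) * sign(delta_k)``, combined as
    ``z = sum(w_k z_k) / sqrt(sum(w_k^2))`` with ``w_k = sqrt(n_k)``, and a
    two-sided meta p.  Evidence in opposite directions cancels.
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(deltas, dtype=float)
    n = np.asarray(ns, dtype=float)
    if not (len(p) == len(d) == len(n)):
        raise ValueError("p_values, deltas and ns must align")
    if len(p) < 2:
        warnings.warn("meta_analyze called with a single cohort; passing through", stacklevel=2)
        return MetaResult(dmr_id, list(p), float(p[0]), None, f"{method}(passthrough)")
    if method != "stouffer":
        raise ValueError(f"unknown meta-analysis method {method!r}")
    p = np.clip(p, 1e-300, 1.0)
    z = stats.norm.isf(p / 2.0) * np.sign(d)
    w = np.sqrt(n)
    meta_z = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    meta_p = float(min(1.0, 2.0 * stats.norm.sf(abs(meta_z))))
    return MetaResult(dmr_id, list(p), max(meta_p, np.nextafter(0, 1)), meta_z, "stouffer")


def pooled_burden(rate_blocks, phenotypes, covariate_blocks, dmr_id: str = "DMR") -> BurdenResult:
    """Alternative meta-analysis: refit the burden test on concatenated
    cohorts with cohort-indicator covariates."""
    R = np.vstack([np.atleast_2d(np.asarray(r, float)) for r in rate_blocks])
    y = np.concatenate([np.asarray(p, float) for p in phenotypes])
    covs = []
    offset = 0
    cohort_dummies = np.zeros((len(y), len(rate_blocks) - 1))
    for k, (r, c) in enumerate(zip(rate_blocks, covariate_blocks)):
        nk = len(np.atleast_2d(np.asarray(r, float)))
        covs.append(np.asarray(c, float))
        if k > 0:
            cohort_dummies[offset : offset + nk, k - 1] = 1.0
        offset += nk
    C = np.vstack(covs)
    X = np.column_stack([C, cohort_dummies])
    return burden_test(R, y, covariates=X, dmr_id=dmr_id, cohort="pooled")


# ---------------------------------------------------------------------------
# cohort orchestration and confirmation
# ---------------------------------------------------------------------------

@dataclass
class CohortValidation:
    """Per-CpG and per-DMR validation results for one cohort."""

    label: str
    per_cpg: pd.DataFrame
    burden: pd.DataFrame
    n_samples: int


def validate_cohort(
    matrix: MethylationCallMatrix,
    samples: pd.DataFrame,
    dmr_regions: pd.DataFrame,
    alpha_bonf: float = 0.05,
    weights=None,
    covariate_names: tuple = ("sex", "age"),
    label: str | None = None,
) -> CohortValidation:
    """Run the per-CpG screen and the burden/FDR stage for one cohort.

    ``dmr_regions`` has 1-based inclusive (chrom, start, end, name) rows.
    The Bonferroni denominator is the total number of CpGs analyzed in the
    cohort.  DMRs with no covered CpGs are reported as untestable (NaN p).
    """
    samples = samples.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    cn, ad = group_masks(samples, matrix.sample_ids)
    label = label or str(samples["cohort"].iloc[0])
    rates = matrix.rates()
    m_tests = matrix.n_sites
    p_raw = per_cpg_test(rates, ad)
    dmr_of_site = np.full(matrix.n_sites, None, dtype=object)
    for _, reg in dmr_regions.iterrows():
        inside = (matrix.chroms == reg["chrom"]) & (matrix.positions >= reg["start"]) & (matrix.positions <= reg["end"])
        dmr_of_site[inside] = str(reg["name"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta_cn = np.nanmean(rates[:, cn], axis=1)
        beta_ad = np.nanmean(rates[:, ad], axis=1)
    per_cpg = pd.DataFrame(
        {
            "chrom": matrix.chroms,
            "pos": matrix.positions,
            "dmr": dmr_of_site,
            "beta_cn": beta_cn,
            "beta_ad": beta_ad,
            "delta_beta": beta_ad - beta_cn,
            "p_raw": p_raw,
            "significant_bonferroni": bonferroni_flag(p_raw, alpha_bonf, m_tests),
            "m_tests": m_tests,
        }
    )

    cov = np.column_stack(
        [
            (samples["sex"].astype(str).str.lower().isin(["male", "m", "1"])).to_numpy(dtype=float),
            samples["age"].to_numpy(dtype=float),
        ]
    ) if covariate_names else None
    y = ad.astype(float)
    rows = []
    for _, reg in dmr_regions.iterrows():
        name = str(reg["name"])
        in_dmr = dmr_of_site == name
        if not in_dmr.any():
            logger.warning("DMR %s has no covered CpGs in cohort %s; untestable", name, label)
            rows.append({"dmr": name, "statistic": np.nan, "p_value": np.nan, "n_cpgs_used": 0, "delta_beta": np.nan})
            continue
        res = burden_test(rates[in_dmr].T, y, covariates=cov, weights=weights, dmr_id=name, cohort=label)
        rows.append(
            {
                "dmr": name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_cpgs_used": res.n_cpgs_used,
                "delta_beta": float(per_cpg.loc[in_dmr, "delta_beta"].mean()),
            }
        )
    burden = pd.DataFrame(rows)
    testable = burden["p_value"].notna()
    burden["fdr_q"] = np.nan
    if testable.any():
        burden.loc[testable, "fdr_q"] = bh_fdr(burden.loc[testable, "p_value"].to_numpy())
    return CohortValidation(label=label, per_cpg=per_cpg, burden=burden, n_samples=matrix.n_samples)


def confirm_dmrs(
    cohort2: CohortValidation,
    cohort3: CohortValidation,
    min_sig_cpgs: int = 3,
    fdr_alpha: float = 0.05,
    meta_alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the confirmation rule chain to two validation cohorts.

    A DMR is confirmed when (1) at least ``min_sig_cpgs`` of its CpGs pass
    per-CpG Bonferroni in cohort 2, (2) its burden FDR q < ``fdr_alpha`` in
    cohort 2, and (3) its cross-cohort meta-analysis p < ``meta_alpha``.
    """
    sig_counts = (
        cohort2.per_cpg[cohort2.per_cpg["significant_bonferroni"]]
        .groupby("dmr")
        .size()
        .to_dict()
    )
    b2 = cohort2.burden.set_index("dmr")
    b3 = cohort3.burden.set_index("dmr")
    rows = []
    for dmr in b2.index:
        if dmr not in b3.index or not np.isfinite(b3.loc[dmr, "p_value"]):
            warnings.warn(f"DMR {dmr} absent or untestable in cohort {cohort3.label}; excluded", stacklevel=2)
            continue
        if not np.isfinite(b2.loc[dmr, "p_value"]):
            warnings.warn(f"DMR {dmr} untestable in cohort {cohort2.label}; excluded", stacklevel=2)
            continue
        n_sig = int(sig_counts.get(dmr, 0))
        eligible = n_sig >= min_sig_cpgs
        q2 = float(b2.loc[dmr, "fdr_q"])
        burden_ok = q2 < fdr_alpha
        meta = meta_analyze(
            [b2.loc[dmr, "p_value"], b3.loc[dmr, "p_value"]],
            [b2.loc[dmr, "delta_beta"], b3.loc[dmr, "delta_beta"]],
            [cohort2.n_samples, cohort3.n_samples],
            dmr_id=str(dmr),
        )
        rows.append(
            {
                "dmr": dmr,
                "n_sig_cpgs_cohort2": n_sig,
                "eligible": eligible,
                "p_cohort2": float(b2.loc[dmr, "p_value"]),
                "fdr_q_cohort2": q2,
                "p_cohort3": float(b3.loc[dmr, "p_value"]),
                "meta_p": meta.meta_p,
                "confirmed": bool(eligible and burden_ok and meta.meta_p < meta_alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dmr",
            "n_sig_cpgs_cohort2",
            "eligible",
            "p_cohort2",
            "fdr_q_cohort2",
            "p_cohort3",
            "meta_p",
            "confirmed",
        ],
    )
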