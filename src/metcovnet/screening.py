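"""Region screens (two-group t-tests) and biomarker partial correlations.

The region screen compares corrected SUVRs between a disease and a control
group per region, choosing a pooled-variance Student t-test or a Welch
(Satterthwaite) t-test via a two-sided F screen on the group variances.
The biomarker screen computes covariate-adjusted (age, sex, BMI) partial
correlations between each flagged region's SUVR and each biomarker,
handling missingness complete-case per (region, biomarker) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SubjectRecord, SUVRTable

__all__ = [
    "RegionTestResult",
    "PartialCorrResult",
    "two_group_test",
    "screen_regions",
    "partial_correlation",
    "partial_correlation_precision",
    "screen_biomarkers",
]

log = logging.getLogger(__name__)


@dataclass
class RegionTestResult:
    region_id: int
    region_name: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    test_used: str  # "student" | "welch"
    direction: int  # sign(mean_a - mean_b), a = disease by convention
    significant: bool = False


@dataclass
class PartialCorrResult:
    region_id: int
    region_name: str
    variable: str
    n: int
    k: int
    r_partial: float
    t: float
    df: int
    p: float
    significant: bool = False


def two_group_test(
    values_a: np.ndarray, values_b: np.ndarray, variance_rule: str = "auto"
) -> tuple[float, float, float, str]:
    """Two-tailed two-sample t-test with automatic Student/Welch choice.

    ``variance_rule``: ``auto`` (two-sided F screen at alpha = 0.05 decides),
    ``student`` (always pooled), or ``welch`` (always Satterthwaite).

    Returns ``(t, df, p, test_used)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 values (got {na} and {nb})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0, "student"
        raise ValueError("zero variance in both groups with unequal means")

    if variance_rule == "auto":
        if va == 0 or vb == 0:
            use_welch = True
        else:
            f = va / vb
            p_f = 2 * min(
                stats.f.cdf(f, na - 1, nb - 1), stats.f.sf(f, na - 1, nb - 1)
            )
            use_welch = p_f < 0.05
    elif variance_rule == "student":
        use_welch = False
    elif variance_rule == "welch":
        use_welch = True
    else:
        raise ValueError(f"unknown variance_rule {variance_rule!r}")

    if use_welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        mode = "welch"
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        df = float(na + nb - 2)
        mode = "student"
    return float(t), float(df), float(p), mode


def screen_regions(
    disease: SUVRTable,
    control: SUVRTable,
    alpha: float = 0.05,
    variance_rule: str = "auto",
    multiple_testing: str | None = None,
) -> list[RegionTestResult]:
    """Per-region disease-vs-control t-tests on (corrected) SUVRs.

    A region is flagged when ``p < alpha``. No multiple-testing correction
    is applied by default (exploratory screen); ``multiple_testing="bh"``
    switches the flagging to Benjamini-Hochberg adjusted p-values.
    """
    if disease.atlas.analysis_ids != control.atlas.analysis_ids:
        raise ValueError("disease and control tables use different atlases")
    results = []
    for j, region in enumerate(disease.atlas.analysis_regions):
        a = disease.values[:, j]
        b = control.values[:, j]
        t, df, p, mode = two_group_test(a, b, variance_rule)
        results.append(
            RegionTestResult(
                region_id=region.id,
                region_name=region.name,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                sd_a=float(a.std(ddof=1)),
                sd_b=float(b.std(ddof=1)),
                t=t,
                df=df,
                p=p,
                test_used=mode,
                direction=int(np.sign(a.mean() - b.mean())),
            )
        )
    pvals = np.array([r.p for r in results])
    if multiple_testing == "bh":
        from statsmodels.stats.multitest import multipletests  # lazy, optional path

        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    elif multiple_testing is None:
        reject = pvals < alpha
    else:
        raise ValueError(f"unknown multiple_testing mode {multiple_testing!r}")
    for r, rej in zip(results, reject):
        r.significant = bool(rej)
    return results


def _residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int, float]:
    """Partial correlation of x and y given covariates, with t-test.

    Both variables are residualized on the covariates (with intercept) by
    least squares; the partial r is the Pearson correlation of the
    residuals, tested with ``t = r * sqrt(df / (1 - r^2))`` on
    ``df = n - 2 - k``. With no covariates this reduces to the plain
    Pearson correlation.

    Returns ``(r_partial, t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    C = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if C.shape[0] != n:
        C = C.T
    k = C.shape[1]
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 complete cases (n={n}, k={k})")
    X = np.column_stack([np.ones(n), C])
    rx = _residualize(x, X)
    ry = _residualize(y, X)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant variable after residualization; correlation undefined")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, np.inf if r > 0 else -np.inf, df, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, float(t), df, p


def partial_correlation_precision(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Partial correlation via the inverse covariance (precision) matrix.

    Independent formulation used for cross-validation of the residual
    method: for the joint covariance of (x, y, covariates), the partial
    correlation is ``-P_xy / sqrt(P_xx * P_yy)`` with P the precision
    matrix.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        z = np.column_stack([x, y])
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != x.size:
            C = C.T
        z = np.column_stack([x, y, C])
    P = np.linalg.inv(np.cov(z, rowvar=False))
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def screen_biomarkers(
    suvr: SUVRTable,
    records: list[SubjectRecord],
    region_ids: list[int],
    biomarkers: list[str],
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    alpha: float = 0.05,
) -> list[PartialCorrResult]:
    """Covariate-adjusted partial correlations for (region, biomarker) pairs.

    Subjects missing the biomarker or any covariate are dropped per pair
    (complete-case), so n varies across pairs. Pairs with too few complete
    cases are skipped with a warning.
    """
    by_id = {r.subject_id: r for r in records}
    recs = [by_id[s] for s in suvr.subject_ids]
    id_to_col = {rid: j for j, rid in enumerate(suvr.atlas.analysis_ids)}
    name_of = {r.id: r.name for r in suvr.atlas.analysis_regions}
    unknown = [rid for rid in region_ids if rid not in id_to_col]
    if unknown:
        raise ValueError(f"region ids not in atlas: {unknown}")
    k = len(covariates)

    def _cov(rec: SubjectRecord, name: str) -> float:
        v = getattr(rec, name)
        return np.nan if v is None else float(v)

    results = []
    for rid in region_ids:
        col = suvr.values[:, id_to_col[rid]]
        for bm in biomarkers:
            bmv = np.array([r.biomarkers.get(bm, np.nan) for r in recs])
            C = np.column_stack([[_cov(r, c) for r in recs] for c in covariates]) if k else np.empty((len(recs), 0))
            keep = np.isfinite(bmv) & np.all(np.isfinite(C), axis=1) & np.isfinite(col)
            n = int(keep.sum())
            if n < k + 3:
                log.warning(
                    "skipping region %s x %s: only %d complete cases (need >= %d)",
                    rid, bm, n, k + 3,
                )
                continue
            r, t, df, p = partial_correlation(col[keep], bmv[keep], C[keep] if k else None)
            results.append(
                PartialCorrResult(
                    region_id=rid,
                    region_name=name_of[rid],
                    variable=bm,
                    n=n,
                    k=k,
                    r_partial=r,
                    t=t,
                    df=df,
                    p=p,
                    significant=bool(p < alpha),
                )
            )
    return results


def results_to_frame(results: list) -> pd.DataFrame:
    """Tidy DataFrame view of a list of result dataclasses."""
    return pd.DataFrame([vars(r) for r in results])
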