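"""Cohort-level statistics for embryo segregation outcomes.

Works on a flat embryo-level table (one row per diagnosed blastocyst with
its carrier's covariates and inferred mode) and reproduces the standard
battery for this design: mode tabulation, stratified 2x2 odds ratios with
the Cochran-Mantel-Haenszel common OR and Breslow-Day homogeneity test,
univariate screening followed by a multivariable random-intercept logistic
model (alternate vs unbalanced), per-mode contrasts vs alternate, and ROC
evaluation of the fitted fixed effects.

Sizes and segment lengths enter the regressions in megabases; ratios
(TAR/TSR/CSR) are dimensionless. No multiple-testing correction is applied
(the number of tests performed is reported instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.contingency_tables import StratifiedTable

from .glmm import GLMMError, GLMMFit, fit_random_intercept_logit

MODE_ORDER = ("alternate", "adjacent-1", "adjacent-2", "3:1", "4:0/other")

#: Covariates screened univariately, in reporting order. Sizes/segments are
#: rescaled to Mb before fitting.
DEFAULT_CANDIDATES = (
    "sex", "age", "size1", "size2", "ts1", "ts2", "cs1", "cs2",
    "tsr", "csr", "tar1", "tar2", "acr_involved",
)
_MB_SCALED = {"size1", "size2", "ts1", "ts2", "cs1", "cs2"}


class CohortError(ValueError):
    """Empty or malformed cohort table."""


# ---------------------------------------------------------------------------
# mode tabulation


def pool_modes(mode: pd.Series) -> pd.Series:
    """Pool 4:0 and ND into the reporting category "4:0/other"."""
    return mode.replace({"4:0": "4:0/other", "ND": "4:0/other"})


def tabulate_modes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per segregation mode, plus the 2:2 aggregate.

    Percentages are over all diagnosed embryos; 2:2 = alternate +
    adjacent-1 + adjacent-2.
    """
    if cohort.empty:
        raise CohortError("empty cohort")
    modes = pool_modes(cohort["mode"])
    n = len(modes)
    counts = modes.value_counts()
    rows = []
    for m in MODE_ORDER:
        c = int(counts.get(m, 0))
        rows.append({"mode": m, "count": c, "percent": 100.0 * c / n})
    two_two = sum(r["count"] for r in rows[:3])
    rows.append({"mode": "2:2", "count": two_two, "percent": 100.0 * two_two / n})
    rows.append({"mode": "total", "count": n, "percent": 100.0})
    return pd.DataFrame(rows).set_index("mode")


# ---------------------------------------------------------------------------
# 2x2 tables


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (a, b) exposed event/non-event, (c, d) unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def exposed_event_pct(self) -> float:
        """Event percentage among the exposed, a / (a + b) * 100."""
        return 100.0 * self.a / (self.a + self.b)

    @property
    def unexposed_event_pct(self) -> float:
        return 100.0 * self.c / (self.c + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")


class UndefinedOddsRatio(ValueError):
    """Both cells of one margin are zero; the OR has no information."""


def odds_ratio(t: TwoByTwo) -> ORResult:
    """OR = ad/bc with Woolf log-normal 95% CI and chi-square p.

    A single zero cell triggers the Haldane-Anscombe 0.5 continuity
    correction (applied to all cells); two zero cells in one margin make
    the OR undefined.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    margins_zero = (
        (a == 0 and b == 0) or (c == 0 and d == 0)
        or (a == 0 and c == 0) or (b == 0 and d == 0)
    )
    if margins_zero:
        raise UndefinedOddsRatio(f"degenerate margin in table {t}")
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    chi2, p, _, _ = sps.chi2_contingency(t.as_array(), correction=False)
    return ORResult(
        or_point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - 1.959964 * se)),
        ci_high=float(np.exp(log_or + 1.959964 * se)),
        p_value=float(p),
    )


@dataclass(frozen=True)
class CMHResult:
    common_or: float
    chi2: float
    p_value: float
    homogeneity_p: float
    per_stratum_or: tuple[float, ...]


def cmh_analysis(
    strata: list[TwoByTwo], *, tarone: bool = False
) -> CMHResult:
    """Mantel-Haenszel common OR, CMH chi-square test and Breslow-Day
    homogeneity p across 2x2 strata.

    No continuity correction on the CMH statistic; ``tarone=True`` applies
    the Tarone adjustment to the Breslow-Day statistic. A single stratum
    degenerates to the plain OR (homogeneity p = 1 by convention).
    """
    if not strata:
        raise ValueError("no strata")
    per_or = []
    for t in strata:
        try:
            per_or.append(odds_ratio(t).or_point)
        except UndefinedOddsRatio:
            per_or.append(float("nan"))
    if len(strata) == 1:
        r = odds_ratio(strata[0])
        return CMHResult(r.or_point, float("nan"), r.p_value, 1.0, tuple(per_or))
    tables = [t.as_array() for t in strata]
    st = StratifiedTable(tables)
    null_test = st.test_null_odds(correction=False)
    return CMHResult(
        common_or=float(st.oddsratio_pooled),
        chi2=float(null_test.statistic),
        p_value=float(null_test.pvalue),
        homogeneity_p=_breslow_day(strata, float(st.oddsratio_pooled), tarone),
        per_stratum_or=tuple(per_or),
    )


def _breslow_day(strata: list[TwoByTwo], psi: float, tarone: bool) -> float:
    """Breslow-Day homogeneity statistic against the MH common OR ``psi``.

    Solves each stratum's expected a-cell under psi (linear case at psi=1,
    else the admissible quadratic root); chi-square with K-1 df.
    """
    stat = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    for t in strata:
        n = t.total
        r1, c1 = t.a + t.b, t.a + t.c
        if psi == 1.0:
            e = r1 * c1 / n
        else:
            qa = 1.0 - psi
            qb = (n - r1 - c1) + psi * (r1 + c1)
            qc = -psi * r1 * c1
            disc = np.sqrt(qb * qb - 4 * qa * qc)
            roots = [(-qb + disc) / (2 * qa), (-qb - disc) / (2 * qa)]
            valid = [
                e for e in roots
                if 0 < e < min(r1, c1) + 1e-9 and n - r1 - c1 + e > -1e-9
            ]
            if not valid:  # pragma: no cover - degenerate stratum
                continue
            e = valid[0]
        others = (r1 - e, c1 - e, n - r1 - c1 + e)
        if e <= 0 or any(o <= 0 for o in others):
            continue
        v = 1.0 / (1 / e + sum(1 / o for o in others))
        stat += (t.a - e) ** 2 / v
        resid_sum += t.a - e
        var_sum += v
    if tarone and var_sum > 0:
        stat -= resid_sum**2 / var_sum
    return float(sps.chi2.sf(stat, len(strata) - 1))


# ---------------------------------------------------------------------------
# GLMM battery


def _validate_cohort(cohort: pd.DataFrame, needed: set[str]) -> None:
    if cohort.empty:
        raise CohortError("empty cohort")
    if missing := needed - set(cohort.columns):
        raise CohortError(f"cohort table missing columns: {sorted(missing)}")


def _design(cohort: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for c in covariates:
        if c == "sex":
            x = (cohort["sex"].astype(str).str.lower() == "female").to_numpy(float)
            names.append("sex_female")
        elif c == "acr_involved":
            x = cohort["acr_involved"].astype(bool).to_numpy(float)
            names.append("acr_involved")
        else:
            x = cohort[c].to_numpy(float)
            if c in _MB_SCALED:
                x = x / 1e6
            names.append(c)
        cols.append(x)
    return np.column_stack(cols), names


def fit_binary_glmm(
    cohort: pd.DataFrame,
    covariates: list[str],
    *,
    outcome: str = "unbalanced",
) -> GLMMFit:
    """Random-intercept-per-carrier logistic fit of unbalanced (non-
    alternate) vs alternate segregation on carrier covariates.

    ORs are exponentiated coefficients: OR > 1 means the covariate raises
    the odds that an embryo is a non-alternate (unbalanced) product.
    """
    _validate_cohort(cohort, {"carrier_id", "mode"} | _needed_cols(covariates))
    if cohort["carrier_id"].nunique() < 2:
        raise CohortError("need at least 2 carriers")
    y = (cohort["mode"] != "alternate").to_numpy(int)
    X, names = _design(cohort, covariates)
    return fit_random_intercept_logit(
        X, y, cohort["carrier_id"].to_numpy(), names, outcome=outcome
    )


def _needed_cols(covariates: list[str]) -> set[str]:
    return {c if c != "sex_female" else "sex" for c in covariates}


def select_covariates(
    cohort: pd.DataFrame,
    candidates: list[str] | tuple[str, ...] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, GLMMFit | Exception]]:
    """Univariate random-intercept screen: keep candidates with p < alpha.

    Returns the selected names (input order preserved) and the per-
    candidate fits; a candidate whose fit fails is recorded with its
    exception and excluded, without aborting the scan.
    """
    selected: list[str] = []
    fits: dict[str, GLMMFit | Exception] = {}
    for cand in candidates:
        try:
            fit = fit_binary_glmm(cohort, [cand])
        except (GLMMError, CohortError, KeyError) as exc:
            fits[cand] = exc
            continue
        fits[cand] = fit
        term = fit.terms[1]
        if fit.p_value(term) < alpha:
            selected.append(cand)
    return selected, fits


def fit_multinomial_glmm(
    cohort: pd.DataFrame,
    covariates_by_contrast: dict[str, list[str]] | None = None,
    *,
    covariates: list[str] | None = None,
    min_events: int = 10,
) -> dict[str, GLMMFit]:
    """Per-mode contrasts vs alternate, each a binary random-intercept fit.

    The multinomial outcome is decomposed into independent two-category
    contrasts (adjacent-1, adjacent-2, 3:1, 4:0/other, each vs alternate)
    fitted on the corresponding row subsets — for a multinomial logit with
    a shared random intercept, each conditional two-category model is
    exactly the binary model with that contrast's coefficients, so the
    decomposition is a documented approximation only through the
    independence of the refitted intercept variances. Contrasts with fewer
    than ``min_events`` embryos are skipped.
    """
    _validate_cohort(cohort, {"carrier_id", "mode"})
    modes = pool_modes(cohort["mode"])
    if covariates_by_contrast is None:
        covariates_by_contrast = {
            m: list(covariates or []) for m in MODE_ORDER[1:]
        }
    out: dict[str, GLMMFit] = {}
    for contrast, covs in covariates_by_contrast.items():
        sub = cohort[(modes == "alternate") | (modes == contrast)]
        n_events = int((pool_modes(sub["mode"]) == contrast).sum())
        if n_events < min_events or n_events == len(sub):
            continue
        sub = sub.copy()
        sub["mode"] = np.where(pool_modes(sub["mode"]) == contrast, "x", "alternate")
        try:
            out[contrast] = fit_binary_glmm(
                sub, covs, outcome=f"{contrast} vs alternate"
            )
        except (GLMMError, CohortError):
            continue
    return out


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class ROCResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float


def roc_evaluate(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """AUC by the rank (Mann-Whitney) statistic plus sensitivity and
    specificity at the Youden-optimal threshold."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    n1, n0 = int(labels.sum()), int((1 - labels).sum())
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    j = int(np.argmax(tpr - fpr))
    return ROCResult(
        auc=float(auc),
        sensitivity=float(tpr[j]),
        specificity=float(1 - fpr[j]),
        threshold=float(thr[j]),
    )


def glmm_scores(fit: GLMMFit, cohort: pd.DataFrame) -> np.ndarray:
    """Fixed-effects linear predictor of a fitted model on a cohort table."""
    covs = [t for t in fit.terms if t != "intercept"]
    covs = ["sex" if t == "sex_female" else t for t in covs]
    X, _ = _design(cohort, covs)
    return X @ fit.coefficients["coef"].to_numpy()


# ---------------------------------------------------------------------------
# report driver


def stratified_sex_acr_tables(cohort: pd.DataFrame) -> dict[str, list[TwoByTwo]]:
    """The two stratifications of the unbalanced outcome: sex as exposure
    within Acr-ch strata, and Acr-ch as exposure within sex strata."""
    _validate_cohort(cohort, {"mode", "sex", "acr_involved"})
    unb = (cohort["mode"] != "alternate").to_numpy()
    female = cohort["sex"].astype(str).str.lower().eq("female").to_numpy()
    acr = cohort["acr_involved"].astype(bool).to_numpy()

    def table(expo: np.ndarray, mask: np.ndarray) -> TwoByTwo:
        return TwoByTwo(
            a=int((mask & expo & unb).sum()),
            b=int((mask & expo & ~unb).sum()),
            c=int((mask & ~expo & unb).sum()),
            d=int((mask & ~expo & ~unb).sum()),
        )

    return {
        "sex_within_acr": [table(female, acr), table(female, ~acr)],
        "acr_within_sex": [table(acr, female), table(acr, ~female)],
    }


def analyze_cohort(
    cohort: pd.DataFrame,
    candidates: list[str] | tuple[str, ...] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
) -> dict:
    """Run the full battery on an embryo-level cohort table.

    Returns a dict with the mode table, univariate screen, multivariable
    binary fit, stratified ORs with CMH, per-mode contrasts (using the
    multivariable covariate set) and the ROC summary of the binary fit.
    """
    _validate_cohort(cohort, {"carrier_id", "mode", "sex", "acr_involved"})
    mode_table = tabulate_modes(cohort)
    selected, uni_fits = select_covariates(cohort, candidates, alpha)
    multi = fit_binary_glmm(cohort, selected) if selected else None
    strata = stratified_sex_acr_tables(cohort)
    cmh = {name: cmh_analysis(tabs) for name, tabs in strata.items()}
    stratum_ors = {
        name: [odds_ratio(t) for t in tabs] for name, tabs in strata.items()
    }
    contrasts = fit_multinomial_glmm(cohort, covariates=selected)
    roc = None
    if multi is not None and multi.converged:
        scores = glmm_scores(multi, cohort)
        roc = roc_evaluate(scores, (cohort["mode"] != "alternate").to_numpy(int))
    n_tests = len(uni_fits) + sum(len(t) for t in strata.values())
    return {
        "mode_table": mode_table,
        "univariate": uni_fits,
        "selected": selected,
        "multivariable": multi,
        "strata": strata,
        "stratum_ors": stratum_ors,
        "cmh": cmh,
        "contrasts": contrasts,
        "roc": roc,
        "n_tests_uncorrected": n_tests,
    }
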