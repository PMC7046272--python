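"""Cohort-level treatment-response statistics.

Implements the statistical toolkit used to relate early MRI/serological
changes to eventual response (responder = CR/VGPR, non-responder =
PR/SD/PD):

* percentage change between baseline and follow-up;
* Wilcoxon signed-rank test with exact enumeration for small samples;
* ROC analysis — Mann–Whitney AUC with tie correction, Hanley–McNeil
  (or DeLong) standard error, and a Youden-maximizing cutoff;
* sensitivity/specificity from confusion counts;
* a logistic response model (binomial GLM with logit link, fitted by
  IRLS via statsmodels) with odds ratios and Wald intervals;
* linear-weighted Cohen's kappa for ordinal rater agreement;
* :func:`cohort_report`, which assembles the per-variable group summary,
  ROC table and multivariable model for a cohort table.

No multiple-testing correction is applied anywhere; reports note this.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "RocResult",
    "GlmResult",
    "CohortReport",
    "percentage_change",
    "wilcoxon_signed_rank",
    "roc_analysis",
    "confusion_stats",
    "confusion_from_counts",
    "fit_logistic",
    "weighted_kappa",
    "cohort_report",
    "DEFAULT_DIRECTIONS",
]

logger = logging.getLogger(__name__)

#: which direction of percentage change points toward response
DEFAULT_DIRECTIONS: dict[str, str] = {
    "m_protein": "lower",
    "b2_microglobulin": "lower",
    "tdv": "lower",
    "hemoglobin": "higher",
    "mean_adc": "higher",
    "ff": "higher",
}


def percentage_change(baseline, followup):
    """100 * (followup - baseline) / baseline, elementwise.

    Zero baselines are undefined: they yield NaN and are counted in a
    logged warning rather than raising.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    zero = baseline == 0
    n_zero = int(np.count_nonzero(zero))
    if n_zero:
        logger.warning("percentage_change: %d zero baselines excluded", n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (followup - baseline) / baseline
    pct = np.where(zero, np.nan, pct)
    return float(pct) if pct.ndim == 0 else pct


def _signed_rank_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p for the signed-rank statistic.

    `ranks2` are the doubled ranks (integers even with midranks); the
    null distribution of the doubled positive-rank sum is built by
    subset-sum dynamic programming over all 2^n equiprobable sign
    assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(baseline, followup=None, exact_max_n: int = 25):
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped.  For n <= `exact_max_n` remaining pairs
    the p-value is exact (enumeration of all 2^n sign assignments, via
    subset-sum DP, valid also with midranks); larger samples use the
    normal approximation with tie correction.  Returns
    ``(W_plus, p_value)``.
    """
    baseline = np.asarray(baseline, dtype=float)
    if followup is None:
        d = baseline
    else:
        d = np.asarray(followup, dtype=float) - baseline
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(np.rint(2 * w))
        p = _signed_rank_exact_p(ranks2, w2)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w, p


@dataclass
class RocResult:
    """ROC summary: AUC with SE/CI, and the Youden-optimal cutoff.

    ``direction`` records whether higher or lower scores point toward the
    positive class; the cutoff is on the original score scale, and a
    positive call is ``score > cutoff`` ('higher') or ``score < cutoff``
    ('lower').  The CI is AUC +- 1.96 SE, untruncated; ``ci_clipped``
    restricts it to [0, 1].
    """

    auc: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    direction: str
    n_positive: int
    n_negative: int

    @property
    def ci_clipped(self) -> tuple[float, float]:
        return (max(0.0, self.ci_low), min(1.0, self.ci_high))


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """Concordance AUC with tie correction, via midranks."""
    allv = np.concatenate([pos, neg])
    ranks = sps.rankdata(allv)
    n1, n0 = pos.size, neg.size
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    # structural components: V10 for cases, V01 for controls
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size
                    for p in pos])
    v01 = np.array([(np.sum(pos > c) + 0.5 * np.sum(pos == c)) / pos.size
                    for c in neg])
    var = (np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)
    return float(np.sqrt(var))


def roc_analysis(
    scores,
    labels,
    direction: str = "higher",
    se_method: str = "hanley",
) -> RocResult:
    """ROC analysis of a continuous score against a binary label.

    AUC is the Mann–Whitney concordance estimator (ties get half
    credit).  The cutoff maximizes Youden's J = sensitivity +
    specificity - 1 over midpoints between consecutive distinct scores;
    ties in J break toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if labels.all() or (~labels).all():
        raise ValueError("roc_analysis needs both classes present")

    s = scores if direction == "higher" else -scores
    pos, neg = s[labels], s[~labels]
    auc = _auc_mann_whitney(pos, neg)
    n1, n0 = pos.size, neg.size
    se = (_delong_se(pos, neg, auc) if se_method == "delong"
          else _hanley_mcneil_se(auc, n1, n0))

    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best = None  # (J, specificity, cutoff, sens, spec)
    for c in cands:
        sens = np.mean(pos > c)
        spec = np.mean(neg <= c)
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > (best[0], best[1]):
            best = (j, spec, c, sens, spec)
    _, _, cut, sens, spec = best
    cutoff = cut if direction == "higher" else -cut
    return RocResult(
        auc=auc,
        se=se,
        ci_low=auc - 1.96 * se,
        ci_high=auc + 1.96 * se,
        cutoff=float(cutoff),
        sensitivity=float(100.0 * sens),
        specificity=float(100.0 * spec),
        direction=direction,
        n_positive=int(n1),
        n_negative=int(n0),
    )


def confusion_from_counts(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity/specificity (percent) from raw confusion counts."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    return {
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def confusion_stats(labels, predicted_positive) -> dict:
    """Sensitivity/specificity of binary predictions against truth."""
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(predicted_positive).astype(bool)
    if labels.size == 0 or labels.shape != pred.shape:
        raise ValueError("labels and predictions must be nonempty and aligned")
    tp = int(np.sum(labels & pred))
    fn = int(np.sum(labels & ~pred))
    tn = int(np.sum(~labels & ~pred))
    fp = int(np.sum(~labels & pred))
    return confusion_from_counts(tp, fn, tn, fp)


@dataclass
class GlmResult:
    """Logistic (binomial GLM, logit link) fit summary.

    ``table`` has one row per predictor: beta, se, odds ratio
    (= exp(beta)), Wald 95% CI on the OR scale, and p.  ``separated``
    flags (quasi-)complete separation — coefficients are then unreliable
    and reported with the flag rather than hidden.
    """

    table: pd.DataFrame
    converged: bool
    separated: bool
    n: int
    llf: float = float("nan")

    def odds_ratio(self, name: str) -> float:
        return float(self.table.loc[name, "odds_ratio"])


def fit_logistic(
    design_matrix,
    binary_outcome,
    feature_names: Sequence[str] | None = None,
    add_intercept: bool = True,
) -> GlmResult:
    """Maximum-likelihood logistic regression via IRLS.

    Wald standard errors and p-values; odds ratios and 95% CIs as
    exp(beta +- 1.96 se).  Separation and non-convergence are flagged on
    the result, never silently ignored and never raised.
    """
    if isinstance(design_matrix, pd.DataFrame):
        X = design_matrix.to_numpy(dtype=float)
        names = list(design_matrix.columns)
    else:
        X = np.asarray(design_matrix, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = (list(feature_names) if feature_names is not None
                 else [f"x{i}" for i in range(X.shape[1])])
    y = np.asarray(binary_outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names

    converged, separated = True, False
    try:
        # separation is detected and flagged below; statsmodels' own
        # warnings about it are redundant here
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            converged = bool(res.converged)
            params, bse, pvals = res.params, res.bse, res.pvalues
            llf = float(res.llf)
            mu = res.fittedvalues
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10) or np.any(bse > 1e3):
            separated = True
    except Exception as exc:  # PerfectSeparationError and kin
        logger.warning("logistic fit failed (%s); returning flagged result", exc)
        params = np.zeros(X.shape[1])
        bse = np.full(X.shape[1], np.inf)
        pvals = np.full(X.shape[1], np.nan)
        llf = float("nan")
        converged, separated = False, True

    with np.errstate(over="ignore"):
        tab = pd.DataFrame(
            {
                "beta": params,
                "se": bse,
                "odds_ratio": np.exp(params),
                "or_ci_low": np.exp(params - 1.96 * bse),
                "or_ci_high": np.exp(params + 1.96 * bse),
                "p": pvals,
            },
            index=pd.Index(names, name="predictor"),
        )
    return GlmResult(table=tab, converged=converged, separated=separated,
                     n=int(X.shape[0]), llf=llf)


def weighted_kappa(ratings_a, ratings_b, k_categories: int | None = None) -> float:
    """Linear-weighted Cohen's kappa for ordinal categories 1..k.

    Agreement weights are ``1 - |i - j| / (k - 1)``; kappa is
    (po - pe) / (1 - pe) with po/pe the observed and chance-expected
    weighted agreement.  Errors when fewer than two categories occur.
    """
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length nonempty vectors")
    k = int(k_categories) if k_categories else int(max(a.max(), b.max()))
    if a.min() < 1 or b.min() < 1 or max(a.max(), b.max()) > k:
        raise ValueError(f"ratings must lie in 1..{k}")
    if np.unique(np.concatenate([a, b])).size < 2:
        raise ValueError("fewer than two categories observed")
    obs = np.zeros((k, k))
    np.add.at(obs, (a - 1, b - 1), 1.0)
    n = obs.sum()
    i, j = np.indices((k, k))
    w = 1.0 - np.abs(i - j) / (k - 1)
    po = float((w * obs).sum() / n)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n**2
    pe = float((w * expected).sum())
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


@dataclass
class CohortReport:
    """Assembled cohort statistics.

    ``group_changes``: per-variable mean ± SD of percentage change per
    group with within-group signed-rank p-values; ``roc``: per-variable
    ROC summary; ``glm``: the multivariable logistic model on predictors
    passing the univariate screen (None when none pass); ``notes``
    records metadata such as the absence of multiplicity correction.
    """

    group_changes: pd.DataFrame
    roc: pd.DataFrame
    glm: GlmResult | None
    selected_predictors: list[str]
    notes: dict = field(default_factory=dict)


def _direction_for(var: str, directions: Mapping[str, str]) -> str:
    """Exact lookup, then prefix match (so 'tdv_ml' or 'ff_L1_L3' inherit
    the 'tdv' / 'ff' conventions); unknown variables default to 'higher'."""
    if var in directions:
        return directions[var]
    for key, direction in directions.items():
        if var.startswith(key):
            return direction
    return "higher"


def _check_groups(table: pd.DataFrame) -> np.ndarray:
    if "group" not in table.columns:
        raise ValueError("cohort_report: cohort table lacks a 'group' column")
    groups = table["group"].to_numpy()
    labels = groups == "responder"
    if labels.all() or (~labels).all():
        raise ValueError(
            "cohort_report: both responder and non-responder groups are required")
    return labels


def cohort_report(
    cohort: pd.DataFrame,
    variables: Sequence[str] | None = None,
    directions: Mapping[str, str] = DEFAULT_DIRECTIONS,
    screen_alpha: float = 0.05,
) -> CohortReport:
    """Build the standard cohort summary from a patient table.

    Expects columns ``group`` plus ``<var>_pct_change`` (and optionally
    ``<var>_baseline`` / ``<var>_followup`` for the paired within-group
    test) for every variable.  The multivariable logistic model includes
    the percentage changes whose univariate logistic p < `screen_alpha`.
    """
    labels = _check_groups(cohort)
    if variables is None:
        variables = [c[: -len("_pct_change")] for c in cohort.columns
                     if c.endswith("_pct_change")]
    if not variables:
        raise ValueError("cohort_report: no percentage-change variables found")

    change_rows, roc_rows = [], []
    y = labels.astype(int)
    univariate_p: dict[str, float] = {}
    for var in variables:
        pct = cohort[f"{var}_pct_change"].to_numpy(dtype=float)
        finite = np.isfinite(pct)
        n_dropped = int(np.count_nonzero(~finite))
        if n_dropped:
            logger.warning("cohort_report: %d undefined %s changes excluded",
                           n_dropped, var)
        row: dict = {"variable": var, "n_excluded": n_dropped}
        for grp, sel in (("responder", labels), ("non-responder", ~labels)):
            vals = pct[sel & finite]
            row[f"{grp}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
            row[f"{grp}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            bcol, fcol = f"{var}_baseline", f"{var}_followup"
            try:
                if bcol in cohort.columns and fcol in cohort.columns:
                    _, p = wilcoxon_signed_rank(
                        cohort.loc[sel, bcol].to_numpy(),
                        cohort.loc[sel, fcol].to_numpy())
                else:
                    _, p = wilcoxon_signed_rank(vals)
            except ValueError:
                p = float("nan")
            row[f"{grp}_wilcoxon_p"] = p
        change_rows.append(row)

        direction = _direction_for(var, directions)
        try:
            roc = roc_analysis(pct[finite], labels[finite], direction=direction)
            roc_rows.append({
                "variable": var,
                "auc": roc.auc,
                "se": roc.se,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "ci_high_clipped": roc.ci_clipped[1],
                "cutoff": roc.cutoff,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "direction": direction,
            })
        except ValueError:
            roc_rows.append({"variable": var, "auc": float("nan"),
                             "direction": direction})
        try:
            uni = fit_logistic(pct[finite][:, None], y[finite],
                               feature_names=[var])
            univariate_p[var] = float(uni.table.loc[var, "p"])
        except ValueError:
            univariate_p[var] = float("nan")

    selected = [v for v, p in univariate_p.items()
                if np.isfinite(p) and p < screen_alpha]
    glm = None
    if selected:
        X = cohort[[f"{v}_pct_change" for v in selected]].to_numpy(dtype=float)
        ok = np.all(np.isfinite(X), axis=1)
        glm = fit_logistic(X[ok], y[ok], feature_names=selected)

    notes = {
        "multiplicity_correction": "none",
        "univariate_screen_alpha": screen_alpha,
        "univariate_p": univariate_p,
        "kurtosis_convention": "Fisher excess",
    }
    return CohortReport(
        group_changes=pd.DataFrame(change_rows).set_index("variable"),
        roc=pd.DataFrame(roc_rows).set_index("variable"),
        glm=glm,
        selected_predictors=selected,
        notes=notes,
    )
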