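"""Biomarker association statistics.

Every comparison returns an :class:`AssociationResult` carrying the effect
size, its confidence interval where defined, the two-sided p-value, the
sample size, and free-text notes (orientation, corrections applied). The
estimators mirror standard clinical-biostatistics practice: cross-product
odds ratio with Fisher's exact p, Mann-Whitney U, trapezoidal ROC AUC with
the Mann-Whitney p, Kaplan-Meier curves with log-rank p and the
Mantel-Haenszel observed/expected hazard ratio, Spearman rank correlation,
and multivariable logistic / Cox models.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, SeparationError, UndefinedComparisonError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationResult:
    """One statistical comparison: effect size, CI, p-value, metadata."""

    method: str
    effect: float
    p_value: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None
    notes: str = ""

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.effect <= self.ci_high) and not any(
                math.isnan(x) or math.isinf(x)
                for x in (self.ci_low, self.effect, self.ci_high)
            ):
                raise ParameterError("effect outside its own confidence interval")

    def as_dict(self) -> dict:
        return {
            "method": self.method, "effect": self.effect,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n": self.n, "notes": self.notes,
        }


def results_to_frame(results) -> pd.DataFrame:
    """Tidy table: one AssociationResult per row."""
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

def fisher_2x2(table) -> AssociationResult:
    """Cross-product odds ratio with two-sided Fisher exact p.

    The point estimate is (a*d)/(b*c) on the table [[a, b], [c, d]]; with a
    zero cell the OR is reported as the 0 or inf sentinel (no continuity
    correction of the estimate) and a Haldane-Anscombe corrected value is
    recorded in the notes. The two-sided p sums hypergeometric probabilities
    no larger than that of the observed table. The CI is Woolf (logit) with
    1.96 SE, defined only when all four cells are positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ParameterError("table counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ParameterError("table counts must be integers")
    if t.sum() == 0:
        raise ParameterError("table has no observations")
    a, b, c, d = t.ravel()
    notes = "OR = (a*d)/(b*c), rows = groups, cols = outcome"
    if b * c == 0 and a * d == 0:
        effect = math.nan
    elif b * c == 0:
        effect = math.inf
    elif a * d == 0:
        effect = 0.0
    else:
        effect = (a * d) / (b * c)
    ci_low = ci_high = None
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = effect * math.exp(-1.96 * se)
        ci_high = effect * math.exp(1.96 * se)
    else:
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        notes += f"; zero cell, Haldane-corrected OR = {haldane:.3g}"
    p = float(sps.fisher_exact(np.round(t).astype(int), alternative="two-sided")[1])
    return AssociationResult(
        method="fisher_exact", effect=float(effect), p_value=p,
        n=int(t.sum()), ci_low=ci_low, ci_high=ci_high, notes=notes,
    )


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def _has_ties(x, y) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney(x, y) -> AssociationResult:
    """Two-sided Mann-Whitney test; the effect is the U statistic of ``x``.

    Exact enumeration when the pooled sample is small (n1 + n2 <= 12) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    method = "exact" if (x.size + y.size <= 12 and not _has_ties(x, y)) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return AssociationResult(
        method="mann_whitney", effect=float(res.statistic),
        p_value=float(res.pvalue), n=int(x.size + y.size),
        notes=f"U of first sample; {method} p",
    )


def roc_auc(scores, labels) -> AssociationResult:
    """ROC AUC of a continuous score for a binary label.

    Trapezoidal rule over the empirical ROC, so tied scores contribute half;
    equivalently U / (n1 * n0). The p-value is the two-sided Mann-Whitney p
    comparing scores between the classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ParameterError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise ParameterError("both classes must be present")
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(labels, scores))
    mw = mann_whitney(scores[labels == 1], scores[labels == 0])
    return AssociationResult(
        method="roc_auc", effect=auc, p_value=mw.p_value, n=int(labels.size),
        notes="AUC of score for label 1; p from Mann-Whitney equivalence",
    )


def spearman(x, y) -> AssociationResult:
    """Spearman rank correlation (midranks) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 pairs")
    rho, p = sps.spearmanr(x, y)
    return AssociationResult(
        method="spearman", effect=float(rho), p_value=float(p), n=int(x.size),
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalComparison:
    """Log-rank comparison of two groups with Mantel-Haenszel hazard ratio."""

    result: AssociationResult
    km_curves: dict = field(default_factory=dict)  # group -> survival DataFrame
    observed: dict = field(default_factory=dict)   # group -> observed events
    expected: dict = field(default_factory=dict)   # group -> expected events


def survival_compare(time, event, group, group_order=None) -> SurvivalComparison:
    """Compare right-censored survival between two groups.

    Kaplan-Meier curves per group; log-rank chi-square p; hazard ratio by the
    Mantel-Haenszel observed/expected method, HR = (O1/E1) / (O2/E2) with the
    first-listed group in the numerator (orientation echoed in the notes).
    The CI is exp(log HR +/- 1.96 * sqrt(1/E1 + 1/E2)).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    if (time < 0).any():
        raise ParameterError("negative survival times")
    labels = list(group_order) if group_order is not None else sorted(set(group.tolist()))
    if len(labels) != 2:
        raise ParameterError(f"expected exactly two groups, got {labels}")
    if not event.any():
        raise UndefinedComparisonError("no events in either group")
    g1 = group == labels[0]
    g2 = group == labels[1]
    if not g1.any() or not g2.any():
        raise ParameterError("both groups must be non-empty")

    # pooled risk sets at each distinct event time: expected events per group
    o = {labels[0]: float(event[g1].sum()), labels[1]: float(event[g2].sum())}
    e = {labels[0]: 0.0, labels[1]: 0.0}
    for t in np.unique(time[event]):
        at_risk1 = float(np.sum(time[g1] >= t))
        at_risk2 = float(np.sum(time[g2] >= t))
        deaths = float(np.sum(event & (time == t)))
        n_at_risk = at_risk1 + at_risk2
        if n_at_risk > 0:
            e[labels[0]] += deaths * at_risk1 / n_at_risk
            e[labels[1]] += deaths * at_risk2 / n_at_risk

    if e[labels[0]] == 0 or e[labels[1]] == 0 or o[labels[1]] == 0:
        hr = math.inf if o[labels[0]] > 0 else math.nan
        ci_low = ci_high = None
    else:
        hr = (o[labels[0]] / e[labels[0]]) / (o[labels[1]] / e[labels[1]])
        se = math.sqrt(1 / e[labels[0]] + 1 / e[labels[1]])
        if hr > 0:
            ci_low = hr * math.exp(-1.96 * se)
            ci_high = hr * math.exp(1.96 * se)
        else:
            ci_low = ci_high = None

    lr = logrank_test(time[g1], time[g2], event_observed_A=event[g1],
                      event_observed_B=event[g2])
    curves = {}
    for lab, mask in ((labels[0], g1), (labels[1], g2)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=str(lab))
        curves[lab] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(lab): "survival"}
        )
    result = AssociationResult(
        method="logrank_mantel_haenszel",
        effect=float(hr),
        p_value=float(lr.p_value),
        n=int(time.size),
        ci_low=ci_low, ci_high=ci_high,
        notes=f"HR = (O/E of '{labels[0]}') / (O/E of '{labels[1]}')",
    )
    return SurvivalComparison(result=result, km_curves=curves, observed=o, expected=e)


# ---------------------------------------------------------------------------
# multivariable models
# ---------------------------------------------------------------------------

def _complete_cases(df: pd.DataFrame, columns) -> pd.DataFrame:
    kept = df.dropna(subset=list(columns))
    dropped = len(df) - len(kept)
    if dropped:
        logger.info("dropped %d incomplete case(s) (missing covariates)", dropped)
    return kept


def _drop_constant(df: pd.DataFrame, covariates) -> list[str]:
    kept = []
    for c in covariates:
        if df[c].nunique() <= 1:
            logger.warning("covariate %r is constant across patients; dropped", c)
        else:
            kept.append(c)
    return kept


def logistic_model(df: pd.DataFrame, outcome: str, covariates) -> tuple[
        list[AssociationResult], AssociationResult]:
    """Multivariable logistic regression of a binary outcome.

    Complete cases only; constant covariates dropped with a warning; perfect
    separation is refused rather than silently fit. Returns one result per
    covariate (effect = log-odds coefficient) plus the in-sample model AUC.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    data = _complete_cases(df, [outcome, *covariates])
    covs = _drop_constant(data, covariates)
    if not covs:
        raise ParameterError("no usable covariates")
    X = sm.add_constant(data[covs].astype(float))
    y = data[outcome].astype(float)
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("error", message=".*[Ss]eparation.*")
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, Warning) as exc:
        raise SeparationError(f"logistic model refused: {exc}") from exc
    if not np.isfinite(fit.bse).all():
        raise SeparationError("logistic model refused: non-finite standard errors")
    conf = fit.conf_int()
    per_cov = {
        c: AssociationResult(
            method="logistic", effect=float(fit.params[c]),
            p_value=float(fit.pvalues[c]), n=int(len(data)),
            ci_low=float(conf.loc[c, 0]), ci_high=float(conf.loc[c, 1]),
            notes=f"log-odds per unit of {c}; adjusted for {sorted(set(covs) - {c})}",
        )
        for c in covs
    }
    model_auc = roc_auc(fit.predict(X), y.astype(int))
    return per_cov, model_auc


def cox_model(df: pd.DataFrame, time: str, event: str, covariates) -> list[AssociationResult]:
    """Multivariable Cox proportional-hazards regression for PFS."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    data = _complete_cases(df, [time, event, *covariates])
    covs = _drop_constant(data, covariates)
    if not covs:
        raise ParameterError("no usable covariates")
    if not data[event].astype(bool).any():
        raise UndefinedComparisonError("no events; Cox model undefined")
    cph = CoxPHFitter()
    try:
        cph.fit(data[[time, event, *covs]].astype(float),
                duration_col=time, event_col=event)
    except ConvergenceError as exc:
        raise SeparationError(f"Cox model refused: {exc}") from exc
    summ = cph.summary
    return {
        c: AssociationResult(
            method="cox", effect=float(summ.loc[c, "coef"]),
            p_value=float(summ.loc[c, "p"]), n=int(len(data)),
            ci_low=float(summ.loc[c, "coef lower 95%"]),
            ci_high=float(summ.loc[c, "coef upper 95%"]),
            notes=f"log hazard per unit of {c}; adjusted for {sorted(set(covs) - {c})}",
        )
        for c in covs
    }


def horizon_auc(df: pd.DataFrame, score: str, time: str, event: str,
                horizon_months: float) -> AssociationResult:
    """Classification AUC of a score for progression by a time horizon.

    Patients censored before the horizon are not evaluable and are excluded;
    the label is "progressed at or before the horizon".
    """
    evaluable = df[(df[event].astype(bool)) | (df[time] >= horizon_months)]
    label = ((evaluable[time] <= horizon_months) & evaluable[event].astype(bool))
    if label.nunique() < 2:
        raise UndefinedComparisonError(
            f"all evaluable patients share one outcome at {horizon_months} months"
        )
    res = roc_auc(evaluable[score], label.astype(int))
    return AssociationResult(
        method="horizon_auc", effect=res.effect, p_value=res.p_value,
        n=int(len(evaluable)),
        notes=f"AUC for progression by {horizon_months} months; "
              f"{len(df) - len(evaluable)} censored-early patient(s) excluded",
    )


def multivariable_models(
    df: pd.DataFrame,
    covariates=("tmb", "pd_l1_pct", "squamous", "smoker", "ecog", "tumor_burden_high"),
    outcome: str = "responder",
    time: str = "pfs_months",
    event: str = "pfs_event",
    horizons=(6.0, 12.0),
) -> dict:
    """Joint logistic (response) and Cox (PFS) adjustment analysis.

    Covariate columns must already be numeric (binary covariates coded 0/1).
    Returns per-covariate results for both models, the logistic model AUC,
    and time-horizon AUCs of the Cox linear predictor at 6 and 12 months
    computed on the patients evaluable at each horizon.
    """
    present = [c for c in covariates if c in df.columns]
    absent = sorted(set(covariates) - set(present))
    if absent:
        logger.warning("covariate(s) %s absent from table; skipped", absent)
    logit_res, logit_auc = logistic_model(df, outcome, present)
    cox_res = cox_model(df, time, event, present)
    data = _complete_cases(df, [time, event, *present])
    covs = list(cox_res)
    lp = data[covs].astype(float) @ np.array([cox_res[c].effect for c in covs])
    scored = data.assign(_risk=lp.to_numpy())
    horizon_res = {}
    for h in horizons:
        try:
            horizon_res[h] = horizon_auc(scored, "_risk", time, event, h)
        except UndefinedComparisonError as exc:
            logger.warning("horizon %.0f months: %s", h, exc)
    return {
        "logistic": logit_res,
        "logistic_auc": logit_auc,
        "cox": cox_res,
        "horizon_auc": horizon_res,
    }


# ---------------------------------------------------------------------------
# composite stratification and gene scans
# ---------------------------------------------------------------------------

def composite_groups(
    tmb,
    pd_l1_pct,
    tmb_threshold: float | None = None,
    pdl1_threshold: float = 1.0,
) -> list[str | None]:
    """Label patients by joint TMB / PD-L1 status: both, one, or neither.

    TMB-high is strict (> threshold; default threshold is the cohort median
    of patients with any TMB). PD-L1-positive is inclusive (>= 1%). Patients
    with missing PD-L1 get label None and are excluded from composite
    analyses rather than imputed.
    """
    tmb = np.asarray(tmb, dtype=float)
    pdl1 = np.array([math.nan if v is None else float(v) for v in pd_l1_pct])
    if tmb_threshold is None:
        tmb_threshold = float(np.median(tmb))
    labels: list[str | None] = []
    for t, p in zip(tmb, pdl1):
        if math.isnan(p):
            labels.append(None)
            continue
        high = t > tmb_threshold
        pos = p >= pdl1_threshold
        labels.append("both" if high and pos else ("one" if high or pos else "neither"))
    return labels


def chi_square_trend(labels, successes) -> AssociationResult:
    """Cochran-Armitage chi-square test for trend in proportions.

    Groups are ordered neither < one < both with scores 0, 1, 2; the effect
    reported is the trend chi-square statistic (1 df).
    """
    order = ["neither", "one", "both"]
    labels = list(labels)
    successes = np.asarray(successes).astype(int)
    mask = np.array([l in order for l in labels])
    lab = np.array([order.index(l) for l, m in zip(labels, mask) if m], dtype=float)
    suc = successes[mask]
    n_i = np.array([np.sum(lab == s) for s in (0.0, 1.0, 2.0)], dtype=float)
    r_i = np.array([suc[lab == s].sum() for s in (0.0, 1.0, 2.0)], dtype=float)
    if (n_i > 0).sum() < 2:
        raise UndefinedComparisonError("need at least two populated groups")
    s = np.array([0.0, 1.0, 2.0])
    n = n_i.sum()
    r = r_i.sum()
    if r == 0 or r == n:
        raise UndefinedComparisonError("all outcomes identical; trend undefined")
    num = n * (n * (s * r_i).sum() - r * (s * n_i).sum()) ** 2
    den = r * (n - r) * (n * (s ** 2 * n_i).sum() - ((s * n_i).sum()) ** 2)
    chi2 = num / den
    p = float(sps.chi2.sf(chi2, df=1))
    return AssociationResult(
        method="chi_square_trend", effect=float(chi2), p_value=p, n=int(n),
        notes="Cochran-Armitage, scores 0/1/2 for neither/one/both",
    )


def gene_level_scan(
    mutation_matrix: pd.DataFrame,
    responder,
    gene_list=None,
) -> pd.DataFrame:
    """Per-gene Fisher test of mutation status against response.

    ``mutation_matrix`` is patients x genes boolean. Zero-cell odds ratios
    carry the 0 / inf sentinels. Reports the unadjusted p and the
    Benjamini-Hochberg q over the tested genes. Genes absent from the matrix
    or mutated in nobody are skipped with a note row.
    """
    from statsmodels.stats.multitest import multipletests

    responder = np.asarray(responder).astype(bool)
    if len(responder) != len(mutation_matrix):
        raise ParameterError("responder vector length != number of patients")
    genes = list(gene_list) if gene_list is not None else list(mutation_matrix.columns)
    rows = []
    for gene in genes:
        if gene not in mutation_matrix.columns:
            rows.append({"gene": gene, "skipped": "absent from matrix"})
            continue
        mut = mutation_matrix[gene].astype(bool).to_numpy()
        if not mut.any():
            rows.append({"gene": gene, "skipped": "mutated in nobody"})
            continue
        a = int(np.sum(mut & responder))
        b = int(np.sum(mut & ~responder))
        c = int(np.sum(~mut & responder))
        d = int(np.sum(~mut & ~responder))
        res = fisher_2x2([[a, b], [c, d]])
        rows.append({
            "gene": gene, "n_mut_responder": a, "n_mut_nonresponder": b,
            "odds_ratio": res.effect, "p_value": res.p_value, "skipped": "",
        })
    out = pd.DataFrame(rows)
    tested = out["skipped"] == "" if "skipped" in out else pd.Series([], dtype=bool)
    if tested.any():
        q = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
        out.loc[tested, "q_value"] = q
    return out
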