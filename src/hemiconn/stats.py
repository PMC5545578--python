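"""Covariate-adjusted statistical battery for hemispheric asymmetry.

The battery mirrors a standard group-comparison workflow on asymmetry
indices (AI) from a three-group cohort (NC / MCI / AD):

1. within-group hemisphere tests — a repeated-measures GLM with hemisphere
   as the two-level within factor and age, sex, hemispheric-ICV difference,
   TR and TE as covariates.  With exactly two within levels this model is
   algebraically identical to regressing the paired difference
   d = right - left on the mean-centred covariates and testing the
   intercept, which is how it is implemented (t with df = n - p - 1;
   positive t = rightward).
2. sex-by-group interaction screen on each AI measure; when the interaction
   is significant the group comparison is stratified by sex.
3. group main effect (3-level F) and Bonferroni-corrected pairwise post
   hocs (AD-NC, AD-MCI, MCI-NC; p x 3, capped at 1), all adjusted for age,
   sex, whole-brain ICV, hemispheric-ICV difference, TR and TE.
4. Benjamini-Hochberg FDR across nodes for the nodal-level families.
5. multiple linear regression of each memory score on each AI measure with
   the same covariates; a negative AI coefficient means stronger rightward
   asymmetry tracks poorer memory.

All tests are two-sided.  Sex is coded female=0, male=1; covariates are
mean-centred within the analysis sample so intercepts are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult", "hemisphere_repeated_test", "interaction_screen",
    "group_main_effect", "posthoc_pairwise", "fdr_bh",
    "association_regression", "run_full_battery", "BatteryConfig",
    "battery_to_json",
]

GROUP_ORDER = ("NC", "MCI", "AD")
POSTHOC_PAIRS = (("AD", "NC"), ("AD", "MCI"), ("MCI", "NC"))


@dataclass
class StatResult:
    effect: str
    stat_kind: str            # 't' or 'F'
    stat: float
    df: tuple                 # (df1, df2) for F, (df,) for t
    p_raw: float
    p_adjusted: float = None
    adjustment: str = "none"
    direction: str = None     # sign convention note for t statistics
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_adjusted is None:
            self.p_adjusted = self.p_raw
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p values must lie in [0, 1]")

    def to_dict(self):
        d = asdict(self)
        d["df"] = list(self.df)
        return d


def _check_design(X: np.ndarray, names) -> None:
    """Reject constant or collinear covariate columns, naming the offender."""
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            raise ValueError(f"covariate {name!r} is constant")
    if np.linalg.matrix_rank(np.column_stack([np.ones(X.shape[0]), X])) < X.shape[1] + 1:
        # find a culprit: first column explained exactly by the previous ones
        for j in range(X.shape[1]):
            sub = np.column_stack([np.ones(X.shape[0]), X[:, :j]])
            resid = X[:, j] - sub @ np.linalg.lstsq(sub, X[:, j], rcond=None)[0]
            if np.allclose(resid, 0.0, atol=1e-10):
                raise ValueError(f"covariate {names[j]!r} is collinear")
        raise ValueError("covariates are collinear")


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS with intercept prepended; returns (beta, se, df_resid, rss)."""
    import statsmodels.api as sm

    n = len(y)
    Xd = np.column_stack([np.ones(n), X]) if X is not None and X.size else np.ones((n, 1))
    if n - Xd.shape[1] <= 0:
        raise ValueError("not enough observations for the design")
    fit = sm.OLS(y, Xd).fit()
    return (np.asarray(fit.params), np.asarray(fit.bse),
            int(fit.df_resid), float(fit.ssr))


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def _covariate_matrix(cov: pd.DataFrame, names) -> np.ndarray:
    X = np.column_stack([np.asarray(cov[c], dtype=float) for c in names])
    _check_design(X, names)
    return _center(X)


def hemisphere_repeated_test(left, right, covariates: pd.DataFrame) -> StatResult:
    """Within-group left/right test as a paired-difference regression.

    Regresses d = right - left on mean-centred covariates and tests the
    intercept; exactly equivalent to the two-level repeated-measures GLM
    (t^2 equals its hemisphere-effect F).  Positive t = rightward.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must be paired, equal length")
    d = right - left
    names = list(covariates.columns)
    X = _covariate_matrix(covariates, names)
    if len(d) < X.shape[1] + 2:
        raise ValueError("too few subjects for the covariate set")
    beta, se, df, _ = _ols(d, X)
    if se[0] == 0.0:
        t = 0.0 if beta[0] == 0.0 else np.inf * np.sign(beta[0])
    else:
        t = beta[0] / se[0]
    p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    if np.all(d == 0.0):
        t, p = 0.0, 1.0
    return StatResult(effect="hemisphere", stat_kind="t", stat=float(t),
                      df=(df,), p_raw=float(p),
                      direction="positive t = rightward (right > left)")


def _group_dummies(group, order=GROUP_ORDER):
    group = np.asarray(group)
    present = [g for g in order if np.any(group == g)]
    cols = [np.asarray(group == g, dtype=float) for g in present[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(group), 0)),
            present)


def _f_test(y, X_full, X_reduced, label) -> StatResult:
    _, _, df_full, rss_full = _ols(y, X_full)
    _, _, _, rss_red = _ols(y, X_reduced)
    q = (X_full.shape[1] if X_full is not None else 0) - \
        (X_reduced.shape[1] if X_reduced is not None else 0)
    if q <= 0:
        raise ValueError("full model must nest the reduced model")
    num = max(rss_red - rss_full, 0.0) / q
    den = rss_full / df_full
    F = num / den if den > 0 else 0.0
    p = sps.f.sf(F, q, df_full) if den > 0 else 1.0
    return StatResult(effect=label, stat_kind="F", stat=float(F),
                      df=(q, df_full), p_raw=float(p))


def interaction_screen(ai, group, sex, covariates: pd.DataFrame,
                       alpha: float = 0.05) -> StatResult:
    """F-test of the sex x group interaction on an AI measure.

    Sets ``extra['stratify_by_sex']`` when the interaction is significant
    at ``alpha`` (the group comparison should then be run per sex).
    """
    ai = np.asarray(ai, dtype=float)
    group = np.asarray(group)
    sex = np.asarray(sex)
    keep = np.isfinite(ai)
    ai, group, sex = ai[keep], group[keep], sex[keep]
    covariates = covariates.loc[np.asarray(keep)]
    sexes = np.unique(sex)
    if sexes.size < 2:
        raise ValueError("both sexes must be present for the interaction screen")
    for g in np.unique(group):
        for s in sexes:
            if not np.any((group == g) & (sex == s)):
                raise ValueError(f"empty sex x group cell: ({s!r}, {g!r})")
    G, present = _group_dummies(group)
    if len(present) < 2:
        raise ValueError("at least 2 groups are required")
    male = np.asarray(sex == "M", dtype=float)
    names = list(covariates.columns)
    C = _covariate_matrix(covariates, names)
    base = np.column_stack([G, male, C])
    inter = G * male[:, None]
    res = _f_test(ai, np.column_stack([base, inter]), base, "sex:group")
    res.extra["stratify_by_sex"] = bool(res.p_raw < alpha)
    return res


def group_main_effect(ai, group, covariates: pd.DataFrame,
                      stratum: str = "all", sex=None) -> StatResult:
    """Covariate-adjusted F-test of the (up to 3-level) group factor.

    ``stratum`` restricts to one sex ('M' or 'F'; requires ``sex``), in
    which case sex must not appear among the covariates.
    """
    ai = np.asarray(ai, dtype=float)
    group = np.asarray(group)
    keep = np.isfinite(ai)
    ai, group = ai[keep], group[keep]
    covariates = covariates.loc[np.asarray(keep)]
    if sex is not None:
        sex = np.asarray(sex)[keep]
    if stratum != "all":
        if sex is None:
            raise ValueError("stratified analysis requires the sex vector")
        keep = np.asarray(sex) == stratum
        ai, group = ai[keep], group[keep]
        covariates = covariates.loc[np.asarray(keep)]
    G, present = _group_dummies(group)
    if len(present) < 2:
        raise ValueError("at least 2 groups are required in the stratum")
    names = list(covariates.columns)
    C = _covariate_matrix(covariates, names)
    res = _f_test(ai, np.column_stack([G, C]), C, f"group({stratum})")
    res.extra["groups"] = present
    return res


def posthoc_pairwise(ai, group, covariates: pd.DataFrame,
                     m: int = 3) -> list:
    """Bonferroni-corrected covariate-adjusted pairwise group contrasts.

    Fits one OLS per pair (AD-NC, AD-MCI, MCI-NC) on that pair's subjects
    with a group indicator plus covariates; p_adjusted = min(1, m * p).
    The t sign follows the first-listed group minus the second.
    """
    ai = np.asarray(ai, dtype=float)
    group = np.asarray(group)
    finite = np.isfinite(ai)
    ai, group = ai[finite], group[finite]
    covariates = covariates.loc[np.asarray(finite)]
    if set(np.unique(group)) != set(GROUP_ORDER):
        raise ValueError("post hoc comparisons require exactly the 3 groups")
    out = []
    for a, b in POSTHOC_PAIRS:
        keep = (group == a) | (group == b)
        if np.sum(group == a) < 2 or np.sum(group == b) < 2:
            raise ValueError(f"group with <2 members in pair {a}-{b}")
        y = ai[keep]
        ind = np.asarray(group[keep] == a, dtype=float)
        names = list(covariates.columns)
        C = _covariate_matrix(covariates.loc[np.asarray(keep)], names)
        X = np.column_stack([ind, C])
        beta, se, df, _ = _ols(y, X)
        if se[1] == 0.0:   # degenerate: identical AI in both groups
            t, p = 0.0, 1.0
        else:
            t = beta[1] / se[1]
            p = 2.0 * sps.t.sf(abs(t), df)
        out.append(StatResult(
            effect=f"{a}-{b}", stat_kind="t", stat=float(t), df=(df,),
            p_raw=float(p), p_adjusted=float(min(1.0, m * p)),
            adjustment="bonferroni",
            direction=f"positive t = {a} > {b}"))
    return out


def fdr_bh(p, q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, crit_index)`` where ``reject`` is a boolean mask
    over the input order and ``crit_index`` is the largest k (1-based, on
    the sorted p-values) with p_(k) <= k*q/m, or 0 when nothing is
    rejected.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    order = np.argsort(p, kind="mergesort")
    m = p.size
    below = p[order] <= (np.arange(1, m + 1) * q / m)
    crit = int(np.max(np.nonzero(below)[0]) + 1) if np.any(below) else 0
    return reject, crit


def association_regression(ai, score, covariates: pd.DataFrame,
                           score_name: str = "score") -> StatResult:
    """Multiple linear regression of a memory score on an AI measure.

    Complete cases only; t and two-sided p for the AI coefficient.
    Negative t: stronger rightward asymmetry tracks a lower score.
    """
    ai = np.asarray(ai, dtype=float)
    score = np.asarray(score, dtype=float)
    names = list(covariates.columns)
    C = np.column_stack([np.asarray(covariates[c], dtype=float) for c in names])
    keep = np.isfinite(ai) & np.isfinite(score) & np.all(np.isfinite(C), axis=1)
    ai, score, C = ai[keep], score[keep], C[keep]
    if len(score) < C.shape[1] + 3:
        raise ValueError("too few complete cases for the covariate set")
    if np.ptp(score) == 0.0:
        raise ValueError("score has zero variance")
    if np.ptp(ai) == 0.0:
        raise ValueError("AI is constant (collinear with the intercept)")
    _check_design(C, names)
    X = _center(np.column_stack([ai, C]))
    beta, se, df, _ = _ols(score, X)
    t = beta[1] / se[1]
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(effect=f"ai~{score_name}", stat_kind="t", stat=float(t),
                      df=(df,), p_raw=float(p),
                      direction="negative t = rightward asymmetry, lower score",
                      extra={"n_complete": int(len(score))})


# ---------------------------------------------------------------------------
# full battery


@dataclass(frozen=True)
class BatteryConfig:
    alpha: float = 0.05
    q: float = 0.05
    bonferroni_m: int = 3
    nodal_restrict_rule: str = "uncorrected"   # or 'fdr'


_WITHIN_COVARS = ["age", "sex01", "icv_diff", "tr", "te"]
_AI_COVARS = ["age", "sex01", "whole_icv", "icv_diff", "tr", "te"]


def _prep_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    c = cohort.copy()
    c["sex01"] = (c["sex"] == "M").astype(float)
    c["icv_diff"] = c["right_icv"] - c["left_icv"]
    return c


def run_full_battery(metrics: pd.DataFrame, ai: pd.DataFrame,
                     cohort: pd.DataFrame,
                     config: BatteryConfig = BatteryConfig()) -> dict:
    """Run the full asymmetry battery on cohort tables.

    Parameters
    ----------
    metrics : long table (subject, hemisphere, measure, node, value)
    ai : table (subject, measure, node, m_right, m_left, ai)
    cohort : per-subject covariate/score table

    Returns a results dictionary:

    * ``within`` — per group x measure hemisphere tests; nodal results
      carry BH-FDR-adjusted significance (q) per group
    * ``screened_nodes`` — nodes significantly asymmetric in >= 1 group
    * ``interaction``, ``group``, ``posthoc`` — AI group comparisons for
      e_glob, e_loc and each screened node
    * ``associations`` — AI x memory-score regressions; nodal family
      restricted to nodes with significant group differences and BH-FDR
      corrected across nodes per score
    """
    ids = set(cohort["id"])
    for name, tab in (("metrics", metrics), ("ai", ai)):
        extra = sorted(set(tab["subject"]) - ids)
        missing = sorted(ids - set(tab["subject"]))
        if extra or missing:
            raise ValueError(
                f"subject id mismatch in {name} table: "
                f"unknown={extra[:5]} missing={missing[:5]}")
    c = _prep_cohort(cohort).set_index("id")
    results = {"config": asdict(config), "within": {}, "interaction": {},
               "group": {}, "posthoc": {}, "associations": {}}

    def aligned(tab, measure, node=-1, col="value", hemisphere=None):
        sel = (tab["measure"] == measure) & (tab["node"] == node)
        if hemisphere is not None:
            sel &= tab["hemisphere"] == hemisphere
        sub = tab[sel].set_index("subject")[col]
        return sub.reindex(c.index).to_numpy(dtype=float)

    nodes = sorted(ai.loc[ai["measure"] == "e_nodal", "node"].unique())

    # -- 1. within-group asymmetry ------------------------------------------
    screened = set()
    for g in GROUP_ORDER:
        gmask = (c["group"] == g).to_numpy()
        gc = c[gmask]
        cov = gc[_WITHIN_COVARS]
        for meas in ("e_glob", "e_loc"):
            l = aligned(metrics, meas, hemisphere="left")[gmask]
            r = aligned(metrics, meas, hemisphere="right")[gmask]
            res = hemisphere_repeated_test(l, r, cov)
            res.extra["significant"] = bool(res.p_raw < config.alpha)
            results["within"][f"{g}/{meas}"] = res
        nodal_res = []
        for nd in nodes:
            l = aligned(metrics, "e_nodal", node=nd, hemisphere="left")[gmask]
            r = aligned(metrics, "e_nodal", node=nd, hemisphere="right")[gmask]
            nodal_res.append(hemisphere_repeated_test(l, r, cov))
        if nodal_res:
            pvec = np.array([r.p_raw for r in nodal_res])
            rej, _ = fdr_bh(pvec, config.q)
            for nd, res, rj in zip(nodes, nodal_res, rej):
                res.adjustment = "fdr_bh"
                res.extra["significant"] = bool(rj)
                results["within"][f"{g}/e_nodal/{nd}"] = res
                if rj:
                    screened.add(nd)
    results["screened_nodes"] = sorted(screened)

    # -- 2/3. AI group comparisons ------------------------------------------
    group_vec = c["group"].to_numpy()
    sex_vec = c["sex"].to_numpy()
    cov_ai = c[_AI_COVARS]
    cov_ai_nosex = c[[v for v in _AI_COVARS if v != "sex01"]]
    group_sig_nodes = set()
    fdr_group_nodes = {}

    def compare(name, values):
        inter = interaction_screen(values, group_vec, sex_vec, cov_ai,
                                   config.alpha)
        results["interaction"][name] = inter
        if inter.extra["stratify_by_sex"]:
            for s in ("M", "F"):
                results["group"][f"{name}/{s}"] = group_main_effect(
                    values, group_vec, cov_ai_nosex, stratum=s, sex=sex_vec)
        grp = group_main_effect(values, group_vec, cov_ai)
        results["group"][name] = grp
        results["posthoc"][name] = posthoc_pairwise(
            values, group_vec, cov_ai, m=config.bonferroni_m)
        return grp

    for meas in ("e_glob", "e_loc"):
        compare(meas, aligned(ai, meas, col="ai"))
    node_group_p = []
    for nd in results["screened_nodes"]:
        grp = compare(f"e_nodal/{nd}", aligned(ai, "e_nodal", node=nd, col="ai"))
        node_group_p.append(grp.p_raw)
        if grp.p_raw < config.alpha:
            group_sig_nodes.add(nd)
    if node_group_p:
        rej, _ = fdr_bh(np.array(node_group_p), config.q)
        fdr_group_nodes = {nd: bool(r) for nd, r
                           in zip(results["screened_nodes"], rej)}
    results["group_significant_nodes"] = sorted(group_sig_nodes)
    results["group_fdr_nodes"] = {str(k): v for k, v in fdr_group_nodes.items()}

    # -- 4. AI--memory associations -----------------------------------------
    scores = ["ravlt_total", "ravlt_tot6", "ravlt_recog"]
    results["associations_skipped"] = {}
    for meas in ("e_glob", "e_loc"):
        vals = aligned(ai, meas, col="ai")
        if np.ptp(vals[np.isfinite(vals)]) == 0.0:
            # degenerate (e.g. perfectly symmetric cohort): nothing to regress
            results["associations_skipped"][meas] = "constant AI"
            continue
        for sc in scores:
            res = association_regression(vals, c[sc].to_numpy(), cov_ai,
                                         score_name=sc)
            res.extra["significant"] = bool(res.p_raw < config.alpha)
            results["associations"][f"{meas}/{sc}"] = res
    restrict = (results["group_significant_nodes"]
                if config.nodal_restrict_rule == "uncorrected"
                else sorted(k for k, v in fdr_group_nodes.items() if v))
    for sc in scores:
        fam = []
        for nd in restrict:
            vals = aligned(ai, "e_nodal", node=nd, col="ai")
            fam.append(association_regression(vals, c[sc].to_numpy(), cov_ai,
                                              score_name=sc))
        if fam:
            rej, _ = fdr_bh(np.array([r.p_raw for r in fam]), config.q)
            for nd, res, rj in zip(restrict, fam, rej):
                res.adjustment = "fdr_bh"
                res.extra["significant"] = bool(rj)
                results["associations"][f"e_nodal/{nd}/{sc}"] = res
    return results


def battery_to_json(results: dict) -> dict:
    """JSON-serializable view of a battery results bundle."""
    def conv(v):
        if isinstance(v, StatResult):
            return v.to_dict()
        if isinstance(v, list):
            return [conv(x) for x in v]
        if isinstance(v, dict):
            return {str(k): conv(x) for k, x in v.items()}
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    return conv(results)
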