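"""Cohort-level statistics and biological scores.

Group comparison of MRE parameters (Welch two-sided t-test by default),
Pearson correlations with laboratory scores, AUC of the heterogeneity
biomarker with a DeLong 95% confidence interval, and the two clinical
calculators used to characterize the disease groups:

* APRI, the AST-to-platelet ratio index,
  ``100 * (AST / AST-ULN) / platelets[10^9/L]``, with the published
  category bands;
* the revised Mayo risk score (MRS) for primary sclerosing cholangitis,
  ``0.0295*age + 0.5373*ln(bilirubin) - 0.8389*albumin + 0.5380*ln(AST)
  + 1.2426*(variceal bleeding)``, with low / intermediate / high risk bands
  at 0 and 2.

Group CV entries of the summary table are means of per-subject CVs (each
subject's intrahepatic SD already normalized by that subject's mean), never
the ratio of group-level summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import SubjectStats

__all__ = [
    "ClinicalRecord",
    "CohortResult",
    "MRS_COEFFICIENTS",
    "two_sided_t_test",
    "pearson_r",
    "auc_ci",
    "apri",
    "mayo_risk_score",
    "build_cohort_table",
]

#: revised Mayo PSC risk model coefficients
MRS_COEFFICIENTS = {
    "age_per_year": 0.0295,
    "log_bilirubin": 0.5373,
    "albumin_per_g_dl": -0.8389,
    "log_ast": 0.5380,
    "variceal_bleeding": 1.2426,
}

ALPHA = 0.05  # single-threshold significance level, no multiplicity correction


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-subject clinical covariates feeding APRI and the Mayo risk score."""

    age_years: float
    ast_u_per_l: float
    ast_uln_u_per_l: float
    platelets_1e9_per_l: float
    bilirubin_mg_per_dl: float
    albumin_g_per_dl: float
    variceal_bleeding: bool
    group_label: str  # "PSC" or "viral"

    def __post_init__(self) -> None:
        for name in (
            "age_years",
            "ast_u_per_l",
            "ast_uln_u_per_l",
            "platelets_1e9_per_l",
            "bilirubin_mg_per_dl",
            "albumin_g_per_dl",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.group_label not in ("PSC", "viral"):
            raise ValueError("group_label must be 'PSC' or 'viral'")


@dataclass
class CohortResult:
    """Summary table, pairwise tests, correlations and AUC of a cohort."""

    summary: pd.DataFrame  # one row per metric, Table-2-shaped
    comparisons: pd.DataFrame  # metric, t, df, p
    correlations: pd.DataFrame  # group, pair, r, p
    auc: pd.DataFrame  # metric, auc, ci_lo, ci_hi


def two_sided_t_test(
    group_a, group_b, *, variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-sided t-test; Welch (unequal variances) unless ``variant='student'``.

    Degenerate input (zero variance in both groups and equal means) returns
    ``(0, df, 1)`` rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.inf * math.copysign(1, a.mean() - b.mean()), df, 0.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc_ci(scores_pos, scores_neg) -> tuple[float, float, float]:
    """AUC (Mann-Whitney, ties counted 1/2) with a DeLong 95% CI.

    The AUC is computed from the placement values of the combined-sample
    midranks, which is algebraically identical to exhaustive pair counting.
    The variance follows DeLong's structural-component estimator; the CI is
    the normal-approximation interval clipped to [0, 1]. With zero variance
    (e.g. perfect separation) the CI degenerates to the point estimate.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be nonempty")
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    # placements: fraction of the other group each observation beats
    v_pos = (all_ranks[:m] - pos_ranks) / n
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v_pos.mean())
    s_pos = v_pos.var(ddof=1) if m > 1 else 0.0
    s_neg = v_neg.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s_pos / m + s_neg / n)
    z = sps.norm.ppf(0.975)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, lo, hi


def apri(record: ClinicalRecord) -> tuple[float, str]:
    """AST-to-platelet ratio index and its published category band.

    Bands: < 0.5 no significant fibrosis; [0.5, 1.0) cirrhosis unlikely;
    [1.0, 1.5) no reliable assessment; [1.5, 2.0] significant fibrosis;
    > 2.0 cirrhosis.
    """
    score = 100.0 * (record.ast_u_per_l / record.ast_uln_u_per_l) / (
        record.platelets_1e9_per_l
    )
    if score < 0.5:
        category = "absence of significant fibrosis"
    elif score < 1.0:
        category = "cirrhosis unlikely"
    elif score < 1.5:
        category = "no reliable assessment"
    elif score <= 2.0:
        category = "presence of significant fibrosis"
    else:
        category = "cirrhosis"
    return score, category


def mayo_risk_score(record: ClinicalRecord) -> tuple[float, str]:
    """Revised Mayo PSC risk score and its risk group.

    Risk groups: MRS <= 0 low; 0 < MRS <= 2 intermediate; MRS > 2 high.
    """
    c = MRS_COEFFICIENTS
    score = (
        c["age_per_year"] * record.age_years
        + c["log_bilirubin"] * math.log(record.bilirubin_mg_per_dl)
        + c["albumin_per_g_dl"] * record.albumin_g_per_dl
        + c["log_ast"] * math.log(record.ast_u_per_l)
        + c["variceal_bleeding"] * float(record.variceal_bleeding)
    )
    if score <= 0:
        group = "low risk"
    elif score <= 2:
        group = "intermediate risk"
    else:
        group = "high risk"
    return score, group


_METRICS: tuple[tuple[str, str], ...] = (
    ("SWS (m/s)", "sws_mean_mps"),
    ("SD of SWS (m/s)", "sws_sd_mps"),
    ("CV of SWS (%)", "sws_cv_percent"),
    ("phi (rad)", "phi_mean_rad"),
    ("SD of phi (rad)", "phi_sd_rad"),
    ("CV of phi (%)", "phi_cv_percent"),
    ("Fibrosis stage", "fibrosis_stage"),
)


def build_cohort_table(
    stats_list: list[SubjectStats],
    records: list[ClinicalRecord],
    *,
    ttest_variant: str = "welch",
) -> CohortResult:
    """Assemble the cohort summary, group tests, correlations and AUC.

    ``stats_list`` and ``records`` are aligned subject-by-subject. The
    summary has one row per MRE metric with per-group mean and
    interindividual SD; the AUC treats the PSC group as positive and uses
    the CV of SWS and of fluidity as classifier scores.
    """
    if len(stats_list) != len(records):
        raise ValueError("stats and clinical records must be aligned")
    df = pd.DataFrame(
        [
            {
                "group": r.group_label,
                **{m: getattr(s, attr) for m, attr in _METRICS},
                "APRI": apri(r)[0],
                "MRS": mayo_risk_score(r)[0],
            }
            for s, r in zip(stats_list, records)
        ]
    )
    groups = {g: df[df["group"] == g] for g in ("PSC", "viral")}
    for g, sub in groups.items():
        if len(sub) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects for tests")

    summary_rows = []
    comp_rows = []
    for metric, _ in _METRICS:
        row = {"metric": metric}
        row["all_mean"] = df[metric].mean()
        row["all_sd"] = df[metric].std(ddof=1)
        for g in ("PSC", "viral"):
            row[f"{g}_mean"] = groups[g][metric].mean()
            row[f"{g}_sd"] = groups[g][metric].std(ddof=1)
        summary_rows.append(row)
        t, dof, p = two_sided_t_test(
            groups["PSC"][metric], groups["viral"][metric], variant=ttest_variant
        )
        comp_rows.append(
            {"metric": metric, "t": t, "df": dof, "p": p, "significant": p < ALPHA}
        )

    corr_rows = []
    pairs = [
        ("SWS (m/s)", "SD of SWS (m/s)"),
        ("SWS (m/s)", "CV of SWS (%)"),
        ("APRI", "SWS (m/s)"),
        ("APRI", "CV of SWS (%)"),
        ("MRS", "SWS (m/s)"),
        ("MRS", "CV of SWS (%)"),
        ("MRS", "phi (rad)"),
        ("MRS", "CV of phi (%)"),
    ]
    for g in ("PSC", "viral"):
        sub = groups[g]
        for a, b in pairs:
            try:
                r, p = pearson_r(sub[a], sub[b])
            except ValueError:
                r, p = float("nan"), float("nan")
            corr_rows.append({"group": g, "x": a, "y": b, "r": r, "p": p})

    auc_rows = []
    for metric in ("CV of SWS (%)", "CV of phi (%)"):
        a, lo, hi = auc_ci(groups["PSC"][metric], groups["viral"][metric])
        auc_rows.append({"metric": metric, "auc": a, "ci_lo": lo, "ci_hi": hi})

    return CohortResult(
        summary=pd.DataFrame(summary_rows),
        comparisons=pd.DataFrame(comp_rows),
        correlations=pd.DataFrame(corr_rows),
        auc=pd.DataFrame(auc_rows),
    )
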