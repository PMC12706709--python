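"""Cohort-level statistics on subject metric tables.

Given a table with one row per subject (group flags, age, sex, plus the
per-region hemodynamic summaries), this module computes:

* Pearson correlations of TKE_tot and TKE_max against velocity, diameter
  and Reynolds-number measures, with 95% confidence intervals from the
  Fisher z-transform;
* a two-way ANCOVA per (region, lesion) sub-cohort versus the shared
  control group — ``outcome ~ VHD + age + VHD:age`` by ordinary least
  squares, controls as the reference level — whose interaction term asks
  whether the presence of valvular heart disease and age act together;
* distribution-aware two-group comparisons (Shapiro-Wilk at alpha = 0.05
  chooses Student's t versus Wilcoxon rank-sum) and sex chi-squared;
* distribution-aware summaries (mean +/- SD versus median [Q1, Q3]).

No multiple-testing correction is applied by default, matching the
reporting convention the pipeline targets; Benjamini-Hochberg can be
switched on for the ANCOVA table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "AncovaResult",
    "pearson_ci",
    "ancova",
    "compare_groups",
    "chi_squared_sex",
    "summarize",
    "correlation_table",
    "ancova_table",
    "simulate_cohort",
    "LESIONS",
    "METRIC_COLUMNS",
    "PREDICTOR_COLUMNS",
]

#: Valvular lesions recognized in the cohort table.
LESIONS = ("AS", "AR", "MR", "PR", "TR")
#: Outcome measures (per region) entering the ANCOVA table.
METRIC_COLUMNS = ("tke_tot", "tke_max", "vel_avg", "vel_max")
#: Predictors correlated against TKE measures.
PREDICTOR_COLUMNS = ("vel_avg", "vel_max", "mean_diam", "max_diam", "re_avg", "re_max")


@dataclass
class CorrelationResult:
    """Pearson coefficient with Fisher-z 95% CI."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class AncovaResult:
    """Per-term OLS estimates for ``outcome ~ group + age + group:age``.

    ``terms`` maps 'VHD', 'age' and 'VHD:age' to dicts with keys
    ``coef``, ``ci_low``, ``ci_high``, ``p``.  Controls are the reference
    level, so the VHD coefficient is the adjusted group difference.
    """

    terms: dict[str, dict[str, float]]
    n: int


def pearson_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with Fisher z-transform confidence interval.

    The CI is ``tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n-3))``; the
    two-sided p-value comes from the t-distribution with n-2 degrees of
    freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    n = len(x)
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zc = stats.norm.ppf(1 - alpha / 2)
    half = zc / np.sqrt(n - 3)
    ci_low, ci_high = np.tanh(z - half), np.tanh(z + half)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return CorrelationResult(r=r, ci_low=float(ci_low), ci_high=float(ci_high), p=p, n=n)


def ancova(outcome, group_flag, age, alpha: float = 0.05) -> AncovaResult:
    """Two-way ANCOVA: ``outcome ~ intercept + group + age + group:age``.

    ``group_flag`` is boolean (True = lesion, False = control).  Fit by
    OLS; 95% CIs and p-values per term come from the t-distribution.
    """
    y = np.asarray(outcome, float)
    g = np.asarray(group_flag).astype(float)
    a = np.asarray(age, float)
    if not (len(y) == len(g) == len(a)):
        raise ValueError("outcome, group_flag and age must have equal length")
    if len(y) <= 4:
        raise ValueError("need more than 4 observations")
    if g.min() == g.max():
        raise ValueError("both groups must be represented")
    X = np.column_stack([np.ones_like(y), g, a, g * a])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (e.g., one group has a single age)")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)
    names = ["intercept", "VHD", "age", "VHD:age"]
    terms = {
        name: {
            "coef": float(fit.params[i]),
            "ci_low": float(ci[i, 0]),
            "ci_high": float(ci[i, 1]),
            "p": float(fit.pvalues[i]),
        }
        for i, name in enumerate(names)
        if name != "intercept"
    }
    return AncovaResult(terms=terms, n=len(y))


def compare_groups(x, y, alpha: float = 0.05) -> dict:
    """Two-group comparison with a distribution gate.

    Shapiro-Wilk at ``alpha`` on both samples: if neither rejects
    normality, Student's two-sample t-test; otherwise the Wilcoxon
    rank-sum (Mann-Whitney U) test — exact for small tie-free samples,
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least 3 observations")
    normal = all(
        np.ptp(s) > 0 and stats.shapiro(s).pvalue >= alpha for s in (x, y)
    )
    if normal:
        res = stats.ttest_ind(x, y)
        return {"test": "t", "statistic": float(res.statistic), "p": float(res.pvalue)}
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"test": "wilcoxon", "statistic": float(res.statistic), "p": float(res.pvalue)}


def chi_squared_sex(counts) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction."""
    table = np.asarray(counts, float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if table.sum() == 0:
        raise ValueError("table total must be positive")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def summarize(values, alpha: float = 0.05) -> dict:
    """Distribution-aware location/spread summary.

    Normally distributed samples (Shapiro-Wilk, alpha = 0.05) are
    reported as mean +/- SD, others as median [Q1, Q3] with
    linearly interpolated quartiles.  Constant samples are flagged
    degenerate and reported as mean +/- 0.
    """
    v = np.asarray(values, float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0:
        return {
            "form": "mean_sd",
            "mean": float(v[0]),
            "sd": 0.0,
            "degenerate": True,
            "text": f"{v[0]:.3g} ± 0",
        }
    if stats.shapiro(v).pvalue >= alpha:
        m, s = float(v.mean()), float(v.std(ddof=1))
        return {"form": "mean_sd", "mean": m, "sd": s, "degenerate": False,
                "text": f"{m:.3g} ± {s:.3g}"}
    med = float(np.median(v))
    q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))
    return {"form": "median_iqr", "median": med, "q1": q1, "q3": q3,
            "degenerate": False, "text": f"{med:.3g} [{q1:.3g}, {q3:.3g}]"}


def correlation_table(cohort: pd.DataFrame, regions=None) -> pd.DataFrame:
    """Pearson correlations of TKE measures vs flow/size measures.

    Expects flattened per-region columns ``{region}_{measure}``.  Returns
    one row per (region, predictor, tke measure) with r, CI, p, n.
    """
    if regions is None:
        regions = sorted(
            {c.split("_")[0] for c in cohort.columns if c.endswith("_tke_tot")}
        )
    rows = []
    for region in regions:
        for target in ("tke_tot", "tke_max"):
            for pred in PREDICTOR_COLUMNS:
                cx, cy = f"{region}_{pred}", f"{region}_{target}"
                if cx not in cohort or cy not in cohort:
                    continue
                sub = cohort[[cx, cy]].dropna()
                res = pearson_ci(sub[cx].to_numpy(), sub[cy].to_numpy())
                rows.append(
                    {
                        "region": region,
                        "tke_measure": target,
                        "predictor": pred,
                        "r": res.r,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def ancova_table(
    cohort: pd.DataFrame,
    regions=None,
    lesions=LESIONS,
    fdr: bool = False,
) -> pd.DataFrame:
    """ANCOVA per (region, lesion) sub-cohort against the shared controls.

    Each lesion sub-cohort (subjects carrying that lesion flag; subjects
    with several lesions enter several fits) is compared with the control
    group for each hemodynamic measure.  Pairs whose design is degenerate
    (missing group, rank-deficient) are skipped.  ``fdr=True`` appends
    Benjamini-Hochberg adjusted p-values per term across all rows.
    """
    if regions is None:
        regions = sorted(
            {c.split("_")[0] for c in cohort.columns if c.endswith("_tke_tot")}
        )
    is_control = cohort["group_flags"].map(lambda f: "control" in f)
    rows = []
    for region in regions:
        for lesion in lesions:
            in_lesion = cohort["group_flags"].map(lambda f, L=lesion: L in f)
            sub = cohort[is_control | in_lesion]
            if in_lesion.sum() < 2 or is_control.sum() < 2:
                continue
            for measure in METRIC_COLUMNS:
                col = f"{region}_{measure}"
                if col not in cohort:
                    continue
                data = sub[[col, "age"]].dropna()
                flags = in_lesion[data.index]
                try:
                    res = ancova(data[col], flags, data["age"])
                except ValueError:
                    continue
                for term, est in res.terms.items():
                    rows.append(
                        {
                            "region": region,
                            "lesion": lesion,
                            "measure": measure,
                            "term": term,
                            "coef": est["coef"],
                            "ci_low": est["ci_low"],
                            "ci_high": est["ci_high"],
                            "p": est["p"],
                            "n": res.n,
                        }
                    )
    table = pd.DataFrame(rows)
    if fdr and len(table):
        table["p_fdr"] = np.nan
        for term in table["term"].unique():
            sel = table["term"] == term
            table.loc[sel, "p_fdr"] = multipletests(
                table.loc[sel, "p"], method="fdr_bh"
            )[1]
    return table


def simulate_cohort(
    n_controls: int = 20,
    n_per_lesion: int = 20,
    seed: int = 0,
    regions=("AAo", "LV"),
    lesion_effect: float = 2.0,
    age_effect: float = 0.05,
    vel_tke_r: float = 0.7,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Synthetic subject table with planted effects, for testing the
    statistics layer end to end.

    Controls are younger than cases (mirroring a typical retrospective
    VHD cohort); each lesion raises TKE_tot by ``lesion_effect`` mJ; age
    adds ``age_effect`` mJ/year; velocity and TKE correlate with
    population coefficient ``vel_tke_r``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    groups = [("control",)] + [(L,) for L in LESIONS[: max(0, 5)]]
    for flags in groups:
        n = n_controls if flags == ("control",) else n_per_lesion
        for _ in range(n):
            is_case = flags != ("control",)
            age = rng.normal(62 if is_case else 40, 10)
            weight = rng.normal(80, 12)
            height = rng.normal(172, 9)
            row = {
                "subject_id": f"S{sid:04d}",
                "group_flags": frozenset(flags),
                "age": age,
                "sex": "F" if rng.random() < 0.45 else "M",
                "weight": weight,
                "height": height,
            }
            for region in regions:
                z = rng.normal()
                vel = 0.8 + 0.2 * z
                tke_base = (
                    1.5
                    + lesion_effect * float(is_case)
                    + age_effect * age
                    + 2.0 * (vel_tke_r * z + np.sqrt(1 - vel_tke_r**2) * rng.normal())
                )
                tke_tot = tke_base + noise_sd * rng.normal() * 0.1
                diam = 0.03 + 0.003 * rng.normal()
                row.update(
                    {
                        f"{region}_vel_avg": 0.6 * vel,
                        f"{region}_vel_max": vel,
                        f"{region}_tke_tot": tke_tot,
                        f"{region}_tke_max": 60.0 * max(tke_tot, 0.1),
                        f"{region}_mean_diam": diam,
                        f"{region}_max_diam": diam * 1.1,
                        f"{region}_re_avg": 1060 * 0.6 * vel * diam / 4e-3,
                        f"{region}_re_max": 1060 * vel * diam * 1.1 / 4e-3,
                    }
                )
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)
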