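"""Cohort-level statistics: impairment classification, group comparisons,
and CP-volume correlations.

The impairment rule follows the CERAD-K convention used in the study
population: a cognitive domain is *affected* if any of its subtests falls
strictly below z = -1.5 against age/education-adjusted norms, and a subject
is *cognitively impaired* if at least two domains are affected.

Group comparisons default to Welch's unequal-variance t-test (a
pooled-variance Student variant is available), 2x2 tables to Pearson's
chi-square without continuity correction, and associations to Pearson
correlation with the t-transform p-value.  All p-values are raw
(per-comparison alpha), with Benjamini-Hochberg available as a clearly
optional extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: CERAD-K domains and the cohort-table subtest columns belonging to each
DOMAIN_SUBTESTS = {
    "frontal_executive": ("verbal_fluency_z", "trail_making_b_z", "stroop_z"),
    "language": ("boston_naming_z",),
    "verbal_memory": ("word_list_memory_z", "word_list_recall_z", "word_list_recognition_z"),
    "visual_memory": ("constructional_recall_z",),
    "global": ("mmse_z",),
}


def subtests_by_domain() -> dict:
    return {d: list(cols) for d, cols in DOMAIN_SUBTESTS.items()}


@dataclass
class ImpairmentResult:
    impaired: bool
    affected_domains: list
    warnings: list = field(default_factory=list)


def classify_impairment(
    domain_scores: dict,
    threshold: float = -1.5,
    min_affected: int = 2,
) -> ImpairmentResult:
    """Apply the impairment rule to per-domain subtest z-scores.

    ``domain_scores`` maps domain name -> {subtest: z}.  A domain is affected
    iff any subtest z is strictly below ``threshold`` (z exactly at the
    threshold does not count).  A domain whose subtests are all missing/NaN
    is skipped with a warning.
    """
    if len(domain_scores) < 2:
        raise ValueError("need at least 2 domains to classify impairment")
    affected = []
    warnings = []
    for domain, scores in domain_scores.items():
        zs = [z for z in scores.values() if z is not None and np.isfinite(z)]
        if not zs:
            warnings.append(f"domain {domain!r} has no usable subtest scores; skipped")
            continue
        if any(z < threshold for z in zs):
            affected.append(domain)
    return ImpairmentResult(
        impaired=len(affected) >= min_affected,
        affected_domains=affected,
        warnings=warnings,
    )


def impairment_prevalence_pct(n_impaired: int, n_total: int) -> float:
    """Prevalence as a percentage, exactly 100 x impaired / total."""
    if n_total <= 0:
        raise ValueError("cohort size must be > 0")
    return 100.0 * n_impaired / n_total


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: float
    p_value: float
    summary: dict = field(default_factory=dict)


def welch_t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    pooled: bool = False,
) -> ComparisonResult:
    """Two-sample t-test from summary statistics (Welch by default).

    SDs are sample standard deviations (ddof=1).  ``pooled=True`` gives the
    classical equal-variance Student test.  If both variances are zero the
    test is undefined; by convention t=0, p=1 when the means are equal, and
    t=±inf, p=0 otherwise.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be >= 0")
    va, vb = sd_a**2, sd_b**2
    if va == 0 and vb == 0:
        delta = mean_a - mean_b
        return ComparisonResult(
            test="welch_t" if not pooled else "student_t",
            statistic=0.0 if delta == 0 else math.copysign(math.inf, delta),
            df=float(n_a + n_b - 2),
            p_value=1.0 if delta == 0 else 0.0,
            summary={"note": "zero variance in both groups; conventional p"},
        )
    if pooled:
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = math.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = float(n_a + n_b - 2)
        name = "student_t"
    else:
        se = math.sqrt(va / n_a + vb / n_b)
        df = (va / n_a + vb / n_b) ** 2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        )
        name = "welch_t"
    t = (mean_a - mean_b) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        test=name,
        statistic=t,
        df=df,
        p_value=float(min(p, 1.0)),
        summary={
            "mean_a": mean_a, "sd_a": sd_a, "n_a": n_a,
            "mean_b": mean_b, "sd_b": sd_b, "n_b": n_b,
        },
    )


def welch_t_test(sample_a, sample_b, pooled: bool = False) -> ComparisonResult:
    """Two-sample t-test on raw samples; delegates to the summary variant."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 finite observations per group")
    return welch_t_from_summary(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
        pooled=pooled,
    )


def chi_square_test(table, correction: bool = False) -> ComparisonResult:
    """Pearson chi-square on a 2x2 table (no continuity correction by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    n = t.sum()
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return ComparisonResult(
        test="chi_square" + ("_yates" if correction else ""),
        statistic=stat,
        df=1.0,
        p_value=p,
        summary={"observed": t.astype(int).tolist(), "expected": expected.tolist()},
    )


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (optional extension; the primary report uses raw p)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def run_study(cohort: pd.DataFrame, config: dict | None = None) -> dict:
    """Reproduce the study's analysis table on a cohort table.

    Returns a machine-readable report with: patient-vs-control comparisons
    of CP% and ALPS; the within-patient impaired-vs-unimpaired CP%
    comparison; Pearson correlations of CP% against every subtest (patients
    only, since controls are untested); and impairment prevalence.
    """
    from .synthetic import SUBTEST_COLUMNS

    cfg = {"threshold": -1.5, "min_affected": 2, "pooled": False, "bh_adjust": False}
    cfg.update(config or {})

    for g in ("ESRD", "control"):
        if not (cohort["group"] == g).any():
            raise ValueError(f"group {g!r} absent from cohort")
    esrd = cohort[cohort["group"] == "ESRD"]
    ctrl = cohort[cohort["group"] == "control"]
    if len(esrd) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs at least 2 subjects")

    # derive impairment flags from scores (authoritative over any stored flag)
    flags = []
    for _, row in esrd.iterrows():
        scores = {d: {c: row.get(c, np.nan) for c in cols} for d, cols in DOMAIN_SUBTESTS.items()}
        flags.append(classify_impairment(scores, cfg["threshold"], cfg["min_affected"]).impaired)
    flags = np.asarray(flags, dtype=bool)

    report: dict = {
        "config": dict(cfg),
        "n": {"ESRD": int(len(esrd)), "control": int(len(ctrl))},
        "comparisons": {},
        "correlations": {},
    }
    for var in ("cp_pct", "alps"):
        res = welch_t_test(esrd[var], ctrl[var], pooled=cfg["pooled"])
        report["comparisons"][f"{var}_esrd_vs_control"] = _comparison_dict(res)

    n_imp = int(flags.sum())
    report["impairment"] = {
        "n_impaired": n_imp,
        "n_total": int(len(esrd)),
        "prevalence_pct": impairment_prevalence_pct(n_imp, len(esrd)),
    }
    if 2 <= n_imp <= len(esrd) - 2:
        res = welch_t_test(
            esrd.loc[flags, "cp_pct"], esrd.loc[~flags, "cp_pct"], pooled=cfg["pooled"]
        )
        report["comparisons"]["cp_pct_impaired_vs_not"] = _comparison_dict(res)
    else:
        report["comparisons"]["cp_pct_impaired_vs_not"] = {
            "note": "too few subjects in one impairment stratum"
        }

    ps = []
    for col in SUBTEST_COLUMNS:
        try:
            r, p = pearson_corr(esrd["cp_pct"], esrd[col])
        except ValueError as exc:
            report["correlations"][col] = {"note": str(exc)}
            continue
        report["correlations"][col] = {"r": r, "p": p}
        ps.append((col, p))
    if cfg["bh_adjust"] and ps:
        q = benjamini_hochberg([p for _, p in ps])
        for (col, _), qv in zip(ps, q):
            report["correlations"][col]["q_bh"] = float(qv)

    return report


def _comparison_dict(res: ComparisonResult) -> dict:
    return {
        "test": res.test,
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p_value,
        **res.summary,
    }


def format_study_report(report: dict) -> str:
    """Human-readable rendering of a run_study report."""
    lines = [
        f"Cohort: {report['n']['ESRD']} patients, {report['n']['control']} controls",
        "",
        "Group comparisons (Welch t unless configured otherwise):",
    ]
    for name, c in report["comparisons"].items():
        if "p" in c:
            lines.append(
                f"  {name}: t={c['statistic']:.3f}, df={c['df']:.1f}, p={c['p']:.4f}"
                + (
                    f"  [{c['mean_a']:.3f}±{c['sd_a']:.3f} vs {c['mean_b']:.3f}±{c['sd_b']:.3f}]"
                    if "mean_a" in c
                    else ""
                )
            )
        else:
            lines.append(f"  {name}: {c.get('note', 'n/a')}")
    imp = report["impairment"]
    lines += [
        "",
        f"Cognitive impairment: {imp['n_impaired']}/{imp['n_total']} "
        f"({imp['prevalence_pct']:.1f}%)",
        "",
        "CP volume % vs CERAD-K subtests (patients, Pearson r):",
    ]
    for col, c in report["correlations"].items():
        if "r" in c:
            lines.append(f"  {col}: r={c['r']:+.3f}, p={c['p']:.4f}")
        else:
            lines.append(f"  {col}: {c.get('note', 'n/a')}")
    return "\n".join(lines)
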