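"""Study-level aggregation and statistics on measurement tables.

Operations mirror a factorial neuropathology study design: per-group case
summaries, averaging of the two mosaic images captured per section, the
synthetic "Isocortex" region (mean of the four isocortical regions per
case), documented case/marker exclusions, fold change relative to the
control group, one-way and two-way ANOVA with Bonferroni, Tukey HSD and
Newman-Keuls post-hoc families, and a Lilliefors-style Kolmogorov-Smirnov
normality check.

Input tables are pandas DataFrames with the ``MeasurementRecord`` columns
(case_id, region, marker, ir_area_percent, ...) optionally joined to the
case table (braak_group, age, ...).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GROUPS, ISOCORTEX_REGIONS

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("age", "braak_stage", "pmd_hours", "fixation_weeks")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed demographic tables)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def summarize_cases(cases: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-group arithmetic means of the demographic columns.

    Values are reported at printed precision (default one decimal, half away
    from zero).  Groups absent from the table are omitted with a warning.
    """
    present = [g for g in GROUPS if g in set(cases["braak_group"])]
    for g in GROUPS:
        if g not in present:
            logger.warning("summarize_cases: group %r has no cases; omitted", g)
    cols = [c for c in SUMMARY_COLUMNS if c in cases.columns]
    means = cases.groupby("braak_group", sort=False)[cols].mean()
    means = means.reindex(present)
    return means.map(lambda v: round_half_away(v, decimals))


def average_mosaics(records: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate (case, region, marker) rows — the two mosaic images
    captured per section — into one row; singletons pass through unchanged.

    More than two duplicates signal a misconfigured pipeline and raise.
    """
    keys = ["case_id", "region", "marker"]
    counts = records.groupby(keys).size()
    if (counts > 2).any():
        bad = counts[counts > 2].index[0]
        raise ValueError(f"more than two records for {dict(zip(keys, bad))}")
    agg: dict = {"ir_area_percent": "mean"}
    for col in records.columns:
        if col in keys or col == "ir_area_percent":
            continue
        agg[col] = "mean" if col in ("roi_area_um2", "n_objects") else "first"
    out = records.groupby(keys, as_index=False, sort=False).agg(agg)
    return out[records.columns.drop("mosaic") if "mosaic" in records.columns else records.columns]


def isocortex_mean(table: pd.DataFrame) -> pd.DataFrame:
    """Append a synthetic "Isocortex" region: per case and marker, the mean of
    the four isocortical regions.  The transentorhinal region never enters.

    Cases missing any isocortical region for a marker are flagged in the log
    and excluded from the Isocortex rows.
    """
    iso_rows = []
    for (case_id, marker), sub in table.groupby(["case_id", "marker"], sort=False):
        regional = sub[sub["region"].isin(ISOCORTEX_REGIONS)]
        if set(regional["region"]) != set(ISOCORTEX_REGIONS):
            missing = set(ISOCORTEX_REGIONS) - set(regional["region"])
            logger.warning(
                "isocortex_mean: case %s marker %s missing %s; excluded",
                case_id,
                marker,
                sorted(missing),
            )
            continue
        row = regional.iloc[0].copy()
        row["region"] = "Isocortex"
        row["ir_area_percent"] = regional["ir_area_percent"].mean()
        if "n_objects" in regional:
            row["n_objects"] = regional["n_objects"].mean()
        iso_rows.append(row)
    if not iso_rows:
        return table.copy()
    return pd.concat([table, pd.DataFrame(iso_rows)], ignore_index=True)


@dataclass(frozen=True)
class ExclusionRule:
    """Remove one case's measurements for one marker (or for all markers)."""

    case_id: str
    scope: str = "all"  # a marker name, or "all"
    reason: str = ""


def apply_exclusions(table: pd.DataFrame, rules: Sequence[ExclusionRule]) -> pd.DataFrame:
    """Return a copy of ``table`` without the rows matched by the rules.

    A rule that references a case absent from the table raises (it would
    silently do nothing, which usually means a typo in the rule file).
    """
    out = table.copy()
    known = set(table["case_id"].astype(str))
    for rule in rules:
        if str(rule.case_id) not in known:
            raise ValueError(f"exclusion rule references unknown case {rule.case_id!r}")
        hit = out["case_id"].astype(str) == str(rule.case_id)
        if rule.scope != "all":
            hit &= out["marker"] == rule.scope
        logger.info(
            "apply_exclusions: case %s scope %s (%s): %d rows removed",
            rule.case_id,
            rule.scope,
            rule.reason,
            int(hit.sum()),
        )
        out = out[~hit]
    return out.reset_index(drop=True)


def fold_change(
    table: pd.DataFrame,
    reference_group: str = "control",
    value: str = "ir_area_percent",
) -> pd.DataFrame:
    """Group mean relative to the control-group mean, per (region, marker).

    The reference group's fold change is exactly 1.  Strata whose reference
    mean is zero are flagged (``undefined`` = True, fold change NaN) rather
    than silently reported as infinite.
    """
    rows = []
    for (region, marker), sub in table.groupby(["region", "marker"], sort=False):
        groups = sub.groupby("braak_group", sort=False)[value].mean()
        if reference_group not in groups.index:
            raise ValueError(f"reference group {reference_group!r} missing in {region}/{marker}")
        ref = groups[reference_group]
        for group in groups.index:
            if group == reference_group:
                fc, undefined = 1.0, False
            elif ref == 0:
                fc, undefined = float("nan"), True
            else:
                fc, undefined = groups[group] / ref, False
            rows.append(
                {
                    "region": region,
                    "marker": marker,
                    "braak_group": group,
                    "fold_change": fc,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosthocComparison:
    family: str  # e.g. "stages_within_region" / "regions_within_stage" / "pairwise"
    stratum: str  # the level held fixed ("" for one-way comparisons)
    level_a: str
    level_b: str
    diff: float
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    """ANOVA decomposition plus the post-hoc family that followed it."""

    table: pd.DataFrame  # index: sources; columns: sum_sq, df, F, p
    alpha: float
    ss_type: int
    balanced: bool
    post_hoc: tuple[PosthocComparison, ...] = ()

    def effect_p(self, source: str) -> float:
        return float(self.table.loc[source, "p"])


def _check_cells(table: pd.DataFrame, factor_a: str, factor_b: str, response: str) -> bool:
    """Validate the factorial layout; return True when balanced."""
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    counts = table.groupby([factor_a, factor_b], sort=False)[response].count()
    full = table[factor_a].nunique() * table[factor_b].nunique()
    if len(counts) < full or (counts < 2).any():
        lacking = [idx for idx in counts.index if counts[idx] < 2]
        a_levels = table[factor_a].unique()
        b_levels = table[factor_b].unique()
        missing = [
            (a, b)
            for a in a_levels
            for b in b_levels
            if (a, b) not in counts.index
        ]
        raise ValueError(
            f"each cell needs >= 2 replicates; deficient cells: {lacking + missing}"
        )
    return counts.nunique() == 1


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str = "braak_group",
    factor_b: str = "region",
    response: str = "ir_area_percent",
    alpha: float = 0.05,
    posthoc: str = "auto",
) -> AnovaResult:
    """Two-factor ANOVA with interaction, Bonferroni pairwise families after it.

    Balanced designs use the classical (type-I) sums of squares, which for
    balanced data coincide with every other type; unbalanced designs (e.g.
    after exclusions) fall back to type-II sums of squares.  When the
    interaction is significant at ``alpha`` (or ``posthoc='always'``), two
    Bonferroni families of pooled-variance t comparisons are reported: levels
    of ``factor_a`` compared within each level of ``factor_b``, and vice
    versa.  Each family is corrected by its own total comparison count.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if posthoc not in ("auto", "always", "never"):
        raise ValueError("posthoc must be 'auto', 'always' or 'never'")
    balanced = _check_cells(table, factor_a, factor_b, response)
    data = table.rename(columns={factor_a: "_A", factor_b: "_B", response: "_y"})
    model = smf.ols("_y ~ C(_A) * C(_B)", data=data).fit()
    typ = 1 if balanced else 2
    raw = sm.stats.anova_lm(model, typ=typ)
    rename = {
        "C(_A)": factor_a,
        "C(_B)": factor_b,
        "C(_A):C(_B)": f"{factor_a}:{factor_b}",
        "Residual": "residual",
    }
    out = raw.rename(index=rename)[["sum_sq", "df", "F", "PR(>F)"]]
    out.columns = ["sum_sq", "df", "F", "p"]

    comparisons: list[PosthocComparison] = []
    interaction_p = out.loc[f"{factor_a}:{factor_b}", "p"]
    run_posthoc = posthoc == "always" or (posthoc == "auto" and interaction_p < alpha)
    if run_posthoc:
        mse = out.loc["residual", "sum_sq"] / out.loc["residual", "df"]
        dof = out.loc["residual", "df"]
        for family, fix, vary in (
            (f"{factor_a}_within_{factor_b}", "_B", "_A"),
            (f"{factor_b}_within_{factor_a}", "_A", "_B"),
        ):
            fam: list[tuple] = []
            for stratum, sub in data.groupby(fix, sort=False):
                cells = sub.groupby(vary, sort=False)["_y"]
                means, ns = cells.mean(), cells.count()
                for la, lb in itertools.combinations(means.index, 2):
                    diff = means[la] - means[lb]
                    se = math.sqrt(mse * (1.0 / ns[la] + 1.0 / ns[lb]))
                    t = diff / se if se > 0 else float("inf") if diff else 0.0
                    p_raw = 2.0 * sps.t.sf(abs(t), dof)
                    fam.append((str(stratum), str(la), str(lb), diff, t, p_raw))
            m = len(fam)
            logger.info("two_way_anova: family %s has m=%d comparisons", family, m)
            for stratum, la, lb, diff, t, p_raw in fam:
                p_adj = min(1.0, m * p_raw)
                comparisons.append(
                    PosthocComparison(
                        family=family,
                        stratum=stratum,
                        level_a=la,
                        level_b=lb,
                        diff=float(diff),
                        statistic=float(t),
                        p_raw=float(p_raw),
                        p_adjusted=float(p_adj),
                        significant=bool(p_adj < alpha),
                    )
                )
    return AnovaResult(
        table=out, alpha=alpha, ss_type=typ, balanced=balanced, post_hoc=tuple(comparisons)
    )


def _one_way_decomposition(groups: Mapping[str, np.ndarray]):
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_between = len(names) - 1
    df_within = int(ns.sum()) - len(names)
    return names, arrays, ns, means, ss_between, ss_within, df_between, df_within


def one_way_anova(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> AnovaResult:
    """One-factor ANOVA with a studentized-range post-hoc family.

    ``posthoc`` selects Tukey's HSD (every pairwise q compared against the
    critical value for the full number of means) or the Newman-Keuls stepwise
    procedure (the critical value depends on the span of each comparison in
    the ordered means, and a non-significant range seals all ranges nested
    inside it).  With all groups identical the residual variance is zero; F
    is reported as 0 when the between-group variance is also zero and no
    comparison is called significant.
    """
    if posthoc not in ("tukey", "newman_keuls", "none"):
        raise ValueError("posthoc must be 'tukey', 'newman_keuls' or 'none'")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    names, arrays, ns, means, ssb, ssw, dfb, dfw = _one_way_decomposition(groups)
    if ssw == 0.0:
        f_stat = 0.0 if ssb == 0.0 else float("inf")
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(f_stat, dfb, dfw))
    out = pd.DataFrame(
        {
            "sum_sq": [ssb, ssw],
            "df": [float(dfb), float(dfw)],
            "F": [f_stat, float("nan")],
            "p": [p, float("nan")],
        },
        index=["group", "residual"],
    )
    comparisons: tuple[PosthocComparison, ...] = ()
    if posthoc != "none" and ssw > 0.0:
        mse = ssw / dfw
        if posthoc == "tukey":
            comparisons = _tukey_hsd(names, means, ns, mse, dfw, alpha)
        else:
            comparisons = _newman_keuls(names, means, ns, mse, dfw, alpha)
    return AnovaResult(table=out, alpha=alpha, ss_type=1, balanced=len(set(ns)) == 1,
                       post_hoc=comparisons)


def _q_stat(mi, mj, ni, nj, mse) -> float:
    # Tukey-Kramer standard error: sqrt(MSE/2 * (1/ni + 1/nj))
    se = math.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
    return abs(mi - mj) / se if se > 0 else float("inf")


def _tukey_hsd(names, means, ns, mse, dfw, alpha) -> tuple[PosthocComparison, ...]:
    k = len(names)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        q = _q_stat(means[i], means[j], ns[i], ns[j], mse)
        p = float(sps.studentized_range.sf(q, k, dfw))
        out.append(
            PosthocComparison(
                family="tukey",
                stratum="",
                level_a=str(names[i]),
                level_b=str(names[j]),
                diff=float(means[i] - means[j]),
                statistic=float(q),
                p_raw=p,
                p_adjusted=p,  # HSD p is already family-wise
                significant=bool(p < alpha),
            )
        )
    return tuple(out)


def _newman_keuls(names, means, ns, mse, dfw, alpha) -> tuple[PosthocComparison, ...]:
    order = np.argsort(means)
    k = len(names)
    sealed = np.zeros((k, k), dtype=bool)  # in rank coordinates, i < j
    results: dict[tuple[int, int], tuple[float, float, bool]] = {}
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            i, j = order[lo], order[hi]
            q = _q_stat(means[i], means[j], ns[i], ns[j], mse)
            p = float(sps.studentized_range.sf(q, span, dfw))
            if sealed[lo, hi]:
                results[(lo, hi)] = (q, p, False)
                continue
            significant = p < alpha
            results[(lo, hi)] = (q, p, significant)
            if not significant:  # seal every range nested inside this one
                for a in range(lo, hi + 1):
                    for b in range(a + 1, hi + 1):
                        sealed[a, b] = True
    out = []
    for (lo, hi), (q, p, significant) in sorted(results.items()):
        i, j = order[lo], order[hi]
        out.append(
            PosthocComparison(
                family="newman_keuls",
                stratum="",
                level_a=str(names[i]),
                level_b=str(names[j]),
                diff=float(means[i] - means[j]),
                statistic=float(q),
                p_raw=p,
                p_adjusted=p,
                significant=significant,
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------


def _ks_statistic_fitted_normal(x: np.ndarray) -> float:
    """Sup-distance between the ECDF and a normal fitted by sample mean/SD."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    cdf = sps.norm.cdf((xs - xs.mean()) / xs.std(ddof=1))
    d_plus = (np.arange(1, n + 1) / n - cdf).max()
    d_minus = (cdf - np.arange(0, n) / n).max()
    return float(max(d_plus, d_minus))


def ks_normality(values: Sequence[float], flavor: str = "lilliefors") -> tuple[float, float]:
    """Kolmogorov-Smirnov test of normality.

    ``flavor='lilliefors'`` (default) tests against a normal with mean and SD
    estimated from the sample, with the correspondingly corrected null
    distribution; ``flavor='fitted'`` uses the same statistic but the naive
    (anti-conservative) KS null.  Raises for n < 3 or a degenerate
    (constant) sample rather than reporting a meaningless p-value.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("ks_normality needs at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined (SD = 0)")
    if flavor == "lilliefors":
        stat = _ks_statistic_fitted_normal(x)
        if x.size >= 4:
            from statsmodels.stats.diagnostic import lilliefors

            _, p = lilliefors(x, dist="norm")
        else:  # n = 3: below the tabulated range; simulate the null (seeded)
            rng = np.random.default_rng(20180629)
            sims = rng.normal(size=(20000, x.size))
            null = np.array([_ks_statistic_fitted_normal(s) for s in sims])
            p = float((null >= stat).mean())
        return float(stat), float(p)
    if flavor == "fitted":
        stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(stat), float(p)
    raise ValueError("flavor must be 'lilliefors' or 'fitted'")


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean, SD/sqrt(n), with n after any exclusions."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("sem needs at least 2 values")
    return float(x.std(ddof=1) / math.sqrt(x.size))
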