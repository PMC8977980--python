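"""Cohort outcome statistics.

Group comparisons use Pearson chi-square (no continuity correction) for
categorical data, Welch's two-sample t-test for continuous variables and
the normal z-test for proportions; 2x2 tables with small expected counts
fall back to Fisher's exact test. Recurrence odds ratios come from
maximum-likelihood logistic fits with Wald 95% CIs, and baseline gender
differences are balanced by logistic propensity-score matching (greedy
1:1 nearest neighbour on the logit within a caliper).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import SeparationError, UndefinedMetricError

RAC_LOCATION_CLASSES = ("none", "inside_only", "outside")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding to match printed tables (half-up, not banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def apply_blanking(cohort: pd.DataFrame, blanking_days: float = 90.0) -> pd.DataFrame:
    """Drop patients whose follow-up does not exceed the blanking window."""
    return cohort[cohort["followup_days"] > blanking_days].reset_index(drop=True)


def recurrence_by_rac_location(cohort: pd.DataFrame) -> pd.DataFrame:
    """Recurrence count and percentage per RAc-location class.

    Expects a cohort already restricted to adequate follow-up (see
    :func:`apply_blanking`). Returns a frame indexed by class with columns
    ``n``, ``recurrences``, ``pct`` (full precision) and ``pct_display``
    (half-up, 1 decimal); an empty class has NaN percentages.
    """
    rows = {}
    for cls in RAC_LOCATION_CLASSES:
        sub = cohort[cohort["rac_location_class"] == cls]
        n = len(sub)
        rec = int(sub["recurrence"].sum())
        pct = 100.0 * rec / n if n else np.nan
        rows[cls] = dict(
            n=n,
            recurrences=rec,
            pct=pct,
            pct_display=round_half_up(pct) if n else np.nan,
        )
    return pd.DataFrame(rows).T[["n", "recurrences", "pct", "pct_display"]]


def chi_square_test(table, correction: bool = False):
    """Pearson chi-square on a contingency table; returns (stat, p, dof, expected)."""
    t = np.asarray(table, dtype=float)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise UndefinedMetricError("zero margin in contingency table")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p), int(dof), expected


def fisher_exact(table):
    """Fisher's exact test on a 2x2 table; returns (odds_ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table))
    return float(odds), float(p)


def contingency_test(table, small_expected: float = 5.0):
    """Chi-square, or Fisher for a 2x2 with any expected cell below 5.

    Returns ``(stat_or_odds, p, method)``.
    """
    t = np.asarray(table, dtype=float)
    _, _, _, expected = chi_square_test(t)
    if t.shape == (2, 2) and np.any(expected < small_expected):
        odds, p = fisher_exact(t)
        return odds, p, "fisher"
    stat, p, _, _ = chi_square_test(t)
    return stat, p, "chi2"


def welch_t_test(x, y):
    """Welch's two-sample t (unequal variances), two-sided."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per arm")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise UndefinedMetricError("zero variance in both arms")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def proportion_z_test(k1: int, n1: int, k2: int, n2: int):
    """Two-sided normal z-test comparing two proportions (pooled SE)."""
    from statsmodels.stats.proportion import proportions_ztest

    z, p = proportions_ztest([k1, k2], [n1, n2])
    return float(z), float(p)


@dataclass(frozen=True)
class OrResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    exposure: str
    adjustment_set: tuple = ()
    penalized: bool = False

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def logistic_or(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str = "recurrence",
    adjustment_set=(),
    penalized: bool = False,
) -> OrResult:
    """Odds ratio of ``exposure`` for a binary outcome by logistic regression.

    ``exposure`` and the adjustment covariates must be numeric columns
    (encode indicator exposures as 0/1 first). Wald 95% CI. Complete
    separation raises :class:`SeparationError` unless ``penalized=True``,
    which switches to an L2-regularized fit (no CI reported).
    """
    cols = [exposure, *adjustment_set]
    x = sm.add_constant(cohort[cols].astype(float), has_constant="add")
    y = cohort[outcome].astype(float)
    if penalized:
        res = sm.Logit(y, x).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        beta = res.params[exposure]
        return OrResult(
            odds_ratio=float(np.exp(beta)),
            ci_low=np.nan,
            ci_high=np.nan,
            p_value=np.nan,
            exposure=exposure,
            adjustment_set=tuple(adjustment_set),
            penalized=True,
        )
    try:
        res = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and numeric failures
        raise SeparationError(
            f"logistic fit failed ({exc}); retry with penalized=True"
        ) from exc
    beta = res.params[exposure]
    if not np.isfinite(res.bse[exposure]) or abs(beta) > 15:
        raise SeparationError(
            "complete or quasi-complete separation detected; retry with penalized=True"
        )
    ci = res.conf_int().loc[exposure]
    return OrResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_value=float(res.pvalues[exposure]),
        exposure=exposure,
        adjustment_set=tuple(adjustment_set),
    )


def standardized_mean_difference(x_t, x_c) -> float:
    """SMD = (mean_t - mean_c) / sqrt((var_t + var_c)/2)."""
    x_t, x_c = np.asarray(x_t, float), np.asarray(x_c, float)
    denom = np.sqrt((np.var(x_t, ddof=1) + np.var(x_c, ddof=1)) / 2.0)
    if denom == 0:
        return 0.0
    return float((x_t.mean() - x_c.mean()) / denom)


@dataclass
class MatchResult:
    matched: pd.DataFrame
    pairs: list  # (treated_index, control_index)
    smd_before: dict
    smd_after: dict
    propensity_smd_before: float
    propensity_smd_after: float
    n_unmatched_treated: int
    caliper_logit: float


def propensity_match(
    cohort: pd.DataFrame,
    treatment: str = "gender",
    treated_value="F",
    covariates=("age", "hypertension", "chadsvasc", "bsa"),
    caliper: float = 0.2,
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 propensity-score matching without replacement.

    The propensity model is a logistic regression of treatment membership
    on the covariates; matching runs on the logit of the score with a
    caliper of ``caliper`` x SD(logit). Treated units are processed in
    descending propensity order; treated units with no control inside the
    caliper are reported unmatched, never silently dropped. Rows with
    missing covariates are excluded up front.
    """
    cols = list(covariates)
    data = cohort.dropna(subset=cols + [treatment]).copy()
    t = (data[treatment] == treated_value).astype(int)
    x = sm.add_constant(data[cols].astype(float), has_constant="add")
    ps = sm.Logit(t, x).fit(disp=0).predict(x)
    eps = 1e-9
    logit = np.log(np.clip(ps, eps, 1 - eps) / np.clip(1 - ps, eps, 1 - eps))
    data = data.assign(_ps=ps, _logit=logit)
    cal = caliper * float(np.std(logit, ddof=1))

    treated = data[t.values == 1].sort_values("_ps", ascending=False)
    controls = data[t.values == 0]
    order = np.argsort(controls["_logit"].values, kind="stable")
    c_logit = controls["_logit"].values[order]
    c_index = controls.index.values[order]
    used = np.zeros(len(c_logit), dtype=bool)
    pairs, unmatched = [], 0
    n_c = len(c_logit)
    for ti, tl in zip(treated.index, treated["_logit"]):
        # expand outward from the insertion point in order of increasing
        # distance; the first unused control encountered is the nearest
        pos = int(np.searchsorted(c_logit, tl))
        left, right = pos - 1, pos
        best_j, best_d = -1, np.inf
        while left >= 0 or right < n_c:
            dl = tl - c_logit[left] if left >= 0 else np.inf
            dr = c_logit[right] - tl if right < n_c else np.inf
            if dl <= dr:
                if not used[left]:
                    best_j, best_d = left, dl
                    break
                left -= 1
            else:
                if not used[right]:
                    best_j, best_d = right, dr
                    break
                right += 1
        if best_j >= 0 and best_d <= cal:
            pairs.append((ti, c_index[best_j]))
            used[best_j] = True
        else:
            unmatched += 1

    keep = [i for p in pairs for i in p]
    matched = data.loc[keep]
    t_m = (matched[treatment] == treated_value).values

    def smds(frame, tmask):
        return {
            c: standardized_mean_difference(
                frame.loc[tmask, c].astype(float), frame.loc[~tmask, c].astype(float)
            )
            for c in cols
        }

    t_all = t.values.astype(bool)
    return MatchResult(
        matched=matched.drop(columns=["_ps", "_logit"]),
        pairs=pairs,
        smd_before=smds(data, t_all),
        smd_after=smds(matched, t_m) if len(pairs) else {c: np.nan for c in cols},
        propensity_smd_before=standardized_mean_difference(
            data.loc[t_all, "_ps"], data.loc[~t_all, "_ps"]
        ),
        propensity_smd_after=standardized_mean_difference(
            matched.loc[t_m, "_ps"], matched.loc[~t_m, "_ps"]
        )
        if len(pairs)
        else np.nan,
        n_unmatched_treated=unmatched,
        caliper_logit=cal,
    )


# ---------------------------------------------------------------------------
# formatted comparison tables


def _fmt_mean_sd(x) -> str:
    x = np.asarray(x, float)
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _fmt_n_pct(k: int, n: int) -> str:
    return f"{k} ({round_half_up(100.0 * k / n):.1f})" if n else "0 (-)"


def build_table(cohort: pd.DataFrame, which: str = "table1") -> pd.DataFrame:
    """Formatted group-comparison table.

    ``table1`` compares demographics by gender; ``table2`` compares mapping
    summaries by RAc presence and by gender; ``table3`` compares mapped and
    outcome variables by recurrence, including the RAc-location class
    breakdown. Continuous rows use Welch's t, binary rows the chi-square
    test; each row carries the raw numbers next to the rendering.
    """
    c = cohort
    rows = []

    def cont_row(label, col, ga, gb, names):
        a, b = c.loc[ga, col].astype(float), c.loc[gb, col].astype(float)
        _, p = welch_t_test(a, b)
        rows.append(
            {
                "variable": label,
                names[0]: _fmt_mean_sd(a),
                names[1]: _fmt_mean_sd(b),
                "p": p,
                "test": "welch_t",
            }
        )

    def bin_row(label, col, ga, gb, names):
        ka, na = int(c.loc[ga, col].sum()), int(ga.sum())
        kb, nb = int(c.loc[gb, col].sum()), int(gb.sum())
        tab = np.array([[ka, na - ka], [kb, nb - kb]])
        stat, p, method = contingency_test(tab)
        rows.append(
            {
                "variable": label,
                names[0]: _fmt_n_pct(ka, na),
                names[1]: _fmt_n_pct(kb, nb),
                "p": p,
                "test": method,
            }
        )

    if which == "table1":
        men, women = (c["gender"] == "M").values, (c["gender"] == "F").values
        if men.sum() == 0 or women.sum() == 0:
            raise UndefinedMetricError("single-gender cohort: comparison undefined")
        names = ("men", "women")
        cont_row("Age (years)", "age", men, women, names)
        bin_row("Hypertension", "hypertension", men, women, names)
        bin_row("Diabetes mellitus", "diabetes", men, women, names)
        bin_row("Heart failure", "heart_failure", men, women, names)
        cont_row("BSA (m2)", "bsa", men, women, names)
        cont_row("CHA2DS2-VASc", "chadsvasc", men, women, names)
    elif which == "table2":
        rac, norac = (c["has_rac"] == 1).values, (c["has_rac"] == 0).values
        names = ("no_rac", "rac")
        for label, col in [
            ("LA volume (cm3)", "la_volume_cm3"),
            ("LA area (cm2)", "la_area_cm2"),
            ("Mean bipolar voltage (mV)", "mean_voltage_mv"),
            ("LA area <0.5 mV (fraction)", "low_voltage_fraction"),
            ("EGM electrical burden", "burden"),
        ]:
            cont_row(label, col, norac, rac, names)
        men, women = (c["gender"] == "M").values, (c["gender"] == "F").values
        bin_row("Num. patients with RAc", "has_rac", men, women, ("men", "women"))
    elif which == "table3":
        free = (c["recurrence"] == 0).values
        rec = (c["recurrence"] == 1).values
        names = ("af_free", "recurrence")
        for label, col in [
            ("LA volume (cm3)", "la_volume_cm3"),
            ("Mean bipolar voltage (mV)", "mean_voltage_mv"),
            ("EGM electrical burden", "burden"),
        ]:
            cont_row(label, col, free, rec, names)
        loc = recurrence_by_rac_location(c)
        for cls in RAC_LOCATION_CLASSES:
            rows.append(
                {
                    "variable": f"RAc location: {cls}",
                    names[0]: int(loc.loc[cls, "n"] - loc.loc[cls, "recurrences"]),
                    names[1]: int(loc.loc[cls, "recurrences"]),
                    "p": np.nan,
                    "test": "count",
                }
            )
    else:
        raise ValueError("which must be table1|table2|table3")
    return pd.DataFrame(rows)
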