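"""Two-group screening statistics and effect sizes.

Conventions (chosen to reproduce published two-decimal values from summary
inputs): unequal-variance (Welch) t with the second-listed group minus the
first in the numerator; pooled-SD Cohen's d with the same sign convention;
Yates continuity-corrected chi-square with the correction clamped at zero;
the bias-corrected Cramer's V computed from the *uncorrected* Pearson
chi-square; and Benjamini-Hochberg step-up adjustment per comparison table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import BINARY_COLUMNS, CODEBOOK, CohortTable

__all__ = [
    "GroupComparison",
    "welch_t",
    "cohens_d_pooled",
    "yates_chi_square",
    "fisher_exact_two_sided",
    "cramers_v_bias_corrected",
    "bh_adjust",
    "compare_groups",
]


@dataclass
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    summary_a: str
    summary_b: str
    statistic_kind: str  # welch_t | yates_chi2 | fisher
    statistic: float | None
    df: float | None
    p: float
    p_adjusted: float | None
    effect_kind: str  # cohens_d | cramers_v_corrected
    effect: float


def welch_t(mean_a: float, sd_a: float, n_a: int,
            mean_b: float, sd_b: float, n_b: int) -> tuple[float, float, float]:
    """Welch two-sample t from summary statistics.

    Returns ``(t, df, p)`` with ``t = (mean_b - mean_a) / se`` (positive when
    the second group is larger) and the Welch-Satterthwaite df.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        if mean_a == mean_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means: "
                         "t statistic undefined")
    t = (mean_b - mean_a) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohens_d_pooled(mean_a: float, sd_a: float, n_a: int,
                    mean_b: float, sd_b: float, n_b: int) -> float:
    """Pooled-SD Cohen's d, ``(mean_b - mean_a) / s_pooled``."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 == 0:
        raise ValueError("pooled standard deviation is zero: d undefined")
    return float((mean_b - mean_a) / math.sqrt(sp2))


def _check_cells(a, b, c, d):
    cells = [a, b, c, d]
    for v in cells:
        if v < 0 or int(v) != v:
            raise ValueError("2x2 cells must be non-negative integers")
    return [int(v) for v in cells]


def yates_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected chi-square for the 2x2 table ``(a, b; c, d)``.

    The |ad - bc| - n/2 correction is clamped at zero, so proportional
    tables give exactly 0.  Zero margins are routed to Fisher's test.
    """
    a, b, c, d = _check_cells(a, b, c, d)
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if n < 1 or any(m == 0 for m in margins):
        raise ValueError("zero margin: use fisher_exact_two_sided instead")
    num = max(0.0, abs(a * d - b * c) - n / 2.0) ** 2
    chi2 = n * num / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(sps.chi2.sf(chi2, 1))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric point probabilities
    not exceeding that of the observed table (margins fixed)."""
    a, b, c, d = _check_cells(a, b, c, d)
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = float(sps.hypergeom.pmf(a, n, col1, row1))
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def cramers_v_bias_corrected(a: int, b: int, c: int, d: int) -> float:
    """Bias-corrected Cramer's V from the uncorrected Pearson chi-square.

    phi-tilde^2 = max(0, chi2/n - (r-1)(c-1)/(n-1)); the row/column counts
    are shrunk the same way before normalising.
    """
    a, b, c, d = _check_cells(a, b, c, d)
    n = a + b + c + d
    if n <= 1:
        raise ValueError("need n >= 2 for Cramer's V")
    r = kcols = 2
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        chi2 = 0.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    phi2 = chi2 / n
    phi2_t = max(0.0, phi2 - (r - 1) * (kcols - 1) / (n - 1))
    r_t = r - (r - 1) ** 2 / (n - 1)
    c_t = kcols - (kcols - 1) ** 2 / (n - 1)
    denom = min(r_t - 1, c_t - 1)
    return float(math.sqrt(phi2_t / denom)) if denom > 0 else 0.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _expected_min(a, b, c, d) -> float:
    n = a + b + c + d
    rows, cols = (a + b, c + d), (a + c, b + d)
    return min(r * col / n for r in rows for col in cols) if n else 0.0


def choose_categorical_test(a: int, b: int, c: int, d: int) -> str:
    """Route a 2x2 table: Fisher when the smallest expected cell is < 5
    (ties break toward Fisher) or any margin is zero, else Yates chi-square."""
    a, b, c, d = _check_cells(a, b, c, d)
    if any(m == 0 for m in (a + b, c + d, a + c, b + d)):
        return "fisher"
    return "fisher" if _expected_min(a, b, c, d) <= 5 else "yates_chi2"


def _summarise_cont(x: pd.Series) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def compare_groups(table: CohortTable, grouping: str,
                   bh_family: list[str] | None = None) -> pd.DataFrame:
    """Screen every indicator between two groups.

    ``grouping`` is ``"gender"`` (male vs female) or ``"lang_improvement"``
    (improvement vs non-improvement).  Continuous indicators get Welch t +
    pooled Cohen's d; binary indicators get the Yates chi-square — or
    Fisher's exact test when the smallest expected cell is below 5 (ties
    break toward Fisher) — plus bias-corrected Cramer's V.  BH adjustment
    runs across the rows of the table (restrictable via ``bh_family``).
    """
    df = table.data
    if grouping == "gender":
        in_a = df["gender"] == "male"
        labels = ("male", "female")
        variables = ["age", "lang"] + [c.name for c in CODEBOOK
                                       if c.name not in ("age",)]
    elif grouping in ("lang_improvement", "lang-improvement"):
        in_a = df["lang"] < 0
        labels = ("improvement", "non_improvement")
        variables = ["gender_male"] + [c.name for c in CODEBOOK]
    else:
        raise ValueError("grouping must be 'gender' or 'lang_improvement'")
    if in_a.all() or (~in_a).all():
        raise ValueError("grouping must split the table into two non-empty groups")

    rows: list[GroupComparison] = []
    for var in variables:
        if var == "gender_male":
            series = (df["gender"] == "male").astype(int)
            kind = "binary"
        else:
            series = df[var]
            kind = "binary" if var in BINARY_COLUMNS else "continuous"
        xa, xb = series[in_a], series[~in_a]
        if kind == "continuous":
            t, dof, p = welch_t(xa.mean(), xa.std(ddof=1), len(xa),
                                xb.mean(), xb.std(ddof=1), len(xb))
            d = cohens_d_pooled(xa.mean(), xa.std(ddof=1), len(xa),
                                xb.mean(), xb.std(ddof=1), len(xb))
            rows.append(GroupComparison(var, labels[0], labels[1],
                                        _summarise_cont(xa), _summarise_cont(xb),
                                        "welch_t", t, dof, p, None, "cohens_d", d))
        else:
            a = int((xa == 1).sum())
            b = int((xa == 0).sum())
            c = int((xb == 1).sum())
            dd = int((xb == 0).sum())
            v = cramers_v_bias_corrected(a, b, c, dd)
            if choose_categorical_test(a, b, c, dd) == "fisher":
                p = fisher_exact_two_sided(a, b, c, dd)
                stat_kind, stat = "fisher", None
            else:
                stat, p = yates_chi_square(a, b, c, dd)
                stat_kind = "yates_chi2"
            pct_a = 100.0 * a / max(1, a + b)
            pct_b = 100.0 * c / max(1, c + dd)
            rows.append(GroupComparison(var, labels[0], labels[1],
                                        f"{a}/{pct_a:.1f}%", f"{c}/{pct_b:.1f}%",
                                        stat_kind, stat, None, p, None,
                                        "cramers_v_corrected", v))

    out = pd.DataFrame([r.__dict__ for r in rows])
    family_mask = out["variable"].isin(bh_family) if bh_family else np.ones(len(out), bool)
    adjusted = np.full(len(out), np.nan)
    adjusted[np.asarray(family_mask)] = bh_adjust(out.loc[family_mask, "p"].to_numpy())
    out["p_adjusted"] = adjusted
    return out
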