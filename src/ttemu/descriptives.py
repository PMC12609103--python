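"""Baseline-characteristics tables: tests, percentages, small-cell suppression.

Categorical characteristics are compared across strategies with the Pearson
chi-square test (no continuity correction — the convention this module is
validated against), continuous summaries with a two-sample t-test from
summary statistics (pooled variance by default, Welch optional).
Unweighted counts below a privacy threshold (default 11) are suppressed;
when a suppressed cell would be recoverable by subtraction from the
column margin, the largest complementary cell is rendered as a bound.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table: (statistic, df, p)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError("chi_square_test: need an r x c table with r, c >= 2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DataError("chi_square_test: zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def two_sample_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float,
                 n2: int, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided t-test from summary statistics: (t, p)."""
    if n1 < 2 or n2 < 2:
        raise DataError("two_sample_t: need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise DataError("two_sample_t: standard deviations must be positive")
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        dof = n1 + n2 - 2
    elif variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise DataError(f"two_sample_t: unknown variant {variant!r}")
    t = (mean1 - mean2) / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(t), float(p)


def arm_percentages(counts, arm_total: int) -> np.ndarray:
    """Within-arm percentages, reported to 2 decimals."""
    if arm_total <= 0:
        raise DataError("arm_percentages: arm total must be positive")
    return np.round(100.0 * np.asarray(counts, dtype=float) / arm_total, 2)


def suppress_small_cells(table, threshold: int = 11) -> pd.DataFrame:
    """Mask cells below the threshold; bound complementary recoverable cells.

    ``table`` is an r x c count array (categories x arms).  Cells < threshold
    render as ``<threshold``.  In a column with exactly one masked cell the
    largest unmasked cell becomes a lower bound (``>b``), since the masked
    value would otherwise be recoverable from the column margin.
    """
    obs = np.asarray(table, dtype=int)
    out = obs.astype(object).copy()
    for j in range(obs.shape[1]):
        col = obs[:, j]
        masked = col < threshold
        for i in np.where(masked)[0]:
            out[i, j] = f"<{threshold}"
        if masked.sum() == 1 and (~masked).sum() >= 1:
            margin = col.sum()
            others = col[~masked].sum()
            i_big = np.where(~masked)[0][col[~masked].argmax()]
            others_rest = others - col[i_big]
            lower = margin - others_rest - (threshold - 1)
            out[i_big, j] = f">{lower - 1}"
    return pd.DataFrame(out)


def baseline_table(cohort: pd.DataFrame, suppress_below: int = 11) -> pd.DataFrame:
    """Baseline-characteristics table by strategy with tests.

    Rows with a suppressed cell are excluded from testing rather than
    imputed; percentages are computed within arm before suppression.
    """
    if not len(cohort):
        return pd.DataFrame(columns=["characteristic", "category", "non_initiator",
                                     "initiator", "p_value", "test_used"])
    arms = ["non_initiator", "initiator"]
    n_by_arm = cohort["strategy"].value_counts().reindex(arms).fillna(0).astype(int)

    rows = []
    cat_chars = [("race_ethnicity", None), ("marital_status", None),
                 ("education_quartile", None), ("charlson", None),
                 ("diabetes", (0, 1)), ("chf", (0, 1)),
                 ("cerebrovascular", (0, 1)), ("hypertension", (0, 1)),
                 ("depression", (0, 1))]
    for char, levels in cat_chars:
        cats = sorted(cohort[char].unique()) if levels is None else list(levels)
        counts = np.zeros((len(cats), 2), dtype=int)
        for a, arm in enumerate(arms):
            sub = cohort[cohort["strategy"] == arm]
            vc = sub[char].value_counts()
            counts[:, a] = [int(vc.get(c, 0)) for c in cats]
        any_suppressed = (counts < suppress_below).any()
        if any_suppressed or (counts.sum(axis=1) == 0).any() or counts.sum() == 0:
            p, test = np.nan, "suppressed"
        else:
            try:
                _, _, p = chi_square_test(counts)
                test = "chi_square"
            except DataError:
                p, test = np.nan, "degenerate"
        disp = suppress_small_cells(counts, suppress_below)
        for i, cat in enumerate(cats):
            rows.append({
                "characteristic": char, "category": cat,
                "non_initiator": _cell(disp.iloc[i, 0], counts[i, 0], n_by_arm[arms[0]]),
                "initiator": _cell(disp.iloc[i, 1], counts[i, 1], n_by_arm[arms[1]]),
                "p_value": round(p, 4) if np.isfinite(p) else np.nan,
                "test_used": test if i == 0 else "",
            })
    for char in ("age", "pcp_visits"):
        g = cohort.groupby("strategy")[char]
        mean, sd, n = g.mean(), g.std(), g.size()
        ok = all(a in mean.index and n[a] >= 2 for a in arms)
        if ok:
            t, p = two_sample_t(mean[arms[0]], max(sd[arms[0]], 1e-12), n[arms[0]],
                                mean[arms[1]], max(sd[arms[1]], 1e-12), n[arms[1]])
        else:
            p = np.nan
        rows.append({
            "characteristic": f"{char}, mean (SD)", "category": "",
            "non_initiator": _summary(mean, sd, arms[0]),
            "initiator": _summary(mean, sd, arms[1]),
            "p_value": round(p, 4) if np.isfinite(p) else np.nan,
            "test_used": "t_pooled" if ok else "suppressed",
        })
    return pd.DataFrame(rows)


def _cell(display, count: int, arm_n: int) -> str:
    if isinstance(display, str):  # suppressed or bounded
        return f"{display}"
    pct = arm_percentages([count], max(arm_n, 1))[0]
    return f"{count} ({pct})"


def _summary(mean: pd.Series, sd: pd.Series, arm: str) -> str:
    if arm not in mean.index:
        return ""
    return f"{mean[arm]:.1f} ({sd[arm]:.1f})"
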