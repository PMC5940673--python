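"""Subject-level aggregation and inferential tests on feature gain.

Gains are first averaged over stimuli within subject for each grouping cell
(ROI, layer, blur, condition, behavioral label), then tested across the
subject means: two-sided one-sample t tests against zero with Bonferroni
correction (family factors supplied by the analysis recipes: 24 for the
layer x blur grid of the 8-layer reference analysis, 8 for per-layer
condition tests, 16 for condition x recognition grids), 95% confidence
intervals across subjects, and fixed-effects factorial ANOVA with
sum-to-zero contrasts and Type II sums of squares (cells become unbalanced
after behavioral grouping, which is where Type II is the appropriate
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AliasingError, DegenerateDataError, InvalidInputError

__all__ = [
    "BONFERRONI_FACTORS",
    "layer_blur_cells",
    "subject_means",
    "TestResult",
    "one_sample_t_bonferroni",
    "ci95_across_subjects",
    "factorial_anova",
    "gain_report",
]

#: Bonferroni family sizes used by the packaged analysis recipes.
BONFERRONI_FACTORS = {
    "layer_by_blur": 24,          # 8 layers x 3 nonzero blur levels
    "condition_by_layer": 8,      # one condition contrast per layer
    "condition_by_recognition": 16,
}


def layer_blur_cells(n_layers: int = 8, n_nonzero_blurs: int = 3) -> int:
    """Number of layer x blur analysis cells (0% excluded)."""
    if n_layers < 1 or n_nonzero_blurs < 1:
        raise InvalidInputError("cell grid needs positive dimensions")
    return n_layers * n_nonzero_blurs


def subject_means(
    gain_table: pd.DataFrame,
    keys: Sequence[str],
    response: str = "gain",
    exclude_zero_blur: bool = True,
) -> pd.DataFrame:
    """Arithmetic mean of ``response`` over stimuli, per subject per key.

    The 0% blur level never contributes to gain summaries.  Cells that end
    up empty are simply absent from the output (mirroring sparse behavioral
    cells); the caller sees one row per populated subject x key combination.
    """
    if gain_table.empty:
        raise InvalidInputError("gain table is empty")
    df = gain_table
    if exclude_zero_blur and "blur" in df.columns:
        df = df[df["blur"] > 0.0]
    group_keys = ["subject"] + [k for k in keys if k != "subject"]
    out = df.groupby(group_keys, as_index=False, observed=True)[response].mean()
    return out


@dataclass(frozen=True)
class TestResult:
    """One-sample t test result with its Bonferroni family."""

    statistic: float
    df: int
    p_value: float
    m: int
    alpha: float
    significant: bool

    @property
    def threshold(self) -> float:
        return self.alpha / self.m


def one_sample_t_bonferroni(
    values: Sequence[float], m: int, alpha: float = 0.05
) -> TestResult:
    """Two-sided one-sample t test of the subject means against zero.

    The significance flag compares the raw p value with ``alpha / m``.
    Zero-variance input raises :class:`DegenerateDataError` rather than
    reporting p = 0, which would silently corrupt a Bonferroni family.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least two subjects")
    if m < 1:
        raise InvalidInputError("Bonferroni factor must be >= 1")
    if np.std(x, ddof=1) == 0.0:
        raise DegenerateDataError("zero variance across subjects")
    t, p = sps.ttest_1samp(x, 0.0)
    return TestResult(
        statistic=float(t), df=int(x.size - 1), p_value=float(p),
        m=int(m), alpha=float(alpha), significant=bool(p < alpha / m),
    )


def ci95_across_subjects(values: Sequence[float]) -> tuple[float, float]:
    """95% confidence interval of the mean across subjects.

    ``mean +/- t_{0.975, n-1} * SD / sqrt(n)``; zero-variance input yields a
    zero-width interval at the mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least two subjects")
    mean = float(x.mean())
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size))
    tcrit = float(sps.t.ppf(0.975, x.size - 1))
    return (mean - tcrit * sem, mean + tcrit * sem)


def factorial_anova(
    summary: pd.DataFrame,
    factors: Sequence[str],
    response: str = "gain",
    max_order: int | None = None,
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA (sum-to-zero contrasts, Type II SS).

    ``summary`` is typically a subject-means table.  Main effects and
    interactions up to ``max_order`` (default: full factorial) are reported
    as rows with sum-of-squares, degrees of freedom, F and p.  Designs with
    empty cells raise :class:`AliasingError` naming the cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = list(factors)
    if not factors:
        raise InvalidInputError("at least one factor required")
    df = summary.copy()
    levels = {}
    for f in factors:
        if f not in df.columns:
            raise InvalidInputError(f"factor {f!r} not in table")
        lv = sorted(df[f].astype(str).unique())
        if len(lv) < 2:
            raise InvalidInputError(f"factor {f!r} needs >= 2 levels")
        levels[f] = lv
        df[f] = df[f].astype(str)

    occupied = set(map(tuple, df[factors].itertuples(index=False, name=None)))
    empty = [cell for cell in product(*(levels[f] for f in factors)) if cell not in occupied]
    if empty:
        raise AliasingError("empty design cells", cells=tuple(empty))

    order = max_order or len(factors)
    terms = []
    for r in range(1, order + 1):
        for combo in combinations(factors, r):
            terms.append(":".join(f"C({f}, Sum)" for f in combo))
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    if model.df_resid < 1:
        raise InvalidInputError("no residual degrees of freedom")
    table = sm.stats.anova_lm(model, typ=2)

    def clean(name: str) -> str:
        return name.replace("C(", "").replace(", Sum)", "")

    out = table.reset_index().rename(
        columns={"index": "effect", "sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    )
    out["effect"] = out["effect"].map(clean)
    return out


def gain_report(
    gain_table: pd.DataFrame,
    m: int,
    alpha: float = 0.05,
    keys: Sequence[str] = ("roi", "layer"),
) -> pd.DataFrame:
    """Per-cell summary: mean gain, 95% CI and Bonferroni-corrected t test."""
    means = subject_means(gain_table, list(keys))
    rows = []
    for cell, sub in means.groupby(list(keys), observed=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        vals = sub["gain"].to_numpy()
        row = dict(zip(keys, cell))
        row["mean_gain"] = float(vals.mean())
        row["n_subjects"] = int(vals.size)
        if vals.size >= 2 and np.std(vals, ddof=1) > 0:
            lo, hi = ci95_across_subjects(vals)
            res = one_sample_t_bonferroni(vals, m=m, alpha=alpha)
            row.update(
                ci_lower=lo, ci_upper=hi, t=res.statistic, df=res.df,
                p=res.p_value, m=res.m, significant=res.significant,
            )
        else:
            row.update(ci_lower=np.nan, ci_upper=np.nan, t=np.nan,
                       df=np.nan, p=np.nan, m=m, significant=False)
        rows.append(row)
    return pd.DataFrame(rows)
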