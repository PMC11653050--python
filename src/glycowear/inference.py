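"""Backward-elimination regression and median-split combination ANOVA.

Two inferential procedures operate on the excursion design table:

* ordinary least squares of a slope response on physiology and nutrient
  predictors, reduced by backward elimination with retention criterion
  P < .20 and optional forced covariates (sex adjustment);
* median-split binary encoding of selected variables into combination
  pattern codes (1 above the pooled median, 0 at/below), followed by a
  one-way ANOVA across pattern groups with the all-zeros code as the
  comparison control and unadjusted pooled-variance contrasts against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from glycowear.datatypes import CHANNELS, NUTRIENTS

#: Default backward-elimination retention criterion.
ALPHA_ELIMINATION = 0.20

#: Default operationalization of "extremely low" pattern-group sizes.
MIN_GROUP_N = 5


class RankDeficientError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


@dataclass
class OLSFit:
    """One ordinary-least-squares fit with complete-case bookkeeping."""

    response: str
    table: pd.DataFrame  # per-predictor coef, se, t, p (index incl. intercept)
    n_used: int
    n_dropped: int
    r_squared: float
    results: object = None  # underlying statsmodels results

    def pvalue(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "p"])


@dataclass
class EliminationResult:
    """Final backward-elimination model plus its ordered removal trace."""

    response: str
    retained: pd.DataFrame  # coef, se, t, p for retained predictors (+ const)
    removed_trace: list[tuple[str, float]]
    n_rows: int
    r_squared: float
    forced: tuple[str, ...] = ()
    alpha: float = ALPHA_ELIMINATION

    @property
    def retained_predictors(self) -> list[str]:
        return [p for p in self.retained.index if p != "const"]


def _complete_cases(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    sub = table.loc[:, list(columns)].apply(pd.to_numeric, errors="coerce")
    return sub.dropna()


def _collinear_set(X: np.ndarray, names: Sequence[str]) -> list[str]:
    # columns loading on the null space of the design
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps
    null = vt[s < tol] if np.any(s < tol) else vt[-1:]
    load = np.abs(null).max(axis=0)
    return [n for n, w in zip(names, load) if w > 1e-8]


def fit_ols(
    table: pd.DataFrame, response: str, predictors: Sequence[str]
) -> OLSFit:
    """OLS with intercept, complete-case deletion, two-sided t-based p.

    Raises :class:`RankDeficientError` naming the offending collinear
    columns when the design matrix is rank deficient, and ``ValueError``
    when fewer complete rows remain than predictors + 2.
    """
    predictors = list(predictors)
    data = _complete_cases(table, [response, *predictors])
    n_used, n_dropped = len(data), len(table) - len(data)
    if n_used < len(predictors) + 2:
        raise ValueError(
            f"only {n_used} complete rows for {len(predictors)} predictors"
        )
    X = sm.add_constant(data[predictors].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_set(X[:, 1:], predictors)
        raise RankDeficientError(f"collinear predictor set: {bad}")
    res = sm.OLS(data[response].to_numpy(dtype=float), X).fit()
    out = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=["const", *predictors],
    )
    return OLSFit(
        response=response,
        table=out,
        n_used=n_used,
        n_dropped=n_dropped,
        r_squared=float(res.rsquared),
        results=res,
    )


def backward_eliminate(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    alpha: float = ALPHA_ELIMINATION,
    forced: Sequence[str] = (),
) -> EliminationResult:
    """Backward elimination: repeatedly drop the non-forced predictor with
    the largest p value while it is ≥ ``alpha``.

    Ties on the maximum p are broken by removing the later column first.
    Forced covariates (e.g. sex) are never removed. Complete cases are
    re-evaluated at every step, as each refit uses only the surviving
    columns.
    """
    candidates = list(candidates)
    forced = tuple(forced)
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    current = [*candidates]
    trace: list[tuple[str, float]] = []
    fit: Optional[OLSFit] = None
    while True:
        cols = [*forced, *current] if forced else current
        if not cols:
            fit = fit_ols(table, response, [])
            break
        fit = fit_ols(table, response, cols)
        removable = [c for c in current]
        if not removable:
            break
        ps = [fit.pvalue(c) for c in removable]
        worst = max(ps)
        if worst < alpha:
            break
        # later column order removed first on ties
        worst_name = [c for c, p in zip(removable, ps) if p == worst][-1]
        trace.append((worst_name, float(worst)))
        current.remove(worst_name)
    return EliminationResult(
        response=response,
        retained=fit.table,
        removed_trace=trace,
        n_rows=fit.n_used,
        r_squared=fit.r_squared,
        forced=forced,
        alpha=alpha,
    )


def regression_candidates(
    columns: Sequence[str],
    response: str,
    features: str = "mean",
    include_nutrients: bool | None = None,
) -> list[str]:
    """Candidate predictor sets for the slope models.

    ``features="mean"`` selects the window channel means plus nutrient
    totals; ``"sd"`` selects the window channel SDs only. Rise-slope models
    exclude the after-peak (``_af``) features, which are reserved for the
    fall-slope analysis.
    """
    if features not in ("mean", "sd"):
        raise ValueError("features must be 'mean' or 'sd'")
    if include_nutrients is None:
        include_nutrients = features == "mean"
    tags = ["", "_30", "_60", "_90"]
    if response == "fall_slope":
        tags.insert(1, "_af")
    cand = [
        f"{ch}{tag}_{features}"
        for ch in CHANNELS
        for tag in tags
        if f"{ch}{tag}_{features}" in columns
    ]
    if include_nutrients:
        cand += [n for n in NUTRIENTS if n in columns]
    return cand


# ---------------------------------------------------------------------------
# Median-split combination patterns and one-way ANOVA


@dataclass
class PatternTable:
    """Rows encoded as binary combination codes over ``variables``.

    ``data`` is the filtered input with an added ``pattern`` column such as
    ``"1011"`` (1 = above the pooled median, 0 = at/below). Rows missing any
    encoded variable are excluded and counted in ``n_excluded``.
    """

    variables: list[str]
    medians: dict[str, float]
    data: pd.DataFrame
    n_excluded: int

    @property
    def reference_code(self) -> str:
        return "0" * len(self.variables)


def median_split_encode(
    table: pd.DataFrame, variables: Sequence[str], medians: Mapping[str, float] | None = None
) -> PatternTable:
    """Encode each variable as 1 above / 0 at-or-below its pooled median.

    The at-median tie goes to 0 so the reference (all-zeros) group absorbs
    boundary rows. Passing precomputed ``medians`` re-encodes against fixed
    cut points (used for idempotence checks and per-participant variants).
    """
    variables = list(variables)
    sub = table.copy()
    num = sub.loc[:, variables].apply(pd.to_numeric, errors="coerce")
    keep = num.notna().all(axis=1)
    n_excluded = int((~keep).sum())
    sub, num = sub.loc[keep], num.loc[keep]
    meds: dict[str, float] = {}
    for v in variables:
        if num[v].nunique() < 2:
            raise ValueError(f"variable {v!r} is constant; median split impossible")
        meds[v] = float(medians[v]) if medians is not None else float(num[v].median())
    codes = ["".join("1" if num[v].iloc[i] > meds[v] else "0" for v in variables) for i in range(len(num))]
    sub = sub.assign(pattern=codes)
    return PatternTable(variables=variables, medians=meds, data=sub, n_excluded=n_excluded)


@dataclass
class AnovaResult:
    """Omnibus one-way ANOVA across pattern groups plus reference contrasts."""

    response: str
    f: float
    df_between: int
    df_within: int
    p: float
    groups: pd.DataFrame  # pattern, n, mean
    contrasts: pd.DataFrame  # pattern, diff vs reference, t, p (unadjusted)
    dropped_groups: list[str] = field(default_factory=list)
    min_group_n: int = MIN_GROUP_N
    reference: str = ""


def pattern_anova(
    pattern_table: PatternTable,
    response: str,
    min_group_n: int = MIN_GROUP_N,
    bonferroni: bool = False,
) -> AnovaResult:
    """One-way ANOVA of ``response`` across surviving pattern groups.

    Groups smaller than ``min_group_n`` are dropped (and listed). The
    all-zeros code is the comparison control; per-group contrasts against
    it use pooled-variance two-sample t tests, unadjusted for multiplicity
    unless ``bonferroni`` is set.
    """
    df = pattern_table.data
    ref = pattern_table.reference_code
    resp = pd.to_numeric(df[response], errors="coerce")
    df = df.loc[resp.notna()].assign(**{response: resp.loc[resp.notna()]})
    sizes = df.groupby("pattern").size()
    dropped = sorted(sizes.index[sizes < min_group_n])
    if ref in dropped:
        raise ValueError(
            f"reference group {ref!r} has n={int(sizes.get(ref, 0))} < "
            f"min_group_n={min_group_n}; lower min_group_n to proceed"
        )
    if ref not in sizes.index:
        raise ValueError(f"reference group {ref!r} not present")
    surviving = sorted(sizes.index[sizes >= min_group_n])
    if len(surviving) < 2:
        raise ValueError("fewer than 2 groups survive the size filter")
    samples = {code: df.loc[df["pattern"] == code, response].to_numpy(dtype=float) for code in surviving}
    f, p = stats.f_oneway(*samples.values())
    n_total = sum(len(v) for v in samples.values())
    groups = pd.DataFrame(
        {
            "pattern": surviving,
            "n": [len(samples[c]) for c in surviving],
            "mean": [float(np.mean(samples[c])) for c in surviving],
        }
    )
    ref_vals = samples[ref]
    k = len(surviving) - 1
    rows = []
    for code in surviving:
        if code == ref:
            continue
        tstat, pval = stats.ttest_ind(samples[code], ref_vals, equal_var=True)
        if bonferroni:
            pval = min(1.0, pval * k)
        rows.append(
            {
                "pattern": code,
                "diff": float(np.mean(samples[code]) - np.mean(ref_vals)),
                "t": float(tstat),
                "p": float(pval),
            }
        )
    return AnovaResult(
        response=response,
        f=float(f),
        df_between=len(surviving) - 1,
        df_within=n_total - len(surviving),
        p=float(p),
        groups=groups,
        contrasts=pd.DataFrame(rows, columns=["pattern", "diff", "t", "p"]),
        dropped_groups=list(dropped),
        min_group_n=min_group_n,
        reference=ref,
    )


def plot_group_means(result: AnovaResult, path: str | Path, label: str = "") -> None:
    """Bar plot of per-group response means keyed by pattern code."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(result.groups)), 3.5))
    ax.bar(result.groups["pattern"], result.groups["mean"], color="#4878a8")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_ylabel(f"mean {result.response}")
    ax.set_xlabel(label or "combination pattern (1 = above median)")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_FLOAT_FMT = "%.12g"


def save_elimination(result: EliminationResult, out_dir: str | Path, stem: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab = result.retained.copy()
    tab.insert(0, "predictor", tab.index)
    tab.to_csv(out / f"{stem}_coefficients.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(result.removed_trace, columns=["predictor", "p_at_removal"]).to_csv(
        out / f"{stem}_trace.csv", index=False, float_format=_FLOAT_FMT
    )


def save_anova(result: AnovaResult, out_dir: str | Path, stem: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = pd.DataFrame(
        [
            {
                "response": result.response,
                "F": result.f,
                "df_between": result.df_between,
                "df_within": result.df_within,
                "p": result.p,
                "reference": result.reference,
                "min_group_n": result.min_group_n,
                "dropped_groups": ";".join(result.dropped_groups),
            }
        ]
    )
    summary.to_csv(out / f"{stem}_anova.csv", index=False, float_format=_FLOAT_FMT)
    result.groups.to_csv(out / f"{stem}_groups.csv", index=False, float_format=_FLOAT_FMT)
    result.contrasts.to_csv(out / f"{stem}_contrasts.csv", index=False, float_format=_FLOAT_FMT)
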