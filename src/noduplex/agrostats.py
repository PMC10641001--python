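"""Agronomic trait statistics for balanced factorial block designs.

Classical balanced two-factor (variety x treatment) ANOVA with a block term
for randomized-complete-block trials, standard error of a difference (SED),
5% least significant difference (LSD) and residual CV, a compact letter
display for LSD mean separation, percent-change summaries between treatments,
one-way ANOVA with Tukey post-hoc letters, and pairwise Pearson trait
correlations.

The RCBD ANOVA is computed by direct balanced deviation sums of squares
(everything reduces to cell/marginal means under balance), which keeps the
null-simulation workload cheap; it refuses unbalanced tables rather than
silently switching to a different sum-of-squares type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "rcbd_factorial_anova",
    "compact_letter_display",
    "percent_change",
    "oneway_anova_tukey",
    "pearson_correlations",
]


@dataclass
class AnovaResult:
    """Balanced RCBD factorial ANOVA summary for one trait."""

    trait: str
    table: pd.DataFrame  # source x (df, SS, MS, F, p)
    grand_mean: float
    cell_means: pd.DataFrame  # variety x treatment
    sed: float
    lsd5: float
    cv_percent: float
    letters: dict[tuple[str, str], str]  # (variety, treatment) -> letters


def _require_balanced(df: pd.DataFrame) -> tuple[list, list, list, int]:
    varieties = sorted(df["variety"].unique())
    treatments = sorted(df["treatment"].unique())
    blocks = sorted(df["block"].unique())
    cv_ = pd.Categorical(df["variety"], categories=varieties).codes.astype(np.int64)
    ct_ = pd.Categorical(df["treatment"], categories=treatments).codes.astype(np.int64)
    cb_ = pd.Categorical(df["block"], categories=blocks).codes.astype(np.int64)
    n_cells = len(varieties) * len(treatments) * len(blocks)
    sizes = np.bincount((cv_ * len(treatments) + ct_) * len(blocks) + cb_,
                        minlength=n_cells)
    if sizes.min() != sizes.max():
        raise ValueError(
            "table is unbalanced: every variety x treatment x block cell must "
            "appear the same number of times"
        )
    return varieties, treatments, blocks, int(sizes[0])


def rcbd_factorial_anova(table: pd.DataFrame, trait: str) -> AnovaResult:
    """Balanced RCBD two-factor ANOVA with SED, LSD(5%), CV and letters.

    ``table`` is long-format with columns variety, treatment, block, trait,
    value (or variety/treatment/block/value for a single-trait table). Blocks
    are complete replicates; with several biological experiments, pass a
    combined block label (e.g. "exp1/b2") so each is a complete replicate.

    SED = sqrt(2 MSE / r) for cell means (r = replicates per cell),
    LSD5 = t(0.975, df_error) * SED, CV% = 100 sqrt(MSE) / grand mean.
    """
    df = table
    if "trait" in df.columns:
        df = df[df["trait"] == trait]
        if df.empty:
            raise ValueError(f"no rows for trait {trait!r}")
    for col in ("variety", "treatment", "block", "value"):
        if col not in df.columns:
            raise ValueError(f"trait table lacks required column {col!r}")
    varieties, treatments, blocks, n_rep = _require_balanced(df)
    if len(blocks) < 2:
        raise ValueError("need at least two blocks")
    y = df["value"].to_numpy(dtype=float)
    N = y.size
    grand = float(y.mean())
    ss_total = float(((y - grand) ** 2).sum())

    cv_ = pd.Categorical(df["variety"], categories=varieties).codes
    ct_ = pd.Categorical(df["treatment"], categories=treatments).codes
    cb_ = pd.Categorical(df["block"], categories=blocks).codes

    def ss_factor(codes: np.ndarray) -> float:
        counts = np.bincount(codes)
        means = np.bincount(codes, weights=y) / counts
        return float((counts * (means - grand) ** 2).sum())

    ss_block = ss_factor(cb_)
    ss_a = ss_factor(cv_)
    ss_b = ss_factor(ct_)
    ss_cells = ss_factor(cv_ * len(treatments) + ct_)
    ss_ab = ss_cells - ss_a - ss_b
    # guard against tiny negative round-off in degenerate (e.g. constant) data
    ss_err = max(ss_total - ss_block - ss_cells, 0.0)
    a, b, r = len(varieties), len(treatments), len(blocks)
    dfs = {
        "block": r - 1,
        "variety": a - 1,
        "treatment": b - 1,
        "variety:treatment": (a - 1) * (b - 1),
    }
    df_err = N - 1 - sum(dfs.values())
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = ss_err / df_err
    rows = []
    for source, ss in (
        ("block", ss_block),
        ("variety", ss_a),
        ("treatment", ss_b),
        ("variety:treatment", ss_ab),
    ):
        dof = dfs[source]
        ms = ss / dof if dof else np.nan
        f = ms / mse if mse > 0 else np.inf
        p = float(stats.f.sf(f, dof, df_err)) if np.isfinite(f) else 0.0
        rows.append((source, dof, ss, ms, f, p))
    rows.append(("error", df_err, ss_err, mse, np.nan, np.nan))
    rows.append(("total", N - 1, ss_total, np.nan, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"]).set_index(
        "source"
    )

    cell_means = (
        df.groupby(["variety", "treatment"])["value"].mean().unstack("treatment")
    )
    r_cell = r * n_rep  # observations per variety x treatment cell
    sed = float(np.sqrt(2.0 * mse / r_cell))
    lsd5 = float(stats.t.ppf(0.975, df_err) * sed)
    cv = float(100.0 * np.sqrt(mse) / grand) if grand != 0 else np.inf
    means_flat = cell_means.stack()
    means_flat.index = [(v, t) for v, t in means_flat.index]
    letters = compact_letter_display(means_flat, lsd5)
    return AnovaResult(
        trait=trait,
        table=anova,
        grand_mean=grand,
        cell_means=cell_means,
        sed=sed,
        lsd5=lsd5,
        cv_percent=cv,
        letters=letters,
    )


def compact_letter_display(means: pd.Series, lsd5: float) -> dict:
    """Letters for LSD mean separation (insert-and-absorb).

    Means sorted descending; every maximal run of means whose extremes differ
    by less than ``lsd5`` becomes one letter class, assigned 'a' from the
    largest mean downwards. Two cells share a letter iff they differ by less
    than ``lsd5``; deterministic.
    """
    if lsd5 < 0:
        raise ValueError("lsd5 must be non-negative")
    order = means.sort_values(ascending=False, kind="mergesort")
    keys = list(order.index)
    vals = order.to_numpy(dtype=float)
    def differs(i: int, j: int) -> bool:
        gap = vals[min(i, j)] - vals[max(i, j)]
        return gap >= lsd5 and gap > 0  # equal means never separate

    return _letters_for_sorted(keys, differs)


def _letters_for_sorted(keys, differs) -> dict:
    """Letter classes as maximal non-differing runs over descending means.

    ``differs(i, j)`` reports whether any pair within positions [i, j] is
    significantly different. Each maximal extensible run gets one letter;
    runs contained in an earlier, wider run are absorbed.
    """
    n = len(keys)
    intervals: list[tuple[int, int]] = []
    last_end = -1
    for i in range(n):
        j = i
        while j + 1 < n and not differs(i, j + 1):
            j += 1
        if j > last_end or not intervals:
            intervals.append((i, j))
            last_end = j
    letters = {k: "" for k in keys}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, (i, j) in zip(alphabet, intervals):
        for k in range(i, j + 1):
            letters[keys[k]] += letter
    return letters


def percent_change(
    cell_means: pd.DataFrame,
    baseline: str,
    comparison: str,
    ndigits: int | None = 0,
) -> tuple[pd.Series, float]:
    """Percent change of each variety's mean between two treatments.

    Returns (per-variety percent changes, maximum across varieties), as
    100 (comparison - baseline) / baseline, rounded to ``ndigits`` (default
    nearest integer; ``None`` disables rounding). A zero baseline is an
    error naming the offending cell.
    """
    for t in (baseline, comparison):
        if t not in cell_means.columns:
            raise ValueError(f"treatment {t!r} not present in the cell-mean table")
    zero = cell_means.index[cell_means[baseline] == 0]
    if len(zero):
        raise ZeroDivisionError(
            f"baseline mean is zero for cell ({zero[0]!r}, {baseline!r})"
        )
    pct = 100.0 * (cell_means[comparison] - cell_means[baseline]) / cell_means[baseline]
    if ndigits is not None:
        pct = pct.round(ndigits)
    return pct, float(pct.max())


def oneway_anova_tukey(
    groups: dict[str, "np.ndarray"], alpha: float = 0.05
) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA with Tukey-HSD letter display.

    Returns (F, p, letters). Letters come from the Tukey pairwise rejection
    pattern: descending group means are split into maximal runs containing no
    rejected pair.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    f, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    reject = {}
    res = tk.summary().data[1:]
    for row in res:
        g1, g2 = str(row[0]), str(row[1])
        reject[frozenset((g1, g2))] = bool(row[-1] is True or str(row[-1]) == "True")
    means = pd.Series({g: a.mean() for g, a in zip(names, arrays)})
    order = means.sort_values(ascending=False, kind="mergesort")
    keys = list(order.index)

    def differs(i: int, j: int) -> bool:
        lo, hi = min(i, j), max(i, j)
        return any(
            reject.get(frozenset((keys[a], keys[b])), False)
            for a in range(lo, hi + 1)
            for b in range(a + 1, hi + 1)
        )

    letters = _letters_for_sorted(keys, differs)
    return float(f), float(p), letters


def pearson_correlations(
    table: pd.DataFrame, traits: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among traits with two-sided p-values.

    ``table`` is wide-format (one column per trait, rows are experimental
    units). Returns (r matrix, p matrix); a zero-variance trait yields NaN
    entries flagged by a warning from scipy.
    """
    for t in traits:
        if t not in table.columns:
            raise ValueError(f"trait {t!r} missing from table")
    sub = table[traits].dropna()
    if len(sub) < 3:
        raise ValueError("need at least three paired observations")
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            if sub[a].std() == 0 or sub[b].std() == 0:
                rr, pp = np.nan, np.nan
            else:
                rr, pp = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p
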