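"""Change-factor (V) competitiveness statistics from nodule occupancy counts.

The competitiveness of each strain of a mixed inoculant is quantified by
comparing its share among nodule isolates with its share in the plated
starter mix:

* a *correction factor* per strain and experiment — the realized inoculum
  proportion, estimated from plated colony counts with an optional
  pseudocount;
* the *enrichment ratio* r_s = p_nodule,s / p_inoculum,s;
* the *change factor* V_s — r_s truncated to zero for depleted strains
  (r < 1), the form in which per-strain changes are reported;
* the *percent of mix* — enrichment ratios averaged across the independent
  biological experiments and normalized to sum to 100, with a standard error
  from the per-experiment percentage vectors.

Percentages are computed from the untruncated mean ratios: averaging first
and normalizing once keeps the statistic a consistent estimator of the
underlying competitiveness weights, while the zero-truncation is applied only
to the reported V values (it is a presentation convention, not part of the
estimator). Per-experiment normalization and truncated percentages remain
available through flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprint import UNASSIGNED

__all__ = [
    "IsolateCountTable",
    "ChangeFactorResult",
    "estimate_mix_proportions",
    "enrichment_ratios",
    "change_factor",
    "percent_of_mix",
    "compute_change_factors",
    "competition_report",
    "counts_from_assignments",
]


@dataclass
class IsolateCountTable:
    """Per-strain isolate counts for one sample (inoculum or nodule origin)."""

    counts: pd.Series  # index: strain tags, values: non-negative ints
    source: str  # "inoculum" | "nodule"
    variety: str = ""
    treatment: str = ""
    experiment: int = 1

    def __post_init__(self) -> None:
        if self.source not in ("inoculum", "nodule"):
            raise ValueError("source must be 'inoculum' or 'nodule'")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ChangeFactorResult:
    """Per-strain change factors and percent-of-mix across experiments."""

    tags: list[str]
    correction_factor: pd.DataFrame  # experiments x tags: inoculum proportions
    ratios: pd.DataFrame  # experiments x tags: untruncated enrichment ratios
    v: pd.DataFrame  # experiments x tags: ratios truncated at zero for depletion
    percent: pd.DataFrame  # experiments x tags: per-experiment percentages
    mean_percent: pd.Series
    se_percent: pd.Series
    n_experiments: int
    flags: list[str] = field(default_factory=list)


def estimate_mix_proportions(counts: pd.Series, pseudocount: float = 0.5) -> pd.Series:
    """Realized inoculum mix proportions from plated colony counts.

    p_s = (count_s + pseudocount) / (n + S * pseudocount). The pseudocount
    guards against strains that a finite plating missed entirely, which would
    otherwise leave their enrichment ratio undefined.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = pd.Series(counts, dtype=float)
    total = counts.sum() + pseudocount * len(counts)
    if total <= 0:
        raise ValueError("all counts are zero and pseudocount is 0: proportions undefined")
    return (counts + pseudocount) / total


def enrichment_ratios(p_inoc: pd.Series, nodule_counts: pd.Series) -> pd.Series:
    """Untruncated enrichment ratios r_s = p_nodule,s / p_inoculum,s."""
    p_inoc = pd.Series(p_inoc, dtype=float)
    nodule_counts = pd.Series(nodule_counts, dtype=float)
    if abs(p_inoc.sum() - 1.0) > 1e-9:
        raise ValueError("inoculum proportions must sum to 1")
    n = nodule_counts.sum()
    if n <= 0:
        raise ValueError("nodule sample is empty (n = 0)")
    p_nod = nodule_counts / n
    bad = (p_inoc == 0) & (p_nod > 0)
    if bad.any():
        raise ZeroDivisionError(
            f"strains {list(p_inoc.index[bad])} appear in nodules but have zero "
            "inoculum proportion; re-estimate the mix with a pseudocount > 0"
        )
    with np.errstate(invalid="ignore"):
        r = (p_nod / p_inoc).fillna(0.0)
    return r


def change_factor(p_inoc: pd.Series, nodule_counts: pd.Series) -> pd.Series:
    """Change factor V per strain: the enrichment ratio, zero for depletion.

    Ratios below 1 mark strains depleted between inoculum and nodules; their
    change factors are set to zero for presentation.
    """
    r = enrichment_ratios(p_inoc, nodule_counts)
    return r.where(r >= 1.0, 0.0)


def percent_of_mix(
    ratios: pd.DataFrame,
    per_experiment: bool = False,
    truncate_percents: bool = False,
) -> ChangeFactorResult:
    """Summarize enrichment ratios across experiments as percent of mix.

    Parameters
    ----------
    ratios : DataFrame
        Untruncated enrichment ratios, experiments x strains.
    per_experiment : bool
        If True, normalize within each experiment first and average the
        percentage vectors (each experiment's bar heights sum to 100). The
        default averages the ratios across experiments before normalizing
        once, which is the less biased estimator of the competitiveness
        weights; the point estimates still sum to 100.
    truncate_percents : bool
        If True, compute percentages from the zero-truncated change factors
        instead of the raw ratios (percentages of depleted strains become 0
        and the displayed bars no longer need to sum to 100 within rounding).
    """
    ratios = pd.DataFrame(ratios, dtype=float)
    if ratios.shape[0] < 1:
        raise ValueError("need at least one experiment")
    flags: list[str] = []
    tags = list(ratios.columns)
    v = ratios.where(ratios >= 1.0, 0.0)
    basis = v if truncate_percents else ratios

    def normalize(vec: pd.Series) -> pd.Series:
        s = vec.sum()
        if s <= 0:
            return pd.Series(0.0, index=vec.index)
        return 100.0 * vec / s

    zero_rows = basis.sum(axis=1) <= 0
    if zero_rows.any():
        flags.append("all-zero")
        warnings.warn(
            "every change factor is zero in at least one experiment; "
            "those percentages are reported as 0",
            stacklevel=2,
        )
    percent = basis.apply(normalize, axis=1)
    if per_experiment:
        mean_percent = percent.mean(axis=0)
    else:
        mean_percent = normalize(basis.mean(axis=0))
    k = ratios.shape[0]
    if k > 1:
        se_percent = percent.std(axis=0, ddof=1) / np.sqrt(k)
    else:
        se_percent = pd.Series(0.0, index=tags)
        flags.append("k=1")
    return ChangeFactorResult(
        tags=tags,
        correction_factor=pd.DataFrame(index=ratios.index, columns=tags, dtype=float),
        ratios=ratios,
        v=v,
        percent=percent,
        mean_percent=mean_percent,
        se_percent=se_percent,
        n_experiments=k,
        flags=flags,
    )


def compute_change_factors(
    inoculum_counts: pd.DataFrame,
    nodule_counts: pd.DataFrame,
    pseudocount: float = 0.5,
    per_experiment: bool = False,
    truncate_percents: bool = False,
) -> ChangeFactorResult:
    """Full change-factor computation from count tables (experiments x tags)."""
    inoculum_counts = pd.DataFrame(inoculum_counts)
    nodule_counts = pd.DataFrame(nodule_counts)
    if not inoculum_counts.index.equals(nodule_counts.index) or list(
        inoculum_counts.columns
    ) != list(nodule_counts.columns):
        raise ValueError("inoculum and nodule tables must share experiments and strains")
    p_rows, r_rows = {}, {}
    for exp in inoculum_counts.index:
        p = estimate_mix_proportions(inoculum_counts.loc[exp], pseudocount)
        p_rows[exp] = p
        r_rows[exp] = enrichment_ratios(p, nodule_counts.loc[exp])
    correction = pd.DataFrame(p_rows).T
    ratios = pd.DataFrame(r_rows).T
    result = percent_of_mix(
        ratios, per_experiment=per_experiment, truncate_percents=truncate_percents
    )
    result.correction_factor = correction
    return result


def counts_from_assignments(
    assignments: pd.DataFrame, tags: list[str], drop_unassigned: bool = True
) -> pd.DataFrame:
    """Tabulate typed isolates into an experiments x tags count table.

    Unassigned isolates are excluded (the sample size shrinks accordingly)
    but their number is recorded in ``attrs["n_unassigned"]``.
    """
    n_unassigned = int((assignments["assigned_tag"] == UNASSIGNED).sum())
    kept = assignments[assignments["assigned_tag"] != UNASSIGNED]
    if not drop_unassigned and n_unassigned:
        raise ValueError("unassigned isolates present and drop_unassigned is False")
    table = (
        kept.groupby(["experiment", "assigned_tag"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=tags, fill_value=0)
        .reindex(index=sorted(assignments["experiment"].unique()), fill_value=0)
    )
    table.index.name = "experiment"
    table.columns.name = None
    table.attrs["n_unassigned"] = n_unassigned
    return table


def competition_report(results: dict[str, ChangeFactorResult]) -> pd.DataFrame:
    """Tidy ranking table across varieties.

    One row per variety x strain with mean percent, SE and the rank of the
    strain within its variety (descending percent, alphabetical tie-break).
    """
    if not results:
        raise ValueError("no results to report")
    rows = []
    for variety, res in results.items():
        order = sorted(res.tags, key=lambda t: (-res.mean_percent[t], t))
        all_zero = bool((res.mean_percent <= 0).all())
        for pos, tag in enumerate(order, start=1):
            rows.append(
                {
                    "variety": variety,
                    "strain": tag,
                    "mean_percent": float(res.mean_percent[tag]),
                    "se_percent": float(res.se_percent[tag]),
                    "rank": 1 if all_zero else pos,
                    "flag": "all-zero" if all_zero else "",
                }
            )
    return pd.DataFrame(rows)
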