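"""Cross-species synthesis: group means, one-tailed Welch tests, counts.

The comparative stage takes Table-1-style summary rows (one per species x
marker partition) and asks whether differentiation statistics differ, on
average, between bryophytes and spermatophytes, separately for cpDNA, nDNA
and both markers combined.  A transcription of the published 28-species
summary table ships with the package as a worked fixture.

Outlier exclusions are explicit configuration, never auto-detected; the
default excludes the Pulvigera lyellii cpDNA row (Gst = Nst = 0.77, near
complete North/South allele segregation).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import SpeciesSummary
from .errors import InputError

#: (species, partition) rows excluded from group synthesis by default
DEFAULT_EXCLUSIONS: tuple[tuple[str, str], ...] = (("Pulvigera lyellii", "cpDNA"),)

_NUMERIC = [
    "gst", "p_gst", "gst_jack_mean", "gst_jack_halfwidth",
    "nst", "p_nst", "nst_jack_mean", "nst_jack_halfwidth", "p_nst_gt_gst",
]


def load_table1() -> pd.DataFrame:
    """The packaged 28-species summary table (rounded published values)."""
    ref = importlib.resources.files("hapstruct.data") / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def summaries_to_frame(rows: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Convert SpeciesSummary objects into the comparative table layout."""
    recs = []
    for r in rows:
        rec = {
            "species": r.species, "group": r.group, "partition": r.partition,
            "n_individuals": r.n_individuals, "n_loci": r.n_loci,
        }
        rec.update({c: getattr(r, c) for c in _NUMERIC})
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def _select(
    rows: pd.DataFrame,
    statistic: str,
    partition: str,
    group: str,
    exclusions: Sequence[tuple[str, str]] = (),
) -> pd.Series:
    if statistic not in rows.columns:
        raise InputError(f"unknown statistic column {statistic!r}")
    sel = rows[(rows["partition"] == partition) & (rows["group"] == group)]
    for species, part in exclusions:
        sel = sel[~((sel["species"] == species) & (sel["partition"] == part))]
    return sel[statistic].dropna()


def group_mean_sd(
    rows: pd.DataFrame,
    statistic: str,
    partition: str,
    group: str,
    exclusions: Sequence[tuple[str, str]] = (),
) -> tuple[float, float, int]:
    """Unweighted mean and sample SD of a statistic over a group's species."""
    vals = _select(rows, statistic, partition, group, exclusions)
    if len(vals) < 2:
        raise InputError(
            f"fewer than 2 usable rows for {statistic} / {partition} / {group}"
        )
    return float(vals.mean()), float(vals.std(ddof=1)), len(vals)


@dataclass
class GroupComparison:
    """One-tailed Welch comparison of a statistic between two groups."""

    statistic_name: str
    partition: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    welch_t: float
    welch_df: float
    p_one_tailed: float
    direction: str
    excluded: list[tuple[str, str]] = field(default_factory=list)


def welch_one_tailed(
    a: Sequence[float], b: Sequence[float], direction: str = "a_greater",
    statistic_name: str = "", partition: str = "",
    excluded: Sequence[tuple[str, str]] = (),
) -> GroupComparison:
    """Welch t-test (unequal variances, Satterthwaite df), one-tailed.

    direction "a_greater" tests H1: mean(a) > mean(b); "b_greater" the
    reverse.  Zero variance in both groups with equal means yields the
    p = 0.5 convention.
    """
    if direction not in ("a_greater", "b_greater"):
        raise InputError(f"unknown direction {direction!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0 and a.mean() == b.mean():
        t, df, p = 0.0, float(len(a) + len(b) - 2), 0.5
    else:
        alt = "greater" if direction == "a_greater" else "less"
        res = sps.ttest_ind(a, b, equal_var=False, alternative=alt)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        statistic_name=statistic_name, partition=partition,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        welch_t=t, welch_df=df, p_one_tailed=p, direction=direction,
        excluded=list(excluded),
    )


def compare_groups(
    rows: pd.DataFrame,
    statistic: str,
    partition: str,
    group_a: str = "spermatophyte",
    group_b: str = "bryophyte",
    direction: str = "a_greater",
    exclusions: Sequence[tuple[str, str]] = DEFAULT_EXCLUSIONS,
) -> GroupComparison:
    """Welch comparison of a summary statistic between the two plant groups."""
    a = _select(rows, statistic, partition, group_a, exclusions)
    b = _select(rows, statistic, partition, group_b, exclusions)
    return welch_one_tailed(
        a, b, direction=direction, statistic_name=statistic,
        partition=partition, excluded=list(exclusions),
    )


def count_significant(
    rows: pd.DataFrame,
    partition: str,
    group: str,
    column: str,
    alpha: float = 0.05,
    exclusions: Sequence[tuple[str, str]] = (),
) -> int:
    """Number of non-NA p-values strictly below alpha in a group x partition."""
    if column not in ("p_gst", "p_nst", "p_nst_gt_gst"):
        raise InputError(f"{column!r} is not a p-value column")
    vals = _select(rows, column, partition, group, exclusions)
    return int((vals < alpha).sum())
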