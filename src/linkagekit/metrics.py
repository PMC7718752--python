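"""Map summary statistics, genome coverage and paired map comparisons.

Genome coverage is the expected fraction of the genome within ``d`` cM of a
mapped marker,

    GC = 1 - exp(-2 d n / L),

where ``d`` is the average spacing between unique mapping positions, ``n``
the total marker count, and ``L`` the summed linkage-group length after
extending each group by ``2 d`` (a group's ends are assumed to reach half a
marker spacing beyond its terminal markers on either side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import LinkageMap


@dataclass
class MapSummary:
    """Summary statistics of one linkage map."""

    family: str
    lengths: dict[str, float]  # per linkage group, max - min cM
    n_markers: int
    d: float  # average spacing between unique positions, pooled over groups
    L: float  # sum of (length_i + 2 d)
    genome_coverage: float
    single_position_groups: list[str] = field(default_factory=list)

    @property
    def sum_of_lengths(self) -> float:
        return float(sum(self.lengths.values()))


def map_summary(lmap: LinkageMap) -> MapSummary:
    """Compute per-group lengths, pooled average spacing and genome coverage.

    Average spacing ``d`` pools gaps between unique cM positions across
    groups: sum of within-group gaps divided by sum of (unique positions -
    1).  Groups with a single unique position contribute no gaps; they are
    flagged and excluded from ``d`` but still counted in markers and length.
    """
    lengths: dict[str, float] = {}
    flagged: list[str] = []
    gap_sum = 0.0
    gap_n = 0
    for lg in lmap.linkage_groups:
        pos = np.sort(lmap.group(lg)["position_cm"].to_numpy(dtype=float))
        lengths[lg] = float(pos[-1] - pos[0])
        unique = np.unique(pos)
        if unique.size < 2:
            flagged.append(lg)
            continue
        gap_sum += float(unique[-1] - unique[0])
        gap_n += unique.size - 1
    if gap_n == 0:
        raise ValueError("no linkage group has >= 2 unique positions")
    d = gap_sum / gap_n
    n = len(lmap.entries)
    gc, L = genome_coverage(d, n, list(lengths.values()), return_L=True)
    return MapSummary(
        family=lmap.family,
        lengths=lengths,
        n_markers=n,
        d=d,
        L=L,
        genome_coverage=gc,
        single_position_groups=flagged,
    )


def genome_coverage(d: float, n: int, lg_lengths, return_L: bool = False):
    """GC = 1 - exp(-2 d n / L) with L = sum(length_i + 2 d) over groups."""
    lengths = np.asarray(lg_lengths, dtype=float)
    L = float(np.sum(lengths + 2.0 * d))
    if L <= 0:
        raise ValueError("total extended map length must be positive")
    gc = 1.0 - np.exp(-2.0 * d * n / L)
    return (gc, L) if return_L else gc


def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t-test on per-family values of two methods.

    Returns ``(t, df, p)`` with a two-sided p-value; df = k - 1.  If every
    difference is zero the test degenerates to t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diffs = x - y
    if np.all(diffs == 0):
        return 0.0, x.size - 1, 1.0
    if np.std(diffs, ddof=1) == 0:  # constant nonzero difference
        return float(np.sign(diffs[0]) * np.inf), x.size - 1, 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def compare_map_sets(
    summaries_a: list[MapSummary], summaries_b: list[MapSummary], labels=("A", "B")
) -> pd.DataFrame:
    """Side-by-side summary table for two map sets over the same families,
    with paired t-tests on sum of lengths, marker totals, spacing and
    genome coverage (one row per family, then mean / t / p rows)."""
    if len(summaries_a) != len(summaries_b):
        raise ValueError("map sets must cover the same families")
    cols: dict[str, list] = {"family": [s.family for s in summaries_a]}
    for label, summaries in zip(labels, (summaries_a, summaries_b)):
        cols[f"sum_lengths_{label}"] = [s.sum_of_lengths for s in summaries]
        cols[f"n_markers_{label}"] = [s.n_markers for s in summaries]
        cols[f"spacing_{label}"] = [s.d for s in summaries]
        cols[f"coverage_{label}"] = [s.genome_coverage for s in summaries]
    df = pd.DataFrame(cols)
    mean_row: dict = {"family": "mean"}
    t_row: dict = {"family": "t"}
    p_row: dict = {"family": "p"}
    for quantity in ("sum_lengths", "n_markers", "spacing", "coverage"):
        a = df[f"{quantity}_{labels[0]}"]
        b = df[f"{quantity}_{labels[1]}"]
        t, _, p = paired_t(a, b)
        mean_row[f"{quantity}_{labels[0]}"] = a.mean()
        mean_row[f"{quantity}_{labels[1]}"] = b.mean()
        t_row[f"{quantity}_{labels[0]}"] = t
        p_row[f"{quantity}_{labels[0]}"] = p
    return pd.concat([df, pd.DataFrame([mean_row, t_row, p_row])], ignore_index=True)


__all__ = ["MapSummary", "map_summary", "genome_coverage", "paired_t", "compare_map_sets"]
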