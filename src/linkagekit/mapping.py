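"""Minimal linkage-map arithmetic.

Mapping functions (Haldane, Kosambi), recombination-fraction estimation for
phase-known gametes and F2 intercross genotype tables, identical-marker
collapsing, and rank-order map comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats


def mapping_distance(r, function: str = "haldane", inverse: bool = False):
    """Convert recombination fraction to map distance (cM), or back.

    Haldane (no interference): d = -50 ln(1 - 2r).
    Kosambi (partial interference): d = 25 ln((1 + 2r) / (1 - 2r)).

    With ``inverse=True`` the argument is a distance in cM and the
    recombination fraction is returned; forward and inverse are exact
    round-trips.
    """
    x = np.asarray(r, dtype=float)
    if function not in ("haldane", "kosambi"):
        raise ValueError(f"unknown mapping function {function!r}")
    if inverse:
        if np.any(x < 0):
            raise ValueError("map distance must be >= 0")
        if function == "haldane":
            out = 0.5 * (1.0 - np.exp(-x / 50.0))
        else:
            out = 0.5 * np.tanh(x / 50.0)
    else:
        if np.any((x < 0) | (x >= 0.5)):
            raise ValueError("recombination fraction must lie in [0, 0.5)")
        if function == "haldane":
            out = -50.0 * np.log1p(-2.0 * x)
        else:
            out = 25.0 * (np.log1p(2.0 * x) - np.log1p(-2.0 * x))
    return out.item() if np.isscalar(r) or np.ndim(r) == 0 else out


def intercross_joint_probs(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities for two linked loci in an F2
    intercross (both parents doubly heterozygous, coupling phase).

    Rows/columns index the genotype at locus 1/2 as allele dosage 0, 1, 2.
    """
    # gamete haplotype probabilities: AB, Ab, aB, ab
    g = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
    dose1 = np.array([1, 1, 0, 0])
    dose2 = np.array([1, 0, 1, 0])
    probs = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            probs[dose1[i] + dose1[j], dose2[i] + dose2[j]] += g[i] * g[j]
    return probs


def estimate_rf(counts) -> float:
    """Estimate the recombination fraction between two loci.

    ``counts`` is either a ``(recombinants, total)`` pair of phase-known
    gamete counts — the estimate is the simple proportion — or a 3x3 array
    of joint F2 intercross genotype counts (allele-dosage order), for which
    the maximum-likelihood estimate is located by bounded scalar search on
    [0, 0.5).
    """
    arr = np.asarray(counts)
    if arr.shape == (2,):
        rec, total = arr
        if total <= 0:
            raise ValueError("need at least one gamete")
        if rec > total or rec < 0:
            raise ValueError("recombinants must lie in [0, total]")
        return float(rec) / float(total)
    if arr.shape != (3, 3):
        raise ValueError("counts must be (recombinants, total) or a 3x3 table")
    if arr.sum() <= 0:
        raise ValueError("need at least one individual")

    def nll(r: float) -> float:
        p = intercross_joint_probs(r)
        return -float(np.sum(arr * np.log(np.maximum(p, 1e-300))))

    res = optimize.minimize_scalar(nll, bounds=(1e-9, 0.5 - 1e-9), method="bounded")
    return float(res.x)


def positions_from_rf(adjacent_r, function: str = "haldane") -> np.ndarray:
    """Cumulative cM positions from adjacent recombination fractions.

    position[0] = 0 and position[i] = position[i-1] + d(r_i).
    """
    rs = np.asarray(adjacent_r, dtype=float)
    if rs.size == 0:
        return np.array([0.0])
    d = np.atleast_1d(mapping_distance(rs, function))
    return np.concatenate([[0.0], np.cumsum(d)])


def map_from_gametes(gametes: pd.DataFrame, function: str = "haldane") -> np.ndarray:
    """Cumulative cM positions from a phase-known gamete haplotype matrix.

    ``gametes`` is markers (in map order) x gametes with 0/1 parental
    haplotype codes; adjacent recombinant fractions are the observed
    mismatch proportions.  Fractions at or above 0.5 (possible by sampling
    noise between distant markers) are clipped just below 0.5.
    """
    h = gametes.to_numpy()
    if h.shape[0] < 2:
        return np.zeros(h.shape[0])
    rec = (h[1:] != h[:-1]).mean(axis=1)
    rec = np.minimum(rec, 0.5 - 1e-9)
    return positions_from_rf(rec, function)


def collapse_identicals(genotypes: pd.DataFrame):
    """Group markers with identical genotype vectors; return representatives.

    Two markers are identical only if they agree at every individual,
    including the pattern of missing calls.  The representative of each
    group is the first member in input order.

    Returns ``(representatives, groups)`` where ``representatives`` is the
    reduced DataFrame and ``groups`` maps each representative marker to the
    full list of member markers (representative first).
    """
    keys: dict[tuple, str] = {}
    groups: dict[str, list[str]] = {}
    filled = genotypes.fillna("\0NA")
    for marker, row in zip(filled.index, filled.to_numpy()):
        key = tuple(row)
        rep = keys.setdefault(key, marker)
        groups.setdefault(rep, []).append(marker)
    reps = list(groups)
    return genotypes.loc[reps], groups


def restore_identicals(groups: dict[str, list[str]]) -> list[str]:
    """All original markers, in representative order (inverse of collapse)."""
    return [m for members in groups.values() for m in members]


def rank_order_r2(pos_a, pos_b) -> float:
    """r-squared of the regression of one map's marker rank order on the
    other's, over common markers.

    ``pos_a`` and ``pos_b`` are cM positions (array-like, same marker
    order).  Ties receive average ranks.  A fully reversed order scores 1.0
    (ranks perfectly anti-correlated).
    """
    a = np.asarray(pos_a, dtype=float)
    b = np.asarray(pos_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 common markers")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    r = stats.pearsonr(ra, rb).statistic
    return float(r * r)


__all__ = [
    "mapping_distance",
    "estimate_rf",
    "intercross_joint_probs",
    "positions_from_rf",
    "map_from_gametes",
    "collapse_identicals",
    "restore_identicals",
    "rank_order_r2",
]
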