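"""Recombination-rate estimation and spatial analysis.

Chromosome-level rates from the two most distal mapped SNPs, a three-way
(family × sex × chromosome) ANOVA partitioning of rate variation,
Marey-map local-regression (loess) rate profiles, per-family
standardization with ±1.28 hot/cold thresholds, quadrat-based complete
spatial randomness tests, and centromere-region minimum-rate checks.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io import LinkageMap


# ---------------------------------------------------------------------------
# Chromosome-level RR


def chromosome_rr(cm, bp) -> float:
    """Chromosome-wide recombination rate in cM/Mb.

    Genetic distance between the two most distal SNPs (chosen by genetic
    position) divided by the physical distance between those same SNPs.
    """
    cm = np.asarray(cm, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if cm.size < 2:
        raise ValueError("need >= 2 mapped SNPs with physical positions")
    order = np.lexsort((bp, cm))  # genetic position first, bp breaks ties
    i_lo, i_hi = int(order[0]), int(order[-1])
    phys = abs(bp[i_hi] - bp[i_lo])
    if phys == 0:
        raise ValueError("zero physical span between distal SNPs")
    return float((cm[i_hi] - cm[i_lo]) / (phys / 1e6))


def rr_table(maps: list[LinkageMap], coords: pd.DataFrame, lg_to_chrom: dict[str, str]) -> pd.DataFrame:
    """Per family × sex × chromosome rates from per-parent maps.

    ``maps`` must be per-parent (``sire``/``dam``) linkage maps; each
    linkage group yields one row (family, sex, chrom, rr).
    """
    pos = coords.set_index("marker")["chrom_pos"]
    rows = []
    for lmap in maps:
        if lmap.parent not in ("sire", "dam"):
            raise ValueError("rr_table needs per-parent maps (sire/dam)")
        for lg in lmap.linkage_groups:
            sub = lmap.group(lg)
            bp = sub["marker"].map(pos)
            keep = bp.notna()
            if keep.sum() < 2:
                continue
            rr = chromosome_rr(sub.loc[keep, "position_cm"], bp[keep])
            rows.append((lmap.family, lmap.parent, lg_to_chrom.get(lg, lg), rr))
    return pd.DataFrame(rows, columns=["family", "sex", "chrom", "rr"])


@dataclass
class AnovaResult:
    """Three-way ANOVA of recombination rate with tailored error terms."""

    table: pd.DataFrame  # term, sum_sq, df, mean_sq, F, p, error_term
    grand_mean: float
    sex_means: dict[str, float]
    sex_difference: float  # dam - sire
    se_sex_difference: float
    residual_df: int
    model_df: int


def rr_anova(table: pd.DataFrame) -> AnovaResult:
    """Partition RR variance among family, sex and chromosome.

    The model has the three main effects and the three two-way
    interactions; with one observation per family × sex × chromosome cell
    the three-way interaction is the residual.  Because families and
    chromosomes are tested at the whole-parent level, the family and
    chromosome F ratios use the family × chromosome interaction mean
    square as denominator; sex and the interactions are tested against the
    residual.
    """
    required = {"family", "sex", "chrom", "rr"}
    if not required <= set(table.columns):
        raise ValueError(f"RR table needs columns {sorted(required)}")
    counts = table.groupby(["family", "sex", "chrom"]).size()
    full = table["family"].nunique() * table["sex"].nunique() * table["chrom"].nunique()
    if len(counts) != full or counts.nunique() != 1:
        raise ValueError(
            f"design is unbalanced: {len(counts)} of {full} cells filled, "
            f"cell sizes {sorted(counts.unique())}"
        )
    model = smf.ols(
        "rr ~ C(family) + C(sex) + C(chrom) + C(family):C(sex) "
        "+ C(family):C(chrom) + C(sex):C(chrom)",
        data=table,
    ).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    ms = aov["sum_sq"] / aov["df"]
    ms_resid = float(ms["Residual"])
    ms_fxc = float(ms["C(family):C(chrom)"])
    df_resid = int(aov.loc["Residual", "df"])
    df_fxc = int(aov.loc["C(family):C(chrom)", "df"])
    error_for = {
        "C(family)": ("C(family):C(chrom)", ms_fxc, df_fxc),
        "C(chrom)": ("C(family):C(chrom)", ms_fxc, df_fxc),
        "C(sex)": ("Residual", ms_resid, df_resid),
        "C(family):C(sex)": ("Residual", ms_resid, df_resid),
        "C(family):C(chrom)": ("Residual", ms_resid, df_resid),
        "C(sex):C(chrom)": ("Residual", ms_resid, df_resid),
    }
    rows = []
    for term in aov.index:
        if term == "Residual":
            rows.append((term, aov.loc[term, "sum_sq"], int(aov.loc[term, "df"]),
                         ms_resid, np.nan, np.nan, ""))
            continue
        err_name, err_ms, err_df = error_for[term]
        f = float(ms[term] / err_ms)
        p = float(stats.f.sf(f, int(aov.loc[term, "df"]), err_df))
        rows.append((term, float(aov.loc[term, "sum_sq"]), int(aov.loc[term, "df"]),
                     float(ms[term]), f, p, err_name))
    out = pd.DataFrame(
        rows, columns=["term", "sum_sq", "df", "mean_sq", "F", "p", "error_term"]
    )
    sex_means = table.groupby("sex")["rr"].mean().to_dict()
    n_half = len(table) / 2
    diff = float(sex_means.get("dam", np.nan) - sex_means.get("sire", np.nan))
    se = math.sqrt(ms_resid * 2.0 / n_half)
    return AnovaResult(
        table=out,
        grand_mean=float(table["rr"].mean()),
        sex_means={k: float(v) for k, v in sex_means.items()},
        sex_difference=diff,
        se_sex_difference=se,
        residual_df=df_resid,
        model_df=int(aov["df"].drop("Residual").sum()),
    )


# ---------------------------------------------------------------------------
# Marey-map profiles


@dataclass
class RRProfile:
    """Local recombination rates along one chromosome.

    ``loci`` has columns bp, cm, rr (cM/Mb) for retained loci, ordered by
    bp and nondecreasing in cm; removed loci are listed with the reason.
    """

    loci: pd.DataFrame
    removed_outliers: list[float] = field(default_factory=list)  # bp of non-monotone loci
    removed_negative: list[float] = field(default_factory=list)  # bp of negative-RR loci
    span: float = 0.3
    degree: int = 1


def longest_nondecreasing(values) -> np.ndarray:
    """Indices of one longest nondecreasing subsequence (O(n log n))."""
    vals = np.asarray(values, dtype=float)
    tails: list[float] = []  # smallest tail value of a subsequence of each length
    tail_idx: list[int] = []
    prev = np.full(vals.size, -1)
    for i, v in enumerate(vals):
        j = bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[j] = v
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j else -1
    out = []
    i = tail_idx[-1] if tail_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1], dtype=int)


def _loess_slopes(x: np.ndarray, y: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Local-polynomial slope at each observed point.

    Tricube weights over the ``ceil(span * n)`` nearest neighbors; the
    slope is the linear coefficient of the local fit centered at the
    point."""
    n = x.size
    k = max(degree + 1, math.ceil(span * n))
    k = min(k, n)
    slopes = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(k)
        dx = x[idx] - x[i]
        design = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(np.maximum(w, 0))
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        slopes[i] = coef[1]
    return slopes


def marey_profile(bp, cm, span: float = 0.3, degree: int = 1) -> RRProfile:
    """Local recombination rates from a Marey map (bp, cM) of one
    chromosome in one family.

    Outlier loci whose genetic position does not increase monotonically
    with physical position are removed first by retaining one longest
    nondecreasing subsequence; a tricube-weighted local-linear fit then
    gives the local slope (cM/bp, reported as cM/Mb) at each retained
    locus; loci with negative rates are removed and the profile refit once
    on the remainder.
    """
    df = pd.DataFrame({"bp": np.asarray(bp, float), "cm": np.asarray(cm, float)})
    df = df.sort_values(["bp", "cm"], kind="stable").reset_index(drop=True)
    n = len(df)
    if n < max(5, math.ceil(span * n)):
        raise ValueError(f"need at least max(5, ceil(span*n)) points, got {n}")
    keep = longest_nondecreasing(df["cm"].to_numpy())
    removed_outliers = df.loc[~df.index.isin(keep), "bp"].tolist()
    df = df.iloc[keep].reset_index(drop=True)
    if len(df) < 5:
        raise ValueError("fewer than 5 loci remain after monotonicity filtering")
    x = df["bp"].to_numpy()
    y = df["cm"].to_numpy()
    rr = _loess_slopes(x, y, span, degree) * 1e6
    negative = rr < 0
    removed_negative = df.loc[negative, "bp"].tolist()
    if negative.any():
        df = df[~negative].reset_index(drop=True)
        if len(df) < 5:
            raise ValueError("fewer than 5 loci remain after negative-rate removal")
        rr = _loess_slopes(df["bp"].to_numpy(), df["cm"].to_numpy(), span, degree) * 1e6
    loci = df.assign(rr=rr)
    return RRProfile(loci, removed_outliers, removed_negative, span, degree)


def standardize(rr, threshold: float = 1.28) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize local rates of one family (genome-wide) to z-scores.

    Returns ``(z, hot, cold)`` where hot/cold are boolean masks for
    z > threshold and z < -threshold (nominal 90th/10th percentiles at
    1.28).  Rates should be pooled over the family's chromosomes so that
    families are comparable.
    """
    values = np.asarray(rr, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 retained loci")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant profile")
    z = (values - values.mean()) / sd
    return z, z > threshold, z < -threshold


def standardize_profiles(
    profiles: dict[str, RRProfile], threshold: float = 1.28, per_chromosome: bool = False
) -> pd.DataFrame:
    """Standardize one family's profiles; returns a long table (chrom, bp,
    cm, rr, z, hot, cold).  Standardization pools the family's chromosomes
    unless ``per_chromosome`` is set."""
    parts = [p.loci.assign(chrom=c) for c, p in profiles.items()]
    df = pd.concat(parts, ignore_index=True)
    if per_chromosome:
        pieces = []
        for _, sub in df.groupby("chrom", sort=False):
            z, hot, cold = standardize(sub["rr"], threshold)
            pieces.append(sub.assign(z=z, hot=hot, cold=cold))
        return pd.concat(pieces, ignore_index=True)
    z, hot, cold = standardize(df["rr"], threshold)
    return df.assign(z=z, hot=hot, cold=cold)


# ---------------------------------------------------------------------------
# Complete spatial randomness


@dataclass
class CSRResult:
    """Nine-quadrat Pearson chi-square test of complete spatial randomness."""

    chi_square: float
    df: int
    p_value: float
    tested: bool
    n: int
    reason: str = ""
    counts: np.ndarray | None = None

    def significant(self, alpha: float = 0.001) -> bool:
        return self.tested and self.p_value < alpha


def csr_quadrat_test(bp, z, min_n: int = 9) -> CSRResult:
    """Test whether extreme standardized rates are randomly scattered.

    The bounding rectangle [min bp, max bp] × [min z, max z] is divided
    into 3 × 3 equal-area quadrats; observed counts are compared to the
    uniform expectation n/9 by a Pearson chi-square with 8 df.  Fewer than
    ``min_n`` points, or a degenerate rectangle, yields an untested
    result.  Points below and above the threshold should be tested
    separately.
    """
    x = np.asarray(bp, dtype=float)
    y = np.asarray(z, dtype=float)
    n = x.size
    if n < min_n:
        return CSRResult(np.nan, 8, np.nan, False, n, reason=f"fewer than {min_n} observations")
    if x.max() == x.min() or y.max() == y.min():
        return CSRResult(np.nan, 8, np.nan, False, n, reason="degenerate bounding rectangle")
    ix = np.minimum((3 * (x - x.min()) / (x.max() - x.min())).astype(int), 2)
    iy = np.minimum((3 * (y - y.min()) / (y.max() - y.min())).astype(int), 2)
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    expected = n / 9.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 8))
    return CSRResult(chi2, 8, p, True, n, counts=counts)


def centromere_min_rr(profile: RRProfile, interval: tuple[int, int], genome_rr=None) -> dict:
    """Minimum local recombination rate inside a putative centromere
    interval, with its genome-wide quantile when ``genome_rr`` (pooled
    rates) is given.  No retained locus in the interval → flagged."""
    lo, hi = interval
    sub = profile.loci[(profile.loci["bp"] >= lo) & (profile.loci["bp"] <= hi)]
    if sub.empty:
        return {"flagged": True, "reason": "no retained locus in interval"}
    i = sub["rr"].idxmin()
    out = {
        "flagged": False,
        "min_rr": float(sub.loc[i, "rr"]),
        "bp_at_min": float(sub.loc[i, "bp"]),
    }
    if genome_rr is not None:
        pool = np.asarray(genome_rr, dtype=float)
        out["quantile"] = float(np.mean(pool <= out["min_rr"]))
    return out


__all__ = [
    "chromosome_rr",
    "rr_table",
    "AnovaResult",
    "rr_anova",
    "RRProfile",
    "longest_nondecreasing",
    "marey_profile",
    "standardize",
    "standardize_profiles",
    "CSRResult",
    "csr_quadrat_test",
    "centromere_min_rr",
]
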