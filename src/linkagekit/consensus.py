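"""Multi-family SNP compendium, consensus linkage groups, the
high-confidence decision tree, chimeric-block detection and contingency /
loglinear analyses of grouping accuracy.

A SNP's *consensus* linkage group is the LG to which the plurality of SNPs
on its contig are assigned.  Runs of contiguous SNPs sharing the same
non-consensus LG are evidence of contig misassembly when replicated across
families ("chimeric blocks").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import LinkageMap


@dataclass
class Compendium:
    """Merged per-SNP records joining physical coordinates to per-family
    linkage assignments.

    ``snps`` has one row per retained physical SNP (marker, contig,
    contig_pos, chrom, chrom_pos, linkage_group, n_families, families,
    methods); ``assignments`` keeps the underlying long table.  SNPs whose
    per-family LG assignments conflict are excluded into ``conflicts``;
    markers translating to a duplicated physical position are removed into
    ``duplicates``; map markers without coordinates are listed in
    ``missing``.
    """

    snps: pd.DataFrame
    assignments: pd.DataFrame
    conflicts: pd.DataFrame
    duplicates: pd.DataFrame
    missing: list[str]
    contig_consensus: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def size(self) -> int:
        """Physical SNPs considered: retained + conflict-excluded."""
        return len(self.snps) + len(self.conflicts)


def merge_compendium(maps: list[LinkageMap], coords: pd.DataFrame) -> Compendium:
    """Merge per-family linkage maps with a SNP coordinate table."""
    rows = []
    for lmap in maps:
        for e in lmap.entries.itertuples():
            rows.append(
                (e.marker, lmap.family, lmap.method, lmap.parent, e.linkage_group, e.position_cm)
            )
    assignments = pd.DataFrame(
        rows, columns=["marker", "family", "method", "parent", "linkage_group", "position_cm"]
    )
    known = set(coords["marker"])
    missing = sorted(set(assignments["marker"]) - known)
    assignments = assignments[assignments["marker"].isin(known)]
    assignments = assignments.merge(coords, on="marker", how="left")

    per_snp = assignments.groupby("marker", sort=False).agg(
        contig=("contig", "first"),
        contig_pos=("contig_pos", "first"),
        chrom=("chrom", "first"),
        chrom_pos=("chrom_pos", "first"),
        n_lgs=("linkage_group", "nunique"),
        linkage_group=("linkage_group", "first"),
        n_families=("family", "nunique"),
        families=("family", lambda s: tuple(sorted(set(s)))),
        methods=("method", lambda s: tuple(sorted(set(s)))),
    ).reset_index()

    conflict_mask = per_snp["n_lgs"] > 1
    conflicts = per_snp[conflict_mask].drop(columns=["n_lgs"]).reset_index(drop=True)
    snps = per_snp[~conflict_mask].drop(columns=["n_lgs"])

    dup_mask = snps.duplicated(subset=["contig", "contig_pos"], keep=False)
    duplicates = snps[dup_mask].reset_index(drop=True)
    snps = snps[~dup_mask].sort_values(["contig", "contig_pos"]).reset_index(drop=True)

    comp = Compendium(snps, assignments.reset_index(drop=True), conflicts, duplicates, missing)
    comp.contig_consensus = _contig_consensus(comp.snps)
    return comp


def consensus_lg(records: pd.DataFrame) -> tuple[str | None, bool]:
    """Plurality linkage group of one contig's SNPs.

    Returns ``(lg, ambiguous)``; an exact tie for the plurality yields
    ``(None, True)`` and excludes the contig from block statistics.
    """
    if records.empty:
        raise ValueError("contig has no SNPs")
    counts = records["linkage_group"].value_counts()
    top = counts.iloc[0]
    winners = counts[counts == top]
    if len(winners) > 1:
        return None, True
    return str(winners.index[0]), False


def _contig_consensus(snps: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for contig, sub in snps.groupby("contig", sort=False):
        lg, ambiguous = consensus_lg(sub)
        rows.append((contig, lg, ambiguous, len(sub)))
    return pd.DataFrame(rows, columns=["contig", "consensus_lg", "ambiguous", "n_snps"])


def classify_snps(comp: Compendium) -> pd.Series:
    """High-confidence decision tree; one label per retained SNP.

    * ``cat1``: assigned to the consensus LG, mapped in more than one family;
    * ``cat2``: assigned to the consensus LG, mapped in one family, on a
      contig that carries a cat1 SNP;
    * ``cat3``: assigned to a non-consensus LG in more than one family;
    * ``low``: everything else;
    * ``unclassifiable``: SNPs on contigs whose consensus is ambiguous.

    cat1–cat3 are the high-confidence SNPs.
    """
    snps = comp.snps.merge(comp.contig_consensus, on="contig", how="left")
    is_con = snps["linkage_group"] == snps["consensus_lg"]
    multi = snps["n_families"] > 1
    cat1 = is_con & multi
    contig_has_cat1 = snps.loc[cat1, "contig"].unique()
    cat2 = is_con & ~multi & snps["contig"].isin(contig_has_cat1)
    cat3 = ~is_con & multi
    labels = np.select(
        [snps["ambiguous"].to_numpy(), cat1, cat2, cat3],
        ["unclassifiable", "cat1", "cat2", "cat3"],
        default="low",
    )
    return pd.Series(labels, index=comp.snps["marker"].to_numpy(), name="category")


HIGH_CONFIDENCE = ("cat1", "cat2", "cat3")


# ---------------------------------------------------------------------------
# Chimeric blocks


def detect_blocks(comp: Compendium, support: str = "union") -> pd.DataFrame:
    """Maximal runs of contiguous same-LG non-consensus SNPs per contig.

    SNPs are taken in contig-position order; a run breaks whenever the next
    SNP is consensus-assigned or carries a different non-consensus LG.
    Runs of length 1 are *single exceptions*; longer runs are *one-family*
    or *multi-family* (chimeric) blocks depending on family support —
    ``support="union"`` pools families over member SNPs, ``"per_snp"``
    requires a single member mapped in more than one family.  Contigs with
    an ambiguous consensus are skipped.
    """
    if support not in ("union", "per_snp"):
        raise ValueError("support must be 'union' or 'per_snp'")
    consensus = comp.contig_consensus.set_index("contig")
    rows = []
    for contig, sub in comp.snps.groupby("contig", sort=False):
        if consensus.loc[contig, "ambiguous"]:
            continue
        con = consensus.loc[contig, "consensus_lg"]
        sub = sub.sort_values("contig_pos", kind="stable")
        run: list[pd.Series] = []
        run_lg = None
        for _, snp in sub.iterrows():
            lg = snp["linkage_group"]
            if lg != con and lg == run_lg:
                run.append(snp)
            else:
                if run:
                    rows.append(_close_run(contig, run_lg, run, support))
                run = [snp] if lg != con else []
                run_lg = lg if lg != con else None
        if run:
            rows.append(_close_run(contig, run_lg, run, support))
    return pd.DataFrame(
        rows,
        columns=["contig", "linkage_group", "start_bp", "end_bp", "length_bp",
                 "n_snps", "snps", "families", "kind"],
    )


def _close_run(contig: str, lg: str, run: list[pd.Series], support: str) -> tuple:
    start = int(run[0]["contig_pos"])
    end = int(run[-1]["contig_pos"])
    families: set[str] = set()
    for snp in run:
        families.update(snp["families"])
    if support == "union":
        multi = len(families) > 1
    else:
        multi = any(snp["n_families"] > 1 for snp in run)
    if len(run) == 1:
        kind = "single_exception"
    elif multi:
        kind = "multi_family_block"
    else:
        kind = "one_family_block"
    return (
        contig, lg, start, end, end - start + 1, len(run),
        tuple(s["marker"] for s in run), tuple(sorted(families)), kind,
    )


def block_stats(blocks: pd.DataFrame) -> dict:
    """Summary over multi-family (chimeric) blocks only."""
    chim = blocks[blocks["kind"] == "multi_family_block"] if len(blocks) else blocks
    if len(chim) == 0:
        return {
            "n_chimeric_contigs": 0, "n_blocks": 0, "mean_snps_per_block": float("nan"),
            "median_length_bp": float("nan"), "total_length_bp": 0,
        }
    return {
        "n_chimeric_contigs": int(chim["contig"].nunique()),
        "n_blocks": int(len(chim)),
        "mean_snps_per_block": float(chim["n_snps"].mean()),
        "median_length_bp": float(chim["length_bp"].median()),
        "total_length_bp": int(chim["length_bp"].sum()),
    }


def partition(comp: Compendium, blocks: pd.DataFrame) -> pd.Series:
    """Exhaustive partition of the compendium (counts sum to its size):
    consensus-assigned, single exception, one-family block member,
    multi-family block member, excluded-conflict, unclassifiable."""
    label = pd.Series("consensus", index=comp.snps["marker"].to_numpy())
    ambiguous = set(
        comp.contig_consensus.loc[comp.contig_consensus["ambiguous"], "contig"]
    )
    on_ambiguous = comp.snps["contig"].isin(ambiguous).to_numpy()
    label[on_ambiguous] = "unclassifiable"
    kind_map = {
        "single_exception": "single_exception",
        "one_family_block": "one_family_block",
        "multi_family_block": "multi_family_block",
    }
    for row in blocks.itertuples():
        for marker in row.snps:
            label[marker] = kind_map[row.kind]
    conflict = pd.Series("excluded_conflict", index=comp.conflicts["marker"].to_numpy())
    return pd.concat([label, conflict])


# ---------------------------------------------------------------------------
# Grouping accuracy: contingency and loglinear analysis


def grouping_table(comp: Compendium, methods: tuple[str, str]) -> np.ndarray:
    """2×2×2 SNP counts over (grouping accuracy) × (mapping method) ×
    (level of family support).

    Axis 0: conLG / non-conLG; axis 1: ``methods[0]`` / ``methods[1]``;
    axis 2: 1 family / >1 family.  Only SNPs mapped by exactly one of the
    two methods enter the table.
    """
    snps = comp.snps.merge(comp.contig_consensus, on="contig", how="left")
    snps = snps[~snps["ambiguous"].astype(bool)]
    table = np.zeros((2, 2, 2), dtype=int)
    for row in snps.itertuples():
        used = [m for m in methods if m in row.methods]
        if len(used) != 1:
            continue
        i = 0 if row.linkage_group == row.consensus_lg else 1
        j = methods.index(used[0])
        k = 0 if row.n_families == 1 else 1
        table[i, j, k] += 1
    return table


def grouping_shares(table: np.ndarray) -> dict:
    """Marginal shares of a 2×2×2 grouping table: fraction of SNPs assigned
    to the consensus LG, mapped by each method, and mapped in one family."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    return {
        "consensus_share": float(table[0].sum() / total),
        "method_shares": (float(table[:, 0].sum() / total), float(table[:, 1].sum() / total)),
        "single_family_share": float(table[:, :, 0].sum() / total),
        "total": int(total),
    }


@dataclass
class OddsRatio:
    """2×2 association: OR = ad/(bc) with a Pearson chi-square (1 df)."""

    odds_ratio: float
    chi_square: float
    p_value: float
    zero_cell: bool = False


def contingency_2x2(a: float, b: float, c: float, d: float) -> OddsRatio:
    """Odds ratio and Pearson chi-square (no continuity correction) for the
    2×2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError("zero marginal")
    zero = bool((table == 0).any())
    if b * c == 0:
        oratio = float("inf") if a * d > 0 else float("nan")
    else:
        oratio = (a * d) / (b * c)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return OddsRatio(float(oratio), float(chi2), float(p), zero)


def ipf_fit(
    observed: np.ndarray,
    margins: list[tuple[int, ...]],
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> np.ndarray:
    """Fit a hierarchical loglinear model by iterative proportional fitting.

    ``margins`` lists the highest-order terms to preserve, as axis tuples
    (e.g. ``[(0, 1), (0, 2), (1, 2)]`` for the all-two-way model).
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.full(obs.shape, obs.sum() / obs.size)
    for _ in range(max_iter):
        prev = fit.copy()
        for axes in margins:
            other = tuple(i for i in range(obs.ndim) if i not in axes)
            target = obs.sum(axis=other, keepdims=True)
            current = fit.sum(axis=other, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(current > 0, target / np.where(current > 0, current, 1.0), 0.0)
            fit = fit * ratio
        if np.max(np.abs(fit - prev)) < tol:
            break
    return fit


def g_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Likelihood-ratio statistic G² = 2 Σ obs·ln(obs/fit) (0·ln0 = 0)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / fit[mask])))


@dataclass
class LoglinearResult:
    """Hierarchy of loglinear fits to a 2×2×2 table.

    ``tests`` reports, per term, the 1-df likelihood-ratio statistic for
    dropping it: the three-way term against the saturated model, each
    two-way term against the all-two-way model.
    """

    tests: pd.DataFrame
    fits: dict[str, np.ndarray]
    structural_zeros: bool


def loglinear_3way(table: np.ndarray) -> LoglinearResult:
    """Hierarchical loglinear analysis of a 2×2×2 contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2, 2):
        raise ValueError("need a 2x2x2 table")
    names = {0: "A", 1: "B", 2: "C"}
    all2 = [(0, 1), (0, 2), (1, 2)]
    fits = {"all_two_way": ipf_fit(obs, all2)}
    g2_all2 = g_squared(obs, fits["all_two_way"])
    rows = [("A x B x C", g2_all2, 1, float(stats.chi2.sf(g2_all2, 1)))]
    for drop in all2:
        kept = [m for m in all2 if m != drop]
        key = "drop_" + "".join(names[a] for a in drop)
        fits[key] = ipf_fit(obs, kept)
        delta = g_squared(obs, fits[key]) - g2_all2
        term = " x ".join(names[a] for a in drop)
        rows.append((term, delta, 1, float(stats.chi2.sf(delta, 1))))
    tests = pd.DataFrame(rows, columns=["term", "G2", "df", "p"])
    return LoglinearResult(tests, fits, structural_zeros=bool((obs == 0).any()))


__all__ = [
    "Compendium",
    "merge_compendium",
    "consensus_lg",
    "classify_snps",
    "HIGH_CONFIDENCE",
    "detect_blocks",
    "block_stats",
    "partition",
    "grouping_table",
    "grouping_shares",
    "OddsRatio",
    "contingency_2x2",
    "ipf_fit",
    "g_squared",
    "LoglinearResult",
    "loglinear_3way",
]
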