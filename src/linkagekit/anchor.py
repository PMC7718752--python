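"""Order and orient contigs into pseudomolecules from multi-map linkage
evidence, and classify concordance against a reference layout.

Each map contributes, per contig, the mean genetic position of the
contig's high-confidence SNPs (min–max normalized to [0, 1] within the
map's linkage group so that per-map affine rescaling of cM cannot change
the order); contigs are ordered by the weight-averaged normalized
position.  Orientation is the sign of the mean rank correlation between
contig-local bp position and cM across maps with at least two distinct
genetic positions on the contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import HIGH_CONFIDENCE, Compendium
from .io import ContigLayout, LinkageMap, layout_from_lengths


def assign_chromosomes(
    comp: Compendium, categories: pd.Series, lg_to_chrom: dict[str, str]
) -> pd.DataFrame:
    """Assign each contig carrying high-confidence SNPs to the chromosome
    of its consensus linkage group.

    Returns a DataFrame (contig, chrom, n_high_confidence); contigs without
    high-confidence SNPs are returned with chrom = NA (unplaced).
    """
    snps = comp.snps.assign(category=categories.loc[comp.snps["marker"]].to_numpy())
    rows = []
    for row in comp.contig_consensus.itertuples():
        sub = snps[snps["contig"] == row.contig]
        n_high = int(sub["category"].isin(HIGH_CONFIDENCE).sum())
        if n_high == 0 or row.ambiguous:
            rows.append((row.contig, None, n_high))
            continue
        if row.consensus_lg not in lg_to_chrom:
            raise KeyError(f"linkage group {row.consensus_lg!r} missing from correspondence")
        rows.append((row.contig, lg_to_chrom[row.consensus_lg], n_high))
    return pd.DataFrame(rows, columns=["contig", "chrom", "n_high_confidence"])


def order_and_orient(
    comp: Compendium,
    maps: list[LinkageMap],
    categories: pd.Series,
    lg_to_chrom: dict[str, str],
    contig_lengths: dict[str, int] | None = None,
    weights: dict | None = None,
    gap: int = 100,
    min_abs_rho: float = 0.1,
) -> ContigLayout:
    """Order and orient placed contigs into a :class:`ContigLayout`.

    Evidence comes from SNPs that are high-confidence and assigned to the
    contig's consensus linkage group.  Maps carry unit weight unless
    ``weights`` (keyed by ``(family, parent, method)``) says otherwise.
    Orientation is "?" when no map sees two distinct genetic positions on
    the contig or when the weighted mean rank correlation is weaker than
    ``min_abs_rho``.
    """
    placement = assign_chromosomes(comp, categories, lg_to_chrom)
    placed = placement.dropna(subset=["chrom"])
    consensus = comp.contig_consensus.set_index("contig")["consensus_lg"]
    snps = comp.snps.assign(category=categories.loc[comp.snps["marker"]].to_numpy())
    usable = snps[
        snps["category"].isin(HIGH_CONFIDENCE)
        & (snps["linkage_group"] == snps["contig"].map(consensus))
    ][["marker", "contig", "contig_pos"]]

    per_contig_pos: dict[str, list[tuple[float, float]]] = {c: [] for c in placed["contig"]}
    per_contig_rho: dict[str, list[tuple[float, float]]] = {c: [] for c in placed["contig"]}
    for lmap in maps:
        w = (weights or {}).get((lmap.family, lmap.parent, lmap.method), 1.0)
        entries = lmap.entries.merge(usable, on="marker")
        for lg, sub in entries.groupby("linkage_group", sort=False):
            lo, hi = sub["position_cm"].min(), sub["position_cm"].max()
            span = hi - lo
            norm = (sub["position_cm"] - lo) / span if span > 0 else pd.Series(0.5, index=sub.index)
            sub = sub.assign(norm=norm)
            for contig, csub in sub.groupby("contig", sort=False):
                if contig not in per_contig_pos:
                    continue
                per_contig_pos[contig].append((w, float(csub["norm"].mean())))
                if csub["position_cm"].nunique() >= 2:
                    rho = stats.spearmanr(csub["contig_pos"], csub["position_cm"]).statistic
                    if not np.isnan(rho):
                        per_contig_rho[contig].append((w, float(rho)))

    n_high = placement.set_index("contig")["n_high_confidence"]
    order: dict[str, list[tuple[str, str, int]]] = {}
    for chrom, group in placed.groupby("chrom", sort=True):
        scored = []
        for contig in group["contig"]:
            obs = per_contig_pos[contig]
            if not obs:
                continue
            wsum = sum(w for w, _ in obs)
            value = sum(w * v for w, v in obs) / wsum
            rhos = per_contig_rho[contig]
            if rhos:
                mean_rho = sum(w * r for w, r in rhos) / sum(w for w, _ in rhos)
                orient = "?" if abs(mean_rho) < min_abs_rho else ("+" if mean_rho > 0 else "-")
            else:
                orient = "?"
            scored.append((value, -int(n_high[contig]), contig, orient))
        scored.sort()
        lengths = contig_lengths or {}
        order[chrom] = [
            (contig, orient, int(lengths.get(contig, _span(usable, contig))))
            for _, _, contig, orient in scored
        ]
    return layout_from_lengths(order, gap=gap)


def _span(usable: pd.DataFrame, contig: str) -> int:
    return int(usable.loc[usable["contig"] == contig, "contig_pos"].max())


_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_pseudomolecules(
    layout: ContigLayout, sequences: dict[str, str], gap_char: str = "N"
) -> dict[str, str]:
    """Concatenate contig sequences per chromosome following the layout.

    Contigs oriented "-" are reverse-complemented; "?" is treated as "+".
    Gaps between contigs are filled with ``gap_char``.  The emitted
    sequence spans exactly match the layout's AGP coordinates.
    """
    out: dict[str, str] = {}
    for chrom, placements in layout.chromosomes.items():
        parts: list[str] = []
        prev_end = 0
        for p in placements:
            if p.contig not in sequences:
                raise KeyError(f"no sequence for contig {p.contig!r}")
            seq = sequences[p.contig]
            if len(seq) != p.end - p.start + 1:
                raise ValueError(
                    f"{p.contig}: sequence length {len(seq)} != layout span "
                    f"{p.end - p.start + 1}"
                )
            if prev_end:
                parts.append(gap_char * (p.start - prev_end - 1))
            parts.append(reverse_complement(seq) if p.orientation == "-" else seq)
            prev_end = p.end
        out[chrom] = "".join(parts)
    return out


CATEGORIES = (
    "identical",
    "different_order",
    "reversed_orientation",
    "orientation_unknown",
    "different_chromosome",
)


@dataclass
class ConcordanceReport:
    """Per-contig concordance of a test layout against a reference."""

    per_contig: pd.DataFrame  # contig, category, offset
    excluded: list[str] = field(default_factory=list)  # absent from reference

    @property
    def counts(self) -> dict[str, int]:
        vc = self.per_contig["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORIES}

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.per_contig)
        return {c: k / n for c, k in self.counts.items()}

    def within_offset(self, k: int) -> int:
        """Different-order contigs whose rank offset is at most ``k``."""
        sub = self.per_contig[self.per_contig["category"] == "different_order"]
        return int((sub["offset"] <= k).sum())


def compare_layouts(test: ContigLayout, reference: ContigLayout) -> ConcordanceReport:
    """Classify every contig of the test layout against the reference.

    Categories: (1) identical — same chromosome, same relative order, same
    orientation; (2) different order on the same chromosome, with the rank
    offset over shared contigs; (3) same order but reversed orientation;
    (4) orientation unknown in the test layout; (5) different chromosome.
    """
    shared = test.contigs & reference.contigs
    excluded = sorted(test.contigs - reference.contigs)
    rows = []
    test_chrom = {c: test.chromosome_of(c) for c in shared}
    ref_chrom = {c: reference.chromosome_of(c) for c in shared}
    same_chrom = {c for c in shared if test_chrom[c] == ref_chrom[c]}
    rank_cache: dict[str, tuple[dict, dict]] = {}
    for contig in sorted(shared):
        if test_chrom[contig] != ref_chrom[contig]:
            rows.append((contig, "different_chromosome", np.nan))
            continue
        chrom = test_chrom[contig]
        if chrom not in rank_cache:
            on_chrom = [c for c in same_chrom if test_chrom[c] == chrom]
            rank_cache[chrom] = (
                test.ranks(chrom, within=on_chrom),
                reference.ranks(chrom, within=on_chrom),
            )
        t_ranks, r_ranks = rank_cache[chrom]
        offset = abs(t_ranks[contig] - r_ranks[contig])
        t_orient = test.orientation_of(contig)
        r_orient = reference.orientation_of(contig)
        if offset == 0 and t_orient == r_orient:
            category = "identical"
        elif offset == 0 and t_orient != "?" and r_orient != "?":
            category = "reversed_orientation"
        elif t_orient == "?":
            category = "orientation_unknown"
        else:
            category = "different_order"
        rows.append((contig, category, offset))
    per_contig = pd.DataFrame(rows, columns=["contig", "category", "offset"])
    return ConcordanceReport(per_contig, excluded)


__all__ = [
    "assign_chromosomes",
    "order_and_orient",
    "reverse_complement",
    "build_pseudomolecules",
    "CATEGORIES",
    "ConcordanceReport",
    "compare_layouts",
]
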