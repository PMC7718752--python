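"""Readers and writers for the tables and formats exchanged by the pipeline.

Tabular files are TSV with ``#`` metadata header lines (``# key=value``),
UTF-8, ``NA`` for missing.  Contig layouts use AGP v2; chimeric blocks use
BED (half-open, 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable

import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Linkage maps


@dataclass
class LinkageMap:
    """One family's ordered markers with linkage group and cM position.

    Parameters
    ----------
    family : str
        Family identifier (e.g. ``"23x31"``).
    parent : str
        Parental context: ``"sire"``, ``"dam"`` or ``"average"`` for a
        sex-averaged map.
    entries : pandas.DataFrame
        Columns ``marker`` (str, unique), ``linkage_group`` (str),
        ``position_cm`` (float) and optionally ``mating_type``.
    method : str
        Mapping method label (free text, e.g. ``"JM"``, ``"LM3"``).
    """

    family: str
    parent: str = "average"
    entries: pd.DataFrame = field(default_factory=pd.DataFrame)
    method: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        required = {"marker", "linkage_group", "position_cm"}
        missing = required - set(df.columns)
        if len(df) and missing:
            raise FormatError(f"linkage map missing columns: {sorted(missing)}")
        if len(df):
            dup = df["marker"][df["marker"].duplicated()]
            if len(dup):
                raise FormatError(f"duplicate marker id: {dup.iloc[0]!r}")
        self.entries = df.reset_index(drop=True)

    @property
    def linkage_groups(self) -> list[str]:
        return sorted(self.entries["linkage_group"].unique()) if len(self.entries) else []

    def group(self, lg: str) -> pd.DataFrame:
        """Entries of one linkage group, sorted by cM position."""
        sub = self.entries[self.entries["linkage_group"] == lg]
        return sub.sort_values(["position_cm", "marker"], kind="stable").reset_index(drop=True)


def read_linkage_map(path: str | Path) -> LinkageMap:
    """Read a linkage map TSV written by :func:`write_linkage_map`."""
    meta, body = _split_meta(path)
    try:
        df = pd.read_csv(StringIO(body), sep="\t", dtype={"marker": str, "linkage_group": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    if "position_cm" not in df.columns:
        raise FormatError(f"{path}: missing required column 'position_cm'")
    cm = pd.to_numeric(df["position_cm"], errors="coerce")
    bad = df.index[cm.isna() & df["position_cm"].notna()]
    if len(bad):
        i = bad[0]
        raise FormatError(
            f"{path}: non-numeric cM {df.loc[i, 'position_cm']!r} at data row {i + 1}"
        )
    df["position_cm"] = cm
    dup = df["marker"][df["marker"].duplicated()]
    if len(dup):
        i = dup.index[0]
        raise FormatError(f"{path}: duplicate marker {dup.iloc[0]!r} at data row {i + 1}")
    return LinkageMap(
        family=meta.get("family", ""),
        parent=meta.get("parent", "average"),
        method=meta.get("method", ""),
        entries=df,
    )


def write_linkage_map(lmap: LinkageMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# family={lmap.family}\n# parent={lmap.parent}\n# method={lmap.method}\n")
        lmap.entries.to_csv(fh, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# SNP coordinates


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a SNP coordinate table: marker, contig, contig_pos, chrom, chrom_pos.

    Positions are 1-based.  One row per marker.
    """
    _, body = _split_meta(path)
    df = pd.read_csv(StringIO(body), sep="\t", dtype={"marker": str, "contig": str, "chrom": str})
    required = {"marker", "contig", "contig_pos", "chrom", "chrom_pos"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: coordinate table missing columns {sorted(missing)}")
    dup = df["marker"][df["marker"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate marker {dup.iloc[0]!r}")
    if (df[["contig_pos", "chrom_pos"]] < 1).any().any():
        raise FormatError(f"{path}: positions must be >= 1")
    return df.reset_index(drop=True)


def write_coordinates(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Contig layouts (AGP v2)


@dataclass
class Placement:
    """One contig placed in an assembled object."""

    contig: str
    orientation: str  # "+", "-" or "?"
    start: int  # 1-based inclusive, in object coordinates
    end: int


@dataclass
class ContigLayout:
    """Ordered, oriented contigs per chromosome with fixed inter-contig gaps."""

    chromosomes: dict[str, list[Placement]] = field(default_factory=dict)
    gap: int = 100

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, placements in self.chromosomes.items():
            prev_end = 0
            for p in placements:
                if p.contig in seen:
                    raise FormatError(f"contig {p.contig!r} placed more than once")
                seen.add(p.contig)
                if p.start <= prev_end:
                    raise FormatError(
                        f"{chrom}: overlapping object coordinates at contig {p.contig!r}"
                    )
                prev_end = p.end

    @property
    def contigs(self) -> set[str]:
        return {p.contig for ps in self.chromosomes.values() for p in ps}

    def chromosome_of(self, contig: str) -> str | None:
        for chrom, ps in self.chromosomes.items():
            if any(p.contig == contig for p in ps):
                return chrom
        return None

    def ranks(self, chrom: str, within: Iterable[str] | None = None) -> dict[str, int]:
        """0-based rank of each contig along ``chrom``, optionally restricted
        to a shared contig subset (ranks recomputed over that subset)."""
        ps = self.chromosomes.get(chrom, [])
        names = [p.contig for p in ps]
        if within is not None:
            keep = set(within)
            names = [c for c in names if c in keep]
        return {c: i for i, c in enumerate(names)}

    def orientation_of(self, contig: str) -> str:
        for ps in self.chromosomes.values():
            for p in ps:
                if p.contig == contig:
                    return p.orientation
        raise KeyError(contig)


def layout_from_lengths(
    order: dict[str, list[tuple[str, str, int]]], gap: int = 100
) -> ContigLayout:
    """Build a :class:`ContigLayout` from per-chromosome ``(contig,
    orientation, length)`` lists, assigning coordinates with ``gap`` bp
    between successive contigs."""
    chroms: dict[str, list[Placement]] = {}
    for chrom, items in order.items():
        placements = []
        pos = 1
        for i, (contig, orient, length) in enumerate(items):
            if i:
                pos += gap
            placements.append(Placement(contig, orient, pos, pos + length - 1))
            pos += length
        chroms[chrom] = placements
    return ContigLayout(chroms, gap=gap)


def read_layout(path: str | Path) -> ContigLayout:
    """Read an AGP v2 file into a :class:`ContigLayout`.

    ``W`` component rows become placements; ``N``/``U`` gap rows set the
    layout's gap length.  Overlapping object coordinates are rejected.
    """
    chroms: dict[str, list[Placement]] = {}
    gap = 100
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{lineno}: AGP row has {len(parts)} fields, need >=8")
            obj, beg, end, _part, ctype = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4]
            if ctype in ("N", "U"):
                gap = int(parts[5])
                continue
            orientation = parts[8] if len(parts) > 8 else "?"
            if orientation not in ("+", "-", "?", "na"):
                raise FormatError(f"{path}:{lineno}: bad orientation {orientation!r}")
            chroms.setdefault(obj, []).append(
                Placement(parts[5], "?" if orientation == "na" else orientation, beg, end)
            )
    return ContigLayout(chroms, gap=gap)


def write_layout(layout: ContigLayout, path: str | Path) -> None:
    """Write a :class:`ContigLayout` as AGP v2 with ``U`` gap rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##agp-version\t2.0\n")
        for chrom, placements in layout.chromosomes.items():
            part = 0
            prev_end = 0
            for p in placements:
                if prev_end:
                    part += 1
                    fh.write(
                        f"{chrom}\t{prev_end + 1}\t{p.start - 1}\t{part}\tU\t"
                        f"{p.start - 1 - prev_end}\tscaffold\tyes\tmap\n"
                    )
                part += 1
                length = p.end - p.start + 1
                fh.write(
                    f"{chrom}\t{p.start}\t{p.end}\t{part}\tW\t{p.contig}\t1\t{length}\t"
                    f"{p.orientation}\n"
                )
                prev_end = p.end


# ---------------------------------------------------------------------------
# BED (chimeric blocks etc.)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals with columns chrom/start/end (+ extras) as BED
    (half-open, 0-based)."""
    cols = ["chrom", "start", "end"] + [c for c in intervals.columns if c not in ("chrom", "start", "end")]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    extra = names or [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = (base + extra)[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Genotype tables


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Markers x individuals genotype table; index is the marker id."""
    _, body = _split_meta(path)
    df = pd.read_csv(StringIO(body), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return df


def write_genotypes(genotypes: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        genotypes.to_csv(fh, sep="\t", na_rep="NA", index_label="marker")


# ---------------------------------------------------------------------------


def _split_meta(path: str | Path) -> tuple[dict[str, str], str]:
    """Split ``# key=value`` header lines from the TSV body."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    k, v = stripped.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


__all__ = [
    "FormatError",
    "LinkageMap",
    "Placement",
    "ContigLayout",
    "layout_from_lengths",
    "read_linkage_map",
    "write_linkage_map",
    "read_coordinates",
    "write_coordinates",
    "read_layout",
    "write_layout",
    "read_bed",
    "write_bed",
    "read_genotypes",
    "write_genotypes",
]
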