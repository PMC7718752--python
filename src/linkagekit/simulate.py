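"""Synthetic genomes, crossover landscapes, F2 families and corrupted
assemblies with complete truth records.

The generator emulates a bivalve-style study system: 10 chromosomes of
~56 Mb tiled by ~300 contigs, F2 families genotyped at markers of three
cross-pollinated mating types (hk×hk bi-parental, lm×ll dam-informative,
nn×np sire-informative), crossovers drawn from a Poisson, no-interference
process over a piecewise-constant recombination landscape (Haldane model),
dam maps ~1.25× longer than sire maps, 2–3% genotyping error, and assembly
corruptions — short chimeric SNP blocks spliced into host contigs and
contig order/orientation shuffles — recorded exactly once in a truth
record so every downstream stage can be tested by recovery.

Coordinates in emitted tables are 1-based inclusive; internal interval
arithmetic is half-open 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ContigLayout, LinkageMap, Placement

#: genotype alphabet per mating type (dam x sire notation: lm x ll markers
#: segregate from the dam, nn x np from the sire, hk x hk from both)
GENOTYPES = {
    "hkxhk": ("hh", "hk", "kk"),
    "lmxll": ("ll", "lm"),
    "nnxnp": ("nn", "np"),
}
MATING_TYPES = tuple(GENOTYPES)


def lg_of_chrom(chrom: str) -> str:
    """Linkage-group label for a chromosome id (``chr3`` -> ``LG3``)."""
    digits = "".join(c for c in chrom if c.isdigit())
    return f"LG{digits or chrom}"


def chrom_of_lg(lg: str) -> str:
    digits = "".join(c for c in lg if c.isdigit())
    return f"chr{digits or lg}"


# ---------------------------------------------------------------------------
# Genome


@dataclass
class GenomeConfig:
    """Specification of a synthetic genome.

    Defaults emulate a 560 Mb genome: 10 chromosomes of 56 Mb tiled by 300
    contigs carrying 3,000 SNPs in total.
    """

    n_chromosomes: int = 10
    chromosome_length: int | list[int] = 56_000_000
    n_contigs: int = 300
    n_snps: int = 3000

    def lengths(self) -> list[int]:
        if isinstance(self.chromosome_length, int):
            return [self.chromosome_length] * self.n_chromosomes
        if len(self.chromosome_length) != self.n_chromosomes:
            raise ValueError("need one length per chromosome")
        return list(self.chromosome_length)


@dataclass
class GenomeModel:
    """A synthetic genome: chromosomes tiled by contigs carrying SNPs.

    ``snps`` has the assembly's claim columns (``contig``, ``contig_pos``,
    ``chrom``, ``chrom_pos``) and the meiotic truth columns (``true_chrom``,
    ``true_pos``); the two agree unless the assembly has been corrupted by
    :func:`corrupt_assembly`.
    """

    chromosomes: pd.DataFrame  # chrom, length
    contigs: pd.DataFrame  # contig, chrom, start, end (1-based inclusive)
    snps: pd.DataFrame  # snp, contig, contig_pos, chrom, chrom_pos, true_chrom, true_pos

    def validate(self) -> None:
        lengths = dict(zip(self.chromosomes["chrom"], self.chromosomes["length"]))
        for chrom, sub in self.contigs.groupby("chrom"):
            sub = sub.sort_values("start")
            if sub["start"].iloc[0] != 1 or sub["end"].iloc[-1] != lengths[chrom]:
                raise ValueError(f"{chrom}: contigs do not tile the chromosome")
            if not (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1] + 1).all():
                raise ValueError(f"{chrom}: contig tiling has gaps or overlaps")
        merged = self.snps.merge(self.contigs, on="contig", suffixes=("", "_ctg"))
        inside = (merged["contig_pos"] >= 1) & (
            merged["contig_pos"] <= merged["end"] - merged["start"] + 1
        )
        if not inside.all():
            raise ValueError("SNP outside its contig")
        if not (merged["chrom_pos"] == merged["start"] + merged["contig_pos"] - 1).all():
            raise ValueError("chrom_pos != contig start + contig_pos - 1")

    def coordinate_table(self) -> pd.DataFrame:
        """The assembly-claim coordinate table (marker, contig, contig_pos,
        chrom, chrom_pos) consumed by the classification pipeline."""
        df = self.snps[["snp", "contig", "contig_pos", "chrom", "chrom_pos"]].copy()
        return df.rename(columns={"snp": "marker"})

    def contig_length(self, contig: str) -> int:
        row = self.contigs.loc[self.contigs["contig"] == contig].iloc[0]
        return int(row["end"] - row["start"] + 1)

    def layout(self, gap: int = 0) -> ContigLayout:
        """The claimed contig layout, all contigs in '+' orientation."""
        chroms: dict[str, list[Placement]] = {}
        for chrom, sub in self.contigs.groupby("chrom"):
            sub = sub.sort_values("start")
            chroms[chrom] = [
                Placement(r.contig, "+", int(r.start), int(r.end)) for r in sub.itertuples()
            ]
        return ContigLayout(chroms, gap=gap)


def _sample_unique(rng: np.random.Generator, low: int, high: int, size: int) -> np.ndarray:
    """``size`` distinct sorted integers in [low, high); avoids
    materializing the range (collisions are resampled)."""
    if high - low < size:
        raise ValueError("range too small for distinct sample")
    out = np.unique(rng.integers(low, high, size=size))
    while out.size < size:
        extra = rng.integers(low, high, size=size - out.size)
        out = np.unique(np.concatenate([out, extra]))
    return out


def build_genome(config: GenomeConfig, seed: int) -> GenomeModel:
    """Generate a random genome satisfying the tiling and coordinate
    invariants; deterministic for a fixed seed."""
    lengths = config.lengths()
    if config.n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if any(ln <= 0 for ln in lengths):
        raise ValueError("zero-length chromosome")
    if config.n_contigs < config.n_chromosomes:
        raise ValueError("need at least one contig per chromosome")
    if config.n_snps <= 0:
        raise ValueError("SNP density must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))

    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes = pd.DataFrame({"chrom": chrom_ids, "length": lengths})
    weights = np.asarray(lengths, dtype=float) / float(sum(lengths))

    extra = rng.multinomial(config.n_contigs - config.n_chromosomes, weights)
    contig_rows = []
    cid = 0
    for chrom, length, k_extra in zip(chrom_ids, lengths, extra):
        k = int(k_extra) + 1
        if k > 1:
            cuts = _sample_unique(rng, 1, length, k - 1)
        else:
            cuts = np.array([], dtype=int)
        starts = np.concatenate([[1], cuts + 1])
        ends = np.concatenate([cuts, [length]])
        for s, e in zip(starts, ends):
            cid += 1
            contig_rows.append(("ctg%04d" % cid, chrom, int(s), int(e)))
    contigs = pd.DataFrame(contig_rows, columns=["contig", "chrom", "start", "end"])

    per_chrom = rng.multinomial(config.n_snps, weights)
    snp_rows = []
    for chrom, length, n in zip(chrom_ids, lengths, per_chrom):
        if n == 0:
            continue
        pos = _sample_unique(rng, 1, length + 1, int(n))
        sub = contigs[contigs["chrom"] == chrom].sort_values("start")
        idx = np.searchsorted(sub["start"].to_numpy(), pos, side="right") - 1
        for p, i in zip(pos, idx):
            row = sub.iloc[i]
            snp_rows.append(
                (f"{chrom}_{p}", row["contig"], int(p - row["start"] + 1), chrom, int(p))
            )
    snps = pd.DataFrame(snp_rows, columns=["snp", "contig", "contig_pos", "chrom", "chrom_pos"])
    snps["true_chrom"] = snps["chrom"]
    snps["true_pos"] = snps["chrom_pos"]
    genome = GenomeModel(chromosomes, contigs, snps)
    genome.validate()
    return genome


def synthesize_sequences(genome: GenomeModel, seed: int) -> dict[str, str]:
    """Random nucleotide sequence for every contig (claim lengths)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    seqs = {}
    for row in genome.contigs.itertuples():
        n = int(row.end - row.start + 1)
        seqs[row.contig] = bytes(rng.integers(0, 4, size=n)).translate(
            bytes.maketrans(bytes(range(4)), b"ACGT")
        ).decode()
    return seqs


# ---------------------------------------------------------------------------
# Recombination landscape


@dataclass
class RecombinationLandscape:
    """Piecewise-constant recombination rates (cM/Mb) per chromosome.

    Segments are half-open 0-based bp intervals.  The cumulative genetic
    map is the integral of the rate; crossover positions are drawn uniform
    in genetic coordinate and mapped back through its inverse.
    """

    segments: dict[str, list[tuple[int, int, float]]]

    def __post_init__(self) -> None:
        self._compiled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, segs in self.segments.items():
            segs = sorted(segs)
            if any(rate < 0 for _, _, rate in segs):
                raise ValueError("rates must be >= 0")
            breaks = np.array([segs[0][0]] + [e for _, e, _ in segs], dtype=float)
            rates = np.array([r for _, _, r in segs], dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(np.diff(breaks) * rates / 1e6)])
            self._compiled[chrom] = (breaks, cum)

    @classmethod
    def uniform(cls, genome: GenomeModel, rate_cm_per_mb: float) -> "RecombinationLandscape":
        return cls(
            {
                r.chrom: [(0, int(r.length), rate_cm_per_mb)]
                for r in genome.chromosomes.itertuples()
            }
        )

    @classmethod
    def from_genetic_lengths(
        cls, genome: GenomeModel, cm_per_chromosome: float = 60.0
    ) -> "RecombinationLandscape":
        """Uniform landscape giving every chromosome the same genetic length
        (default 60 cM, ~1.07 cM/Mb on a 56 Mb chromosome)."""
        return cls(
            {
                r.chrom: [(0, int(r.length), cm_per_chromosome / (r.length / 1e6))]
                for r in genome.chromosomes.itertuples()
            }
        )

    def with_interval(
        self, chrom: str, start: int, end: int, factor: float
    ) -> "RecombinationLandscape":
        """New landscape with rates in ``[start, end)`` of ``chrom``
        multiplied by ``factor`` (>1 hotspot, <1 coldspot)."""
        segs = []
        for s, e, r in self.segments[chrom]:
            pieces = sorted({s, e, min(max(start, s), e), min(max(end, s), e)})
            for a, b in zip(pieces[:-1], pieces[1:]):
                segs.append((a, b, r * factor if (a >= start and b <= end) else r))
        new = {c: list(v) for c, v in self.segments.items()}
        new[chrom] = segs
        return RecombinationLandscape(new)

    def genetic_length(self, chrom: str) -> float:
        return float(self._compiled[chrom][1][-1])

    def cm_at(self, chrom: str, bp) -> np.ndarray:
        """Cumulative genetic position (cM) at physical position(s)."""
        breaks, cum = self._compiled[chrom]
        return np.interp(np.asarray(bp, dtype=float), breaks, cum)

    def bp_at(self, chrom: str, cm) -> np.ndarray:
        """Inverse of the cumulative map (plateaus resolved leftward)."""
        breaks, cum = self._compiled[chrom]
        return np.interp(np.asarray(cm, dtype=float), cum, breaks)


def simulate_crossovers(
    landscape: RecombinationLandscape,
    chrom: str,
    multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
    obligate: bool = False,
) -> np.ndarray:
    """Crossover bp positions for one gamete.

    The count is Poisson with mean ``genetic length x multiplier / 100``
    (no interference); positions are uniform in genetic coordinate, mapped
    to bp through the inverse cumulative map.  With ``obligate=True`` at
    least one crossover is forced per gamete (a simplified obligate
    chiasma; default off).
    """
    rng = rng if rng is not None else np.random.default_rng()
    total_cm = landscape.genetic_length(chrom) * multiplier
    if total_cm <= 0:
        return np.array([], dtype=float)
    n = rng.poisson(total_cm / 100.0)
    if obligate and n == 0:
        n = 1
    u = rng.uniform(0.0, landscape.genetic_length(chrom), size=n)
    return np.sort(landscape.bp_at(chrom, u))


# ---------------------------------------------------------------------------
# Families


@dataclass
class FamilyDesign:
    """One F2 family: parents, progeny count, per-parent landscape
    multipliers, per-marker mating types, and nuisance rates.

    ``mating_types`` maps SNP id to one of ``hkxhk``/``lmxll``/``nnxnp``;
    markers absent from it do not segregate in the family.
    """

    family: str
    sire: str
    dam: str
    n_progeny: int
    mating_types: dict[str, str] = field(default_factory=dict)
    sire_multiplier: float = 1.0
    dam_multiplier: float = 1.25
    error_rate: float = 0.025
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("need at least one progeny")
        for rate in (self.error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        bad = set(self.mating_types.values()) - set(MATING_TYPES)
        if bad:
            raise ValueError(f"unknown mating type(s): {sorted(bad)}")


def random_mating_types(
    genome: GenomeModel,
    rng: np.random.Generator,
    probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    inclusion: float = 1.0,
) -> dict[str, str]:
    """Random mating type per SNP; each SNP segregates in the family with
    probability ``inclusion``."""
    types: dict[str, str] = {}
    for snp in genome.snps["snp"]:
        if rng.random() < inclusion:
            types[snp] = MATING_TYPES[rng.choice(3, p=probs)]
    return types


@dataclass
class FamilyResult:
    """Simulated family: clean genotypes, per-parent transmitted haplotypes
    and true genetic positions, plus per-gamete crossover truth."""

    design: FamilyDesign
    genotypes: pd.DataFrame  # markers x progeny, clean calls
    gametes: dict[str, pd.DataFrame]  # role ("sire"/"dam") -> markers x progeny 0/1
    true_positions: pd.DataFrame  # snp, chrom, cm_sire, cm_dam (true map)
    crossovers: list[dict]  # {role, progeny, chrom, positions}


def simulate_family(
    genome: GenomeModel, landscape: RecombinationLandscape, design: FamilyDesign
) -> FamilyResult:
    """Simulate meioses and genotypes for one F2 family.

    Both parents are heterozygous at hk×hk markers, only the dam at lm×ll,
    only the sire at nn×np; phase is coupling (haplotype 0 carries the
    first allele at every marker).  Meiotic positions use the truth columns
    of the genome, so chimeric SNPs injected by :func:`corrupt_assembly`
    segregate with their true chromosome.
    """
    snps = genome.snps[genome.snps["snp"].isin(design.mating_types)].copy()
    if snps.empty:
        raise ValueError("no segregating marker in this family")
    snps = snps.sort_values(["true_chrom", "true_pos"], kind="stable").reset_index(drop=True)
    mtypes = snps["snp"].map(design.mating_types)

    progeny_ids = [f"{design.family}_p{i + 1}" for i in range(design.n_progeny)]
    roles = {"sire": design.sire_multiplier, "dam": design.dam_multiplier}
    hap: dict[str, np.ndarray] = {}
    crossovers: list[dict] = []
    chrom_groups = list(snps.groupby("true_chrom", sort=False))
    for role_idx, (role, mult) in enumerate(roles.items()):
        mat = np.empty((len(snps), design.n_progeny), dtype=np.int8)
        for j in range(design.n_progeny):
            rng = np.random.default_rng(
                np.random.SeedSequence(design.seed, spawn_key=(role_idx, j))
            )
            for chrom, sub in chrom_groups:
                xo = simulate_crossovers(landscape, chrom, mult, rng)
                start = int(rng.integers(2))
                h = (start + np.searchsorted(xo, sub["true_pos"].to_numpy())) % 2
                mat[sub.index.to_numpy(), j] = h
                crossovers.append(
                    {"role": role, "progeny": progeny_ids[j], "chrom": chrom,
                     "positions": xo.tolist()}
                )
        hap[role] = mat

    alleles = {
        "hkxhk": ("hk", "hk"),  # (sire haplotype alleles, dam haplotype alleles)
        "lmxll": ("ll", "lm"),
        "nnxnp": ("np", "nn"),
    }
    geno = np.empty((len(snps), design.n_progeny), dtype=object)
    for i, mt in enumerate(mtypes):
        sire_alleles, dam_alleles = alleles[mt]
        for j in range(design.n_progeny):
            a = sire_alleles[hap["sire"][i, j]]
            b = dam_alleles[hap["dam"][i, j]]
            geno[i, j] = "".join(sorted(a + b))
    genotypes = pd.DataFrame(geno, index=snps["snp"].tolist(), columns=progeny_ids)

    true_positions = pd.DataFrame(
        {
            "snp": snps["snp"],
            "chrom": snps["true_chrom"],
            "mating_type": mtypes.to_numpy(),
        }
    )
    for role, mult in roles.items():
        cm = np.concatenate(
            [landscape.cm_at(chrom, sub["true_pos"].to_numpy()) * mult
             for chrom, sub in chrom_groups]
        )
        order = np.concatenate([sub.index.to_numpy() for _, sub in chrom_groups])
        out = np.empty(len(snps))
        out[order] = cm
        true_positions[f"cm_{role}"] = out

    gametes = {
        role: pd.DataFrame(hap[role], index=snps["snp"].tolist(), columns=progeny_ids)
        for role in roles
    }
    return FamilyResult(design, genotypes, gametes, true_positions, crossovers)


def degrade_genotypes(
    genotypes: pd.DataFrame,
    error_rate: float,
    missing_rate: float,
    mating_types: dict[str, str],
    seed: int,
) -> pd.DataFrame:
    """Apply genotyping error and missingness.

    Each call is independently replaced by a *different* legal genotype of
    its marker's mating type with probability ``error_rate``, then set
    missing (NA) with probability ``missing_rate``.
    """
    for rate in (error_rate, missing_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    out = genotypes.copy()
    values = out.to_numpy(dtype=object)
    flip = rng.random(values.shape) < error_rate
    miss = rng.random(values.shape) < missing_rate
    choose = rng.random(values.shape)
    for i, marker in enumerate(out.index):
        legal = GENOTYPES[mating_types[marker]]
        for j in np.nonzero(flip[i])[0]:
            others = [g for g in legal if g != values[i, j]]
            values[i, j] = others[int(choose[i, j] * len(others))]
    values[miss] = np.nan
    return pd.DataFrame(values, index=out.index, columns=out.columns)


def maps_from_truth(
    genome: GenomeModel,
    landscape: RecombinationLandscape,
    designs: list[FamilyDesign],
    method: str = "TRUE",
) -> list[LinkageMap]:
    """Error-free per-parent linkage maps from the simulator's truth.

    Stands in for an idealized mapper: each parent's map contains the
    markers informative through that parent (hk×hk both, lm×ll dam,
    nn×np sire) at their true cumulative genetic positions, grouped by
    their true chromosome's linkage group.
    """
    informative = {"sire": ("hkxhk", "nnxnp"), "dam": ("hkxhk", "lmxll")}
    maps = []
    for design in designs:
        snps = genome.snps[genome.snps["snp"].isin(design.mating_types)]
        mt = snps["snp"].map(design.mating_types)
        for role, mult in (("sire", design.sire_multiplier), ("dam", design.dam_multiplier)):
            keep = snps[mt.isin(informative[role]).to_numpy()]
            if keep.empty:
                continue
            cm = np.concatenate(
                [
                    landscape.cm_at(chrom, sub["true_pos"].to_numpy()) * mult
                    for chrom, sub in keep.groupby("true_chrom", sort=False)
                ]
            )
            order = np.concatenate(
                [sub.index.to_numpy() for _, sub in keep.groupby("true_chrom", sort=False)]
            )
            entries = pd.DataFrame(
                {
                    "marker": keep["snp"].to_numpy(),
                    "linkage_group": keep["true_chrom"].map(lg_of_chrom).to_numpy(),
                    "position_cm": pd.Series(cm, index=order).sort_index().to_numpy(),
                    "mating_type": keep["snp"].map(design.mating_types).to_numpy(),
                }
            )
            maps.append(LinkageMap(design.family, role, entries, method=method))
    return maps


# ---------------------------------------------------------------------------
# Assembly corruption


@dataclass
class CorruptionPlan:
    """What to break in a genome's assembly claim."""

    n_chimeric_blocks: int = 0
    block_n_snps: tuple[int, int] = (2, 4)  # inclusive range
    block_bp_span: tuple[int, int] = (20, 80)  # median tens of bp
    n_flips: int = 0
    n_moves: int = 0


@dataclass
class TruthRecord:
    """Exact record of the corruptions applied to a genome."""

    blocks: list[dict] = field(default_factory=list)
    flips: list[str] = field(default_factory=list)
    moves: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


def corrupt_assembly(
    genome: GenomeModel, plan: CorruptionPlan, seed: int
) -> tuple[GenomeModel, TruthRecord]:
    """Apply a corruption plan to the genome's assembly claim.

    Chimeric blocks splice a short run of SNPs whose meiotic truth lies on
    a different chromosome into a host contig.  Flips reverse a contig's
    internal coordinates (the claim stays '+' in its own frame); moves
    relocate a contig within its chromosome.  Meiotic truth columns of
    pre-existing SNPs are never touched.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    contigs = genome.contigs.copy()
    snps = genome.snps.copy()
    truth = TruthRecord()
    chrom_lengths = dict(zip(genome.chromosomes["chrom"], genome.chromosomes["length"]))
    contig_info = contigs.set_index("contig")

    # --- chimeric blocks
    snp_counts = snps["contig"].value_counts()
    eligible = [
        c
        for c in contigs["contig"]
        if snp_counts.get(c, 0) >= 3
        and (contig_info.loc[c, "end"] - contig_info.loc[c, "start"] + 1) > plan.block_bp_span[1] * 2
    ]
    if plan.n_chimeric_blocks > len(eligible):
        raise ValueError("not enough eligible host contigs for requested blocks")
    hosts = rng.choice(eligible, size=plan.n_chimeric_blocks, replace=False)
    new_rows = []
    for host in hosts:
        info = contig_info.loc[host]
        host_len = int(info["end"] - info["start"] + 1)
        host_chrom = info["chrom"]
        others = [c for c in chrom_lengths if c != host_chrom]
        source = others[rng.integers(len(others))]
        k = int(rng.integers(plan.block_n_snps[0], plan.block_n_snps[1] + 1))
        span = int(rng.integers(plan.block_bp_span[0], plan.block_bp_span[1] + 1))
        span = max(span, k)
        if span > host_len:
            raise ValueError(f"chimeric block longer than host contig {host}")
        taken = set(snps.loc[snps["contig"] == host, "contig_pos"])
        for _ in range(1000):
            ins = int(rng.integers(1, host_len - span + 2))
            if k == 1:
                pos = np.array([ins])
            else:
                inner = rng.choice(np.arange(ins + 1, ins + span - 1), size=k - 2, replace=False)
                pos = np.sort(np.concatenate([[ins, ins + span - 1], inner]))
            if not taken.intersection(pos):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not place block in {host}")
        src_start = int(rng.integers(1, chrom_lengths[source] - span))
        true_pos = src_start + pos - pos[0]
        ids = [f"{host}_chim_{p}" for p in pos]
        for snp_id, p, tp in zip(ids, pos, true_pos):
            new_rows.append(
                {
                    "snp": snp_id,
                    "contig": host,
                    "contig_pos": int(p),
                    "chrom": host_chrom,
                    "chrom_pos": int(info["start"] + p - 1),
                    "true_chrom": source,
                    "true_pos": int(tp),
                }
            )
        truth.blocks.append(
            {
                "contig": host,
                "snps": ids,
                "start_bp": int(pos[0]),
                "end_bp": int(pos[-1]),
                "true_chrom": source,
            }
        )
    if new_rows:
        snps = pd.concat([snps, pd.DataFrame(new_rows)], ignore_index=True)

    # --- orientation flips: reverse the contig's internal coordinates
    flippable = [c for c in contigs["contig"] if c not in set(hosts)]
    flips = rng.choice(flippable, size=min(plan.n_flips, len(flippable)), replace=False)
    for contig in flips:
        info = contig_info.loc[contig]
        length = int(info["end"] - info["start"] + 1)
        sel = snps["contig"] == contig
        snps.loc[sel, "contig_pos"] = length - snps.loc[sel, "contig_pos"] + 1
        truth.flips.append(str(contig))

    # --- order moves: relocate a contig within its chromosome
    for _ in range(plan.n_moves):
        chrom = genome.chromosomes["chrom"].iloc[int(rng.integers(len(chrom_lengths)))]
        order = contigs[contigs["chrom"] == chrom].sort_values("start")["contig"].tolist()
        if len(order) < 2:
            continue
        i = int(rng.integers(len(order)))
        j = int(rng.integers(len(order) - 1))
        if j >= i:
            j += 1
        moved = order.pop(i)
        order.insert(j, moved)
        pos = 1
        for contig in order:
            length = int(contig_info.loc[contig, "end"] - contig_info.loc[contig, "start"] + 1)
            contigs.loc[contigs["contig"] == contig, ["start", "end"]] = (pos, pos + length - 1)
            pos += length
        contig_info = contigs.set_index("contig")
        truth.moves.append({"chrom": str(chrom), "contig": str(moved), "from": i, "to": j})

    # recompute claim chrom_pos from (possibly moved) contig starts
    starts = contig_info["start"]
    snps["chrom_pos"] = (
        snps["contig"].map(starts).to_numpy(dtype=int) + snps["contig_pos"].to_numpy() - 1
    )
    snps["chrom"] = snps["contig"].map(contig_info["chrom"]).to_numpy()
    snps = snps.sort_values(["chrom", "chrom_pos"], kind="stable").reset_index(drop=True)
    corrupted = GenomeModel(genome.chromosomes.copy(), contigs, snps)
    corrupted.validate()
    return corrupted, truth


__all__ = [
    "GENOTYPES",
    "MATING_TYPES",
    "lg_of_chrom",
    "chrom_of_lg",
    "GenomeConfig",
    "GenomeModel",
    "build_genome",
    "synthesize_sequences",
    "RecombinationLandscape",
    "simulate_crossovers",
    "FamilyDesign",
    "FamilyResult",
    "random_mating_types",
    "simulate_family",
    "degrade_genotypes",
    "maps_from_truth",
    "CorruptionPlan",
    "TruthRecord",
    "corrupt_assembly",
]
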