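"""Shared synteny blocks across three genomes from an orthologue table.

Anchors are gene families present exactly once in each genome.  Pairwise
collinear chains are computed by sparse dynamic programming over anchor
pairs (score = anchors minus a small per-gene gap penalty, maximized over
the anchor DAG), in both orientations, with gaps of up to
``max_gap_genes`` intervening genes tolerated — the signature left by
post-polyploidy fractionation.  Three-genome blocks are maximal runs of
reference-ordered anchors lying in one chain against each of the other
two genomes; each block is then a signed marker, and the three genomes
become signed block orders ready for DCJ arithmetic.  The ancestral
"painting" maps every extant block placement to the median chromosome
carrying its block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome_model import Chromosome, Genome, Marker, validate_genome_set

__all__ = [
    "ChainParams",
    "Chain",
    "BlockPlacement",
    "Block",
    "BlockSet",
    "load_syntelog_table",
    "prepare_table",
    "chain_pairwise",
    "build_blocks",
    "blocks_to_genomes",
    "paint_ancestral",
    "write_painting_bed",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["family_id", "genome", "chromosome", "start_bp", "end_bp", "strand"]


@dataclass(frozen=True)
class ChainParams:
    """Chaining thresholds: gene-gap tolerance and minimum anchors per chain."""

    max_gap_genes: int = 5
    min_anchors: int = 3
    max_gap_bp: int | None = None
    gap_penalty: float = 0.01  # per intervening gene; breaks score ties toward tight chains

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap_genes < 0:
            raise ValueError("max_gap_genes must be >= 0")


@dataclass(frozen=True)
class Chain:
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: int  # +1 collinear, -1 inverted
    families: tuple[str, ...]
    score: float


@dataclass(frozen=True)
class BlockPlacement:
    chromosome: str
    start_bp: int
    end_bp: int
    orientation: int
    families: tuple[str, ...]


@dataclass
class Block:
    block_id: int
    placements: dict[str, BlockPlacement]


@dataclass
class BlockSet:
    blocks: list[Block]
    genomes: tuple[str, ...]
    universe_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            for label, p in sorted(b.placements.items()):
                rows.append(
                    {
                        "block_id": b.block_id,
                        "genome": label,
                        "chromosome": p.chromosome,
                        "start_bp": p.start_bp,
                        "end_bp": p.end_bp,
                        "orientation": "+" if p.orientation > 0 else "-",
                        "n_families": len(p.families),
                    }
                )
        return pd.DataFrame(rows)


def load_syntelog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "chromosome": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"syntelog table missing columns {missing}")
    return prepare_table(df)


def prepare_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate columns and add per-(genome, chromosome) order_index if absent."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"syntelog table missing columns {missing}")
    if (df["start_bp"] > df["end_bp"]).any():
        raise ValueError("start_bp must not exceed end_bp")
    df = df.copy()
    if "order_index" not in df.columns:
        df = df.sort_values(["genome", "chromosome", "start_bp"], kind="stable")
        df["order_index"] = df.groupby(["genome", "chromosome"]).cumcount() + 1
    return df.reset_index(drop=True)


def _single_copy(df: pd.DataFrame, genomes: Sequence[str]) -> pd.DataFrame:
    """Keep families with exactly one row in every requested genome."""
    sub = df[df["genome"].isin(genomes)]
    counts = sub.groupby(["family_id", "genome"]).size().unstack(fill_value=0)
    for g in genomes:
        if g not in counts.columns:
            raise ValueError(f"genome label {g!r} absent from table")
    good = counts.index[(counts[list(genomes)] == 1).all(axis=1)]
    dropped = len(counts.index) - len(good)
    if dropped:
        log.info("dropped %d families without a 1:1 copy in every genome", dropped)
    return sub[sub["family_id"].isin(good)]


def chain_pairwise(
    table: pd.DataFrame, genome_a: str, genome_b: str, params: ChainParams
) -> list[Chain]:
    """Collinear anchor chains between two genomes.

    Strictly monotone in both genomes' gene order (increasing or
    decreasing in b per chain), each anchor in at most one chain; chains
    extracted greedily best-score-first per chromosome pair.
    """
    table = prepare_table(table)
    for g in (genome_a, genome_b):
        if g not in set(table["genome"]):
            raise ValueError(f"unknown genome label {g!r}")
    sub = _single_copy(table, [genome_a, genome_b])
    a = sub[sub["genome"] == genome_a].set_index("family_id")
    b = sub[sub["genome"] == genome_b].set_index("family_id")
    fams = a.index.intersection(b.index)
    # gaps are measured in anchor ranks (intervening anchors), not raw gene
    # indices: fractionation thins the anchor set far below gene density, so
    # gene-index gaps would shatter chains at unrearranged junctions
    a = a.loc[fams].sort_values(["chromosome", "order_index"], kind="stable")
    a["rank"] = a.groupby("chromosome").cumcount()
    b = b.loc[fams].sort_values(["chromosome", "order_index"], kind="stable")
    b["rank"] = b.groupby("chromosome").cumcount()
    pts = pd.DataFrame(
        {
            "family_id": fams,
            "chrom_a": a.loc[fams, "chromosome"].values,
            "ia": a.loc[fams, "rank"].values,
            "chrom_b": b.loc[fams, "chromosome"].values,
            "ib": b.loc[fams, "rank"].values,
            # relative strand: forward chains take concordant anchors only,
            # reverse chains discordant ones — keeps inversion boundaries sharp
            "rel": [
                1 if a.loc[f, "strand"] == b.loc[f, "strand"] else -1 for f in fams
            ],
        }
    )
    chains: list[Chain] = []
    for (ca, cb), grp in pts.groupby(["chrom_a", "chrom_b"], sort=True):
        anchors = list(
            grp.sort_values("ia")[["ia", "ib", "family_id", "rel"]].itertuples(index=False)
        )
        chains.extend(
            _extract_chains(anchors, genome_a, genome_b, str(ca), str(cb), params)
        )
    return chains


def _extract_chains(
    anchors: list, genome_a: str, genome_b: str, ca: str, cb: str, params: ChainParams
) -> list[Chain]:
    remaining = list(anchors)
    out: list[Chain] = []
    while len(remaining) >= params.min_anchors:
        best = None
        for orient in (1, -1):
            chain, score = _best_chain(
                [p for p in remaining if p.rel == orient], orient, params
            )
            if chain and (best is None or score > best[1]):
                best = (chain, score, orient)
        if best is None or len(best[0]) < params.min_anchors:
            break
        chain, score, orient = best
        out.append(
            Chain(
                genome_a,
                genome_b,
                ca,
                cb,
                orient,
                tuple(p.family_id for p in chain),
                score,
            )
        )
        used = {p.family_id for p in chain}
        remaining = [p for p in remaining if p.family_id not in used]
    return out


def _best_chain(pts: list, orient: int, params: ChainParams):
    """Highest-scoring monotone chain by DP over anchors sorted in genome a."""
    n = len(pts)
    if n == 0:
        return [], 0.0
    gap = params.max_gap_genes
    dp = [1.0] * n
    back = [-1] * n
    for i in range(n):
        ia_i, ib_i = pts[i].ia, pts[i].ib
        for j in range(i - 1, -1, -1):
            ia_j, ib_j = pts[j].ia, pts[j].ib
            ga = ia_i - ia_j - 1
            if ga > gap:
                break  # pts sorted by ia: earlier anchors only farther away
            if ga < 0:
                continue
            gb = (ib_i - ib_j - 1) if orient > 0 else (ib_j - ib_i - 1)
            if gb < 0 or gb > gap:
                continue
            cand = dp[j] + 1.0 - params.gap_penalty * (ga + gb)
            if cand > dp[i]:
                dp[i] = cand
                back[i] = j
    end = max(range(n), key=lambda i: (dp[i], -i))
    chain = []
    i = end
    while i != -1:
        chain.append(pts[i])
        i = back[i]
    chain.reverse()
    return chain, dp[end]


def build_blocks(table: pd.DataFrame, params: ChainParams | None = None) -> BlockSet:
    """Three-genome synteny blocks from a syntelog table.

    Blocks are maximal runs of reference-ordered anchors sharing one
    chain against each non-reference genome (reference = alphabetically
    first label).  Per-genome orientation is assigned by majority strand
    agreement with the reference.
    """
    params = params or ChainParams()
    table = prepare_table(table)
    labels = sorted(set(table["genome"]))
    if len(labels) != 3:
        raise ValueError(f"exactly three genomes required, got {labels}")
    ref, g2, g3 = labels
    log.info("reference genome for orientation: %s", ref)
    chains2 = chain_pairwise(table, ref, g2, params)
    chains3 = chain_pairwise(table, ref, g3, params)
    fam_chain2 = {f: i for i, ch in enumerate(chains2) for f in ch.families}
    fam_chain3 = {f: i for i, ch in enumerate(chains3) for f in ch.families}
    sub = _single_copy(table, labels)
    ref_rows = (
        sub[sub["genome"] == ref]
        .sort_values(["chromosome", "order_index"], kind="stable")
        .reset_index(drop=True)
    )
    # anchor rank among the 1:1:1 families on each reference chromosome;
    # unchained anchors still occupy ranks and therefore widen gaps
    ref_rows["rank"] = ref_rows.groupby("chromosome").cumcount()
    runs: list[list[str]] = []
    cur_key = None
    prev_rank = None
    cur_run: list[str] = []
    for row in ref_rows.itertuples(index=False):
        f = row.family_id
        c2, c3 = fam_chain2.get(f), fam_chain3.get(f)
        if c2 is None or c3 is None:
            continue
        key = (row.chromosome, c2, c3)
        gap_break = prev_rank is not None and row.rank - prev_rank - 1 > params.max_gap_genes
        if key != cur_key or gap_break:
            if cur_run:
                runs.append(cur_run)
            cur_run = []
            cur_key = key
        cur_run.append(f)
        prev_rank = row.rank
    if cur_run:
        runs.append(cur_run)
    runs = [r for r in runs if len(r) >= params.min_anchors]

    by_gf = sub.set_index(["genome", "family_id"])
    blocks: list[Block] = []
    for bid, fams in enumerate(runs, 1):
        placements: dict[str, BlockPlacement] = {}
        ref_strands = {f: by_gf.loc[(ref, f), "strand"] for f in fams}
        for g in labels:
            rows = by_gf.loc[[(g, f) for f in fams]]
            chroms = set(rows["chromosome"])
            if len(chroms) != 1:
                # chain constraints should prevent this; split responsibility is theirs
                raise RuntimeError(f"block {bid} spans multiple chromosomes in {g}")
            if g == ref:
                orient = 1
            else:
                agree = sum(
                    1
                    for f in fams
                    if by_gf.loc[(g, f), "strand"] == ref_strands[f]
                )
                orient = 1 if agree * 2 >= len(fams) else -1
            placements[g] = BlockPlacement(
                chromosome=str(chroms.pop()),
                start_bp=int(rows["start_bp"].min()),
                end_bp=int(rows["end_bp"].max()),
                orientation=orient,
                families=tuple(fams),
            )
        blocks.append(Block(bid, placements))
    return BlockSet(blocks=blocks, genomes=tuple(labels), universe_size=len(blocks))


def blocks_to_genomes(bs: BlockSet) -> list[Genome]:
    """Signed block-order genomes from a block set (sorted by chromosome, start)."""
    missing = [
        b.block_id for b in bs.blocks for g in bs.genomes if g not in b.placements
    ]
    if missing:
        raise ValueError(f"blocks missing in some genome: {sorted(set(missing))}")
    genomes = []
    for g in bs.genomes:
        placed = sorted(
            ((b.placements[g], b.block_id) for b in bs.blocks),
            key=lambda t: (t[0].chromosome, t[0].start_bp),
        )
        genome = Genome(g)
        cur_chrom = None
        markers: list[Marker] = []
        for p, bid in placed:
            if p.chromosome != cur_chrom:
                if markers:
                    genome.chromosomes.append(Chromosome(cur_chrom, tuple(markers)))
                cur_chrom, markers = p.chromosome, []
            markers.append(Marker(bid, p.orientation))
        if markers:
            genome.chromosomes.append(Chromosome(cur_chrom, tuple(markers)))
        genomes.append(genome)
    rep = validate_genome_set(genomes)
    if not rep.ok:
        raise RuntimeError("block-order genomes failed validation: " + "; ".join(rep.messages))
    return genomes


def paint_ancestral(bs: BlockSet, median: Genome) -> pd.DataFrame:
    """Map every extant block placement to its ancestral (median) chromosome."""
    anc_of = {m.id: c.name for c in median.chromosomes for m in c.markers}
    ids = {b.block_id for b in bs.blocks}
    if set(anc_of) != ids:
        raise ValueError("median marker universe does not match block ids")
    rows = []
    for b in bs.blocks:
        for g, p in sorted(b.placements.items()):
            rows.append(
                {
                    "genome": g,
                    "chromosome": p.chromosome,
                    "start_bp": p.start_bp,
                    "end_bp": p.end_bp,
                    "block_id": b.block_id,
                    "orientation": "+" if p.orientation > 0 else "-",
                    "ancestral_chromosome": anc_of[b.block_id],
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["genome", "chromosome", "start_bp"], kind="stable"
    ).reset_index(drop=True)


def write_painting_bed(painting: pd.DataFrame, path: str | Path) -> None:
    """BED-like output: chrom, start (0-based), end, block_id, 0, strand, ancestral chromosome."""
    with open(path, "w") as fh:
        for row in painting.itertuples(index=False):
            fh.write(
                f"{row.genome}.{row.chromosome}\t{row.start_bp}\t{row.end_bp}\t"
                f"block_{row.block_id}\t0\t{row.orientation}\t{row.ancestral_chromosome}\n"
            )
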