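"""Signed block-order genomes: data model, validation, and GRIMM/TSV I/O.

A genome here is nothing more than an ordered arrangement of signed
markers (synteny blocks) on named chromosomes.  No sequence, no base-pair
coordinates: rearrangement mathematics (double-cut-and-join and the median
problem) depends only on marker order and orientation.  Coordinates live
in the synteny-block layer, not here.

Two text carriers are supported:

* GRIMM-like: ``>label`` headers, one chromosome per line as
  whitespace-separated signed integers, terminated by ``$`` (linear) or
  ``@`` (circular).
* A TSV dialect with columns ``genome, chromosome, index, block_id,
  strand`` (header required, 1-based index).

Genome equality is *structural*: two genomes are equal when their
adjacency/telomere sets coincide, so chromosome naming, listing order and
whole-chromosome flips are all irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

__all__ = [
    "Marker",
    "Chromosome",
    "Genome",
    "Extremity",
    "ValidationReport",
    "GenomeFormatError",
    "genome_elements",
    "chromosome_elements",
    "read_genomes",
    "write_genomes",
    "validate_genome_set",
]


class GenomeFormatError(ValueError):
    """Raised for malformed genome files or inconsistent genome content."""


@dataclass(frozen=True, slots=True)
class Marker:
    """An oriented synteny block: positive integer identity plus a sign."""

    id: int
    sign: int

    def __post_init__(self) -> None:
        if not (isinstance(self.id, int) and self.id >= 1):
            raise ValueError(f"marker id must be a positive integer, got {self.id!r}")
        if self.sign not in (1, -1):
            raise ValueError(f"marker sign must be +1 or -1, got {self.sign!r}")

    def flipped(self) -> "Marker":
        return Marker(self.id, -self.sign)

    def token(self) -> str:
        return str(self.id) if self.sign > 0 else f"-{self.id}"

    @staticmethod
    def from_token(tok: str) -> "Marker":
        sign = 1
        if tok.startswith("-"):
            sign, tok = -1, tok[1:]
        elif tok.startswith("+"):
            tok = tok[1:]
        if not tok.isdigit() or int(tok) < 1:
            raise GenomeFormatError(f"malformed marker token {tok!r}")
        return Marker(int(tok), sign)


class Extremity(NamedTuple):
    """One end of an oriented marker: its head (``h``) or tail (``t``)."""

    marker_id: int
    side: str  # "h" | "t"

    def other(self) -> "Extremity":
        return Extremity(self.marker_id, "t" if self.side == "h" else "h")


def _left(m: Marker) -> Extremity:
    """Extremity entering the marker when read left-to-right."""
    return Extremity(m.id, "t" if m.sign > 0 else "h")


def _right(m: Marker) -> Extremity:
    return Extremity(m.id, "h" if m.sign > 0 else "t")


@dataclass(frozen=True)
class Chromosome:
    """An ordered, signed run of markers; linear by default.

    Equality is orientation-free: a chromosome equals its reversed,
    sign-flipped image (and, if circular, any rotation thereof).
    """

    name: str
    markers: tuple[Marker, ...]
    topology: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if not self.markers:
            raise ValueError("chromosome must carry at least one marker")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def reversed(self) -> "Chromosome":
        return Chromosome(
            self.name,
            tuple(m.flipped() for m in reversed(self.markers)),
            self.topology,
        )

    def _canonical(self) -> tuple:
        fwd = tuple((m.id, m.sign) for m in self.markers)
        rev = tuple((m.id, -m.sign) for m in reversed(self.markers))
        if self.topology == "linear":
            return ("linear", min(fwd, rev))
        rots = [fwd[i:] + fwd[:i] for i in range(len(fwd))]
        rots += [rev[i:] + rev[:i] for i in range(len(rev))]
        return ("circular", min(rots))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromosome):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())


def chromosome_elements(chrom: Chromosome) -> frozenset[frozenset[Extremity]]:
    """Adjacencies and telomeres of one chromosome as frozensets.

    Adjacencies are two-element sets of extremities, telomeres singletons;
    a circular chromosome has no telomeres, its closing adjacency joining
    last and first marker.
    """
    out: set[frozenset[Extremity]] = set()
    ms = chrom.markers
    for a, b in zip(ms, ms[1:]):
        out.add(frozenset({_right(a), _left(b)}))
    if chrom.topology == "linear":
        out.add(frozenset({_left(ms[0])}))
        out.add(frozenset({_right(ms[-1])}))
    else:
        out.add(frozenset({_right(ms[-1]), _left(ms[0])}))
    return frozenset(out)


@dataclass
class Genome:
    """A labelled set of chromosomes over a marker universe.

    The invariant enforced by :func:`validate_genome_set` is that every
    marker id occurs exactly once across all chromosomes.  Equality
    compares adjacency/telomere sets (content), not labels or chromosome
    order.
    """

    label: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def marker_ids(self) -> list[int]:
        return [m.id for c in self.chromosomes for m in c.markers]

    def universe(self) -> frozenset[int]:
        return frozenset(self.marker_ids())

    def n_markers(self) -> int:
        return len(self.marker_ids())

    def elements(self) -> frozenset[frozenset[Extremity]]:
        return genome_elements(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return genome_elements(self) == genome_elements(other)

    def __hash__(self) -> int:
        return hash(genome_elements(self))


def genome_elements(g: Genome) -> frozenset[frozenset[Extremity]]:
    """The adjacency/telomere set of a genome — its structural identity."""
    out: set[frozenset[Extremity]] = set()
    for c in g.chromosomes:
        out |= chromosome_elements(c)
    return frozenset(out)


@dataclass
class ValidationReport:
    """Outcome of marker-content validation across a genome set."""

    ok: bool
    duplicated_ids: list[tuple[str, int]]
    missing_ids: list[tuple[str, int]]
    messages: list[str] = field(default_factory=list)


def validate_genome_set(genomes: Sequence[Genome]) -> ValidationReport:
    """Check that every genome carries the shared marker universe exactly once.

    The universe is the union of all marker ids seen; any genome missing
    part of it, or carrying an id more than once, is reported.  Always
    returns a report, never raises.
    """
    if not genomes:
        return ValidationReport(False, [], [], ["empty genome set"])
    universe: set[int] = set()
    for g in genomes:
        universe |= set(g.marker_ids())
    dup: list[tuple[str, int]] = []
    mis: list[tuple[str, int]] = []
    msgs: list[str] = []
    labels = [g.label for g in genomes]
    if len(set(labels)) != len(labels):
        msgs.append("duplicate genome labels")
    for g in genomes:
        ids = g.marker_ids()
        seen: set[int] = set()
        for i in ids:
            if i in seen:
                dup.append((g.label, i))
            seen.add(i)
        for i in sorted(universe - seen):
            mis.append((g.label, i))
    for lab, i in dup:
        msgs.append(f"genome {lab}: marker {i} duplicated")
    for lab, i in mis:
        msgs.append(f"genome {lab}: marker {i} missing from shared universe")
    ok = not dup and not mis and len(set(labels)) == len(labels)
    return ValidationReport(ok, dup, mis, msgs)


# ---------------------------------------------------------------------------
# I/O


def read_genomes(path: str | Path, format: str = "grimm") -> list[Genome]:
    path = Path(path)
    if format == "grimm":
        return _read_grimm(path)
    if format == "tsv":
        return _read_tsv(path)
    raise GenomeFormatError(f"unknown format {format!r}")


def _read_grimm(path: Path) -> list[Genome]:
    genomes: list[Genome] = []
    labels: set[str] = set()
    cur: Genome | None = None
    pending: list[Marker] = []
    nchrom = 0

    def finish_genome() -> None:
        nonlocal cur, pending, nchrom
        if pending:
            raise GenomeFormatError(
                f"{path}: chromosome without '$'/'@' terminator in genome "
                f"{cur.label if cur else '?'}"
            )
        cur, pending, nchrom = None, [], 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur is not None:
                    finish_genome()
                label = line[1:].strip()
                if not label:
                    raise GenomeFormatError(f"{path}:{lineno}: empty genome label")
                if label in labels:
                    raise GenomeFormatError(f"{path}:{lineno}: duplicate genome label {label!r}")
                labels.add(label)
                cur = Genome(label)
                genomes.append(cur)
                nchrom = 0
                continue
            if cur is None:
                raise GenomeFormatError(f"{path}:{lineno}: data before first '>' header")
            for tok in line.split():
                if tok in ("$", "@"):
                    if not pending:
                        raise GenomeFormatError(f"{path}:{lineno}: empty chromosome")
                    nchrom += 1
                    topo = "linear" if tok == "$" else "circular"
                    cur.chromosomes.append(
                        Chromosome(f"chr{nchrom}", tuple(pending), topo)
                    )
                    pending = []
                else:
                    try:
                        pending.append(Marker.from_token(tok))
                    except GenomeFormatError as e:
                        raise GenomeFormatError(f"{path}:{lineno}: {e}") from None
    if cur is not None:
        finish_genome()
    if not genomes:
        raise GenomeFormatError(f"{path}: no genomes found")
    return genomes


def _read_tsv(path: Path) -> list[Genome]:
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "chromosome": str})
    required = {"genome", "chromosome", "index", "block_id", "strand"}
    if not required.issubset(df.columns):
        raise GenomeFormatError(
            f"{path}: TSV requires columns {sorted(required)}, got {list(df.columns)}"
        )
    genomes: list[Genome] = []
    for label, gdf in df.groupby("genome", sort=True):
        g = Genome(str(label))
        for chrom, cdf in gdf.groupby("chromosome", sort=True):
            cdf = cdf.sort_values("index")
            markers = []
            for _, row in cdf.iterrows():
                strand = str(row["strand"])
                if strand not in ("+", "-"):
                    raise GenomeFormatError(f"{path}: bad strand {strand!r}")
                markers.append(Marker(int(row["block_id"]), 1 if strand == "+" else -1))
            g.chromosomes.append(Chromosome(str(chrom), tuple(markers)))
        genomes.append(g)
    return genomes


def write_genomes(
    genomes: Sequence[Genome], path: str | Path, format: str = "grimm"
) -> None:
    """Serialize genomes deterministically (genomes by label, chromosomes by name)."""
    if not genomes:
        raise ValueError("refusing to write an empty genome set")
    for g in genomes:
        if not g.chromosomes:
            raise ValueError(f"genome {g.label!r} has no chromosomes")
    path = Path(path)
    ordered = sorted(genomes, key=lambda g: g.label)
    if format == "grimm":
        with open(path, "w") as fh:
            for g in ordered:
                fh.write(f">{g.label}\n")
                for c in sorted(g.chromosomes, key=lambda c: c.name):
                    term = "$" if c.topology == "linear" else "@"
                    fh.write(" ".join(m.token() for m in c.markers) + f" {term}\n")
    elif format == "tsv":
        rows = []
        for g in ordered:
            for c in sorted(g.chromosomes, key=lambda c: c.name):
                for i, m in enumerate(c.markers, 1):
                    rows.append(
                        {
                            "genome": g.label,
                            "chromosome": c.name,
                            "index": i,
                            "block_id": m.id,
                            "strand": "+" if m.sign > 0 else "-",
                        }
                    )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise GenomeFormatError(f"unknown format {format!r}")
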