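"""Backsplice-junction records, coordinate-convention handling and set overlap.

Most circRNA databases identify a circRNA solely by its backsplice junction —
the genomic coordinate pair joined head-to-tail — but they disagree on the
coordinate convention (0- vs 1-based starts, inclusive vs exclusive ends).
Comparing catalogs therefore needs 1-bp adjustments per source dialect. The
canonical internal convention here is BED-style: 0-based, half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "JunctionError",
    "BackspliceJunction",
    "JunctionDialect",
    "BUILTIN_DIALECTS",
    "load_dialects",
    "normalize_junction",
    "denormalize_junction",
    "JunctionOverlap",
    "compare_junction_sets",
    "read_bed",
    "write_bed",
]

STRANDS = ("+", "-", ".")


class JunctionError(ValueError):
    """Invalid junction coordinates or dialect."""


@dataclass(frozen=True, order=True)
class BackspliceJunction:
    """A backsplice junction in canonical 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise JunctionError("empty chromosome name")
        if self.start < 0:
            raise JunctionError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise JunctionError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise JunctionError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def key(self, with_strand: bool = False):
        base = (self.chrom, self.start, self.end)
        return base + (self.strand,) if with_strand else base


@dataclass(frozen=True)
class JunctionDialect:
    """How a source annotates junction boundaries.

    ``start_basis`` is 0 or 1 (the coordinate of the first base);
    ``end_inclusive`` says whether the end coordinate is the last included
    base (True) or one past it (False).
    """

    name: str
    start_basis: int
    end_inclusive: bool

    def __post_init__(self) -> None:
        if self.start_basis not in (0, 1):
            raise JunctionError(f"start_basis must be 0 or 1, got {self.start_basis}")


CANONICAL = JunctionDialect("bed", start_basis=0, end_inclusive=False)

#: Built-in registry. The per-database conventions are documented best guesses
#: (databases rarely state them); override with :func:`load_dialects`.
BUILTIN_DIALECTS: dict[str, JunctionDialect] = {
    d.name: d
    for d in (
        CANONICAL,
        JunctionDialect("one_based_inclusive", 1, True),
        # CIRCexplorer2 emits BED, so 0-based half-open.
        JunctionDialect("circexplorer2", 0, False),
        # circAtlas and circBase publish 1-based fully-closed coordinates.
        JunctionDialect("circatlas", 1, True),
        JunctionDialect("circbase", 1, True),
        JunctionDialect("mioncocirc", 1, True),
    )
}


def load_dialects(path) -> dict[str, JunctionDialect]:
    """Load a dialect registry from YAML: ``name: {start_basis, end_inclusive}``.

    Entries extend/override the built-in registry.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    registry = dict(BUILTIN_DIALECTS)
    for name, spec in raw.items():
        registry[name] = JunctionDialect(
            name, int(spec["start_basis"]), bool(spec["end_inclusive"])
        )
    return registry


def normalize_junction(
    chrom: str, start: int, end: int, dialect: JunctionDialect, strand: str = "."
) -> BackspliceJunction:
    """Convert raw coordinates under ``dialect`` to the canonical convention."""
    start0 = start - dialect.start_basis
    end0 = end - dialect.start_basis + (1 if dialect.end_inclusive else 0)
    return BackspliceJunction(chrom, start0, end0, strand)


def denormalize_junction(
    j: BackspliceJunction, dialect: JunctionDialect
) -> tuple[str, int, int, str]:
    """Inverse of :func:`normalize_junction`: canonical → dialect coordinates."""
    start = j.start + dialect.start_basis
    end = j.end + dialect.start_basis - (1 if dialect.end_inclusive else 0)
    return (j.chrom, start, end, j.strand)


@dataclass
class JunctionOverlap:
    """Overlap report for two normalized junction sets."""

    a_only: int
    b_only: int
    shared: int
    shared_junctions: list = field(default_factory=list)

    @property
    def total_a(self) -> int:
        return self.a_only + self.shared

    @property
    def total_b(self) -> int:
        return self.b_only + self.shared


def compare_junction_sets(
    a, b, match_strand: bool = False
) -> JunctionOverlap:
    """Exact-coordinate overlap of two sets of canonical junctions.

    Identity is ``(chrom, start, end)`` equality, plus strand when
    ``match_strand``. Inputs must already be :class:`BackspliceJunction`
    (i.e. normalized); anything else raises.
    """
    def keyset(js, label):
        keys = set()
        for j in js:
            if not isinstance(j, BackspliceJunction):
                raise JunctionError(
                    f"unnormalized record in set {label}: {j!r}; "
                    "call normalize_junction first"
                )
            keys.add(j.key(with_strand=match_strand))
        return keys

    ka, kb = keyset(a, "a"), keyset(b, "b")
    shared_keys = ka & kb
    shared = sorted(
        BackspliceJunction(*k) if len(k) == 4 else BackspliceJunction(*k[:3])
        for k in shared_keys
    )
    return JunctionOverlap(
        a_only=len(ka - kb),
        b_only=len(kb - ka),
        shared=len(shared_keys),
        shared_junctions=shared,
    )


def read_bed(path, dialect: JunctionDialect = CANONICAL) -> list[BackspliceJunction]:
    """Read junctions from a BED-like file (chrom, start, end[, name, score, strand]).

    Coordinates are interpreted under ``dialect`` and normalized.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise JunctionError(f"{path}:{lineno}: expected ≥3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise JunctionError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            out.append(normalize_junction(fields[0], start, end, dialect, strand))
    return out


def write_bed(junctions, path) -> None:
    """Write canonical junctions as 6-column BED (name '.', score 0)."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t.\t0\t{j.strand}\n")
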