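"""Annotated toy-genome types shared by the simulator and the metaplot stages.

Coordinates are 0-based half-open throughout; BED/bedGraph files are written
in their native dialect, which is the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome records (name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has nonpositive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def n_bins(self, chrom: str, resolution: int) -> int:
        return -(-self.length(chrom) // resolution)


@dataclass(frozen=True)
class Origin:
    """A replication origin (ARS) with its population firing time.

    ``position`` is the element midpoint used as the metaplot anchor;
    ``firing_time`` is minutes into S phase.
    """

    id: str
    chrom: str
    position: int
    firing_time: float

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"origin {self.id}: negative position {self.position}")
        if self.firing_time < 0:
            raise ValueError(f"origin {self.id}: negative firing time {self.firing_time}")


@dataclass(frozen=True)
class GeneAnnot:
    """A gene interval with strand and a TPM-like expression abundance."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    expression: float = 0.0

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.id}: start {self.start} must be < end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.expression < 0:
            raise ValueError(f"gene {self.id}: negative expression {self.expression}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start: BED start for + genes, end − 1 for − genes."""
        return self.start if self.strand == "+" else self.end - 1


def validate_origins(origins, genome: GenomeModel) -> None:
    """Check every origin sits inside its chromosome; raise naming offenders."""
    for o in origins:
        if o.chrom not in genome:
            raise ValueError(f"origin {o.id} on unknown chromosome {o.chrom!r}")
        if not 0 <= o.position < genome.length(o.chrom):
            raise ValueError(
                f"origin {o.id} position {o.position} outside {o.chrom} "
                f"(length {genome.length(o.chrom)})"
            )


def validate_genes(genes, genome: GenomeModel) -> None:
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom!r}")
        if g.end > genome.length(g.chrom):
            raise ValueError(
                f"gene {g.id} end {g.end} beyond {g.chrom} length {genome.length(g.chrom)}"
            )
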