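"""Binned signal containers and readers/writers for the pipeline's text formats.

All tracks are fixed-width binned per chromosome (default 200 bp).  bedGraph
intervals are length-weighted averaged into bins on read; on write, maximal
runs of equal-valued bins are merged into single intervals, so a read/write
round trip at equal resolution is the identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import GeneAnnot, GenomeModel, Origin

CONDITIONS = ("SR", "SR_IAA", "NR_IAA")
KINDS = ("IP", "input", "enrichment")


@dataclass
class SignalTrack:
    """Per-chromosome binned signal with time/condition/kind metadata."""

    genome: GenomeModel
    resolution: int
    data: dict[str, np.ndarray]
    time: float | None = None
    condition: str | None = None
    kind: str | None = None

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for chrom in self.genome.names:
            if chrom not in self.data:
                raise ValueError(f"track missing chromosome {chrom!r}")
            expect = self.genome.n_bins(chrom, self.resolution)
            if len(self.data[chrom]) != expect:
                raise ValueError(
                    f"{chrom}: expected {expect} bins at {self.resolution} bp, "
                    f"got {len(self.data[chrom])}"
                )
        if self.kind in ("IP", "input"):
            for chrom, v in self.data.items():
                if np.any(v < 0):
                    raise ValueError(f"negative values on {chrom} in a {self.kind} track")

    @classmethod
    def zeros(cls, genome: GenomeModel, resolution: int, **meta) -> "SignalTrack":
        data = {
            c: np.zeros(genome.n_bins(c, resolution)) for c in genome.names
        }
        return cls(genome, resolution, data, **meta)

    def same_grid(self, other: "SignalTrack") -> bool:
        return (
            self.genome.chromosomes == other.genome.chromosomes
            and self.resolution == other.resolution
        )

    def genome_mean(self) -> float:
        """Genome-wide mean over all bins (bins are equal width, so unweighted)."""
        return float(np.mean(np.concatenate([self.data[c] for c in self.genome.names])))

    def copy(self) -> "SignalTrack":
        return replace(self, data={c: v.copy() for c, v in self.data.items()})


@dataclass
class TimeCourse:
    """Ordered (time, track) series sharing genome, resolution, condition, kind."""

    tracks: list[SignalTrack]

    def __post_init__(self):
        if not self.tracks:
            raise ValueError("empty time course")
        times = [t.time for t in self.tracks]
        if any(t is None for t in times):
            raise ValueError("every member track needs a time label")
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError(f"times must be strictly increasing, got {times}")
        first = self.tracks[0]
        for t in self.tracks[1:]:
            if not first.same_grid(t):
                raise ValueError("member tracks are not dimensionally identical")
            if t.condition != first.condition or t.kind != first.kind:
                raise ValueError("member tracks mix conditions or kinds")

    @property
    def times(self) -> list[float]:
        return [t.time for t in self.tracks]

    @property
    def genome(self) -> GenomeModel:
        return self.tracks[0].genome

    @property
    def resolution(self) -> int:
        return self.tracks[0].resolution

    @property
    def condition(self) -> str | None:
        return self.tracks[0].condition

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self):
        return len(self.tracks)


@dataclass(frozen=True)
class SpikeInCounts:
    """The four read tallies entering the spike-in calibration factor k.

    ``*_sample`` are sample-genome (S. cerevisiae) reads, ``*_spike`` are
    spike-in-genome (S. pombe) reads, for the IP and the input libraries.
    """

    ip_sample: int
    ip_spike: int
    in_sample: int
    in_spike: int

    def __post_init__(self):
        for name in ("ip_sample", "ip_spike", "in_sample", "in_spike"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.ip_spike == 0:
            raise ValueError("ip_spike is zero: the IP spike-in tally is a denominator of k")
        if self.in_sample == 0:
            raise ValueError("in_sample is zero: the input sample tally is a denominator of k")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path, genome: GenomeModel, resolution: int, **meta
) -> SignalTrack:
    """Read a 4-column bedGraph into a fixed-bin track.

    Interval values are length-weighted averaged into bins; uncovered bins
    read as 0.  Intervals must lie within the genome and must not overlap.
    """
    acc = {c: np.zeros(genome.n_bins(c, resolution)) for c in genome.names}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= s < e <= genome.length(chrom):
                raise ValueError(f"{path}:{lineno}: interval [{s},{e}) outside {chrom}")
            if s < last_end.get(chrom, 0):
                raise ValueError(f"{path}:{lineno}: overlapping interval on {chrom}")
            last_end[chrom] = e
            _spread(acc[chrom], s, e, v, resolution)
    data = {}
    for c in genome.names:
        # divide accumulated mass by each bin's physical width (the final
        # bin of a chromosome may be narrower than the resolution), so that
        # sum(value * width) always equals the bedGraph integral
        n = genome.n_bins(c, resolution)
        widths = np.minimum(resolution, genome.length(c) - np.arange(n) * resolution)
        data[c] = acc[c] / widths
    return SignalTrack(genome, resolution, data, **meta)


def _spread(acc: np.ndarray, start: int, end: int, value: float, res: int):
    """Add ``value * overlap`` over [start, end) into bin accumulators."""
    b0, b1 = start // res, (end - 1) // res
    for b in range(b0, b1 + 1):
        lo, hi = max(start, b * res), min(end, (b + 1) * res)
        acc[b] += value * (hi - lo)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as bedGraph, merging maximal runs of equal-valued bins."""
    res = track.resolution
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            vals = track.data[chrom]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values on {chrom}")
            length = track.genome.length(chrom)
            if len(vals) == 0:
                continue
            run_start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[run_start]:
                    s = run_start * res
                    e = min(i * res, length)
                    fh.write(f"{chrom}\t{s}\t{e}\t{vals[run_start]:.17g}\n")
                    run_start = i


# ---------------------------------------------------------------------------
# annotation tables


def read_genome_table(path) -> GenomeModel:
    """Two-column TSV (chrom, length), optional header."""
    chroms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
            chroms.append((parts[0], int(parts[1])))
    return GenomeModel(tuple(chroms))


def read_origins(bed_path, timing_path, genome: GenomeModel | None = None) -> list[Origin]:
    """BED6 of origin intervals (anchor = midpoint) joined with a firing-time TSV.

    The timing sidecar has columns ``id`` and ``firing_time_min``.  Every BED
    origin must have a timing row.
    """
    timings: dict[str, float] = {}
    with open(timing_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] in ("id", "origin_id"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{timing_path}:{lineno}: expected id<TAB>firing_time_min")
            if parts[0] in timings:
                raise ValueError(f"{timing_path}:{lineno}: duplicate origin id {parts[0]!r}")
            timings[parts[0]] = float(parts[1])
    origins = []
    seen = set()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{bed_path}:{lineno}: BED needs >= 4 columns for origins")
            chrom, s, e, oid = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if oid in seen:
                raise ValueError(f"{bed_path}:{lineno}: duplicate origin id {oid!r}")
            seen.add(oid)
            if oid not in timings:
                raise ValueError(f"origin {oid!r} has no firing time in {timing_path}")
            origins.append(Origin(oid, chrom, (s + e) // 2, timings[oid]))
    missing = set(timings) - seen
    if missing:
        raise ValueError(f"timing rows without BED origins: {sorted(missing)}")
    if genome is not None:
        from .genome import validate_origins

        validate_origins(origins, genome)
    return origins


def read_genes(bed_path, expression_path=None, genome: GenomeModel | None = None) -> list[GeneAnnot]:
    """BED6 genes; if an expression TSV is given, every gene must appear in it."""
    expr: dict[str, float] = {}
    if expression_path is not None:
        expr = read_expression(expression_path)
    genes = []
    seen = set()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{bed_path}:{lineno}: gene BED needs 6 columns (strand)")
            chrom, s, e, gid, _score, strand = parts[:6]
            if gid in seen:
                raise ValueError(f"{bed_path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            abundance = 0.0
            if expression_path is not None:
                if gid not in expr:
                    raise ValueError(f"gene {gid!r} missing from expression table {expression_path}")
                abundance = expr[gid]
            genes.append(GeneAnnot(gid, chrom, int(s), int(e), strand, abundance))
    if genome is not None:
        from .genome import validate_genes

        validate_genes(genes, genome)
    return genes


def read_expression(path) -> dict[str, float]:
    """TSV with header (gene_id, abundance)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene_id<TAB>abundance")
            if parts[0] in out:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {parts[0]!r}")
            v = float(parts[1])
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative abundance {v}")
            out[parts[0]] = v
    return out


def read_spike_counts(path) -> dict[tuple[str, float], SpikeInCounts]:
    """TSV with header (condition, time_min, ip_sample, ip_spike, in_sample, in_spike)."""
    out: dict[tuple[str, float], SpikeInCounts] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"condition", "time_min", "ip_sample", "ip_spike", "in_sample", "in_spike"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        for row in reader:
            key = (row["condition"], float(row["time_min"]))
            if key in out:
                raise ValueError(f"{path}: duplicate entry for {key}")
            out[key] = SpikeInCounts(
                ip_sample=int(row["ip_sample"]),
                ip_spike=int(row["ip_spike"]),
                in_sample=int(row["in_sample"]),
                in_spike=int(row["in_spike"]),
            )
    return out
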