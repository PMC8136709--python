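"""Feature-anchored averaging and stratified group summaries.

Covers the figure-level analyses: origin (ARS) metaprofiles by
replication-time quartile, TSS/gene-body profiles by expression quartile or
by gene-length bin, unit-range rescaling for cross-group comparison,
half-rise-time extraction (the delay statistic), and the origin-to-telomere
distance control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .genome import GeneAnnot, GenomeModel, Origin
from .tracks import SignalTrack, TimeCourse

log = logging.getLogger(__name__)

LENGTH_BINS = ((500, 1000), (1000, 1500), (1500, 2000), (2000, None))


@dataclass
class MetaProfile:
    """Per-offset mean signal around a set of anchors (5'->3' orientation)."""

    offsets: np.ndarray  # bp relative to the anchor; negative = upstream
    values: np.ndarray
    n_features: int
    label: str = ""

    def __post_init__(self):
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values differ in length")
        if self.n_features < 1:
            raise ValueError("profile needs at least one contributing feature")


@dataclass
class GroupSummary:
    """Scalar mean per timepoint for one feature group."""

    label: str
    times: np.ndarray
    values: np.ndarray
    rescaled: np.ndarray | None = None

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")


# ---------------------------------------------------------------------------
# grouping


def quantile_groups(features, key, n_groups: int = 4, labels=None):
    """Rank-based equal-count groups, ascending in ``key``.

    Ties break by feature id (stable); when the count does not divide
    evenly the earliest groups take the remainder.  Returns a list of
    (label, [features]) pairs covering the input disjointly.
    """
    feats = list(features)
    if len(feats) < n_groups:
        raise ValueError(f"{len(feats)} features cannot fill {n_groups} groups")
    feats.sort(key=lambda f: (key(f), f.id))
    base, rem = divmod(len(feats), n_groups)
    if labels is None:
        labels = [f"Q{i + 1}" for i in range(n_groups)]
    out = []
    pos = 0
    for i in range(n_groups):
        size = base + (1 if i < rem else 0)
        out.append((labels[i], feats[pos:pos + size]))
        pos += size
    return out


def length_groups(genes):
    """Fixed gene-length bins: [500,1000), [1000,1500), [1500,2000), [2000,inf).

    Genes shorter than 500 bp are excluded (logged).
    """
    out = [(f"{lo}-{hi}bp" if hi else f">{lo}bp", []) for lo, hi in LENGTH_BINS]
    for g in genes:
        L = g.length
        if L < 500:
            log.info("length_groups: excluding %s (%d bp < 500 bp)", g.id, L)
            continue
        for (lo, hi), (_, bucket) in zip(LENGTH_BINS, out):
            if L >= lo and (hi is None or L < hi):
                bucket.append(g)
                break
    return out


# ---------------------------------------------------------------------------
# anchored averaging


def anchored_profile(
    track: SignalTrack, anchors, flank: int, label: str = ""
) -> MetaProfile:
    """Mean track value at each bin-grid offset in [-flank, +flank].

    ``anchors`` are (chrom, position, strand) triples or objects with those
    attributes; for '-' anchors the offset axis is flipped so it always runs
    5'->3'.  Anchors whose window leaves the chromosome are dropped and
    counted in the log.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    res = track.resolution
    offsets = np.arange(-(flank // res), flank // res + 1) * res
    total = np.zeros(len(offsets))
    used = 0
    dropped = 0
    for a in anchors:
        chrom, pos, strand = _anchor_fields(a)
        if chrom not in track.genome:
            raise ValueError(f"anchor on unknown chromosome {chrom!r}")
        length = track.genome.length(chrom)
        if pos - flank < 0 or pos + flank >= length:
            dropped += 1
            continue
        v = track.data[chrom]
        signed = offsets if strand != "-" else -offsets
        total += v[(pos + signed) // res]
        used += 1
    if used == 0:
        raise ValueError("all anchors dropped (windows exceed chromosome bounds)")
    if dropped:
        log.info("anchored_profile: dropped %d of %d anchors", dropped, used + dropped)
    return MetaProfile(offsets, total / used, used, label=label)


def _anchor_fields(a):
    if isinstance(a, tuple):
        chrom, pos = a[0], a[1]
        strand = a[2] if len(a) > 2 else "+"
        return chrom, int(pos), strand
    if isinstance(a, Origin):
        return a.chrom, a.position, "+"
    if isinstance(a, GeneAnnot):
        return a.chrom, a.tss, a.strand
    return a.chrom, int(a.position), getattr(a, "strand", "+")


# ---------------------------------------------------------------------------
# group time series


def ars_window_series(
    course: TimeCourse,
    origins,
    flank: int = 2_000,
    exclusion: int = 500,
    label: str = "",
) -> GroupSummary:
    """Mean signal within +-flank of each origin, excluding the central NDR.

    Bins fully inside [pos - flank, pos + flank) that do not overlap the
    centered exclusion window (pos +- exclusion/2) are averaged per origin;
    origins are then averaged per timepoint.
    """
    origins = list(origins)
    if not origins:
        raise ValueError("empty origin group")
    if flank <= exclusion / 2:
        raise ValueError("flank must exceed half the exclusion window")
    res = course.resolution
    picks = []  # (chrom, bin indices) per origin
    for o in origins:
        length = course.genome.length(o.chrom)
        lo, hi = o.position - flank, o.position + flank
        b = np.arange(max(lo, 0) // res, min(hi, length) // res + 1)
        starts, ends = b * res, (b + 1) * res
        inside = (starts >= lo) & (ends <= hi)
        ex_lo, ex_hi = o.position - exclusion / 2, o.position + exclusion / 2
        overlaps = (starts < ex_hi) & (ends > ex_lo)
        sel = b[inside & ~overlaps]
        if sel.size:
            picks.append((o.chrom, sel))
    if not picks:
        raise ValueError("no usable bins around any origin in the group")
    values = []
    for trk in course:
        per_origin = [trk.data[c][sel].mean() for c, sel in picks]
        values.append(float(np.mean(per_origin)))
    return GroupSummary(label, np.asarray(course.times, float), np.asarray(values))


def gene_body_series(
    course: TimeCourse,
    genes,
    exclude_first: int = 350,
    label: str = "",
) -> GroupSummary:
    """Mean signal over gene bodies, excluding the first ``exclude_first`` bp.

    The excluded stretch is measured from the TSS in transcription
    orientation.  The remaining interval is averaged base-accurately
    (partial bins weighted by overlap); genes shorter than the exclusion are
    dropped with a log entry.
    """
    res = course.resolution
    weights = []  # (chrom, bin indices, bp weights) per gene
    for g in genes:
        if g.length <= exclude_first:
            log.info("gene_body_series: dropping %s (%d bp <= %d bp excluded)",
                     g.id, g.length, exclude_first)
            continue
        if g.strand == "+":
            lo, hi = g.start + exclude_first, g.end
        else:
            lo, hi = g.start, g.end - exclude_first
        b = np.arange(lo // res, (hi - 1) // res + 1)
        w = np.minimum((b + 1) * res, hi) - np.maximum(b * res, lo)
        weights.append((g.chrom, b, w.astype(float)))
    if not weights:
        raise ValueError("no gene in the group survives the exclusion")
    values = []
    for trk in course:
        per_gene = [
            float(np.dot(trk.data[c][b], w) / w.sum()) for c, b, w in weights
        ]
        values.append(float(np.mean(per_gene)))
    return GroupSummary(label, np.asarray(course.times, float), np.asarray(values))


# ---------------------------------------------------------------------------
# scalar statistics


def rescale_unit_range(values: np.ndarray) -> np.ndarray:
    """(v - min) / (max - min); errors on a constant series."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant series")
    return (v - lo) / (hi - lo)


def half_rise_time(series: GroupSummary) -> float:
    """Earliest time the unit-range-rescaled series reaches 0.5.

    Linear interpolation between the bracketing timepoints.  Requires at
    least two timepoints and a net increase over the course.
    """
    t, v = series.times, series.values
    if len(t) < 2:
        raise ValueError("series needs at least two timepoints")
    if not v[-1] > v[0]:
        raise ValueError(
            f"series {series.label!r} does not rise (start {v[0]:.4g}, end {v[-1]:.4g})"
        )
    r = rescale_unit_range(v)
    if r[0] >= 0.5:
        return float(t[0])
    idx = np.nonzero(r >= 0.5)[0]
    if idx.size == 0:
        raise ValueError("rescaled series never reaches 0.5")
    i = int(idx[0])
    frac = (0.5 - r[i - 1]) / (r[i] - r[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def telomere_distance(origins, genome: GenomeModel):
    """Distance of each origin to its nearest chromosome end, plus the
    Spearman rank correlation between firing time and that distance.

    Returns (distances: dict id -> bp, rho, p_value).
    """
    origins = list(origins)
    dist = {}
    for o in origins:
        L = genome.length(o.chrom)
        dist[o.id] = int(min(o.position, L - o.position))
    if len(origins) >= 3:
        rho, p = spearmanr(
            [o.firing_time for o in origins], [dist[o.id] for o in origins]
        )
        rho, p = float(rho), float(p)
    else:
        rho, p = float("nan"), float("nan")
    return dist, rho, p


def plot_profiles(profiles: list[MetaProfile], path, xlabel="offset (bp)", title=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.offsets, p.values, label=f"{p.label} (n={p.n_features})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean signal")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_series(series: list[GroupSummary], path, rescaled=False, title=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series:
        y = rescale_unit_range(s.values) if rescaled else s.values
        ax.plot(s.times, y, marker="o", label=s.label)
    ax.set_xlabel("time after release (min)")
    ax.set_ylabel("signal (unit range)" if rescaled else "mean signal")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
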