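"""Chromosome-by-time relative heatmaps.

The plotted quantity is the log2 of a 15-kb moving-window average (stepped
every 2 kb) minus the mean of that log2 value across the time course, so
each window row is centered on zero and the matrix shows when, relative to
its own average, a chromosomal region gains or loses the mark.  Around an
early origin this paints the characteristic triangle: the above-average
region widens at fork speed as S phase proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import SignalTrack, TimeCourse


@dataclass
class WindowedTrack:
    """Moving-window means of a binned track.

    ``windows`` holds (chrom, center bp) records aligned with ``values``.
    """

    windows: list[tuple[str, int]]
    values: np.ndarray
    window: int
    step: int
    time: float | None = None
    condition: str | None = None


@dataclass
class HeatmapMatrix:
    """log2-relative window x time matrix; every row mean is ~0."""

    windows: list[tuple[str, int]]
    times: list[float]
    values: np.ndarray  # shape (n_windows, n_times)
    condition: str | None = None

    def __post_init__(self):
        if self.values.shape != (len(self.windows), len(self.times)):
            raise ValueError("matrix shape does not match window/time labels")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[f"t{t:g}" for t in self.times])
        df.insert(0, "chrom", [c for c, _ in self.windows])
        df.insert(1, "center", [p for _, p in self.windows])
        return df


def moving_window_bin(track: SignalTrack, window: int, step: int) -> WindowedTrack:
    """Mean of the fixed bins fully inside each [start, start + window).

    Window starts run 0, step, 2*step, ...; windows extending past the
    chromosome end are dropped, so every window averages the same width.
    Chromosomes shorter than one window contribute no windows.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    if window < track.resolution:
        raise ValueError("window must be at least one bin wide")
    res = track.resolution
    if window % res or step % res:
        raise ValueError("window and step must be multiples of the bin resolution")
    wb, sb = window // res, step // res
    labels: list[tuple[str, int]] = []
    values: list[np.ndarray] = []
    for chrom, length in track.genome.chromosomes:
        v = track.data[chrom]
        n_full = length // res  # only bins fully inside the chromosome
        n_win = (n_full - wb) // sb + 1 if n_full >= wb else 0
        if n_win <= 0:
            continue
        csum = np.concatenate([[0.0], np.cumsum(v[:n_full])])
        starts = np.arange(n_win) * sb
        values.append((csum[starts + wb] - csum[starts]) / wb)
        labels.extend((chrom, int(s * res + window // 2)) for s in starts)
    vals = np.concatenate(values) if values else np.empty(0)
    return WindowedTrack(labels, vals, window, step, time=track.time, condition=track.condition)


def relative_log2_heatmap(windowed: list[WindowedTrack]) -> HeatmapMatrix:
    """H[w, t] = log2 v[w, t] - mean_t log2 v[w, t].

    All window values must be strictly positive (enrichment tracks are, by
    construction).  Rows are centered exactly, so permuting the time order
    permutes columns without changing row means.
    """
    if not windowed:
        raise ValueError("empty windowed time course")
    first = windowed[0]
    for w in windowed[1:]:
        if w.windows != first.windows:
            raise ValueError("windowed tracks do not share the same window grid")
    times = [w.time for w in windowed]
    if any(t is None for t in times):
        raise ValueError("every windowed track needs a time label")
    mat = np.stack([w.values for w in windowed], axis=1)
    bad = np.argwhere(mat <= 0)
    if bad.size:
        wi, ti = bad[0]
        raise ValueError(
            f"nonpositive window value at window {first.windows[wi]} t={times[ti]:g}"
        )
    logs = np.log2(mat)
    H = logs - logs.mean(axis=1, keepdims=True)
    return HeatmapMatrix(list(first.windows), list(times), H, condition=first.condition)


def heatmap_from_course(course: TimeCourse, window: int = 15_000, step: int = 2_000) -> HeatmapMatrix:
    """Window every track of a time course and build the relative heatmap."""
    return relative_log2_heatmap([moving_window_bin(trk, window, step) for trk in course])


def triangle_widths(
    hm: HeatmapMatrix, chrom: str, position: int, threshold: float = 0.1
) -> dict[float, int]:
    """Width (bp) of the contiguous above-threshold region around a position.

    For each time column, finds the maximal run of consecutive same-chromosome
    windows with H > threshold whose span covers ``position`` (or, failing
    that, the nearest such run touching the window that contains it).  Width
    is (number of windows in the run) * step.  Returns 0 when the window at
    the position is below threshold.
    """
    idx = [i for i, (c, _) in enumerate(hm.windows) if c == chrom]
    if not idx:
        raise ValueError(f"no windows on chromosome {chrom!r}")
    centers = np.array([hm.windows[i][1] for i in idx])
    sub = hm.values[idx, :]
    anchor = int(np.argmin(np.abs(centers - position)))
    step = int(centers[1] - centers[0]) if len(centers) > 1 else 0
    widths: dict[float, int] = {}
    for j, t in enumerate(hm.times):
        above = sub[:, j] > threshold
        if not above[anchor]:
            widths[t] = 0
            continue
        lo = anchor
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = anchor
        while hi < len(above) - 1 and above[hi + 1]:
            hi += 1
        widths[t] = (hi - lo + 1) * step
    return widths


def _ridge_time(origin, schedule) -> float:
    """Replication time of the barrier separating this domain from its
    neighbours: walking away from the origin on either side, the first local
    maximum of T(x).  The contiguous above-threshold region around the
    origin stays confined to its own domain until the later-replicating
    barrier bins catch up, i.e. roughly until T(barrier)."""
    T = schedule.times[origin.chrom]
    b = origin.position // schedule.resolution
    ridges = []
    for stepdir in (-1, 1):
        i = b
        while 0 <= i + stepdir < len(T) and T[i + stepdir] >= T[i] - 1e-9:
            i += stepdir
        ridges.append(T[i])
    return float(min(ridges))


def _usable_times(origin, schedule, timepoints, min_lag, merge_margin):
    """Timepoints where the 2 v (t - t0) growth law is cleanly measurable.

    Needs a lag of ``min_lag`` minutes after firing (so the finite window
    support smears the edges by less than the tolerance) and must end
    ``merge_margin`` minutes before the inter-domain barrier replicates
    (population firing-time jitter closes the below-threshold gap ahead of
    the barrier's median replication time).
    """
    t_close = _ridge_time(origin, schedule)
    return [
        t for t in timepoints
        if t - origin.firing_time >= min_lag and t <= t_close - merge_margin
    ]


def select_isolated_early_origin(
    origins,
    schedule,
    timepoints,
    min_lag: float = 13.0,
    merge_margin: float = 8.0,
):
    """The origin around which the fork-speed growth law is best measurable.

    Maximizes the number of usable sampled timepoints (see
    :func:`_usable_times`); ties break toward the later-closing barrier,
    then the earlier origin.
    """
    origins = list(origins)
    if not origins:
        raise ValueError("no origins supplied")

    def score(o):
        usable = _usable_times(o, schedule, timepoints, min_lag, merge_margin)
        return (len(usable), _ridge_time(o, schedule), -o.firing_time)

    return max(origins, key=score)


def triangle_growth(
    hm: HeatmapMatrix,
    origin,
    fork_speed: float,
    schedule=None,
    threshold: float = 0.1,
    min_lag: float = 13.0,
    merge_margin: float = 8.0,
):
    """Measured vs predicted width of the spreading above-threshold region.

    Returns (widths, ratios): per-time contiguous widths around the origin,
    and measured/predicted ratios against 2 v (t - firing_time) at the
    usable timepoints (lagged past firing, clear of neighbouring domains;
    see :func:`_usable_times`).  Without a schedule every lagged timepoint
    counts as usable.
    """
    widths = triangle_widths(hm, origin.chrom, origin.position, threshold)
    if schedule is not None:
        usable = _usable_times(origin, schedule, widths.keys(), min_lag, merge_margin)
    else:
        usable = [t for t in widths if t - origin.firing_time >= min_lag]
    ratios = {}
    for t in usable:
        pred = 2.0 * fork_speed * (t - origin.firing_time)
        if pred > 0 and widths[t] > 0:
            ratios[t] = widths[t] / pred
    return widths, ratios


def plot_heatmap(hm: HeatmapMatrix, path, title: str | None = None) -> None:
    """Render one panel per chromosome, time on the vertical axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({c for c, _ in hm.windows}, key=[c for c, _ in hm.windows].index)
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False
    )
    vmax = float(np.abs(hm.values).max() or 1.0)
    for ax, chrom in zip(axes[:, 0], chroms):
        idx = [i for i, (c, _) in enumerate(hm.windows) if c == chrom]
        img = hm.values[idx, :].T
        ax.imshow(
            img, aspect="auto", origin="upper", cmap="RdBu_r",
            vmin=-vmax, vmax=vmax,
            extent=(hm.windows[idx[0]][1], hm.windows[idx[-1]][1],
                    hm.times[-1], hm.times[0]),
        )
        ax.set_ylabel(f"{chrom}\ntime (min)")
    axes[-1, 0].set_xlabel("position (bp)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
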