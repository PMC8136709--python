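"""Spike-in calibration, enrichment-ratio tracks, and time-course detrending.

The calibration factor is the published spike-in formula

    k = (IP_sample / IP_spike) * (IN_spike / IN_sample)

i.e. the IP recovery of sample chromatin relative to the constant-level
spike chromatin, with the input ratio correcting for the admixture
proportion.  Enrichment tracks are a pseudocounted IP/input ratio scaled by
k (a deliberate, documented substitute for MACS2 track building).
Detrending fits a low-degree polynomial to the genome-wide track means over
time and divides each track by its fitted value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks import SignalTrack, SpikeInCounts, TimeCourse


@dataclass
class NormalizedTimeCourse:
    """An enrichment time course plus calibration/detrending provenance."""

    course: TimeCourse
    k_values: dict[float, float] = field(default_factory=dict)
    poly_degree: int | None = None
    poly_coeffs: tuple[float, ...] | None = None

    def __post_init__(self):
        for t, k in self.k_values.items():
            if k <= 0:
                raise ValueError(f"k must be positive at t={t}, got {k}")

    @property
    def times(self):
        return self.course.times


def spike_in_factor(counts: SpikeInCounts) -> float:
    """k = (ip_sample / ip_spike) * (in_spike / in_sample), as published."""
    if counts.ip_spike == 0:
        raise ValueError("ip_spike is zero (denominator of k)")
    if counts.in_sample == 0:
        raise ValueError("in_sample is zero (denominator of k)")
    return (counts.ip_sample / counts.ip_spike) * (counts.in_spike / counts.in_sample)


def enrichment_track(
    ip: SignalTrack,
    input_track: SignalTrack,
    k: float = 1.0,
    pseudocount: float = 0.5,
) -> SignalTrack:
    """e(x) = k * (ip(x) + pseudocount) / (input(x) + pseudocount).

    Strictly positive by construction, so later log2 stages are safe.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    if not ip.same_grid(input_track):
        raise ValueError("IP and input tracks are not on the same grid")
    data = {
        c: k * (ip.data[c] + pseudocount) / (input_track.data[c] + pseudocount)
        for c in ip.genome.names
    }
    return SignalTrack(
        ip.genome, ip.resolution, data,
        time=ip.time, condition=ip.condition, kind="enrichment",
    )


def calibrate_time_course(
    ip_course: TimeCourse,
    input_course: TimeCourse,
    spike_counts: dict[float, SpikeInCounts],
    pseudocount: float = 0.5,
) -> NormalizedTimeCourse:
    """Per-timepoint spike-in factors applied to the enrichment ratio."""
    tracks = []
    k_values = {}
    for ip, inp in zip(ip_course, input_course):
        if ip.time != inp.time:
            raise ValueError("IP and input courses have mismatched time grids")
        if ip.time not in spike_counts:
            raise ValueError(f"no spike counts for t={ip.time}")
        k = spike_in_factor(spike_counts[ip.time])
        tracks.append(enrichment_track(ip, inp, k, pseudocount))
        k_values[ip.time] = k
    return NormalizedTimeCourse(TimeCourse(tracks), k_values)


def polynomial_detrend(
    ntc: NormalizedTimeCourse, degree: int = 2, mode: str = "divide"
) -> NormalizedTimeCourse:
    """Remove the fitted trend of the genome-wide means across the course.

    A degree-``degree`` polynomial is least-squares fitted to
    (time, genome-wide mean) and each track is divided by (default) or has
    subtracted (``mode='subtract'``) its fitted value, so the corrected
    genome-wide means sit at 1 (or 0) up to fit residuals.  Division is the
    default because it preserves positivity for the log2 heatmap stage.
    """
    times = np.asarray(ntc.times, dtype=float)
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    if len(times) < degree + 1:
        raise ValueError(f"need >= {degree + 1} timepoints for degree {degree}")
    means = np.array([trk.genome_mean() for trk in ntc.course])
    if np.any(means <= 0) and mode == "divide":
        raise ValueError("genome-wide means must be positive to detrend by division")
    coeffs = np.polynomial.polynomial.polyfit(times, means, degree)
    fitted = np.polynomial.polynomial.polyval(times, coeffs)
    if mode == "divide" and np.any(fitted <= 0):
        bad = times[fitted <= 0][0]
        raise ValueError(f"degenerate fit: p(t) <= 0 at t={bad:g}")
    tracks = []
    for trk, f in zip(ntc.course, fitted):
        if mode == "divide":
            data = {c: v / f for c, v in trk.data.items()}
        elif mode == "subtract":
            data = {c: v - f for c, v in trk.data.items()}
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tracks.append(
            SignalTrack(trk.genome, trk.resolution, data,
                        time=trk.time, condition=trk.condition, kind="enrichment")
        )
    return NormalizedTimeCourse(
        TimeCourse(tracks), dict(ntc.k_values),
        poly_degree=degree, poly_coeffs=tuple(float(c) for c in coeffs),
    )
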