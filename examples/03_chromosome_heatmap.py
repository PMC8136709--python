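"""Chromosome-scale relative heatmap and the spreading 'triangle'.

15-kb moving windows (2-kb step) are log2-transformed and centered on each
window's own time-course mean.  Around an early origin the above-average
region widens at twice the fork speed as the two forks move apart.
"""

from replichron import SimConfig, TimeCourse, polynomial_detrend
from replichron.heatmap import (
    heatmap_from_course,
    select_isolated_early_origin,
    triangle_growth,
    triangle_widths,
)
from replichron.normalization import calibrate_time_course
from replichron.simulate import simulate_condition, simulate_replication_timing

cfg = SimConfig(seed=1)
samples, genome, origins, genes = simulate_condition(cfg, "SR")
ips = TimeCourse([samples[t][1] for t in cfg.timepoints])
inps = TimeCourse([samples[t][2] for t in cfg.timepoints])
ntc = calibrate_time_course(ips, inps, {t: samples[t][3] for t in cfg.timepoints})

schedule = simulate_replication_timing(genome, origins, cfg.fork_speed, cfg.resolution)
origin = select_isolated_early_origin(origins, schedule, cfg.timepoints)
print(f"reference origin {origin.id} at {origin.chrom}:{origin.position:,}, "
      f"fires {origin.firing_time:g} min")

hm = heatmap_from_course(ntc.course)
widths = triangle_widths(hm, origin.chrom, origin.position)
print("contiguous above-0.1 region (bp) by time:")
for t, w in widths.items():
    print(f"  t={t:>4g} min   width = {w:>7,}")

# growth law pooled over every origin with a cleanly measurable timepoint,
# on the detrended course (no genome-wide column offsets)
hm_det = heatmap_from_course(polynomial_detrend(ntc, 2).course)
pooled = []
for o in origins:
    _, ratios = triangle_growth(hm_det, o, cfg.fork_speed, schedule=schedule)
    pooled.extend((o.id, t, r) for t, r in ratios.items())
for oid, t, r in pooled:
    print(f"{oid} t={t:g}: measured/predicted width = {r:.2f}")
print("ratios near 1 mean the above-average region spreads at 2 x fork")
print("speed, the signature of replication-coupled deposition of the mark.")
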