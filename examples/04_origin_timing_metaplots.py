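"""Origin-anchored averages stratified by replication timing.

Origins are split into firing-time quartiles; the mean calibrated signal
within +-2 kb of each origin (excluding the central 500 bp NDR) is tracked
over the release and summarized by its half-rise time — the interpolated
minute at which the rescaled series reaches half its dynamic range.
"""

import numpy as np

from replichron import (
    SimConfig, TimeCourse, ars_window_series, half_rise_time, quantile_groups,
)
from replichron.normalization import calibrate_time_course
from replichron.simulate import simulate_condition

cfg = SimConfig(seed=1)
samples, genome, origins, genes = simulate_condition(cfg, "SR")
ips = TimeCourse([samples[t][1] for t in cfg.timepoints])
inps = TimeCourse([samples[t][2] for t in cfg.timepoints])
ntc = calibrate_time_course(ips, inps, {t: samples[t][3] for t in cfg.timepoints})

groups = quantile_groups(origins, key=lambda o: o.firing_time,
                         labels=["early", "early-mid", "mid-late", "late"])
print("quartile      n   mean firing   half-rise of the +-2 kb window mean")
for lab, grp in groups:
    series = ars_window_series(ntc.course, grp, flank=2_000, exclusion=500, label=lab)
    hr = half_rise_time(series)
    print(f"{lab:<11} {len(grp):>3}   {np.mean([o.firing_time for o in grp]):>8.1f}"
          f"      {hr:>5.1f} min")
print("half-rise times increase early -> late: the mark returns in the")
print("order in which the origins replicate.")
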