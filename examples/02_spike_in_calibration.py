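"""Spike-in calibration: from four read tallies to comparable tracks.

Each ChIP sample carries a fixed admixture (3-5%) of foreign-genome
chromatin.  The factor k = (IP_sample/IP_spike) * (IN_spike/IN_sample)
measures how efficiently sample chromatin was immunoprecipitated relative
to the constant spike, so multiplying tracks by k puts all timepoints on a
common absolute scale.
"""

from replichron import SimConfig, SpikeInCounts, TimeCourse, spike_in_factor
from replichron.normalization import calibrate_time_course
from replichron.simulate import simulate_condition

print("worked example:", spike_in_factor(SpikeInCounts(300, 10, 100, 5)),
      "= (300/10) * (5/100)")

cfg = SimConfig(seed=1)
samples, *_ = simulate_condition(cfg, "SR")
ips = TimeCourse([samples[t][1] for t in cfg.timepoints])
inps = TimeCourse([samples[t][2] for t in cfg.timepoints])
counts = {t: samples[t][3] for t in cfg.timepoints}
ntc = calibrate_time_course(ips, inps, counts)
print("per-timepoint k on the simulated SR course:")
for t, k in ntc.k_values.items():
    print(f"  t={t:>4g} min   k = {k:.3f}")
print("k rises through S phase: the genome-wide acetyl level grows as")
print("replication deposits the mark, and the spike-in makes that visible.")
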