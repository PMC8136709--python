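"""Transcription-coupled delay of the mark's return, and its ablation.

Gene bodies (first 350 bp excluded) are averaged per expression quartile.
With transcription-coupled turnover active, the most expressed genes reach
half their dynamic range later than the least expressed; setting the
turnover amplitude to zero collapses the difference, pinning the delay on
turnover rather than on replication timing.
"""

from replichron import (
    SimConfig, TimeCourse, gene_body_series, half_rise_time, quantile_groups,
)
from replichron.normalization import calibrate_time_course
from replichron.simulate import simulate_condition


def expression_half_rises(cfg):
    samples, genome, origins, genes = simulate_condition(cfg, "SR")
    ips = TimeCourse([samples[t][1] for t in cfg.timepoints])
    inps = TimeCourse([samples[t][2] for t in cfg.timepoints])
    ntc = calibrate_time_course(ips, inps, {t: samples[t][3] for t in cfg.timepoints})
    out = {}
    for lab, grp in quantile_groups(genes, key=lambda g: g.expression,
                                    labels=["bottom 25%", "25-50%", "50-75%", "top 25%"]):
        out[lab] = half_rise_time(gene_body_series(ntc.course, grp, 350, label=lab))
    return out


for lam0, title in [(None, "default turnover"), (0.0, "turnover ablated (lambda0 = 0)")]:
    cfg = SimConfig(seed=1) if lam0 is None else SimConfig(seed=1, lambda0=0.0)
    hr = expression_half_rises(cfg)
    print(title)
    for lab, v in hr.items():
        print(f"  {lab:<11} half-rise {v:5.1f} min")
    print(f"  top - bottom = {hr['top 25%'] - hr['bottom 25%']:+.1f} min\n")
print("the positive gap under default turnover disappears in the ablation.")
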