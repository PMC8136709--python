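# replichron

Quantitative analysis of replication-coupled histone-mark dynamics in
synchronized ChIP-seq time courses, with a built-in mechanistic simulator
that makes every stage verifiable end-to-end without any external data.

## The problem

In budding yeast, most H4 K16 acetylation is written by the SAS-I complex
on newly deposited histones at the replication fork. A synchronized
experiment makes this visible genome-wide: cells are arrested in early S
phase with hydroxyurea, released, and sampled every 10 minutes for an hour
(t = 0…60 min) under three conditions — writer intact (**SR**), writer
degraded via an auxin degron (**SR+IAA**), and writer degraded without
release (**NR+IAA**). Each ChIP sample carries 3–5% *S. pombe* spike-in
chromatin so that absolute signal levels are comparable across timepoints.

`replichron` implements the analysis chain for such a study:

1. **Spike-in calibration.** Per sample,
   `k = (IP_sc / IP_sp) · (IN_sp / IN_sc)` from the sample (sc) and
   spike (sp) read tallies of IP and input libraries; enrichment tracks are
   `e(x) = k · (IP(x) + c) / (IN(x) + c)` with pseudocount `c`.
2. **Time-course detrending.** A low-degree polynomial fitted to the
   genome-wide track means over time; dividing by the fit flattens the
   global trend (optional; used where relative spatial timing is the
   question).
3. **Relative heatmaps.** 15-kb moving-window averages (2-kb step),
   log2-transformed and centered on each window's own time-course mean:
   `H[w,t] = log2 v[w,t] − mean_t log2 v[w,t]`. Around an early origin
   the above-average region widens at `2·v·(t − t_fire)` — the "triangle"
   signature of bidirectional forks depositing the mark.
4. **Feature-anchored metaplots.** Origin (ARS) windows (±2 kb, central
   500 bp NDR excluded) stratified by replication-timing quartile; gene
   bodies (first 350 bp after the TSS excluded, strand-aware) stratified by
   expression quartile or length bin; unit-range rescaling and the
   **half-rise time** — the interpolated minute at which a rescaled group
   series reaches 0.5 — as the delay statistic.
5. **Synthetic data.** A population-analytic simulator: min-plus fork
   geometry `T(x) = min_i(t_i + |x − x_i|/v)`, normal-CDF population
   spread, 50/50 parental histone transfer, deposition acetylation with
   probability `p_sas` (writer-dependent), transcription-coupled turnover
   that delays the mark's return on highly expressed genes, and Poisson
   read rendering with spike-in tallies.

## Worked example

```bash
python examples/04_origin_timing_metaplots.py
```

```
quartile      n   mean firing   half-rise of the +-2 kb window mean
early         6        6.8       13.9 min
early-mid     6       15.6       17.6 min
mid-late      6       27.5       27.1 min
late          6       39.6       36.3 min
```

The mark returns around origins in the order they fire: the half-rise
times of the four replication-timing quartiles track their mean firing
times. On the same run, `examples/05_expression_delay.py` prints the
transcription-coupled delay:

```
default turnover
  bottom 25%  half-rise  28.6 min
  top 25%     half-rise  31.5 min
  top - bottom = +2.9 min
turnover ablated (lambda0 = 0)
  top - bottom = +0.2 min
```

The most expressed genes reach half their dynamic range ~3 minutes later
than the least expressed; switching turnover off collapses the gap, so the
delay is caused by turnover, not by replication timing.

The other examples cover the fixture writer (`01`), the spike-in factor
(`02`), the chromosome heatmap and the fork-speed growth law (`03`), and
the one-call pipeline (`06`). A thin CLI mirrors the stages:

```bash
replichron simulate --seed 1 --out fixture/
replichron normalize --fixture fixture/ --out tracks/
replichron heatmap  --fixture fixture/ --out plots/
replichron metaplot --fixture fixture/ --out plots/ --anchor ars
replichron run --config-seed 1 --out run/
```

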