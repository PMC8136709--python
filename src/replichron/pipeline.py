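"""End-to-end orchestration: simulate -> calibrate -> heatmap -> metaplot.

One :class:`RunConfig` drives a fully reproducible run: the synthetic study
is written to disk, read back through the text-format readers (so the IO
layer is exercised, not bypassed), calibrated with the per-sample spike-in
factors, and summarized as chromosome heatmaps, stratified group series and
a half-rise-time table.  Identical configs produce byte-identical text
outputs; the manifest records SHA-256 checksums of every text artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metaplot as mp
from .heatmap import heatmap_from_course, plot_heatmap
from .normalization import calibrate_time_course, polynomial_detrend
from .simulate import SimConfig, write_fixture
from .tracks import (
    CONDITIONS,
    TimeCourse,
    read_bedgraph,
    read_genes,
    read_genome_table,
    read_origins,
    read_spike_counts,
)

log = logging.getLogger(__name__)

ARS_LABELS = ["early", "early-mid", "mid-late", "late"]
EXPR_LABELS = ["expr 0-25%", "expr 25-50%", "expr 50-75%", "expr 75-100%"]


@dataclass
class RunConfig:
    """Paths/parameters for one pipeline run; defaults follow the study."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str | Path = "replichron_run"
    pseudocount: float = 0.5
    poly_degree: int = 2
    detrend: bool = False        # optional drift correction; see methods note
    window: int = 15_000
    step: int = 2_000
    ars_flank: int = 2_000
    ars_exclusion: int = 500
    tss_flank: int = 2_000
    gene_exclude_first: int = 350
    n_groups: int = 4
    figures: bool = True


def load_fixture_courses(fixture_dir: Path, sim: SimConfig):
    """Read a written fixture back into typed objects and time courses."""
    genome = read_genome_table(fixture_dir / "genome.tsv")
    origins = read_origins(
        fixture_dir / "origins.bed", fixture_dir / "origins_timing.tsv", genome
    )
    genes = read_genes(fixture_dir / "genes.bed", fixture_dir / "expression.tsv", genome)
    spike = read_spike_counts(fixture_dir / "spike_counts.tsv")
    courses = {}
    for condition in CONDITIONS:
        ips, inps = [], []
        for t in sim.timepoints:
            stem = f"{condition}_t{int(t):02d}"
            ips.append(read_bedgraph(
                fixture_dir / f"{stem}_ip.bedgraph", genome, sim.resolution,
                time=t, condition=condition, kind="IP"))
            inps.append(read_bedgraph(
                fixture_dir / f"{stem}_input.bedgraph", genome, sim.resolution,
                time=t, condition=condition, kind="input"))
        courses[condition] = (TimeCourse(ips), TimeCourse(inps))
    return genome, origins, genes, spike, courses


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (name -> sha256)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    provenance: dict = {"seed": config.sim.seed, "stages": {}}

    def emit(name: str, text: str):
        (outdir / name).write_text(text)
        files[name] = hashlib.sha256(text.encode()).hexdigest()

    def stage(name):
        log.info("stage %s", name)

    stage("simulate")
    fixture_dir = outdir / "fixture"
    fixture_manifest = write_fixture(config.sim, fixture_dir)
    files.update({f"fixture/{k}": v for k, v in fixture_manifest.items()})
    provenance["stages"]["simulate"] = {"n_files": len(fixture_manifest)}

    stage("load")
    genome, origins, genes, spike, courses = load_fixture_courses(fixture_dir, config.sim)

    stage("normalize")
    enriched = {}
    for condition, (ips, inps) in courses.items():
        counts = {t: spike[(condition, t)] for t in config.sim.timepoints}
        ntc = calibrate_time_course(ips, inps, counts, config.pseudocount)
        if config.detrend:
            ntc = polynomial_detrend(ntc, config.poly_degree)
        enriched[condition] = ntc
        provenance["stages"].setdefault("normalize", {})[condition] = {
            "k": {f"{t:g}": round(k, 6) for t, k in ntc.k_values.items()},
            "poly_degree": ntc.poly_degree,
            "poly_coeffs": list(ntc.poly_coeffs) if ntc.poly_coeffs else None,
        }

    stage("heatmap")
    heatmaps = {}
    for condition, ntc in enriched.items():
        hm = heatmap_from_course(ntc.course, config.window, config.step)
        heatmaps[condition] = hm
        emit(f"heatmap_{condition}.tsv",
             hm.to_frame().to_csv(sep="\t", index=False, float_format="%.6g"))
        if config.figures:
            plot_heatmap(hm, outdir / f"heatmap_{condition}.png",
                         title=f"{condition}: log2 signal relative to time-course mean")

    stage("metaplot")
    ars_groups = mp.quantile_groups(
        origins, key=lambda o: o.firing_time, n_groups=config.n_groups,
        labels=ARS_LABELS[: config.n_groups]
        if config.n_groups <= len(ARS_LABELS) else None)
    expr_groups = mp.quantile_groups(
        genes, key=lambda g: g.expression, n_groups=config.n_groups,
        labels=EXPR_LABELS[: config.n_groups]
        if config.n_groups <= len(EXPR_LABELS) else None)
    len_groups = mp.length_groups(genes)

    summary_rows = ["condition\tstratum\tgroup\tn\thalf_rise_min\tdelta_0_60"]
    series_rows = ["condition\tstratum\tgroup\ttime_min\tmean_signal"]
    for condition, ntc in enriched.items():
        course = ntc.course
        strata = (
            [("ars", lab, mp.ars_window_series(
                course, grp, config.ars_flank, config.ars_exclusion, label=lab), len(grp))
             for lab, grp in ars_groups]
            + [("expression", lab, mp.gene_body_series(
                course, grp, config.gene_exclude_first, label=lab), len(grp))
               for lab, grp in expr_groups]
            + [("length", lab, mp.gene_body_series(
                course, grp, config.gene_exclude_first, label=lab), len(grp))
               for lab, grp in len_groups if grp]
        )
        for stratum, lab, series, n in strata:
            for t, v in zip(series.times, series.values):
                series_rows.append(
                    f"{condition}\t{stratum}\t{lab}\t{t:g}\t{v:.6g}")
            try:
                hr = f"{mp.half_rise_time(series):.3f}"
            except ValueError:
                hr = "NA"
            delta = series.values[-1] - series.values[0]
            summary_rows.append(
                f"{condition}\t{stratum}\t{lab}\t{n}\t{hr}\t{delta:.6g}")
        if config.figures and condition == "SR":
            profiles = [
                mp.anchored_profile(course.tracks[-1], grp, config.ars_flank, label=lab)
                for lab, grp in ars_groups
            ]
            mp.plot_profiles(profiles, outdir / "ars_profiles_SR_t60.png",
                             title="SR t=60: signal around origins by timing quartile")
    emit("group_series.tsv", "\n".join(series_rows) + "\n")
    emit("summary_half_rise.tsv", "\n".join(summary_rows) + "\n")

    dist, rho, p = mp.telomere_distance(origins, genome)
    tel_rows = ["origin\tfiring_time_min\ttelomere_distance_bp"]
    by_id = {o.id: o for o in origins}
    tel_rows += [f"{oid}\t{by_id[oid].firing_time:g}\t{d}" for oid, d in sorted(dist.items())]
    emit("telomere_distance.tsv", "\n".join(tel_rows) + "\n")
    provenance["stages"]["telomere"] = {"spearman_rho": round(rho, 4), "p": round(p, 4)}

    emit("provenance.json", json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    manifest = "".join(f"{k}\t{v}\n" for k, v in sorted(files.items()))
    (outdir / "manifest.tsv").write_text(manifest)
    return files
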