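"""Replication-coupled acetylation simulator.

Simulates a hydroxyurea-arrest/release S-phase time course (samples every
10 min for 60 min) of a histone acetyl mark written mainly at replication
(the SAS-I paradigm for H4 K16ac) under three conditions:

* ``SR``      synchronized release, writer active
* ``SR_IAA``  synchronized release, writer depleted (degron)
* ``NR_IAA``  writer depleted, never released: only an ``escape_fraction``
              of cells leaks through the arrest

The model is population-analytic: each bin has a deterministic median
replication time T(x) from fork geometry, a firing-time jitter sigma_f
spreads the population (normal CDF), and acetylation follows first-order
kinetics per bin.  Parental histones are split 50/50 to the daughters with
their acetylation retained; new histones are acetylated at deposition with
probability ``p_sas`` only while the writer is active; turnover-incorporated
histones are unacetylated, and a slow background writer (Esa1-like,
``k_esa``) pushes every bin toward ``a_max``.

Two optional refinements shape transcription-coupled turnover (both default
on, both reduce to the plain first-order model when disabled):

* ``tss_decay_bp``  turnover is concentrated near the TSS and decays along
  the gene body, so long genes escape it at their 3' ends;
* ``arrest_program_tau``  the expression ranking is measured in arrested
  cells, and the arrest transcription program relaxes after release with
  this time constant, so turnover at the hottest genes subsides during the
  course.  This is what delays the return of the mark on highly expressed
  genes: acetylation deposited early behind the fork is stripped while the
  arrest program is still hot, and only the later deposition survives.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .genome import GeneAnnot, GenomeModel, Origin, validate_genes, validate_origins
from .tracks import CONDITIONS, SignalTrack, SpikeInCounts, write_bedgraph

DEFAULT_TIMEPOINTS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


def condition_sas_active(condition: str) -> bool:
    """The acetyl writer survives only in the no-auxin condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    return condition == "SR"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the study-condition defaults.

    Rates are 1/min, speeds bp/min, times minutes, lengths bp.
    """

    n_chroms: int = 2
    chrom_length: int = 750_000
    origin_spacing: int = 60_000
    fork_speed: float = 1_500.0          # v
    firing_jitter: float = 4.0           # sigma_f, population spread of firing
    firing_min: float = 5.0              # earliest origin firing time
    firing_max: float = 45.0             # latest origin firing time
    escape_fraction: float = 0.05        # HU-arrest leakage, NR_IAA only
    p_sas: float = 0.75                  # P(new histone acetylated | writer on)
    k_esa: float = 0.005                 # slow background acetylation
    k_basal: float = 0.02                # replication-independent basal turnover
    lambda0: float = 1.0                 # maximal transcription-coupled turnover
    tss_decay_bp: float | None = 1500.0  # e-folding of turnover along gene body
    arrest_program_tau: float | None = 12.0  # decay of arrest transcription after release
    a_max: float = 0.8                   # ceiling acetyl fraction
    spike_fraction: float = 0.04         # S. pombe chromatin admixture (3-5%)
    spike_acetyl: float = 0.5            # constant acetyl level of the spike genome
    ip_background: float = 0.05          # beta: non-specific IP pulldown
    ip_reference: float | None = None    # A_ref normalizer; defaults to a_max
    read_depth: float = 100.0            # expected reads per bin
    resolution: int = 200                # bp per bin
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    seed: int = 0

    def __post_init__(self):
        for name in ("fork_speed", "firing_jitter", "read_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k_esa", "k_basal", "lambda0", "ip_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("escape_fraction", "p_sas", "spike_fraction", "spike_acetyl", "a_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("genome dimensions must be positive")

    @property
    def a_ref(self) -> float:
        return self.a_max if self.ip_reference is None else self.ip_reference


@dataclass
class ReplicationSchedule:
    """Per-bin population-median replication time T(x), minutes."""

    genome: GenomeModel
    resolution: int
    times: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom in self.genome.names:
            expect = self.genome.n_bins(chrom, self.resolution)
            if len(self.times[chrom]) != expect:
                raise ValueError(f"{chrom}: schedule has wrong bin count")


# ---------------------------------------------------------------------------
# genome construction


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), *key]))


def build_genome(config: SimConfig) -> GenomeModel:
    names = ["chrI", "chrII", "chrIII", "chrIV", "chrV", "chrVI", "chrVII", "chrVIII"]
    if config.n_chroms > len(names):
        names = [f"chr{i+1}" for i in range(config.n_chroms)]
    return GenomeModel(tuple((names[i], config.chrom_length) for i in range(config.n_chroms)))


def build_origins(config: SimConfig, genome: GenomeModel | None = None) -> list[Origin]:
    """Evenly spaced origins with firing times uniform on [firing_min, firing_max]."""
    genome = genome or build_genome(config)
    rng = _rng(config, 1)
    origins = []
    i = 0
    for chrom, length in genome.chromosomes:
        pos = config.origin_spacing // 2
        pos -= pos % config.resolution  # align anchors to the bin grid
        while pos < length:
            t = float(rng.uniform(config.firing_min, config.firing_max))
            origins.append(Origin(f"ori{i+1:03d}", chrom, int(pos), round(t, 2)))
            i += 1
            pos += config.origin_spacing
    return origins


def build_genes(config: SimConfig, genome: GenomeModel | None = None,
                origins: list[Origin] | None = None) -> list[GeneAnnot]:
    """Tile genes along each chromosome, keeping origin NDRs gene-free.

    Lengths are lognormal around ~1.4 kb (clipped to [300, 6000] bp) so the
    four length strata are all populated, including sub-500 bp genes that
    the length grouping excludes.  Expression is lognormal (TPM-like) and is
    dealt across replication-timing strata in a balanced round-robin, so the
    expression quartiles have matched timing distributions.  On a real
    genome (~6000 genes over ~300 origin domains) expression and replication
    timing decorrelate by sheer numbers; a toy genome with a couple of dozen
    domains needs the balancing to reproduce that regime instead of a
    seed-dependent timing confound.
    """
    genome = genome or build_genome(config)
    origins = origins if origins is not None else build_origins(config, genome)
    rng = _rng(config, 2)
    ndr = [(o.chrom, o.position) for o in origins]
    placed = []  # (chrom, start, end, strand)
    for chrom, length in genome.chromosomes:
        ori_pos = sorted(p for c, p in ndr if c == chrom)
        cursor = 0
        while True:
            gap = int(rng.uniform(200, 800))
            start = cursor + gap
            glen = int(np.clip(rng.lognormal(math.log(1400.0), 0.55), 300, 6000))
            end = start + glen
            if end >= length:
                break
            cursor = end
            if any(start - 500 < p < end + 500 for p in ori_pos):
                continue  # leave the origin NDR intergenic
            strand = "+" if rng.random() < 0.5 else "-"
            placed.append((chrom, start, end, strand))

    # replication time of each gene midpoint, min-plus over its chromosome
    t_gene = []
    for chrom, start, end, _ in placed:
        mid = (start + end) // 2
        t_gene.append(min(
            o.firing_time + abs(mid - o.position) / config.fork_speed
            for o in origins if o.chrom == chrom
        ))
    exprs = np.sort(rng.lognormal(2.0, 1.3, size=len(placed)))[::-1]
    n_strata = min(8, max(len(placed), 1))
    strata = np.array_split(np.argsort(t_gene, kind="stable"), n_strata)
    pools = [list(rng.permutation(s)) for s in strata]
    expr_of = np.empty(len(placed))
    turn = 0
    for e in exprs:
        while not pools[turn % n_strata]:
            turn += 1
        expr_of[pools[turn % n_strata].pop()] = e
        turn += 1
    return [
        GeneAnnot(f"g{i+1:04d}", chrom, start, end, strand, round(float(expr_of[i]), 3))
        for i, (chrom, start, end, strand) in enumerate(placed)
    ]


# ---------------------------------------------------------------------------
# replication


def simulate_replication_timing(
    genome: GenomeModel, origins, v: float, resolution: int = 200
) -> ReplicationSchedule:
    """Min-plus fork geometry: T(x) = min_i (firing_time_i + |x - x_i| / v).

    x runs over bin start coordinates on the fixed grid.  Around an isolated
    origin T is piecewise linear with slope +-1/v; between origins forks meet
    where the two branches cross.
    """
    if v <= 0:
        raise ValueError("fork speed must be positive")
    validate_origins(origins, genome)
    times: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        here = [o for o in origins if o.chrom == chrom]
        if not here:
            raise ValueError(f"chromosome {chrom!r} has no origin")
        x = np.arange(genome.n_bins(chrom, resolution)) * resolution
        t = np.full(x.shape, np.inf)
        for o in here:
            np.minimum(t, o.firing_time + np.abs(x - o.position) / v, out=t)
        times[chrom] = t
    return ReplicationSchedule(genome, resolution, times)


def population_replication_fraction(
    schedule: ReplicationSchedule,
    t: float,
    sigma_f: float,
    condition: str,
    escape_fraction: float = 0.05,
) -> dict[str, np.ndarray]:
    """Fraction of the population that has replicated each bin by time t.

    Released conditions: F(x,t) = Phi((t - T(x)) / sigma_f).  In NR_IAA only
    the escaping minority replicates, so F is scaled by ``escape_fraction``.
    """
    if sigma_f <= 0:
        raise ValueError("sigma_f must be positive")
    if t < 0:
        raise ValueError("t must be nonnegative")
    if escape_fraction < 0:
        raise ValueError("escape_fraction must be nonnegative")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    scale = escape_fraction if condition == "NR_IAA" else 1.0
    return {
        chrom: scale * norm.cdf((t - T) / sigma_f)
        for chrom, T in schedule.times.items()
    }


# ---------------------------------------------------------------------------
# acetylation kinetics


def turnover_rate_track(
    genome: GenomeModel, genes, config: SimConfig
) -> dict[str, np.ndarray]:
    """Per-bin turnover rate at t = 0 (arrest program fully active).

    lambda(x) = k_basal + lambda0 * min(expr / expr_ref, 1) * exp(-d_TSS / tss_decay_bp)
    inside gene bodies (d_TSS measured in transcription orientation), and
    k_basal in intergenic space.  The saturation reference expr_ref is the
    95th expression percentile: TPM-like abundances are heavy-tailed, so
    normalizing by the single maximum would leave every other gene with a
    negligible rate.
    """
    res = config.resolution
    lam = {c: np.full(genome.n_bins(c, res), config.k_basal) for c in genome.names}
    exprs = [g.expression for g in genes]
    expr_ref = float(np.quantile(exprs, 0.95)) if exprs else 0.0
    if expr_ref <= 0:
        expr_ref = max(exprs, default=0.0)
    if expr_ref <= 0:
        return lam
    for g in genes:
        b0, b1 = g.start // res, -(-g.end // res)
        centers = (np.arange(b0, b1) + 0.5) * res
        d_tss = centers - g.start if g.strand == "+" else g.end - centers
        d_tss = np.clip(d_tss, 0.0, None)
        shape = (
            np.exp(-d_tss / config.tss_decay_bp)
            if config.tss_decay_bp is not None
            else np.ones_like(d_tss)
        )
        rate = config.lambda0 * min(g.expression / expr_ref, 1.0) * shape
        lam[g.chrom][b0:b1] = np.maximum(lam[g.chrom][b0:b1], config.k_basal + rate)
    return lam


def steady_state_acetylation(
    genome: GenomeModel, genes, config: SimConfig
) -> SignalTrack:
    """Arrest steady state: A_ss(x) = a_max / (1 + lambda(x) / max(k_esa, eps)).

    Inside gene bodies the transcription-coupled turnover lambda(x) scales
    with expression relative to the most expressed gene, so A_ss is
    non-increasing in expression; intergenic space sits at the basal-turnover
    balance (the ``baseline factor`` times a_max).
    """
    validate_genes(genes, genome)
    lam = turnover_rate_track(genome, genes, config)
    eps = 1e-12
    data = {
        c: config.a_max / (1.0 + lam[c] / max(config.k_esa, eps))
        for c in genome.names
    }
    return SignalTrack(genome, config.resolution, data)


def _lambda_from_ass(a_ss: np.ndarray, config: SimConfig) -> np.ndarray:
    """Invert A_ss = a_max k / (k + lambda) for the per-bin turnover rate."""
    a = np.clip(a_ss, 1e-9, config.a_max)
    return config.k_esa * (config.a_max / a - 1.0)


def evolve_acetylation(
    a_ss: SignalTrack,
    schedule: ReplicationSchedule,
    config: SimConfig,
    condition: str,
    sas_active: bool,
    t: float,
) -> SignalTrack:
    """Population acetyl fraction at time t after release.

    Unreplicated cells hold the arrest balance (which drifts only if the
    arrest transcription program is allowed to relax); cells that replicated
    bin x at T(x) restart from the parental-dilution value
    ``0.5 A_arr + 0.5 p_sas`` (writer on) or ``0.5 A_arr`` (writer off) and
    relax under dA/dtau = k_esa (a_max - A) - lambda(x) A.  The population
    value is the F-weighted mixture of the two states.

    With ``arrest_program_tau = None`` the turnover rate is constant and the
    closed-form solution is used exactly; otherwise the linear ODE with the
    decaying rate is integrated with per-step exponential updates (0.25 min
    steps), which is exact in each frozen-rate step.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    F = population_replication_fraction(
        schedule, t, config.firing_jitter, condition, config.escape_fraction
    )
    k, amax, p = config.k_esa, config.a_max, config.p_sas
    pulse = p if sas_active else 0.0
    data = {}
    for chrom in a_ss.genome.names:
        ass = a_ss.data[chrom]
        lam0 = _lambda_from_ass(ass, config)
        lam_e = np.maximum(lam0 - config.k_basal, 0.0)  # expression-coupled part
        lam_b = np.minimum(lam0, config.k_basal)        # basal part
        T = schedule.times[chrom]
        if config.arrest_program_tau is None:
            # constant rates: closed form
            rate = k + lam0
            a_eq = np.where(rate > 0, k * amax / np.maximum(rate, 1e-300), ass)
            a_arr = a_eq + (ass - a_eq) * np.exp(-rate * t)  # == ass (arrest balance)
            tau = np.clip(t - T, 0.0, None)
            a_new = 0.5 * a_arr + 0.5 * pulse
            a_rep = a_eq + (a_new - a_eq) * np.exp(-rate * tau)
        else:
            a_arr, a_rep = _integrate_decaying_turnover(
                ass, lam_b, lam_e, T, config, pulse, t
            )
        data[chrom] = np.clip((1.0 - F[chrom]) * a_arr + F[chrom] * a_rep, 0.0, 1.0)
    return SignalTrack(a_ss.genome, config.resolution, data, time=t, condition=condition)


def _integrate_decaying_turnover(ass, lam_b, lam_e, T, config, pulse, t_end, dt=0.25):
    """Exponential-integrator stepping of the two per-bin states.

    lambda(x, s) = lam_b + lam_e * exp(-s / arrest_program_tau); each step
    freezes the rate at its midpoint and applies the exact one-step solution.
    """
    k, amax, tau_p = config.k_esa, config.a_max, config.arrest_program_tau
    # Unreplicated templates keep the arrest transcription program, so their
    # balance does not move: A_arr == A_ss throughout.  Replicated chromatin
    # is re-populated under the current, relaxing program, whose
    # transcription-coupled turnover decays as exp(-t / arrest_program_tau).
    a_arr = ass.copy()
    a_rep = 0.5 * a_arr + 0.5 * pulse  # pre-replication: pulse not yet relaxed
    replicated = T <= 0.0
    s = 0.0
    while s < t_end - 1e-12:
        step = min(dt, t_end - s)
        lam = lam_b + lam_e * math.exp(-(s + 0.5 * step) / tau_p)
        rate = k + lam
        a_eq = k * amax / np.maximum(rate, 1e-300)
        decay = np.exp(-rate * step)
        a_rep = np.where(
            replicated,
            a_eq + (a_rep - a_eq) * decay,
            0.5 * a_arr + 0.5 * pulse,
        )
        s += step
        crossing = (~replicated) & (T <= s)
        if np.any(crossing):
            # start exactly at T(x) and relax over the partial step s - T
            a_new = 0.5 * a_arr + 0.5 * pulse
            part = np.exp(-rate * np.clip(s - T, 0.0, step))
            a_rep = np.where(crossing, a_eq + (a_new - a_eq) * part, a_rep)
            replicated = replicated | crossing
    return a_arr, a_rep


# ---------------------------------------------------------------------------
# observation model


def render_chipseq(
    acetyl: SignalTrack,
    config: SimConfig,
    condition: str,
    t: float,
    seed: int,
) -> tuple[SignalTrack, SignalTrack, SpikeInCounts]:
    """Poisson read-count rendering of an acetyl-fraction track.

    Input coverage is Poisson(read_depth) per bin; IP coverage is
    Poisson(read_depth * (A + beta) / (A_ref + beta)).  The spike-in genome
    carries a constant acetyl level in every sample, and its expected input
    share is ``spike_fraction`` of the total expected input reads.
    """
    if config.read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 97]))
    beta, aref, depth = config.ip_background, config.a_ref, config.read_depth
    ip_data, in_data = {}, {}
    ip_total = 0
    in_total = 0
    for chrom in acetyl.genome.names:
        a = acetyl.data[chrom]
        if np.any((a < 0) | (a > 1)):
            raise ValueError(f"acetyl fractions on {chrom} outside [0, 1]")
        ip_rate = depth * (a + beta) / (aref + beta)
        ip = rng.poisson(ip_rate).astype(float)
        inp = rng.poisson(depth, size=a.shape).astype(float)
        ip_data[chrom], in_data[chrom] = ip, inp
        ip_total += int(ip.sum())
        in_total += int(inp.sum())
    n_bins = sum(acetyl.genome.n_bins(c, config.resolution) for c in acetyl.genome.names)
    exp_input = depth * n_bins
    in_spike = int(rng.poisson(config.spike_fraction * exp_input))
    ip_spike = int(
        rng.poisson(
            config.spike_fraction * exp_input * (config.spike_acetyl + beta) / (aref + beta)
        )
    )
    meta = dict(time=t, condition=condition)
    ip_track = SignalTrack(acetyl.genome, config.resolution, ip_data, kind="IP", **meta)
    in_track = SignalTrack(acetyl.genome, config.resolution, in_data, kind="input", **meta)
    counts = SpikeInCounts(
        ip_sample=ip_total, ip_spike=max(ip_spike, 1),
        in_sample=max(in_total, 1), in_spike=in_spike,
    )
    return ip_track, in_track, counts


def sample_seed(config: SimConfig, condition: str, t: float) -> int:
    """Stable per-sample seed derived from the config seed."""
    key = f"{config.seed}:{condition}:{t:g}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def simulate_condition(
    config: SimConfig,
    condition: str,
    genome: GenomeModel | None = None,
    origins=None,
    genes=None,
):
    """Full forward model for one condition.

    Returns (timepoint -> (acetyl, ip, input, SpikeInCounts)) plus the shared
    annotation objects, so callers can reuse the genome across conditions.
    """
    genome = genome or build_genome(config)
    origins = origins if origins is not None else build_origins(config, genome)
    genes = genes if genes is not None else build_genes(config, genome, origins)
    schedule = simulate_replication_timing(genome, origins, config.fork_speed, config.resolution)
    a_ss = steady_state_acetylation(genome, genes, config)
    sas = condition_sas_active(condition)
    out = {}
    for t in config.timepoints:
        acetyl = evolve_acetylation(a_ss, schedule, config, condition, sas, t)
        ip, inp, counts = render_chipseq(
            acetyl, config, condition, t, sample_seed(config, condition, t)
        )
        out[t] = (acetyl, ip, inp, counts)
    return out, genome, origins, genes


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(config: SimConfig, outdir) -> dict[str, str]:
    """Render the whole study to disk as plain-text files.

    Emits the genome table, origin BED + firing-time TSV, gene BED,
    expression TSV, one IP and one input bedGraph per condition and
    timepoint, the spike-count table, the flat config file and a manifest of
    SHA-256 checksums.  The output is a pure function of the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = build_genome(config)
    origins = build_origins(config, genome)
    genes = build_genes(config, genome, origins)

    files: dict[str, str] = {}

    def emit(name: str, text: str):
        path = outdir / name
        path.write_text(text)
        files[name] = hashlib.sha256(text.encode()).hexdigest()

    emit("genome.tsv", "chrom\tlength\n" + "".join(
        f"{c}\t{l}\n" for c, l in genome.chromosomes))
    emit("origins.bed", "".join(
        f"{o.chrom}\t{o.position}\t{o.position + 1}\t{o.id}\t0\t+\n" for o in origins))
    emit("origins_timing.tsv", "id\tfiring_time_min\n" + "".join(
        f"{o.id}\t{o.firing_time:g}\n" for o in origins))
    emit("genes.bed", "".join(
        f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n" for g in genes))
    emit("expression.tsv", "gene_id\tabundance\n" + "".join(
        f"{g.id}\t{g.expression:g}\n" for g in genes))
    emit("config.txt", "".join(
        f"{k}\t{v}\n" for k, v in sorted(asdict(config).items())))

    spike_rows = ["condition\ttime_min\tip_sample\tip_spike\tin_sample\tin_spike"]
    for condition in CONDITIONS:
        samples, *_ = simulate_condition(config, condition, genome, origins, genes)
        for t, (_acetyl, ip, inp, counts) in samples.items():
            for kind, track in (("ip", ip), ("input", inp)):
                name = f"{condition}_t{int(t):02d}_{kind}.bedgraph"
                path = outdir / name
                write_bedgraph(track, path)
                files[name] = hashlib.sha256(path.read_bytes()).hexdigest()
            spike_rows.append(
                f"{condition}\t{t:g}\t{counts.ip_sample}\t{counts.ip_spike}"
                f"\t{counts.in_sample}\t{counts.in_spike}"
            )
    emit("spike_counts.tsv", "\n".join(spike_rows) + "\n")

    manifest = "".join(f"{name}\t{digest}\n" for name, digest in sorted(files.items()))
    (outdir / "manifest.tsv").write_text(manifest)
    files["manifest.tsv"] = hashlib.sha256(manifest.encode()).hexdigest()
    return files
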