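"""Forward simulator of the replicated cage experiment.

Emulates the design of the host-switch study: 3 pigeon colors x 2 preening
treatments x 4 replicates, one louse population per aviary (24 populations
on 96 birds), founders of 25 lice per bird, pooled sequencing (~85X) at
6-month intervals plus individual sequencing (~18X) at 36 months.  Founder
allele frequencies follow a rare-allele-skewed neutral spectrum; polygenic
color selection acts only in normally-preening, non-control populations.

Each population evolves by Wright-Fisher binomial resampling of 2*Ne gene
copies per generation.  Selected sites get the deterministic per-generation
update p' = p(1+s)/(1+ps) before drift (independent additive loci, the
default), or truncation selection on an additive polygenic score across the
trait loci (individual-based mode).  Sequencing adds the two pool-seq noise
stages: lice sampled from the population, then reads drawn off the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .popgen import generations_elapsed
from .variants_io import SyncTable, _ALLELE_INDEX

COLOR_NAMES = ("white", "gray", "black", "color4", "color5", "color6")
PREENING_NAMES = ("preen", "impaired")
CONTROL_COLOR = "gray"

_BASES = np.array(list("ATCG"))


@dataclass
class DesignConfig:
    """Layout and sequencing parameters of the cage experiment."""

    n_colors: int = 3
    n_preening: int = 2
    n_replicates: int = 4
    birds_per_aviary: int = 4
    founders_per_bird: int = 25
    pooled_timepoints_months: tuple = (6, 12, 18, 24, 30, 42, 48)
    individual_timepoint_month: int = 36
    generation_days: float = 24.5
    pool_coverage: float = 85.0
    individual_coverage: float = 18.0
    sample_cap: int = 50

    def __post_init__(self) -> None:
        for name in ("n_colors", "n_preening", "n_replicates",
                     "birds_per_aviary", "founders_per_bird", "sample_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        months = list(self.pooled_timepoints_months)
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("pooled timepoint months must be strictly increasing")
        if self.generation_days <= 0:
            raise ValueError("generation_days must be positive")
        if self.pool_coverage <= 0 or self.individual_coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def founders_per_population(self) -> int:
        return self.birds_per_aviary * self.founders_per_bird

    def generations_at(self, month: float) -> int:
        return generations_elapsed(month, self.generation_days)


@dataclass
class SelectionRegime:
    """Per-locus selection strength and trait architecture."""

    s: float = 0.1
    n_trait_loci: int = 10
    ne: int = 200
    direction: str = "darker"          # {lighter, darker, neutral}
    mode: str = "additive"             # {additive, truncation}
    truncation_survival: float = 0.5   # fraction kept in truncation mode

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.n_trait_loci < 0:
            raise ValueError("number of trait loci must be >= 0")
        if self.ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.direction not in ("lighter", "darker", "neutral"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.mode not in ("additive", "truncation"):
            raise ValueError(f"unknown selection mode {self.mode!r}")


@dataclass
class Population:
    pop_id: str
    color: str
    preening: str
    replicate: int

    @property
    def is_control(self) -> bool:
        return self.color == CONTROL_COLOR

    @property
    def under_selection(self) -> bool:
        """Color selection operates only where hosts preen and differ from
        the ancestral color."""
        return self.preening == "preen" and not self.is_control


@dataclass
class PoolSample:
    sample_id: str
    pop_id: str          # "" for ancestral pools
    month: float
    replicate: int
    ancestral: bool = False


@dataclass
class Design:
    config: DesignConfig
    populations: list[Population]
    pooled_manifest: list[PoolSample]

    @property
    def n_birds(self) -> int:
        return len(self.populations) * self.config.birds_per_aviary

    @property
    def pop_ids(self) -> list[str]:
        return [p.pop_id for p in self.populations]


def build_design(config: DesignConfig) -> Design:
    """Enumerate populations (one per aviary: color x preening x replicate)
    and the pooled-sample manifest, including one ancestral pool per
    replicate sampled when the replicate was started."""
    colors = COLOR_NAMES[: config.n_colors]
    preenings = PREENING_NAMES[: config.n_preening]
    pops = [
        Population(f"{c}_{p}_r{r}", c, p, r)
        for r in range(1, config.n_replicates + 1)
        for c in colors
        for p in preenings
    ]
    manifest = [
        PoolSample(f"ancestral_r{r}", "", 0.0, r, ancestral=True)
        for r in range(1, config.n_replicates + 1)
    ]
    for pop in pops:
        for month in config.pooled_timepoints_months:
            manifest.append(
                PoolSample(f"{pop.pop_id}_m{month:g}", pop.pop_id, month, pop.replicate)
            )
    return Design(config, pops, manifest)


def simulate_founders(
    n_sites: int,
    n_founders: int,
    skew: str = "neutral",
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Draw founder alt-allele frequencies from a site frequency spectrum.

    ``skew='neutral'`` samples allele counts i in 1..2n-1 with probability
    proportional to 1/i (the standard neutral SFS, heavy in rare alleles);
    ``skew='uniform'`` is the flat control spectrum.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if n_founders < 1:
        raise ValueError("need at least one founder")
    rng = np.random.default_rng(rng)
    two_n = 2 * n_founders
    i = np.arange(1, two_n)
    if skew == "neutral":
        w = 1.0 / i
    elif skew == "uniform":
        w = np.ones_like(i, dtype=float)
    else:
        raise ValueError(f"unknown skew {skew!r}")
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / two_n


def selection_update(p: np.ndarray, s: "float | np.ndarray") -> np.ndarray:
    """Deterministic one-generation change under genic selection:
    p' = p(1+s) / (1 + p s)."""
    return p * (1.0 + s) / (1.0 + p * s)


def wright_fisher(
    p0: np.ndarray,
    two_ne: int,
    n_generations: int,
    s: "np.ndarray | None" = None,
    rng: "np.random.Generator | None" = None,
) -> np.ndarray:
    """Binomial Wright-Fisher trajectories; returns (n_generations+1, n_sites)
    allele frequencies, row 0 being the (resampled-to-counts) start."""
    rng = np.random.default_rng(rng)
    p0 = np.asarray(p0, dtype=float)
    traj = np.empty((n_generations + 1, p0.size))
    k = rng.binomial(two_ne, p0)
    traj[0] = k / two_ne
    for g in range(1, n_generations + 1):
        p = k / two_ne
        if s is not None:
            p = selection_update(p, s)
        k = rng.binomial(two_ne, p)
        traj[g] = k / two_ne
    return traj


def _truncation_generation(
    dosages: np.ndarray, sign: float, survival: float, rng: np.random.Generator
) -> np.ndarray:
    """One generation of truncation selection on an additive score.

    ``dosages`` is (n_individuals, L) in {0,1,2}.  The top ``survival``
    fraction by score (sign-adjusted, random tie-break) become parents;
    offspring alleles are drawn per locus from two random parents.
    """
    n = dosages.shape[0]
    score = sign * dosages.sum(axis=1) + rng.uniform(0, 1e-6, size=n)
    n_keep = max(2, int(round(survival * n)))
    parents = dosages[np.argsort(score)[-n_keep:]]
    mothers = parents[rng.integers(n_keep, size=n)]
    fathers = parents[rng.integers(n_keep, size=n)]
    return rng.binomial(1, mothers / 2.0) + rng.binomial(1, fathers / 2.0)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    selected_sites: list          # (chrom, position, s, effect_sign)
    selected_indices: np.ndarray  # row indices into the site table
    founder_frequencies: np.ndarray
    census_series: dict           # pop_id -> {month: lice counted}


@dataclass
class SimulatedExperiment:
    design: Design
    regime: SelectionRegime
    chroms: np.ndarray
    positions: np.ndarray
    refs: np.ndarray
    alts: np.ndarray
    chrom_sizes: dict
    trajectories: dict            # pop_id -> (n_generations+1, n_sites) freq array
    ancestral_freqs: dict         # replicate -> founder-sample freq per site
    truth: SimTruth
    seed: int

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def freqs_at(self, pop_id: str, month: float) -> np.ndarray:
        gen = self.design.config.generations_at(month)
        return self.trajectories[pop_id][gen]


def _site_table(
    n_sites: int, chrom_sizes: Mapping[str, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_sites, p=sizes / sizes.sum())
    chroms = np.array([names[i] for i in chrom_idx], dtype=object)
    positions = np.empty(n_sites, dtype=np.int64)
    for i, c in enumerate(names):
        m = chrom_idx == i
        positions[m] = np.sort(rng.choice(int(sizes[i]), size=m.sum(), replace=False)) + 1
    order = np.lexsort((positions, chroms.astype(str)))
    refs = _BASES[rng.integers(4, size=n_sites)].astype(object)
    alts = np.array(
        [rng.choice([b for b in "ATCG" if b != r]) for r in refs], dtype=object
    )
    return chroms[order], positions[order], refs, alts


DEFAULT_CHROM_SIZES = {f"chr{i}": 5_000_000 for i in range(1, 5)}


def simulate_experiment(
    design: "Design | DesignConfig",
    regime: SelectionRegime,
    n_generations: "int | None" = None,
    seed: "int | None" = 0,
    n_sites: int = 2000,
    chrom_sizes: "Mapping[str, int] | None" = None,
    founder_skew: str = "neutral",
    census_base: int = 250,
    bottleneck_months: "Sequence[float] | None" = None,
    bottleneck_size: int = 30,
) -> SimulatedExperiment:
    """Run the replicated Wright-Fisher experiment and return trajectories
    plus ground truth.

    Trait loci are chosen among sites with founder minor-allele frequency
    >= 0.05 (selection on an absent allele is invisible); they experience
    selection only in normally-preening, non-control populations.  The
    census series is Poisson around ``census_base`` with optional
    bottlenecks at the given months.
    """
    if isinstance(design, DesignConfig):
        design = build_design(design)
    cfg = design.config
    if regime.ne < 2:
        raise ValueError("Ne must be >= 2")
    if n_generations is None:
        last_month = max(
            max(cfg.pooled_timepoints_months), cfg.individual_timepoint_month
        )
        n_generations = cfg.generations_at(last_month)
    root = np.random.default_rng(seed)
    site_rng, founder_rng = root.spawn(2)

    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    chroms, positions, refs, alts = _site_table(n_sites, chrom_sizes, site_rng)
    p_anc = simulate_founders(
        n_sites, cfg.founders_per_population, founder_skew, founder_rng
    )

    # trait loci drawn once, shared by every selected population
    maf = np.minimum(p_anc, 1 - p_anc)
    candidates = np.flatnonzero(maf >= 0.05)
    if candidates.size < regime.n_trait_loci:
        candidates = np.argsort(maf)[-max(regime.n_trait_loci, 1):]
    sel_idx = np.sort(
        founder_rng.choice(candidates, size=regime.n_trait_loci, replace=False)
    ) if regime.n_trait_loci else np.array([], dtype=int)
    sign = -1.0 if regime.direction == "lighter" else 1.0
    truth_sites = [
        (chroms[i], int(positions[i]), regime.s, sign) for i in sel_idx
    ]

    two_ne = 2 * regime.ne
    s_vec = np.zeros(n_sites)
    s_vec[sel_idx] = regime.s
    trajectories: dict[str, np.ndarray] = {}
    census: dict[str, dict] = {}
    ancestral: dict[int, np.ndarray] = {}
    two_nf = 2 * cfg.founders_per_population
    for pop in design.populations:
        rng = root.spawn(1)[0]
        # founder sampling: each population seeds from the wild pool
        k_found = rng.binomial(two_nf, p_anc)
        p0 = k_found / two_nf
        if pop.replicate not in ancestral:
            ancestral[pop.replicate] = rng.binomial(two_nf, p_anc) / two_nf
        selected = pop.under_selection and regime.direction != "neutral" and regime.s > 0
        if selected and regime.mode == "truncation":
            traj = _simulate_truncation_pop(
                p0, sel_idx, regime, n_generations, rng
            )
        else:
            traj = wright_fisher(
                p0, two_ne, n_generations, s_vec if selected else None, rng
            )
        trajectories[pop.pop_id] = traj
        months = list(cfg.pooled_timepoints_months) + [cfg.individual_timepoint_month]
        census[pop.pop_id] = {
            m: (bottleneck_size if bottleneck_months and m in bottleneck_months
                else int(rng.poisson(census_base)))
            for m in sorted(months)
        }

    truth = SimTruth(truth_sites, sel_idx, p_anc, census)
    return SimulatedExperiment(
        design, regime, chroms, positions, refs, alts, chrom_sizes,
        trajectories, ancestral, truth, seed if seed is not None else -1,
    )


def _simulate_truncation_pop(
    p0: np.ndarray,
    sel_idx: np.ndarray,
    regime: SelectionRegime,
    n_generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trait loci evolve individual-based under truncation selection; all
    other sites drift neutrally."""
    n_sites = p0.size
    neutral_mask = np.ones(n_sites, dtype=bool)
    neutral_mask[sel_idx] = False
    traj = np.empty((n_generations + 1, n_sites))
    traj[:, neutral_mask] = wright_fisher(
        p0[neutral_mask], 2 * regime.ne, n_generations, None, rng
    )
    sign = -1.0 if regime.direction == "lighter" else 1.0
    dos = rng.binomial(2, p0[sel_idx], size=(regime.ne, sel_idx.size))
    traj[0, sel_idx] = dos.mean(axis=0) / 2.0
    for g in range(1, n_generations + 1):
        dos = _truncation_generation(dos, sign, regime.truncation_survival, rng)
        traj[g, sel_idx] = dos.mean(axis=0) / 2.0
    return traj


# -- sequencing -----------------------------------------------------------


def pool_read_counts(
    freqs: np.ndarray,
    pool_individuals: int,
    mean_depth: float,
    rng: np.random.Generator,
    population_copies: "int | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage pool-seq sampling at each site.

    Stage 1 draws the 2n allele copies that enter the pool (hypergeometric
    from the finite population when ``population_copies`` is given, else
    binomial); stage 2 draws reads binomially at Poisson(mean_depth).
    Returns (alt_reads, total_depth).
    """
    if mean_depth <= 0:
        raise ValueError("coverage must be positive")
    two_n = 2 * pool_individuals
    if population_copies is not None:
        k_pop = np.rint(freqs * population_copies).astype(np.int64)
        n_draw = min(two_n, population_copies)
        pooled = rng.hypergeometric(k_pop, population_copies - k_pop, n_draw)
        pool_freq = pooled / n_draw
    else:
        pool_freq = rng.binomial(two_n, freqs) / two_n
    depth = rng.poisson(mean_depth, size=freqs.shape)
    alt = rng.binomial(depth, pool_freq)
    return alt, depth


@dataclass
class SequencedExperiment:
    """Pooled read counts per (population, month) and individual genotypes
    at the individual-sequencing month."""

    sim: SimulatedExperiment
    pooled: dict           # (pop_id, month) -> (alt_reads, depth)
    ancestral_pools: dict  # replicate -> (alt_reads, depth)
    individuals: dict      # pop_id -> (n_individuals, n_sites) alt dosage
    seed: int

    def counts_at(self, month: float, pops: "Sequence[str] | None" = None
                  ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(ref_counts, alt_counts, pop_ids) at one month: read counts at
        pooled months, genotype-derived allele copies at the individual
        month (2 per louse, the pooled-data analogue)."""
        cfg = self.sim.design.config
        pops = list(pops) if pops is not None else self.sim.design.pop_ids
        ref = np.empty((self.sim.n_sites, len(pops)), dtype=np.int64)
        alt = np.empty_like(ref)
        for j, pid in enumerate(pops):
            if month == cfg.individual_timepoint_month:
                dos = self.individuals[pid]
                alt[:, j] = dos.sum(axis=0)
                ref[:, j] = 2 * dos.shape[0] - alt[:, j]
            else:
                a, d = self.pooled[(pid, month)]
                alt[:, j] = a
                ref[:, j] = d - a
        return ref, alt, pops

    def sync_at(self, month: float, pops: "Sequence[str] | None" = None) -> SyncTable:
        ref, alt, pops = self.counts_at(month, pops)
        sim = self.sim
        counts = np.zeros((sim.n_sites, len(pops), 6), dtype=np.int64)
        ridx = np.array([_ALLELE_INDEX[b] for b in sim.refs])
        aidx = np.array([_ALLELE_INDEX[b] for b in sim.alts])
        rows = np.arange(sim.n_sites)[:, None]
        cols = np.arange(len(pops))[None, :]
        counts[rows, cols, ridx[:, None]] = ref
        counts[rows, cols, aidx[:, None]] = alt
        return SyncTable(sim.chroms, sim.positions, sim.refs, list(pops), counts)


def sample_sequencing(
    sim: SimulatedExperiment, seed: "int | None" = 0
) -> SequencedExperiment:
    """Sequence the simulated experiment: pooled read counts at every
    manifest month (plus ancestral pools) and Hardy-Weinberg individual
    genotypes at the individual-sequencing month."""
    cfg = sim.design.config
    root = np.random.default_rng(seed)
    two_ne = 2 * sim.regime.ne
    pooled: dict = {}
    ancestral: dict = {}
    for smp in sim.design.pooled_manifest:
        rng = root.spawn(1)[0]
        if smp.ancestral:
            freqs = sim.ancestral_freqs[smp.replicate]
            pool_n = cfg.sample_cap
            pop_copies = None
        else:
            gen = cfg.generations_at(smp.month)
            freqs = sim.trajectories[smp.pop_id][gen]
            census = sim.truth.census_series[smp.pop_id].get(smp.month)
            n_avail = census if census is not None else cfg.sample_cap
            pool_n = min(cfg.sample_cap, max(1, n_avail))
            pop_copies = two_ne
        alt, depth = pool_read_counts(freqs, pool_n, cfg.pool_coverage, rng, pop_copies)
        if smp.ancestral:
            ancestral[smp.replicate] = (alt, depth)
        else:
            pooled[(smp.pop_id, smp.month)] = (alt, depth)

    individuals: dict = {}
    month = cfg.individual_timepoint_month
    gen = cfg.generations_at(month)
    for pop in sim.design.populations:
        rng = root.spawn(1)[0]
        census = sim.truth.census_series[pop.pop_id].get(month, cfg.sample_cap)
        n_ind = min(cfg.sample_cap, max(2, census))
        freqs = sim.trajectories[pop.pop_id][gen]
        individuals[pop.pop_id] = rng.binomial(
            2, freqs, size=(n_ind, sim.n_sites)
        ).astype(np.int8)
    return SequencedExperiment(sim, pooled, ancestral, individuals,
                               seed if seed is not None else -1)
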