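"""Forward-time diploid Wright-Fisher simulator with an allele-gated hotspot.

A diploid population evolves with non-overlapping generations.  Each
individual carries a pair of haplotypes over a fixed SNP map spanning a
window (200 kb by default).  A causal SNP sits at the hotspot center: a
parent carrying at least one *hot* allele performs meiosis with an
elevated crossover probability (0.01 per meiosis vs a background of
0.001, i.e. one crossover per 200 Mb scaled to the window), and at most
one crossover occurs per transmitted gamete, its position drawn from a
Normal centered on the hotspot (sd = half the hotspot width by default)
truncated to the window.  There is no mutation.

The benchmark scenario starts the hot allele at 99% and wants it near
50% at sampling time.  Pure drift essentially never makes that journey,
so the run can be *conditioned*: rejection-sample runs until the final
frequency lands in the target band, optionally helped by a weak
selection coefficient against the hot allele (``selection="auto"``
computes the deterministic logit-decay coefficient).  Hotspot alleles
eroding over time is exactly the behaviour expected from biased gene
conversion at real hotspots, so the selective proxy is biologically
sensible as well as practical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .hapio import HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Population",
    "MeiosisDetail",
    "ConditioningError",
    "site_positions",
    "initialize_population",
    "meiosis",
    "evolve",
    "run_conditioned",
    "sample_panels",
]


class ConditioningError(RuntimeError):
    """Raised when no run reaches the target final frequency."""


@dataclass
class SimulationConfig:
    """Benchmark simulation parameters (defaults follow the benchmark design).

    ``selection`` is ``None`` (pure drift), a coefficient against the
    hot allele, or ``"auto"`` to derive the coefficient that carries the
    frequency from ``init_hot_freq`` to ``final_hot_freq_target``
    deterministically over the run.
    """

    pop_size: int = 5000
    generations: int = 3000
    window_length_bp: float = 200_000.0
    n_sites: int = 200
    causal_pos_bp: float = 100_000.0
    hotspot_center_bp: float = 100_000.0
    hotspot_width_bp: float = 2_000.0
    p_xover_background: float = 0.001
    p_xover_hot: float = 0.01
    xover_sd_bp: float | None = None  # defaults to hotspot_width / 2
    xover_position_dist: str = "normal"  # or "uniform"
    penetrance: str = "dominant"  # or "additive"
    init_hot_freq: float | None = 0.99  # None: leave the causal column as drawn
    final_hot_freq_target: float = 0.50
    final_hot_freq_tol: float = 0.05
    init_mode: str = "independent"  # or "coalescent" (realistic standing LD)
    init_Ne: float = 5000.0
    init_recomb_rate: float = 1e-8  # per bp per generation, coalescent mode
    init_mut_rate: float = 2e-8
    selection: float | str | None = None
    n_subsets: int = 10
    subset_individuals: int = 90
    seed: int = 0
    positions_bp: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for p in (self.p_xover_background, self.p_xover_hot):
            if not 0.0 <= p <= 1.0:
                raise ValueError("crossover probabilities must be in [0, 1]")
        if not 0.0 < self.causal_pos_bp < self.window_length_bp:
            raise ValueError("causal position must be inside the window")
        if self.subset_individuals > self.pop_size:
            raise ValueError("subset larger than population")
        if self.xover_sd_bp is None:
            self.xover_sd_bp = self.hotspot_width_bp / 2.0
        if self.xover_position_dist not in ("normal", "uniform"):
            raise ValueError("xover_position_dist must be 'normal' or 'uniform'")
        if self.init_mode not in ("independent", "coalescent"):
            raise ValueError("init_mode must be 'independent' or 'coalescent'")
        if self.penetrance not in ("dominant", "additive"):
            raise ValueError("penetrance must be 'dominant' or 'additive'")

    @classmethod
    def table_preset(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """The full benchmark scale: N=5000, 3000 generations, 200 sites."""
        return cls(seed=seed, selection="auto", **overrides)

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Reduced scale for routine runs: N=500, 300 generations, 40 sites."""
        kwargs = dict(
            pop_size=500,
            generations=300,
            n_sites=40,
            subset_individuals=90,
            selection="auto",
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def desk_null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Desk scale with no causal SNP: the hotspot fires at the hot
        rate for every meiosis (no allele-dependence), and the central
        site is an ordinary neutral SNP.  This is the null for
        *association with hotspot intensity* — the hotspot exists, but
        no allele modulates it."""
        kwargs = dict(
            pop_size=500,
            generations=300,
            n_sites=40,
            subset_individuals=90,
            p_xover_background=0.01,
            p_xover_hot=0.01,
            init_hot_freq=None,
            final_hot_freq_target=0.5,
            final_hot_freq_tol=0.5,
            selection=None,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def selection_coefficient(self) -> float:
        """Fixed per-generation coefficient (0 for drift or "auto" mode)."""
        if self.selection is None or self.selection == "auto":
            return 0.0
        return float(self.selection)


def site_positions(config: SimulationConfig) -> np.ndarray:
    """SNP coordinates (bp): evenly spaced interior positions with the
    site nearest the causal position snapped onto it."""
    if config.positions_bp is not None:
        pos = np.asarray(config.positions_bp, dtype=float).copy()
    else:
        pos = np.linspace(0.0, config.window_length_bp, config.n_sites + 2)[1:-1]
    idx = int(np.argmin(np.abs(pos - config.causal_pos_bp)))
    pos[idx] = config.causal_pos_bp
    if not np.all(np.diff(pos) > 0):
        raise ValueError("site positions are not strictly increasing")
    return pos


def causal_index(config: SimulationConfig) -> int:
    pos = site_positions(config)
    return int(np.argmin(np.abs(pos - config.causal_pos_bp)))


@dataclass
class Population:
    """Evolving diploid population: haplotypes ``(N, 2, L)`` over the map."""

    haplotypes: np.ndarray
    positions_bp: np.ndarray
    causal_index: int
    generation: int = 0
    freq_trace: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    def hot_allele_freq(self) -> float:
        return float(np.mean(self.haplotypes[:, :, self.causal_index] == 1))


@dataclass
class MeiosisDetail:
    crossed: bool
    position_bp: float | None
    start_strand: int


def _coalescent_haplotypes(config: SimulationConfig, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Standing variation from a neutral coalescent with recombination.

    Simulates ``2 * pop_size`` haplotypes over the window, then for each
    target site position picks the nearest unused segregating site with
    sample MAF >= 0.1.  Returns ``(haplotypes (2N, L), positions_bp)``.
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=config.pop_size,
        ploidy=2,
        sequence_length=config.window_length_bp,
        recombination_rate=config.init_recomb_rate,
        population_size=config.init_Ne,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.init_mut_rate,
        random_seed=(seed % (2**31 - 2)) + 2,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    geno = ts.genotype_matrix()  # (n_var, 2N)
    var_pos = np.array([v.position for v in ts.variants()])
    n = geno.shape[1]
    mafs = np.minimum(geno.mean(axis=1), 1 - geno.mean(axis=1))
    usable = np.flatnonzero(mafs >= 0.1)
    targets = site_positions(config)
    if usable.size < targets.size:
        raise RuntimeError(
            f"coalescent init produced only {usable.size} common sites; "
            "raise init_mut_rate"
        )
    chosen: list[int] = []
    taken = np.zeros(usable.size, dtype=bool)
    for t in targets:
        order = np.argsort(np.abs(var_pos[usable] - t))
        for o in order:
            if not taken[o]:
                taken[o] = True
                chosen.append(usable[o])
                break
    chosen_arr = np.array(sorted(chosen))
    haps = geno[chosen_arr].T.astype(np.int8)  # (2N, L)
    return np.ascontiguousarray(haps), var_pos[chosen_arr]


def initialize_population(config: SimulationConfig, seed: int | None = None) -> Population:
    """Standing variation at generation 0.

    ``independent`` mode (default): non-causal sites draw an allele-1
    frequency from Uniform(0.1, 0.9) and haplotypes site-independently
    from it (no initial LD).  ``coalescent`` mode: founder haplotypes are
    drawn from a neutral coalescent with recombination, giving realistic
    standing LD, and site positions follow the simulated variants.  In
    both modes the causal site's hot allele (coded 1) starts at
    ``init_hot_freq``.
    """
    the_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(the_seed)
    if config.init_mode == "coalescent":
        flat, pos = _coalescent_haplotypes(config, the_seed)
        ci = int(np.argmin(np.abs(pos - config.causal_pos_bp)))
        if config.init_hot_freq is not None:
            # overwrite the causal column so the hot allele starts at the
            # configured frequency (near-fixed, so the LD impact is nil)
            flat[:, ci] = (rng.random(flat.shape[0]) < config.init_hot_freq).astype(np.int8)
        haps = flat.reshape(config.pop_size, 2, pos.size)
    else:
        pos = site_positions(config)
        ci = int(np.argmin(np.abs(pos - config.causal_pos_bp)))
        L = pos.size
        freqs = rng.uniform(0.1, 0.9, size=L)
        if config.init_hot_freq is not None:
            freqs[ci] = config.init_hot_freq
        haps = (rng.random((config.pop_size, 2, L)) < freqs).astype(np.int8)
    pop = Population(haplotypes=haps, positions_bp=pos.astype(float), causal_index=ci)
    pop.freq_trace.append(pop.hot_allele_freq())
    return pop


def _crossover_prob(parent: np.ndarray, config: SimulationConfig, ci: int) -> float:
    hot_count = int(parent[0, ci] == 1) + int(parent[1, ci] == 1)
    if config.penetrance == "dominant":
        return config.p_xover_hot if hot_count >= 1 else config.p_xover_background
    return config.p_xover_background + (
        config.p_xover_hot - config.p_xover_background
    ) * hot_count / 2.0


def _draw_position(config: SimulationConfig, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    if config.xover_position_dist == "uniform":
        return rng.random(size) * config.window_length_bp
    x = rng.normal(config.hotspot_center_bp, config.xover_sd_bp, size)
    bad = (x < 0) | (x > config.window_length_bp)
    while bad.any():
        x[bad] = rng.normal(config.hotspot_center_bp, config.xover_sd_bp, int(bad.sum()))
        bad = (x < 0) | (x > config.window_length_bp)
    return x


def meiosis(
    parent: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    positions_bp: np.ndarray | None = None,
    detail: bool = False,
):
    """One gamete from a diploid parent ``(2, L)``.

    With the genotype-dependent probability a single crossover occurs at
    a truncated-Normal (or uniform) position and the gamete is the
    mosaic of the two parental haplotypes from a fair starting strand;
    otherwise one haplotype is transmitted intact (fair coin).
    """
    if positions_bp is None:
        positions_bp = site_positions(config)
    ci = int(np.argmin(np.abs(positions_bp - config.causal_pos_bp)))
    p = _crossover_prob(parent, config, ci)
    start = int(rng.integers(0, 2))
    crossed = bool(rng.random() < p)
    if not crossed:
        gam = parent[start].copy()
        return (gam, MeiosisDetail(False, None, start)) if detail else gam
    x = float(_draw_position(config, rng, 1)[0])
    left = positions_bp < x
    gam = np.where(left, parent[start], parent[1 - start]).astype(np.int8)
    return (gam, MeiosisDetail(True, x, start)) if detail else gam


def _gamete_batch(
    haps: np.ndarray,
    parents: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    positions_bp: np.ndarray,
    ci: int,
) -> np.ndarray:
    """Vectorized meioses for ``parents`` (indices into the population)."""
    M = parents.shape[0]
    g0 = haps[parents, 0, :]
    g1 = haps[parents, 1, :]
    hot0 = g0[:, ci] == 1
    hot1 = g1[:, ci] == 1
    if config.penetrance == "dominant":
        p = np.where(hot0 | hot1, config.p_xover_hot, config.p_xover_background)
    else:
        cnt = hot0.astype(float) + hot1.astype(float)
        p = config.p_xover_background + (
            config.p_xover_hot - config.p_xover_background
        ) * cnt / 2.0
    start = rng.integers(0, 2, M)
    crossed = rng.random(M) < p
    x = _draw_position(config, rng, M)
    a = np.where(start[:, None] == 0, g0, g1)
    b = np.where(start[:, None] == 0, g1, g0)
    right = positions_bp[None, :] >= x[:, None]
    return np.where(crossed[:, None] & right, b, a).astype(np.int8)


def evolve(
    pop: Population,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_generations: int | None = None,
) -> Population:
    """Evolve in place for ``config.generations`` non-overlapping generations.

    Each offspring takes one gamete from each of two uniformly chosen
    parents (fitness-weighted when selection is active); population size
    is constant and the causal-allele frequency trace is appended every
    generation.  Loss or fixation of the causal allele flags the run.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    gens = config.generations if n_generations is None else n_generations
    N = pop.size
    s_fixed = config.selection_coefficient()
    auto = config.selection == "auto"
    if auto:
        # logit-linear target path from the current frequency to the
        # conditioning target; the per-generation coefficient is set by
        # feedback so the expected trajectory tracks the path.
        p_now = min(max(pop.freq_trace[-1], 1e-9), 1 - 1e-9)
        pt = min(max(config.final_hot_freq_target, 1e-9), 1 - 1e-9)
        path = np.linspace(np.log(p_now / (1 - p_now)), np.log(pt / (1 - pt)), gens + 1)
    for g in range(gens):
        haps = pop.haplotypes
        if auto:
            p = pop.freq_trace[-1]
            if 0.0 < p < 1.0:
                s = float(np.clip(np.log(p / (1 - p)) - path[g + 1], -0.3, 0.3))
            else:
                s = 0.0
        else:
            s = s_fixed
        if s != 0.0:
            hot_cnt = (haps[:, :, pop.causal_index] == 1).sum(axis=1)
            w = (1.0 - s) ** hot_cnt if s > 0 else (1.0 - abs(s)) ** (2 - hot_cnt)
            probs = w / w.sum()
            idx = rng.choice(N, size=2 * N, p=probs)
        else:
            idx = rng.integers(0, N, size=2 * N)
        gam_a = _gamete_batch(haps, idx[:N], config, rng, pop.positions_bp, pop.causal_index)
        gam_b = _gamete_batch(haps, idx[N:], config, rng, pop.positions_bp, pop.causal_index)
        pop.haplotypes = np.stack((gam_a, gam_b), axis=1)
        pop.generation += 1
        f = pop.hot_allele_freq()
        pop.freq_trace.append(f)
    final = pop.freq_trace[-1]
    if final in (0.0, 1.0):
        pop.meta["causal_allele_fixed"] = True
        if config.p_xover_hot != config.p_xover_background:
            logger.warning("causal allele lost or fixed (freq %.2f)", final)
    return pop


def run_conditioned(config: SimulationConfig, max_attempts: int = 20) -> Population:
    """Evolve with fresh sub-seeds until the final hot-allele frequency
    lands in ``final_hot_freq_target +/- final_hot_freq_tol``.

    Returns the first accepted run (its attempt seed and the rejected
    attempts recorded in ``meta``); raises after ``max_attempts``.
    """
    lo = config.final_hot_freq_target - config.final_hot_freq_tol
    hi = config.final_hot_freq_target + config.final_hot_freq_tol
    attempts: list[tuple[int, float]] = []
    base = np.random.SeedSequence(config.seed)
    for attempt, child in enumerate(base.spawn(max_attempts)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        pop = initialize_population(config, seed=sub_seed)
        evolve(pop, config, rng=np.random.default_rng(sub_seed + 1))
        final = pop.freq_trace[-1]
        attempts.append((sub_seed, final))
        if lo <= final <= hi and final not in (0.0, 1.0):
            pop.meta.update(
                {"accepted_seed": sub_seed, "attempt": attempt, "attempts": attempts}
            )
            return pop
    raise ConditioningError(
        f"no run reached final frequency in [{lo:.2f}, {hi:.2f}] after "
        f"{max_attempts} attempts; (seed, final) pairs: {attempts}"
    )


def sample_panels(
    pop: Population,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[HaplotypePanel]:
    """Draw ``n_subsets`` benchmark panels of ``2 * subset_individuals``
    haplotypes each; individuals are sampled without replacement within a
    subset.  Monomorphic sites are retained (filtering is analysis-side);
    positions attach in kb."""
    if config.subset_individuals > pop.size:
        raise ValueError("subset larger than population")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 7)
    panels = []
    pos_kb = pop.positions_bp / 1000.0
    for s in range(config.n_subsets):
        inds = rng.choice(pop.size, size=config.subset_individuals, replace=False)
        rows = pop.haplotypes[inds].reshape(-1, pop.haplotypes.shape[2])
        labels = [f"s{s}_ind{i}_h{h}" for i in inds for h in (0, 1)]
        panels.append(
            HaplotypePanel(alleles=rows.copy(), positions=pos_kb, labels=labels, unit="kb")
        )
    return panels
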