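"""Genetic-algorithm parametrization of the membrane force field.

A genome is a real vector (the six force-field scalars, or the eight
cross-interaction LJ coefficients in mixed-resolution mode).  Selection
is fitness-proportionate roulette-wheel sampling, recombination is
single-point crossover, and mutation is adaptive Gaussian: an accepted
mutation adds sigma_gene * N(0, 1), where sigma_gene is the spread of
that gene across the previous generation.

The cost is the weighted sum of five squared relative deviations from
the point targets (weight 0.15 each) plus two Earth Mover's Distances
against reference distributions (weight 0.125 each); the weights sum to
one.  Genomes whose evaluation fails or returns non-finite properties
are flagged unfit and replaced by fresh random genomes next generation.

Note on selection: a literal fitness-proportionate rule applied to raw
costs would favor HIGH costs.  Fitness is therefore the decreasing
transform F = 1/(cost + delta), which realizes survival of the fittest
for a minimization problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .constants import kbt_to_kjmol
from .forcefield import ForceFieldParams
from .observables import Profile1D, PropertyReport, emd

__all__ = [
    "Genome",
    "Population",
    "TargetSpec",
    "CostReport",
    "GAConfig",
    "UNFIT_COST",
    "membrane_bounds",
    "geometric_repair",
    "init_population",
    "cost",
    "select_rws",
    "crossover_sp",
    "mutate_adaptive_gaussian",
    "step_generation",
    "run_evolution",
    "MembraneEvaluator",
    "genes_to_params",
]

UNFIT_COST = 1.0e9
FITNESS_DELTA = 1.0e-6

MEMBRANE_GENES = ("epsilon", "r_min", "r_shift_on", "r_cut", "k_bond", "k_angle")

#: geometric ordering constraint applies to these three genes when present
_GEOMETRIC = ("r_min", "r_shift_on", "r_cut")


def membrane_bounds(temperature: float = 315.0) -> dict[str, tuple[float, float]]:
    """Per-gene search bounds; epsilon bounds are 2-10 kB*T in kJ/mol."""
    return {
        "epsilon": (kbt_to_kjmol(2.0, temperature), kbt_to_kjmol(10.0, temperature)),
        "r_min": (0.7, 1.4),
        "r_shift_on": (1.2, 2.2),
        "r_cut": (1.8, 3.0),
        "k_bond": (500.0, 5000.0),
        "k_angle": (50.0, 1000.0),
    }


@dataclass
class Genome:
    genes: np.ndarray
    cost: float | None = None
    report: PropertyReport | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)

    @property
    def unfit(self) -> bool:
        return self.cost is not None and self.cost >= UNFIT_COST

    def copy(self) -> "Genome":
        return Genome(self.genes.copy(), self.cost, self.report)


@dataclass
class Population:
    genomes: list[Genome]
    generation: int = 0
    sigmas: np.ndarray | None = None
    gene_names: tuple[str, ...] = MEMBRANE_GENES
    bounds: np.ndarray | None = None  # (n_genes, 2)

    @property
    def size(self) -> int:
        return len(self.genomes)

    def costs(self) -> np.ndarray:
        return np.array(
            [g.cost if g.cost is not None else math.nan for g in self.genomes]
        )

    def best(self) -> Genome:
        costs = self.costs()
        return self.genomes[int(np.nanargmin(costs))]


@dataclass
class TargetSpec:
    """Point targets, acceptance bands, reference curves, and weights."""

    apl: float = 0.68               # nm^2
    ka: float = 230.0               # mN/m
    line_tension: float = 10.0      # pN
    kc: float = 12.0                # kBT
    ptt: float = 270.0              # K
    bands: dict = field(default_factory=lambda: {
        "apl": (0.55, 0.77),
        "ka": (180.0, 330.0),
        "line_tension": (6.5, 30.0),
        "kc": (8.0, 42.0),
        "ptt": (250.0, 315.0),
    })
    rdf_ref: Profile1D | None = None
    density_ref: Profile1D | None = None
    w_scalar: float = 0.15
    w_dist: float = 0.125

    def point_targets(self) -> dict[str, float]:
        return {"apl": self.apl, "ka": self.ka, "line_tension": self.line_tension,
                "kc": self.kc, "ptt": self.ptt}

    @classmethod
    def default(cls) -> "TargetSpec":
        from .fixtures import reference_density_profile, reference_rdf

        return cls(rdf_ref=reference_rdf(), density_ref=reference_density_profile())


@dataclass
class CostReport:
    terms: dict[str, float]
    cost1: float
    cost2: float

    @property
    def total(self) -> float:
        return self.cost1 + self.cost2


def cost(report: PropertyReport, targets: TargetSpec) -> CostReport:
    """Weighted-sum cost of one evaluated parameter set.

    Scalar term i: w1 * (sim_i/target_i - 1)^2; distribution term:
    w2 * EMD(normalized sim, normalized reference).  Properties the
    evaluation tier did not produce (NaN / None) are skipped, so partial
    tiers yield partial costs on the same scale.
    """
    terms: dict[str, float] = {}
    cost1 = 0.0
    sims = report.scalar_properties()
    for name, target in targets.point_targets().items():
        sim = sims[name]
        if sim is None or math.isnan(sim):
            continue
        if not math.isfinite(sim):
            return CostReport({name: UNFIT_COST}, UNFIT_COST, 0.0)
        term = targets.w_scalar * (sim / target - 1.0) ** 2
        terms[name] = term
        cost1 += term

    cost2 = 0.0
    for name, sim_profile, ref in (
        ("rdf", report.rdf, targets.rdf_ref),
        ("density", report.density, targets.density_ref),
    ):
        if sim_profile is None or ref is None:
            continue
        ref_on_grid = ref.resample(sim_profile.centers)
        term = targets.w_dist * emd(sim_profile, ref_on_grid)
        terms[name] = term
        cost2 += term
    return CostReport(terms, cost1, cost2)


# ---------------------------------------------------------------------------
# genome construction and repair
# ---------------------------------------------------------------------------

def geometric_repair(
    genes: np.ndarray,
    gene_names: Sequence[str],
    bounds: np.ndarray | None = None,
) -> np.ndarray:
    """Clip genes to bounds and restore the r_min < r1 < rc ordering.

    A violated ordering is repaired by sorting the three values into the
    three slots (the least disruptive fix that keeps the gene values).
    """
    genes = np.asarray(genes, dtype=float).copy()
    if bounds is not None:
        genes = np.clip(genes, bounds[:, 0], bounds[:, 1])
    idx = [gene_names.index(n) for n in _GEOMETRIC if n in gene_names]
    if len(idx) >= 2:
        vals = np.sort(genes[idx])
        # enforce strict ordering with a small margin
        for k in range(1, len(vals)):
            if vals[k] <= vals[k - 1]:
                vals[k] = vals[k - 1] + 1e-3
        genes[idx] = vals
    return genes


def genes_to_params(
    genes: np.ndarray,
    gene_names: Sequence[str] = MEMBRANE_GENES,
    base: ForceFieldParams | None = None,
) -> ForceFieldParams:
    """Build force-field parameters from a (possibly partial) gene vector."""
    base = base or ForceFieldParams.optimal()
    kwargs = {name: float(v) for name, v in zip(gene_names, genes)}
    full = {f: getattr(base, f) for f in MEMBRANE_GENES}
    full.update(kwargs)
    return ForceFieldParams(**full)


def init_population(
    size: int,
    bounds: dict[str, tuple[float, float]] | np.ndarray,
    seed: int = 0,
    gene_names: tuple[str, ...] = MEMBRANE_GENES,
) -> Population:
    """Uniform random population within bounds; deterministic per seed."""
    if size % 2 or size < 4:
        raise ValueError("population size must be even and at least 4")
    if isinstance(bounds, dict):
        b = np.array([bounds[n] for n in gene_names], dtype=float)
    else:
        b = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(seed)
    genomes = []
    for _ in range(size):
        raw = rng.uniform(b[:, 0], b[:, 1])
        genomes.append(Genome(geometric_repair(raw, gene_names, b)))
    return Population(genomes, generation=0, gene_names=gene_names, bounds=b)


# ---------------------------------------------------------------------------
# GA operators
# ---------------------------------------------------------------------------

def _rng_from(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def select_rws(pop: Population, n_select: int, seed) -> list[Genome]:
    """Roulette-wheel selection by cumulative-probability inversion.

    Selection probability P_i = F_i / sum F_j with F = 1/(cost + delta);
    a uniform draw u picks genome i with C_{i-1} < u <= C_i.
    """
    rng = _rng_from(seed)
    costs = pop.costs()
    if np.any(np.isnan(costs)):
        raise ValueError("population has unevaluated genomes")
    fitness = np.where(costs >= UNFIT_COST, 0.0, 1.0 / (costs + FITNESS_DELTA))
    total = fitness.sum()
    if total <= 0:
        raise ValueError("all genomes unfit: no selection possible")
    cum = np.cumsum(fitness / total)
    draws = rng.uniform(0.0, 1.0, n_select)
    picks = np.searchsorted(cum, draws, side="left")
    return [pop.genomes[int(i)].copy() for i in picks]


def crossover_sp(parent_a: Genome, parent_b: Genome, seed,
                 gene_names: Sequence[str] = MEMBRANE_GENES,
                 bounds: np.ndarray | None = None) -> tuple[Genome, Genome]:
    """Single-point crossover: swap the tails after a random cut point."""
    rng = _rng_from(seed)
    a, b = parent_a.genes, parent_b.genes
    if len(a) != len(b):
        raise ValueError("parent genomes differ in length")
    if len(a) < 2:
        raise ValueError("single-point crossover needs at least 2 genes")
    k = int(rng.integers(1, len(a)))
    child_a = np.concatenate([a[:k], b[k:]])
    child_b = np.concatenate([b[:k], a[k:]])
    return (
        Genome(geometric_repair(child_a, gene_names, bounds)),
        Genome(geometric_repair(child_b, gene_names, bounds)),
    )


def mutate_adaptive_gaussian(
    genome: Genome,
    sigmas: np.ndarray,
    pm: float,
    seed,
    gene_names: Sequence[str] = MEMBRANE_GENES,
    bounds: np.ndarray | None = None,
) -> Genome:
    """Per-gene Bernoulli(pm) trigger; accepted genes get sigma*N(0,1)."""
    if not (0.0 <= pm <= 1.0):
        raise ValueError("mutation probability must be in [0, 1]")
    rng = _rng_from(seed)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be non-negative")
    genes = genome.genes.copy()
    trigger = rng.uniform(0.0, 1.0, len(genes)) < pm
    noise = rng.standard_normal(len(genes))
    genes = np.where(trigger, genes + sigmas * noise, genes)
    return Genome(geometric_repair(genes, gene_names, bounds))


def _adaptive_sigmas(pop: Population, floor_frac: float = 0.01) -> np.ndarray:
    """Per-gene population spread, floored at 1% of the bound range."""
    mat = np.stack([g.genes for g in pop.genomes])
    sig = mat.std(axis=0)
    if pop.bounds is not None:
        sig = np.maximum(sig, floor_frac * (pop.bounds[:, 1] - pop.bounds[:, 0]))
    return sig


# ---------------------------------------------------------------------------
# generation loop
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    pop_size: int = 32
    pm: float = 0.1                  # per-gene mutation probability
    max_iters: int = 50
    threshold: float = 0.0           # stop when mean top-decile cost below this
    elitism: int = 0                 # number of best genomes copied unchanged
    seed: int = 0
    elite_fraction: float = 0.1      # "best genomes" share used for termination


def _evaluate(pop: Population, evaluator: Callable) -> None:
    for i, g in enumerate(pop.genomes):
        if g.cost is not None:
            continue
        try:
            result = evaluator(g.genes, pop.generation, i)
        except Exception:
            g.cost = UNFIT_COST
            continue
        if isinstance(result, tuple):
            g.cost, g.report = result
        else:
            g.cost = float(result)
        if g.cost is None or not math.isfinite(g.cost):
            g.cost = UNFIT_COST


def step_generation(
    pop: Population, evaluator: Callable, cfg: GAConfig
) -> Population:
    """Evaluate, select a mating pool, cross over, mutate, replace.

    Population size is invariant; unfit genomes are replaced by fresh
    uniform genomes; optional elitism carries the best genomes through
    unchanged.
    """
    _evaluate(pop, evaluator)
    rng = np.random.default_rng((cfg.seed, pop.generation))
    sigmas = pop.sigmas if pop.sigmas is not None else _adaptive_sigmas(pop)

    n_children = pop.size - cfg.elitism
    parents = select_rws(pop, n_children + (n_children % 2), rng)
    children: list[Genome] = []
    for i in range(0, len(parents), 2):
        ca, cb = crossover_sp(parents[i], parents[i + 1], rng,
                              pop.gene_names, pop.bounds)
        children.extend([ca, cb])
    children = children[:n_children]
    children = [
        mutate_adaptive_gaussian(c, sigmas, cfg.pm, rng, pop.gene_names, pop.bounds)
        for c in children
    ]

    elite = sorted(
        (g for g in pop.genomes if not g.unfit),
        key=lambda g: g.cost,
    )[: cfg.elitism]
    new_genomes = [g.copy() for g in elite] + children

    # replace any carried-over unfit genomes with fresh random ones
    if pop.bounds is not None:
        for i, g in enumerate(new_genomes):
            if g.unfit:
                raw = rng.uniform(pop.bounds[:, 0], pop.bounds[:, 1])
                new_genomes[i] = Genome(
                    geometric_repair(raw, pop.gene_names, pop.bounds)
                )

    return Population(
        genomes=new_genomes,
        generation=pop.generation + 1,
        sigmas=_adaptive_sigmas(pop),
        gene_names=pop.gene_names,
        bounds=pop.bounds,
    )


def run_evolution(
    cfg: GAConfig,
    evaluator: Callable,
    bounds: dict[str, tuple[float, float]] | np.ndarray | None = None,
    gene_names: tuple[str, ...] = MEMBRANE_GENES,
    initial: Population | None = None,
) -> list[dict]:
    """Full GA loop; returns per-generation history records.

    Terminates when the mean cost of the best `elite_fraction` of the
    population drops below `cfg.threshold`, or after `cfg.max_iters`
    generations.  History entries carry generation, best/mean cost, and
    the best genome, enough to checkpoint and resume deterministically.
    """
    if initial is not None:
        pop = initial
    else:
        if bounds is None:
            bounds = membrane_bounds()
        pop = init_population(cfg.pop_size, bounds, cfg.seed, gene_names)

    history: list[dict] = []
    for _ in range(cfg.max_iters):
        _evaluate(pop, evaluator)
        costs = pop.costs()
        fit = np.sort(costs[costs < UNFIT_COST])
        n_elite = max(1, int(math.ceil(cfg.elite_fraction * pop.size)))
        elite_mean = float(fit[:n_elite].mean()) if len(fit) else math.inf
        best = pop.best()
        history.append({
            "generation": pop.generation,
            "best_cost": float(best.cost),
            "mean_cost": float(np.mean(fit)) if len(fit) else math.inf,
            "elite_mean_cost": elite_mean,
            "best_genes": best.genes.copy(),
        })
        if elite_mean < cfg.threshold:
            break
        pop = step_generation(pop, evaluator, cfg)
    return history


# ---------------------------------------------------------------------------
# membrane evaluator with protocol tiers
# ---------------------------------------------------------------------------

#: simulation protocol per tier: (lipids per leaflet, equilibration steps,
#: production steps, properties computed)
TIERS = {
    "smoke": dict(n_per_leaflet=36, equil=800, prod=1500,
                  properties=("apl",)),
    "desk": dict(n_per_leaflet=64, equil=2000, prod=8000,
                 properties=("apl", "ka", "line_tension", "rdf", "density")),
    "paper": dict(n_per_leaflet=512, equil=40_000, prod=400_000,
                  properties=("apl", "ka", "line_tension", "kc", "ptt",
                              "rdf", "density")),
}


class MembraneEvaluator:
    """Scores a gene vector by simulating the membrane it parametrizes.

    Tiers trade cost for coverage: "smoke" measures only the area per
    lipid on a small patch, "desk" adds compressibility, line tension and
    the two distributions at moderate size, "paper" is the full
    seven-property protocol at publication scale (hours per genome).
    """

    def __init__(
        self,
        targets: TargetSpec | None = None,
        tier: str = "smoke",
        gene_names: tuple[str, ...] = MEMBRANE_GENES,
        temperature: float = 315.0,
        seed: int = 0,
    ) -> None:
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        self.targets = targets or TargetSpec.default()
        self.tier = tier
        self.gene_names = gene_names
        self.temperature = temperature
        self.seed = seed

    def __call__(self, genes, generation: int, index: int):
        report = self.evaluate_report(genes, base_seed=(self.seed, generation, index))
        c = cost(report, self.targets)
        return c.total, report

    def evaluate_report(self, genes, base_seed=(0,)) -> PropertyReport:
        from . import observables as obs
        from .engine import SimConfig, build_bilayer, build_ribbon, minimize, run_ld

        spec = TIERS[self.tier]
        ff = genes_to_params(np.asarray(genes, dtype=float), self.gene_names)
        report = PropertyReport(tier=self.tier)

        sys_ = build_bilayer(spec["n_per_leaflet"], ff=ff)
        sys_ = minimize(sys_, ff, max_steps=200)
        rng = np.random.default_rng((*base_seed, 1))
        sys_.thermalize(self.temperature, rng)
        equil_cfg = SimConfig(temperature=self.temperature, n_steps=spec["equil"],
                              seed=abs(hash((*base_seed, 2))) % 2**31,
                              report_interval=0)
        traj = run_ld(sys_, ff, equil_cfg)
        want_frames = any(p in spec["properties"] for p in ("rdf", "density", "kc"))
        prod_cfg = SimConfig(temperature=self.temperature, n_steps=spec["prod"],
                             seed=abs(hash((*base_seed, 3))) % 2**31,
                             report_interval=20,
                             traj_interval=spec["prod"] // 20 if want_frames else 0)
        traj = run_ld(traj.final_system, ff, prod_cfg)
        series = obs.BoxSeries.from_trajectory(traj)
        n_leaf = sys_.meta["n_per_leaflet"]
        apl, apl_err = obs.area_per_lipid(series, n_leaf)
        report.apl = apl
        report.errors["apl"] = apl_err

        if "ka" in spec["properties"]:
            ka, ka_err = obs.area_compressibility(series, self.temperature)
            report.ka = ka
            report.errors["ka"] = ka_err

        if want_frames and traj.snapshots:
            final = traj.final_system
            tail_mask = final.types == 1
            rdf_frames = [
                (pos[tail_mask], box)
                for pos, box in zip(traj.snapshots, traj.snapshot_boxes)
            ]
            report.rdf = obs.lateral_rdf(rdf_frames).normalize()
            head_mask = final.types == 0
            dens_frames = [
                (pos[head_mask], final.masses[head_mask], box)
                for pos, box in zip(traj.snapshots, traj.snapshot_boxes)
            ]
            report.density = obs.density_profile(dens_frames).normalize()

        if "kc" in spec["properties"]:
            grid = max(8, int(traj.final_system.box[0] // 1.0))
            fields = [
                obs.height_field(pos, box, grid)
                for pos, box in zip(traj.snapshots, traj.snapshot_boxes)
            ]
            spectrum = obs.undulation_spectrum(fields, float(traj.final_system.box[0]))
            kc, kc_err = obs.fit_bending_modulus(spectrum, self.temperature)
            report.kc = kc
            report.errors["kc"] = kc_err

        if "line_tension" in spec["properties"]:
            ribbon = build_ribbon(2 * spec["n_per_leaflet"], ff=ff)
            ribbon = minimize(ribbon, ff, max_steps=200)
            ribbon.thermalize(self.temperature, np.random.default_rng((*base_seed, 4)))
            rib_cfg = SimConfig(temperature=self.temperature, barostat="off",
                                n_steps=spec["equil"] + spec["prod"],
                                seed=abs(hash((*base_seed, 5))) % 2**31,
                                report_interval=20)
            rib_traj = run_ld(ribbon, ff, rib_cfg)
            skip = len(rib_traj.records) // 4
            lt, lt_err = obs.line_tension(
                rib_traj.pressures[skip:],
                float(ribbon.box[0]), float(ribbon.box[2]),
            )
            report.line_tension = lt
            report.errors["line_tension"] = lt_err

        if "ptt" in spec["properties"]:
            report.ptt = self._transition_scan(ff, base_seed)
        return report

    def _transition_scan(self, ff: ForceFieldParams, base_seed) -> float:
        """Coarse 20 K two-phase enthalpy scan (paper tier only)."""
        from . import observables as obs
        from .engine import SimConfig, build_two_phase, run_ld

        temps = np.arange(200.0, 341.0, 20.0)
        series = []
        for i, t in enumerate(temps):
            sys_ = build_two_phase(256, ff=ff, seed=abs(hash((*base_seed, 6, i))) % 2**31)
            cfg = SimConfig(temperature=float(t), n_steps=100_000,
                            seed=abs(hash((*base_seed, 7, i))) % 2**31,
                            report_interval=100)
            traj = run_ld(sys_, ff, cfg)
            series.append(traj.enthalpy())
        ptt, _ = obs.detect_transition(temps, series)
        return ptt if ptt is not None else math.nan
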