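"""Success-history adaptive differential evolution with linear population
size reduction (L-SHADE), plus a random-search baseline.

The engine maximizes a black-box objective over the unit box [0, 1]^N;
integer/categorical hyperparameters are handled by decoding genomes through
a :class:`~emgtune.space.HyperparamSpace`.

Per generation, for each parent x_i:

* a history cell k is drawn uniformly from the H-cell memory and the
  control parameters sampled as SF ~ Cauchy(M_SF[k], 0.1) (resampled while
  <= 0, clipped to 1) and CR ~ Normal(M_CR[k], 0.1) clipped to [0, 1];
* a trial is built by current-to-pbest/1 mutation with an external archive
  of replaced parents, binomial crossover with a guaranteed j_rand
  coordinate, and midpoint repair of out-of-box coordinates;
* a strictly improving trial records (SF, CR, |Δf|) as a success.

After the generation, each memory pair is updated toward the Δf-weighted
Lehmer mean of the successful values, blended with the old cell as
M_new = c * M_old + (1 - c) * mean_wl (c defaults to 0.5), and the
population shrinks linearly in consumed evaluations:

    NP = round((NP_min - NP_max) / NF_max * NF + NP_max)

eliminating the worst-fitness individuals (among ties, older index first).

RNG call order per individual (relied on by the degenerate-DE equivalence
test): memory index k; Cauchy draws for SF; normal draw for CR; pbest
index; r1 draws; r2 draws; j_rand; crossover mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import OptimizationError
from .features import FeatureMatrix
from .space import Candidate, HyperparamSpace

__all__ = [
    "LShadeConfig",
    "HistoryMemory",
    "SuccessArchive",
    "GenerationStats",
    "sample_parameters",
    "propose_trial",
    "weighted_lehmer_mean",
    "update_memory",
    "lpsr_size",
    "reduce_population",
    "optimize",
    "random_search",
    "tune",
]


@dataclass
class LShadeConfig:
    """L-SHADE budget and adaptation settings.

    ``nf_max`` caps objective evaluations (the LPSR schedule's clock);
    ``max_generations`` optionally caps generations as well.  When only a
    generation cap is given, ``nf_max`` defaults to
    ``np_init * max_generations``.
    """

    np_init: int = 100
    np_min: int = 4
    memory_size: int = 6
    blend_c: float = 0.5
    nf_max: int | None = None
    max_generations: int | None = None
    pbest_frac: float = 0.11
    archive_rate: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.np_min < 4:
            raise OptimizationError("np_min must be >= 4 (mutation needs 4 distinct members)")
        if self.np_init <= self.np_min:
            raise OptimizationError("np_init must exceed np_min")
        if self.memory_size < 1:
            raise OptimizationError("memory_size must be >= 1")
        if not 0 < self.blend_c <= 1:
            raise OptimizationError("blend_c must lie in (0, 1]")
        if not 0 < self.pbest_frac <= 1:
            raise OptimizationError("pbest_frac must lie in (0, 1]")
        if self.archive_rate < 0:
            raise OptimizationError("archive_rate must be >= 0")
        if self.nf_max is None:
            if self.max_generations is None:
                raise OptimizationError("set nf_max and/or max_generations")
            self.nf_max = self.np_init * self.max_generations
        if self.nf_max < self.np_init:
            raise OptimizationError("nf_max must cover at least the initial population")


class HistoryMemory:
    """The H success-history cells (M_SF, M_CR), all initialized at 0.5."""

    def __init__(self, size: int):
        self.m_sf = np.full(size, 0.5)
        self.m_cr = np.full(size, 0.5)
        self.write_index = 0

    @property
    def size(self) -> int:
        return self.m_sf.size

    def snapshot(self) -> tuple[list[float], list[float]]:
        return self.m_sf.tolist(), self.m_cr.tolist()


@dataclass
class SuccessArchive:
    """Per-generation successful (SF, CR) values with their fitness gains."""

    s_sf: list[float] = field(default_factory=list)
    s_cr: list[float] = field(default_factory=list)
    delta_f: list[float] = field(default_factory=list)

    def add(self, sf: float, cr: float, df: float) -> None:
        if not df > 0:
            raise OptimizationError("success entries require a strictly positive gain")
        self.s_sf.append(sf)
        self.s_cr.append(cr)
        self.delta_f.append(df)

    def __len__(self) -> int:
        return len(self.delta_f)

    @property
    def weights(self) -> np.ndarray:
        df = np.asarray(self.delta_f, dtype=float)
        return df / df.sum()


def sample_parameters(mem: HistoryMemory, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one (SF, CR) pair from a uniformly chosen memory cell."""
    k = int(rng.integers(mem.size))
    sf = 0.0
    while sf <= 0.0:
        sf = mem.m_sf[k] + 0.1 * rng.standard_cauchy()
    sf = min(sf, 1.0)
    cr = float(np.clip(rng.normal(mem.m_cr[k], 0.1), 0.0, 1.0))
    return float(sf), cr


def propose_trial(
    pop: np.ndarray,
    fitness: np.ndarray,
    i: int,
    sf: float,
    cr: float,
    pbest_pool: np.ndarray,
    archive: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """current-to-pbest/1 mutation + binomial crossover + midpoint repair.

    ``pbest_pool`` holds the population indices eligible as pbest; ``archive``
    is a (n_arch, D) array of replaced parents (r2 is drawn from population
    plus archive).
    """
    n, d = pop.shape
    if n < 4:
        raise OptimizationError("population must hold at least 4 individuals")
    x = pop[i]
    pb = pop[int(pbest_pool[rng.integers(pbest_pool.size)])]
    r1 = i
    while r1 == i:
        r1 = int(rng.integers(n))
    n_ext = n + archive.shape[0]
    r2 = i
    while r2 == i or r2 == r1:
        r2 = int(rng.integers(n_ext))
    x_r2 = pop[r2] if r2 < n else archive[r2 - n]
    v = x + sf * (pb - x) + sf * (pop[r1] - x_r2)
    # midpoint repair against the unit box
    low = v < 0.0
    high = v > 1.0
    v[low] = x[low] / 2.0
    v[high] = (x[high] + 1.0) / 2.0
    j_rand = int(rng.integers(d))
    mask = rng.random(d) < cr
    mask[j_rand] = True
    u = np.where(mask, v, x)
    return u


def weighted_lehmer_mean(arch: SuccessArchive, which: str = "SF") -> float:
    """Δf-weighted Lehmer mean Σ w S² / Σ w S of the successful values."""
    if len(arch) == 0:
        raise OptimizationError("success archive is empty")
    s = np.asarray(arch.s_sf if which.upper() == "SF" else arch.s_cr, dtype=float)
    w = arch.weights
    denom = float((w * s).sum())
    if denom == 0.0:
        return 0.0
    return float((w * s * s).sum() / denom)


def update_memory(mem: HistoryMemory, arch: SuccessArchive, c: float = 0.5) -> HistoryMemory:
    """Blend the cell at the cycling write index toward the Lehmer means.

    An empty archive leaves the memory (and the write index) untouched.
    """
    if not 0 < c <= 1:
        raise OptimizationError("blend parameter c must lie in (0, 1]")
    if len(arch) == 0:
        return mem
    k = mem.write_index
    mem.m_sf[k] = c * mem.m_sf[k] + (1 - c) * weighted_lehmer_mean(arch, "SF")
    mem.m_cr[k] = c * mem.m_cr[k] + (1 - c) * weighted_lehmer_mean(arch, "CR")
    mem.write_index = (k + 1) % mem.size
    return mem


def lpsr_size(cfg: LShadeConfig, nf: int) -> int:
    """Linear population-size schedule in consumed evaluations."""
    if not 0 <= nf <= cfg.nf_max:
        raise OptimizationError(f"nf={nf} outside [0, nf_max={cfg.nf_max}]")
    np_g = int(round((cfg.np_min - cfg.np_init) / cfg.nf_max * nf + cfg.np_init))
    return max(cfg.np_min, min(cfg.np_init, np_g))


def reduce_population(
    pop: np.ndarray, fitness: np.ndarray, new_np: int
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``new_np`` fittest members; among equal fitness the older
    (lower-index) member is eliminated first."""
    if not 0 < new_np <= pop.shape[0]:
        raise OptimizationError("new population size out of range")
    order = sorted(range(pop.shape[0]), key=lambda j: (-fitness[j], -j))
    keep_idx = np.sort(np.array(order[:new_np]))
    return pop[keep_idx], fitness[keep_idx]


@dataclass
class GenerationStats:
    generation: int
    nf: int
    np_size: int
    best_fitness: float
    m_sf: list[float]
    m_cr: list[float]


def _eval_objective(objective, cand: Candidate) -> float:
    value = objective(cand)
    if value is None or not math.isfinite(value):
        warnings.warn("objective returned non-finite value; treating candidate as worst")
        return -np.inf
    return float(value)


def optimize(
    objective,
    space: HyperparamSpace,
    cfg: LShadeConfig,
) -> tuple[Candidate, list[GenerationStats]]:
    """Run L-SHADE, maximizing ``objective(candidate)``.

    Returns the best candidate found and a per-generation trace (NP, NF,
    best fitness, memory snapshots).  The best-so-far sequence in the trace
    is non-decreasing and total evaluations never exceed ``cfg.nf_max``.
    """
    rng = np.random.default_rng(cfg.seed)
    d = space.n_dims
    pop = rng.random((cfg.np_init, d))
    fitness = np.empty(cfg.np_init)
    for i in range(cfg.np_init):
        fitness[i] = _eval_objective(objective, Candidate(pop[i].copy(), space.decode(pop[i])))
    nf = cfg.np_init
    mem = HistoryMemory(cfg.memory_size)
    archive = np.empty((0, d))
    best_i = int(np.argmax(fitness))
    best = Candidate(pop[best_i].copy(), space.decode(pop[best_i]), float(fitness[best_i]))
    trace: list[GenerationStats] = []
    gen = 0

    while nf < cfg.nf_max and (cfg.max_generations is None or gen < cfg.max_generations):
        gen += 1
        n = pop.shape[0]
        order = np.argsort(-fitness, kind="stable")  # best first
        pool = order[: max(2, int(math.ceil(cfg.pbest_frac * n)))]
        success = SuccessArchive()
        replaced_parents = []
        for i in range(n):
            if nf >= cfg.nf_max:
                break
            sf, cr = sample_parameters(mem, rng)
            u = propose_trial(pop, fitness, i, sf, cr, pool, archive, rng)
            cand = Candidate(u.copy(), space.decode(u))
            f_u = _eval_objective(objective, cand)
            nf += 1
            if f_u >= fitness[i]:
                if f_u > fitness[i]:
                    df = abs(f_u - fitness[i])
                    if math.isfinite(df):
                        success.add(sf, cr, df)
                    replaced_parents.append(pop[i].copy())
                pop[i] = u
                fitness[i] = f_u
            if f_u > best.fitness:
                best = Candidate(u.copy(), space.decode(u), f_u)

        update_memory(mem, success, cfg.blend_c)

        if cfg.archive_rate > 0 and replaced_parents:
            archive = np.vstack([archive, np.array(replaced_parents)])

        new_np = lpsr_size(cfg, nf)
        if new_np < pop.shape[0]:
            pop, fitness = reduce_population(pop, fitness, new_np)

        cap = int(round(cfg.archive_rate * pop.shape[0]))
        if archive.shape[0] > cap:
            sel = rng.choice(archive.shape[0], size=cap, replace=False)
            archive = archive[np.sort(sel)]

        m_sf, m_cr = mem.snapshot()
        trace.append(
            GenerationStats(
                generation=gen,
                nf=nf,
                np_size=pop.shape[0],
                best_fitness=best.fitness,
                m_sf=m_sf,
                m_cr=m_cr,
            )
        )
    return best, trace


def random_search(
    objective,
    space: HyperparamSpace,
    nf_max: int,
    seed: int = 0,
) -> tuple[Candidate, list[float]]:
    """Uniform random search at the same evaluation budget (baseline)."""
    rng = np.random.default_rng(seed)
    best: Candidate | None = None
    history: list[float] = []
    for _ in range(nf_max):
        g = rng.random(space.n_dims)
        cand = Candidate(g, space.decode(g))
        cand.fitness = _eval_objective(objective, cand)
        history.append(cand.fitness)
        if best is None or cand.fitness > best.fitness:
            best = cand
    return best, history


# ---------------------------------------------------------------------------
# hyperparameter tuning front-end
# ---------------------------------------------------------------------------

def _contiguous_cv_folds(m: FeatureMatrix, n_folds: int) -> list[np.ndarray]:
    """Per-class contiguous blocks -> n_folds validation index sets."""
    folds: list[list[np.ndarray]] = [[] for _ in range(n_folds)]
    for cls in m.classes:
        rows = np.flatnonzero(m.gesture == cls)
        if rows.size < n_folds:
            raise OptimizationError(
                f"class {cls!r} has {rows.size} rows; need >= {n_folds} for CV"
            )
        for f, chunk in enumerate(np.array_split(rows, n_folds)):
            folds[f].append(chunk)
    return [np.sort(np.concatenate(parts)) for parts in folds]


def cv_accuracy(
    train: FeatureMatrix, backend: str, hp: dict, seed: int = 0, n_folds: int = 3
) -> float:
    """Mean accuracy of contiguous-block cross-validation within train."""
    from .model_eval import evaluate, train_classifier

    folds = _contiguous_cv_folds(train, n_folds)
    accs = []
    all_idx = np.arange(train.n_rows)
    for val_idx in folds:
        fit_idx = np.setdiff1d(all_idx, val_idx)
        model = train_classifier(backend, hp, train.take(fit_idx), seed=seed)
        accs.append(evaluate(model, train.take(val_idx)).accuracy)
    return float(np.mean(accs))


def tune(
    train: FeatureMatrix,
    backend: str = "ET",
    space: HyperparamSpace | None = None,
    cfg: LShadeConfig | None = None,
    fitness_protocol: str = "cv3",
    test: FeatureMatrix | None = None,
) -> tuple[dict, list[dict]]:
    """L-SHADE hyperparameter tuning of a classifier backend.

    The default objective is 3-fold contiguous-block cross-validation
    accuracy within ``train`` (no leakage); ``fitness_protocol="holdout"``
    instead scores candidates directly on the supplied ``test`` matrix
    (faster, but the tuned score is then not an unbiased estimate).

    Returns the best decoded hyperparameters and the full evaluation
    history (one dict of hyperparameters + fitness per objective call).
    """
    from .space import default_et_space

    space = space or default_et_space(n_features=len(train.columns))
    cfg = cfg or LShadeConfig(np_init=20, max_generations=20)
    if fitness_protocol == "holdout":
        if test is None:
            raise OptimizationError("holdout protocol requires a test matrix")
    elif fitness_protocol != "cv3":
        raise OptimizationError(f"unknown fitness protocol {fitness_protocol!r}")

    history: list[dict] = []

    def objective(cand: Candidate) -> float:
        hp = cand.decoded
        if fitness_protocol == "cv3":
            acc = cv_accuracy(train, backend, hp, seed=cfg.seed)
        else:
            from .model_eval import evaluate, train_classifier

            model = train_classifier(backend, hp, train, seed=cfg.seed)
            acc = evaluate(model, test).accuracy
        history.append({**hp, "fitness": acc})
        return acc

    best, _trace = optimize(objective, space, cfg)
    return dict(best.decoded), history
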