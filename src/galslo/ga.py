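"""Genetic search over ECG lead subsets and segment lengths.

An individual is the 13-element chromosome ``C = [T_L, L_1..L_12]``: segment
length in seconds (1-9) plus a binary inclusion mask over the canonical
leads, at least one of which must be set. Fitness trades classification
quality against complexity:

    fitness = alpha * F1 + beta * Acc - gamma * T_L - sigma * sum(L_i)

with defaults alpha = beta = 1, gamma = 0.002, sigma = 0.01. Each generation
keeps the 50 fittest individuals as parents, adds 40 children from 20
crossover pairs and 10 mutants, restoring the population to 100. Crossover
exchanges genes atomically within anatomical lead groups — leads viewing the
same part of the heart travel together:

    {[T_L], [L1,L5], [L2,L3,L6], [L4], [L7,L8], [L9,L10], [L11,L12]}

with swap probabilities [0.8, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]. Mutation
resamples T_L among the other lengths with probability 0.8 and flips each
gene with probability 0.5. The search stops after 20 generations or when the
population maximum fitness is unchanged for three consecutive generations,
returning the best individual ever evaluated.

Evaluations are memoized per chromosome and seeded from a stable chromosome
hash, so fitness is reproducible and the stall rule compares exact values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .cache import FeatureCache
from .lam import HeadClassifier, LamMlpClassifier, MlpClassifier
from .metrics import confusion, macro_report
from .preprocess import LEAD_ORDER

__all__ = [
    "Chromosome",
    "FitnessConfig",
    "GaConfig",
    "EvaluatedIndividual",
    "fitness",
    "Evaluator",
    "init_population",
    "select_parents",
    "crossover",
    "mutate",
    "evolve",
    "exhaustive_search",
    "CROSSOVER_GROUPS",
]

#: Anatomical crossover groups as 1-based gene indices; None marks the T_L slot.
CROSSOVER_GROUPS: tuple[tuple[int, ...] | None, ...] = (
    None, (1, 5), (2, 3, 6), (4,), (7, 8), (9, 10), (11, 12))


@dataclass(frozen=True)
class Chromosome:
    T_L: int
    mask: tuple[int, ...]

    def __post_init__(self):
        if self.T_L not in range(1, 10):
            raise ValueError(f"T_L must be in 1..9, got {self.T_L}")
        mask = tuple(int(v) for v in self.mask)
        if len(mask) != 12 or any(v not in (0, 1) for v in mask):
            raise ValueError("mask must be 12 binary genes")
        if sum(mask) == 0:
            raise ValueError("at least one lead must be selected")
        object.__setattr__(self, "mask", mask)

    @property
    def n_leads(self) -> int:
        return sum(self.mask)

    @property
    def leads(self) -> tuple[int, ...]:
        """Selected 1-based lead indices, canonical order."""
        return tuple(i + 1 for i, v in enumerate(self.mask) if v)

    def decode(self) -> tuple[int, tuple[str, ...]]:
        """(segment length, selected lead symbols in canonical order)."""
        return self.T_L, tuple(LEAD_ORDER[i - 1] for i in self.leads)

    @classmethod
    def from_vector(cls, vec) -> "Chromosome":
        vec = [int(v) for v in vec]
        if len(vec) != 13:
            raise ValueError("chromosome vector must have 13 elements")
        return cls(T_L=vec[0], mask=tuple(vec[1:]))

    def to_vector(self) -> tuple[int, ...]:
        return (self.T_L, *self.mask)

    def __str__(self) -> str:
        return ",".join(str(v) for v in self.to_vector())


@dataclass(frozen=True)
class FitnessConfig:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.002
    sigma: float = 0.01

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.sigma) < 0:
            raise ValueError("fitness coefficients must be non-negative")


def fitness(f1: float, acc: float, c: Chromosome,
            cfg: FitnessConfig = FitnessConfig()) -> float:
    """alpha*F1 + beta*Acc - gamma*T_L - sigma*n_leads; F1, Acc in [0, 1]."""
    if not (0.0 <= f1 <= 1.0 and 0.0 <= acc <= 1.0):
        raise ValueError("f1 and acc must lie in [0, 1]")
    return (cfg.alpha * f1 + cfg.beta * acc
            - cfg.gamma * c.T_L - cfg.sigma * c.n_leads)


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 100
    max_generations: int = 20
    n_parents: int = 50
    n_crossover_pairs: int = 20
    n_mutants: int = 10
    stall_limit: int = 3
    group_swap_probs: tuple[float, ...] = (0.8, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
    tl_mutation_prob: float = 0.8
    gene_mutation_prob: float = 0.5
    lengths: tuple[int, ...] = tuple(range(1, 10))
    leads: tuple[int, ...] = tuple(range(1, 13))
    fixed_lead_count: int | None = None
    fixed_T_L: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_parents + 2 * self.n_crossover_pairs + self.n_mutants \
                != self.population_size:
            raise ValueError("parents + 2*pairs + mutants must equal population size")
        probs = (*self.group_swap_probs, self.tl_mutation_prob,
                 self.gene_mutation_prob)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.group_swap_probs) != len(CROSSOVER_GROUPS):
            raise ValueError("one swap probability per crossover group required")
        if not self.lengths or not self.leads:
            raise ValueError("search space must contain lengths and leads")
        if self.fixed_lead_count is not None and not (
                1 <= self.fixed_lead_count <= len(self.leads)):
            raise ValueError("fixed_lead_count out of range for the lead set")
        if self.fixed_T_L is not None and self.fixed_T_L not in self.lengths:
            raise ValueError("fixed_T_L must be one of the allowed lengths")

    @property
    def effective_lengths(self) -> tuple[int, ...]:
        return (self.fixed_T_L,) if self.fixed_T_L is not None else self.lengths


@dataclass(frozen=True)
class EvaluatedIndividual:
    chromosome: Chromosome
    fitness: float
    f1: float
    acc: float
    seed: int
    split: str = "val"


def _repair(mask: list[int], cfg: GaConfig, rng: np.random.Generator) -> tuple[int, ...]:
    """Force validity: nonzero mask, only allowed leads, fixed count if set."""
    allowed = [i - 1 for i in cfg.leads]
    for i in range(12):
        if i not in allowed:
            mask[i] = 0
    target = cfg.fixed_lead_count
    if target is None:
        if sum(mask) == 0:
            mask[allowed[rng.integers(len(allowed))]] = 1
        return tuple(mask)
    while sum(mask) > target:
        ones = [i for i in allowed if mask[i]]
        mask[ones[rng.integers(len(ones))]] = 0
    while sum(mask) < target:
        zeros = [i for i in allowed if not mask[i]]
        mask[zeros[rng.integers(len(zeros))]] = 1
    return tuple(mask)


def init_population(cfg: GaConfig,
                    rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Uniform initial population: T_L uniform over the allowed lengths,
    each allowed gene Bernoulli(0.5), invalid masks repaired."""
    rng = rng or np.random.default_rng(cfg.seed)
    lengths = cfg.effective_lengths
    population = []
    for _ in range(cfg.population_size):
        T_L = int(lengths[rng.integers(len(lengths))])
        mask = [0] * 12
        for lead in cfg.leads:
            mask[lead - 1] = int(rng.random() < 0.5)
        population.append(Chromosome(T_L=T_L, mask=_repair(mask, cfg, rng)))
    return population


def _selection_key(item: tuple[int, EvaluatedIndividual]):
    order, ev = item
    return (-ev.fitness, ev.chromosome.n_leads, ev.chromosome.T_L, order)


def select_parents(evaluated: list[EvaluatedIndividual],
                   n_parents: int) -> list[EvaluatedIndividual]:
    """Top individuals by fitness; ties broken toward fewer leads, then
    shorter segments, then insertion order."""
    ranked = sorted(enumerate(evaluated), key=_selection_key)
    return [ev for _, ev in ranked[:n_parents]]


def crossover(p1: Chromosome, p2: Chromosome, cfg: GaConfig,
              rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Group-wise exchange: each anatomical group swaps atomically with its
    configured probability, producing two complementary children."""
    t1, t2 = p1.T_L, p2.T_L
    m1, m2 = list(p1.mask), list(p2.mask)
    for group, prob in zip(CROSSOVER_GROUPS, cfg.group_swap_probs):
        if rng.random() >= prob:
            continue
        if group is None:
            t1, t2 = t2, t1
        else:
            for lead in group:
                i = lead - 1
                m1[i], m2[i] = m2[i], m1[i]
    if cfg.fixed_T_L is not None:
        t1 = t2 = cfg.fixed_T_L
    return (Chromosome(T_L=t1, mask=_repair(m1, cfg, rng)),
            Chromosome(T_L=t2, mask=_repair(m2, cfg, rng)))


def mutate(p: Chromosome, cfg: GaConfig, rng: np.random.Generator) -> Chromosome:
    """Elementwise mutation: T_L resampled among the other allowed lengths
    with probability 0.8, each allowed gene flipped with probability 0.5."""
    T_L = p.T_L
    lengths = cfg.effective_lengths
    if len(lengths) > 1 and rng.random() < cfg.tl_mutation_prob:
        others = [t for t in lengths if t != p.T_L]
        T_L = int(others[rng.integers(len(others))])
    mask = list(p.mask)
    for lead in cfg.leads:
        if rng.random() < cfg.gene_mutation_prob:
            mask[lead - 1] ^= 1
    return Chromosome(T_L=T_L, mask=_repair(mask, cfg, rng))


def _chromosome_seed(c: Chromosome, base_seed: int) -> int:
    payload = f"{base_seed}:{c}".encode()
    return zlib.crc32(payload) % (2 ** 31)


class Evaluator:
    """Memoized fitness evaluation of chromosomes on a feature cache.

    To keep the search honest, fitness is measured on a validation split
    carved inter-patient from the cache's training patients (20% of
    patients, fixed once per evaluator); the held-out test split is reserved
    for final reporting. Head training is seeded per chromosome from a
    stable hash combined with the evaluator seed, so results are
    reproducible and memoizable.
    """

    def __init__(self, cache: FeatureCache, head: str = "lam",
                 fitness_cfg: FitnessConfig = FitnessConfig(),
                 seed: int = 0, val_fraction: float = 0.2,
                 head_kwargs: dict | None = None):
        if head not in ("lam", "mlp"):
            raise ValueError("head must be 'lam' or 'mlp'")
        self.cache = cache
        self.head = head
        self.fitness_cfg = fitness_cfg
        self.seed = seed
        self.val_fraction = val_fraction
        self.head_kwargs = dict(head_kwargs or {})
        self._memo: dict[tuple[int, ...], EvaluatedIndividual] = {}
        self.n_trainings = 0
        rng = np.random.default_rng(seed)
        label_of: dict = {}
        for key in cache.keys():
            if key[2] != "train":
                continue
            _, labels, patients = cache.get(*key)
            label_of.update(zip(patients, labels))
        if not label_of:
            raise ValueError("feature cache has no training patients")
        # stratified carve-out: a fraction of each class's patients
        by_class: dict = {}
        for pid in sorted(label_of):
            by_class.setdefault(str(label_of[pid]), []).append(pid)
        self._val_patients = set()
        for lab in sorted(by_class):
            pids = by_class[lab]
            order = rng.permutation(len(pids))
            n_val = max(1, int(round(val_fraction * len(pids))))
            self._val_patients.update(pids[i] for i in order[:n_val])

    def _make_head(self, n_leads: int, seed: int) -> HeadClassifier:
        cls = LamMlpClassifier if self.head == "lam" else MlpClassifier
        kwargs = dict(self.head_kwargs)
        kwargs.setdefault("epochs", 30)
        return cls(n_leads=n_leads, width=self.cache.feature_width,
                   n_classes=len(self.cache.classes), seed=seed, **kwargs)

    def evaluate(self, c: Chromosome) -> EvaluatedIndividual:
        key = c.to_vector()
        if key in self._memo:
            return self._memo[key]
        X, labels, patients = self.cache.block(c.T_L, c.leads, "train")
        in_val = np.array([p in self._val_patients for p in patients])
        if in_val.all() or not in_val.any():
            raise ValueError("validation carve-out left an empty split")
        seed = _chromosome_seed(c, self.seed)
        head = self._make_head(c.n_leads, seed)
        head.fit(X[~in_val], labels[~in_val])
        self.n_trainings += 1
        pred = head.predict(X[in_val])
        f1, acc = _macro_scores(labels[in_val], pred, self.cache.classes)
        ev = EvaluatedIndividual(chromosome=c,
                                 fitness=fitness(f1, acc, c, self.fitness_cfg),
                                 f1=f1, acc=acc, seed=seed)
        self._memo[key] = ev
        return ev

    def final_report(self, c: Chromosome, head: str | None = None):
        """Retrain on the full training split and score the held-out test
        split; returns ``(MetricsReport, predictions, head)``."""
        X, labels, _ = self.cache.block(c.T_L, c.leads, "train")
        Xt, yt, _ = self.cache.block(c.T_L, c.leads, "test")
        orig = self.head
        if head is not None:
            self.head = head
        try:
            clf = self._make_head(c.n_leads, _chromosome_seed(c, self.seed))
        finally:
            self.head = orig
        clf.fit(X, labels)
        pred = clf.predict(Xt)
        report = macro_report(confusion(yt, pred, self.cache.classes))
        return report, pred, clf


def _macro_scores(y_true, y_pred, classes) -> tuple[float, float]:
    """(macro F1, overall accuracy) on the 0-1 scale used inside fitness."""
    cm = confusion(y_true, y_pred, classes)
    rep = macro_report(cm)
    acc = float(np.trace(cm.counts)) / cm.total
    return rep.macro["F1"] / 100.0, acc


def evolve(evaluator: Evaluator, cfg: GaConfig
           ) -> tuple[EvaluatedIndividual, list[dict]]:
    """Run the generational loop; returns the best individual ever
    evaluated plus a per-generation history log."""
    missing = [(lead, T_L) for T_L in cfg.effective_lengths for lead in cfg.leads
               if (lead, T_L, "train") not in evaluator.cache]
    if missing:
        raise ValueError(f"feature cache lacks entries for (lead, T_L): {missing[:6]}")
    rng = np.random.default_rng(cfg.seed)
    population = init_population(cfg, rng)
    best: EvaluatedIndividual | None = None
    history: list[dict] = []
    prev_max: float | None = None
    stall = 0
    for generation in range(cfg.max_generations + 1):
        evaluated = [evaluator.evaluate(c) for c in population]
        gen_max = max(ev.fitness for ev in evaluated)
        for ev in evaluated:
            if best is None or ev.fitness > best.fitness:
                best = ev
        history.append({
            "generation": generation,
            "population_size": len(population),
            "max_fitness": gen_max,
            "mean_fitness": float(np.mean([ev.fitness for ev in evaluated])),
            "best_chromosome": str(best.chromosome),
            "fitnesses": [ev.fitness for ev in evaluated],
        })
        if prev_max is not None and gen_max == prev_max:
            stall += 1
        else:
            stall = 0
        prev_max = gen_max
        if stall >= cfg.stall_limit or generation == cfg.max_generations:
            break
        parents = select_parents(evaluated, cfg.n_parents)
        next_pop = [ev.chromosome for ev in parents]
        for _ in range(cfg.n_crossover_pairs):
            i, j = rng.choice(cfg.n_parents, size=2, replace=False)
            c1, c2 = crossover(parents[i].chromosome, parents[j].chromosome,
                               cfg, rng)
            next_pop.extend([c1, c2])
        for _ in range(cfg.n_mutants):
            k = int(rng.integers(cfg.n_parents))
            next_pop.append(mutate(parents[k].chromosome, cfg, rng))
        population = next_pop
    assert best is not None
    return best, history


def enumerate_space(cfg: GaConfig) -> list[Chromosome]:
    """Every valid chromosome in the configured search space."""
    from itertools import product
    out = []
    for T_L in cfg.effective_lengths:
        for bits in product((0, 1), repeat=len(cfg.leads)):
            if sum(bits) == 0:
                continue
            if cfg.fixed_lead_count is not None and sum(bits) != cfg.fixed_lead_count:
                continue
            mask = [0] * 12
            for lead, b in zip(cfg.leads, bits):
                mask[lead - 1] = b
            out.append(Chromosome(T_L=int(T_L), mask=tuple(mask)))
    return out


def exhaustive_search(evaluator: Evaluator, cfg: GaConfig) -> EvaluatedIndividual:
    """Brute-force optimum over the whole space (oracle for small spaces)."""
    best = None
    for c in enumerate_space(cfg):
        ev = evaluator.evaluate(c)
        if best is None or ev.fitness > best.fitness or (
                ev.fitness == best.fitness
                and (c.n_leads, c.T_L) < (best.chromosome.n_leads, best.chromosome.T_L)):
            best = ev
    assert best is not None
    return best
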