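"""Evolutionary optimizer for multi-receptor peptide candidates.

Evolves a population of token sequences under the additive multi-objective
fitness

    F = H + P + Pmin + B + N + D

with H = number of receptors predicted active (p >= 0.5), P = mean predicted
probability, Pmin = minimum probability, B = biological plausibility,
N = novelty versus the training set and D = population diversity (each
component optionally weighted).  Operators: tournament selection (k = 3),
single-point crossover with independent cut points (80%), adaptive mutation
(10%, doubled when diversity collapses, capped at 30%; a 70/20/10 mix of
point, conservative and modified-residue events), elitism (top 10%), and
motif-preserving repair of invalid offspring.  Termination: generation cap,
fitness convergence (3-generation moving average of improvement < 0.1) or
diversity stagnation over 10 generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np

from . import design_scoring
from .design_scoring import (
    CONSERVATIVE_GROUPS,
    MotifSpec,
    PlausibilityResult,
    plausibility,
)
from .seqio import STANDARD_AA, TokenSeq

log = logging.getLogger(__name__)

AA_ORDER = sorted(STANDARD_AA)


class Predictor(Protocol):
    """Anything that maps sequences to per-receptor activation probabilities."""

    def predict_proba(self, seqs: Sequence[TokenSeq]) -> np.ndarray: ...


@dataclass(frozen=True)
class FitnessComponents:
    """The additive fitness terms for one candidate."""

    h_active: int        # receptors with p >= 0.5
    p_mean: float        # mean probability
    p_min: float         # minimum probability
    b_plaus: float       # plausibility total
    novelty: float
    diversity: float
    total: float


@dataclass
class GAConfig:
    pop_size: int = 100
    len_min: int = 25
    len_max: int = 35
    max_generations: int = 50
    tournament_k: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)
    elite_fraction: float = 0.1
    activity_threshold: float = 0.5
    convergence_eps: float = 0.1
    convergence_window: int = 3
    stagnation_window: int = 10
    stagnation_eps: float = 1e-3
    fitness_threshold: Optional[float] = None
    #: weights for (H, P, Pmin, B, N, D)
    fitness_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    low_diversity_threshold: float = 0.2
    mutation_rate_cap: float = 0.3
    init_max_attempts_factor: int = 100
    diversity_sample: int = 20
    seed: int = 0

    def __post_init__(self):
        for r in (self.crossover_rate, self.mutation_rate, self.elite_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if abs(sum(self.mutation_mix) - 1.0) > 1e-9:
            raise ValueError("mutation_mix must sum to 1")
        if self.len_min > self.len_max or self.len_min < 2:
            raise ValueError("invalid length bounds")


@dataclass
class Individual:
    seq: TokenSeq
    fitness: Optional[FitnessComponents] = None


@dataclass
class GAResult:
    best_seq: TokenSeq
    best_fitness: FitnessComponents
    population: list[Individual]
    generation_stats: list[dict]
    stop_reason: str
    seed: int


# ---------------------------------------------------------------------------
# fitness


def fitness(
    seq: TokenSeq,
    predictions: np.ndarray,
    plaus: PlausibilityResult,
    novelty: float,
    diversity: float,
    config: GAConfig,
) -> FitnessComponents:
    """Combine predicted activities and design scores into the additive fitness."""
    p = np.asarray(predictions, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    h = int((p >= config.activity_threshold).sum())
    comps = (h, float(p.mean()), float(p.min()), plaus.b_total, novelty, diversity)
    total = float(sum(w * c for w, c in zip(config.fitness_weights, comps)))
    return FitnessComponents(h, comps[1], comps[2], plaus.b_total,
                             novelty, diversity, total)


# ---------------------------------------------------------------------------
# operators


def _hormone_sampler(rng: np.random.Generator):
    comp = design_scoring.native_composition() + 0.01
    comp /= comp.sum()

    def draw(n: int) -> list[str]:
        return list(rng.choice(AA_ORDER, size=n, p=comp))

    return draw


def random_candidate(config: GAConfig, rng: np.random.Generator) -> TokenSeq:
    """A random sequence with residues drawn from the native-hormone composition."""
    draw = _hormone_sampler(rng)
    length = int(rng.integers(config.len_min, config.len_max + 1))
    return TokenSeq(tuple(draw(length)))


def initialize_population(
    config: GAConfig,
    rng: np.random.Generator,
    motif_specs: Optional[Sequence[MotifSpec]] = None,
    templates: Optional[Sequence[TokenSeq]] = None,
    template_mutation_rate: float = 0.4,
) -> list[Individual]:
    """Plausibility-filtered initial population of exactly pop_size.

    By default candidates are fully random draws from the native-hormone
    residue composition.  With ``templates``, candidates are point-mutated,
    length-adjusted template variants instead — the scaffold-anchored start
    the optimizer needs when de-novo assembly of discrete motifs is not the
    goal of the run.
    """
    draw = _hormone_sampler(rng)
    population: list[Individual] = []
    attempts = 0
    max_attempts = config.init_max_attempts_factor * config.pop_size
    while len(population) < config.pop_size:
        if attempts >= max_attempts:
            raise RuntimeError(
                "could not assemble a plausible initial population; "
                "consider seeding the run with template sequences")
        attempts += 1
        if templates is None:
            seq = random_candidate(config, rng)
        else:
            base = list(templates[int(rng.integers(len(templates)))].tokens)
            length = int(rng.integers(config.len_min, config.len_max + 1))
            if len(base) > length:
                base = base[:length]
            elif len(base) < length:
                base = base + draw(length - len(base))
            tokens = [draw(1)[0] if rng.random() < template_mutation_rate else t
                      for t in base]
            seq = TokenSeq(tuple(tokens))
        if plausibility(seq, motif_specs).pass_flag:
            population.append(Individual(seq=seq))
    return population


def tournament_select(
    population: Sequence[Individual], k: int, rng: np.random.Generator
) -> Individual:
    """Best of k members drawn without replacement; ties -> earliest index."""
    if len(population) < k:
        raise ValueError(f"population of {len(population)} smaller than k={k}")
    idx = rng.choice(len(population), size=k, replace=False)
    idx.sort()
    best = max(idx, key=lambda i: (population[i].fitness.total, -i))
    return population[best]


def crossover(
    parent_a: TokenSeq, parent_b: TokenSeq, rng: np.random.Generator
) -> tuple[TokenSeq, TokenSeq]:
    """Single-point crossover with independent cut points in each parent."""
    if len(parent_a) < 2 or len(parent_b) < 2:
        raise ValueError("parents must have length >= 2")
    ca = int(rng.integers(1, len(parent_a)))
    cb = int(rng.integers(1, len(parent_b)))
    child_a = TokenSeq(parent_a.tokens[:ca] + parent_b.tokens[cb:])
    child_b = TokenSeq(parent_b.tokens[:cb] + parent_a.tokens[ca:])
    return child_a, child_b


def draw_mutation_event(rng: np.random.Generator,
                        mix: tuple[float, float, float]) -> int:
    """Sample the event class: 0 = point, 1 = conservative, 2 = modified."""
    return int(rng.choice(3, p=mix))


def adaptive_mutation_rate(config: GAConfig, population_diversity: float) -> float:
    """Base rate, doubled (capped) when the population loses diversity."""
    rate = config.mutation_rate
    if population_diversity < config.low_diversity_threshold:
        rate = min(2 * rate, config.mutation_rate_cap)
    return rate


def mutate(
    seq: TokenSeq,
    config: GAConfig,
    population_diversity: float,
    rng: np.random.Generator,
) -> TokenSeq:
    """Adaptive mutation: one 70/20/10 point/conservative/modified event.

    The mutation probability doubles (capped) when mean population diversity
    drops below the low-diversity threshold.
    """
    rate = adaptive_mutation_rate(config, population_diversity)
    if rng.random() >= rate:
        return seq
    tokens = list(seq.tokens)
    event = draw_mutation_event(rng, config.mutation_mix)
    i = int(rng.integers(len(tokens)))
    if event == 0:  # point substitution to a random standard residue
        tokens[i] = AA_ORDER[int(rng.integers(len(AA_ORDER)))]
    elif event == 1:  # conservative substitution within the residue's class
        base = design_scoring._GROUP_OF.get(
            tokens[i] if len(tokens[i]) == 1 else None)
        if base is None:
            tokens[i] = AA_ORDER[int(rng.integers(len(AA_ORDER)))]
        else:
            choices = sorted(base)
            tokens[i] = choices[int(rng.integers(len(choices)))]
    else:  # modified residue: lipidated lysine or D-enantiomer
        lys_positions = [j for j, t in enumerate(tokens) if t == "K"]
        if lys_positions and rng.random() < 0.5:
            j = lys_positions[int(rng.integers(len(lys_positions)))]
            tokens[j] = "[K (yE-C16)]"
        elif len(tokens[i]) == 1:
            tokens[i] = f"[d{tokens[i]}]"
    return TokenSeq(tuple(tokens))


def repair(
    seq: TokenSeq,
    parents: tuple[Individual, Individual],
    config: GAConfig,
    motif_specs: Optional[Sequence[MotifSpec]] = None,
    rng: Optional[np.random.Generator] = None,
) -> TokenSeq:
    """Clamp offspring length and restore plausibility via motif anchors.

    Over-long offspring are trimmed at the C-terminus; short ones borrow the
    fitter parent's C-terminal tokens.  If plausibility still fails, up to
    five rounds re-instate motif anchor residues; as a last resort the fitter
    parent is returned unchanged.
    """
    specs = design_scoring.default_motifs() if motif_specs is None else list(motif_specs)
    fitter = max(parents, key=lambda ind: ind.fitness.total if ind.fitness else 0.0)
    tokens = list(seq.tokens)
    if len(tokens) > config.len_max:
        tokens = tokens[: config.len_max]
    elif len(tokens) < config.len_min:
        donor = fitter.seq.tokens
        need = config.len_min - len(tokens)
        tokens = tokens + list(donor[-need:])
        while len(tokens) < config.len_min:  # very short donor: pad with repeats
            tokens.append(donor[-1])
    candidate = TokenSeq(tuple(tokens))
    if plausibility(candidate, specs).pass_flag:
        return candidate
    rng = rng or np.random.default_rng(0)
    anchors = []
    for m in specs:
        anchors.extend(m.anchor_indices(len(tokens)))
    mismatched = [(i, r) for i, r in anchors if tokens[i] != r]
    order = rng.permutation(len(mismatched))
    for round_no in range(min(5, len(mismatched))):
        i, r = mismatched[order[round_no]]
        tokens[i] = r
        candidate = TokenSeq(tuple(tokens))
        if plausibility(candidate, specs).pass_flag:
            return candidate
    return fitter.seq


# ---------------------------------------------------------------------------
# convergence


def check_convergence(
    best_fitness_history: Sequence[float],
    diversity_history: Sequence[float],
    config: GAConfig,
) -> tuple[bool, str]:
    """Stop decision from the fitness and diversity trajectories."""
    g = len(best_fitness_history)
    if g >= config.max_generations:
        return True, "max_gen"
    if (config.fitness_threshold is not None and best_fitness_history
            and best_fitness_history[-1] >= config.fitness_threshold):
        return True, "fitness_threshold"
    w = config.convergence_window
    if g >= w + 1:
        improvements = np.diff(best_fitness_history[-(w + 1):])
        if float(np.mean(improvements)) < config.convergence_eps:
            return True, "converged"
    sw = config.stagnation_window
    if len(diversity_history) >= sw + 1:
        deltas = np.abs(np.diff(diversity_history[-(sw + 1):]))
        if np.all(deltas < config.stagnation_eps):
            return True, "stagnated"
    return False, ""


# ---------------------------------------------------------------------------
# main loop


def _score_population(
    population: list[Individual],
    predictor: Predictor,
    training_seqs: Sequence[TokenSeq],
    config: GAConfig,
    motif_specs: Optional[Sequence[MotifSpec]],
    rng: np.random.Generator,
) -> float:
    """Fill in fitness for newly created members; returns mean diversity.

    Fitness is evaluated once, when an individual enters the population;
    elites carry their score unchanged between generations, which is what
    makes the best-fitness trajectory non-decreasing (the diversity term is
    population-dependent, so re-scoring copies could lower it).
    """
    seqs = [ind.seq for ind in population]
    new_idx = [i for i, ind in enumerate(population) if ind.fitness is None]
    probs = predictor.predict_proba([seqs[i] for i in new_idx]) if new_idx else None
    diversities = []
    for rank, i in enumerate(new_idx):
        ind = population[i]
        others = seqs[:i] + seqs[i + 1:]
        d = design_scoring.diversity_score(ind.seq, others,
                                           max_sample=config.diversity_sample,
                                           rng=rng)
        ind.fitness = fitness(
            ind.seq, probs[rank], plausibility(ind.seq, motif_specs),
            design_scoring.novelty_score(ind.seq, training_seqs), d, config)
    for ind in population:
        diversities.append(ind.fitness.diversity)
    return float(np.mean(diversities))


def evolve(
    config: GAConfig,
    predictor: Predictor,
    training_seqs: Sequence[TokenSeq],
    motif_specs: Optional[Sequence[MotifSpec]] = None,
    initial_population: Optional[Sequence[TokenSeq]] = None,
) -> GAResult:
    """Run the full evolutionary loop and return the optimized population."""
    rng = np.random.default_rng(config.seed)
    if initial_population is not None:
        population = [Individual(seq=s) for s in initial_population]
        if len(population) != config.pop_size:
            raise ValueError("initial population size mismatch")
    else:
        population = initialize_population(config, rng, motif_specs)

    best_history: list[float] = []
    diversity_history: list[float] = []
    stats: list[dict] = []
    stop_reason = "max_gen"
    n_elite = max(1, int(config.elite_fraction * config.pop_size))

    generation = 0
    while True:
        mean_div = _score_population(population, predictor, training_seqs,
                                     config, motif_specs, rng)
        totals = np.array([ind.fitness.total for ind in population])
        best_history.append(float(totals.max()))
        diversity_history.append(mean_div)
        stats.append({
            "generation": generation,
            "best_fitness": float(totals.max()),
            "mean_fitness": float(totals.mean()),
            "std_fitness": float(totals.std()),
            "mean_diversity": mean_div,
            "n_triple_active": int(sum(ind.fitness.h_active == 3
                                       for ind in population)),
        })
        stop, reason = check_convergence(best_history, diversity_history, config)
        if stop:
            stop_reason = reason
            break

        order = np.argsort(-totals, kind="stable")
        elites = [population[i] for i in order[:n_elite]]
        next_pop: list[Individual] = [Individual(seq=e.seq, fitness=e.fitness)
                                      for e in elites]
        while len(next_pop) < config.pop_size:
            pa = tournament_select(population, config.tournament_k, rng)
            pb = tournament_select(population, config.tournament_k, rng)
            if rng.random() < config.crossover_rate:
                ca, cb = crossover(pa.seq, pb.seq, rng)
            else:
                ca, cb = pa.seq, pb.seq
            for child in (ca, cb):
                if len(next_pop) >= config.pop_size:
                    break
                child = mutate(child, config, mean_div, rng)
                child = repair(child, (pa, pb), config, motif_specs, rng)
                next_pop.append(Individual(seq=child))
        population = next_pop
        generation += 1

    best_idx = int(np.argmax([ind.fitness.total for ind in population]))
    log.info("GA stopped after generation %d (%s); best fitness %.3f",
             generation, stop_reason, population[best_idx].fitness.total)
    return GAResult(
        best_seq=population[best_idx].seq,
        best_fitness=population[best_idx].fitness,
        population=population,
        generation_stats=stats,
        stop_reason=stop_reason,
        seed=config.seed,
    )
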