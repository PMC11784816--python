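"""Quantum-inspired genetic algorithm over fixed-length bitstrings.

The optimizer maintains, for every population slot, a register of *qubits*:
amplitude pairs ``(alpha, beta)`` with ``alpha**2 + beta**2 = 1``, where
``beta**2`` is the probability that the corresponding binary gene is observed
as 1.  Each generation the registers are *observed* (collapsed to concrete
bitstrings), the bitstrings are scored by a user-supplied fitness function,
and every register is nudged toward the best individual found so far by a
2x2 trigonometric rotation gate applied gene-by-gene.  Elitism guarantees
the stored best fitness never decreases.

Amplitudes are stored as reals: the rotation dynamics never leave the real
plane, so complex amplitudes would carry no observable information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "QGAConfig",
    "QubitRegister",
    "Individual",
    "RunState",
    "initialize_register",
    "observe",
    "rotate_gene",
    "update_register",
    "quantum_mutate",
    "run",
    "QuantumGeneticAlgorithm",
]

_NORM_TOL = 1e-9


@dataclass
class QGAConfig:
    """Hyperparameters of a QGA run.

    Parameters
    ----------
    population_size : int
        Number of qubit registers (and observed individuals) per generation.
    max_generations : int
        Hard cap ``t_max`` on the number of update generations.
    mutation_rate : float
        Per-gene probability of an amplitude swap ``(alpha, beta) -> (beta,
        alpha)`` after each update; inverts the gene's bit probabilities.
    rotation_magnitude : float
        Magnitude (radians) of the rotation applied to a gene whose observed
        bit disagrees with the stored best individual.
    stall_patience : int or None
        Stop early after this many consecutive generations without an
        improvement of the best fitness.  ``None`` disables the check
        (equivalent to ``max_generations``).
    saturation : float
        Keep every gene's 1-probability ``beta**2`` inside
        ``[saturation, 1 - saturation]`` so no gene collapses irreversibly.
    seed : int
        Seed for the single PRNG driving observation and mutation.
    """

    population_size: int = 20
    max_generations: int = 50
    mutation_rate: float = 0.01
    rotation_magnitude: float = 0.05 * np.pi
    stall_patience: int | None = None
    saturation: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0.0 < self.rotation_magnitude <= np.pi / 2:
            raise ValueError("rotation_magnitude must lie in (0, pi/2]")
        if not 0.0 < self.saturation < 0.5:
            raise ValueError("saturation must lie in (0, 0.5)")
        if self.stall_patience is not None and self.stall_patience < 1:
            raise ValueError("stall_patience must be >= 1 or None")


@dataclass
class QubitRegister:
    """A length-``m`` vector of amplitude pairs ``(alpha_i, beta_i)``."""

    amplitudes: np.ndarray  # shape (m, 2)

    @property
    def m(self) -> int:
        return self.amplitudes.shape[0]

    def validate(self, tol: float = _NORM_TOL) -> None:
        norms = np.sum(self.amplitudes**2, axis=1)
        dev = np.max(np.abs(norms - 1.0))
        if dev > tol:
            raise ValueError(f"register violates normalization by {dev:.3e}")

    def bit_probabilities(self) -> np.ndarray:
        """Probability of observing 1 at each gene (``beta_i**2``)."""
        return self.amplitudes[:, 1] ** 2


@dataclass
class Individual:
    """An observed bitstring with its evaluated fitness."""

    bits: np.ndarray  # shape (m,), dtype int8
    fitness: float
    generation_born: int


@dataclass
class RunState:
    """Full record of a QGA run: registers, population, best, history."""

    generation: int
    registers: list[QubitRegister]
    population: list[Individual]
    best: Individual
    best_history: np.ndarray  # best-so-far fitness per generation
    mean_history: np.ndarray  # population mean fitness per generation
    config: QGAConfig
    n_evaluations: int = 0

    def to_record(self) -> dict:
        """JSON-serializable run record (config, seed, histories, best)."""
        cfg = dict(self.config.__dict__)
        cfg["stall_patience"] = cfg["stall_patience"]
        return {
            "config": cfg,
            "seed": self.config.seed,
            "generations": int(self.generation),
            "n_evaluations": int(self.n_evaluations),
            "best_fitness": float(self.best.fitness),
            "best_bits": "".join(str(int(b)) for b in self.best.bits),
            "best_history": [float(v) for v in self.best_history],
            "mean_history": [float(v) for v in self.mean_history],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_record(), **kwargs)


def initialize_register(m: int, seed: int | None = None) -> QubitRegister:
    """Uniform-superposition register: every gene has alpha = beta = 1/sqrt(2).

    The ``seed`` argument is accepted for interface symmetry; initialization
    is deterministic.
    """
    if m < 1:
        raise ValueError("gene count m must be >= 1")
    amp = np.full((m, 2), 1.0 / np.sqrt(2.0))
    return QubitRegister(amplitudes=amp)


def observe(register: QubitRegister, rng: np.random.Generator) -> np.ndarray:
    """Collapse a register to a bitstring: bit i is 1 with probability beta_i**2."""
    register.validate()
    p1 = register.bit_probabilities()
    return (rng.random(register.m) < p1).astype(np.int8)


def rotate_gene(pair: Sequence[float], dtheta: float) -> tuple[float, float]:
    """Apply the 2x2 rotation gate to one amplitude pair.

    ``alpha' = cos(dtheta) * alpha - sin(dtheta) * beta``
    ``beta'  = sin(dtheta) * alpha + cos(dtheta) * beta``

    Norm-preserving for any angle.
    """
    alpha, beta = float(pair[0]), float(pair[1])
    if abs(alpha * alpha + beta * beta - 1.0) > 1e-6:
        raise ValueError("amplitude pair is not normalized")
    c, s = np.cos(dtheta), np.sin(dtheta)
    return (c * alpha - s * beta, s * alpha + c * beta)


def _signed_angles(
    register: QubitRegister,
    bits: np.ndarray,
    best_bits: np.ndarray,
    magnitude: float,
    saturation: float,
) -> np.ndarray:
    """Per-gene signed rotation angles moving probability mass toward the best bits.

    Genes where the observed bit agrees with the best individual's bit get a
    zero angle.  Disagreeing genes rotate by ``magnitude`` toward the best
    bit, clamped so ``beta**2`` stays within ``[saturation, 1 - saturation]``.
    """
    amp = register.amplitudes
    # Current polar angle of each gene in the (alpha, beta) plane.
    phi = np.arctan2(amp[:, 1], amp[:, 0])
    phi_lo = np.arcsin(np.sqrt(saturation))  # beta**2 == saturation
    phi_hi = np.arcsin(np.sqrt(1.0 - saturation))  # beta**2 == 1 - saturation

    disagree = bits != best_bits
    toward_one = best_bits == 1
    dtheta = np.zeros(register.m)
    # Rotating by +angle moves phi -> phi + angle, raising beta**2 while
    # phi < pi/2; the clamp stops the move at the saturation bound.
    up = disagree & toward_one
    dn = disagree & ~toward_one
    dtheta[up] = np.minimum(magnitude, np.maximum(0.0, phi_hi - phi[up]))
    dtheta[dn] = -np.minimum(magnitude, np.maximum(0.0, phi[dn] - phi_lo))
    return dtheta


def update_register(
    register: QubitRegister,
    individual: Individual,
    best: Individual,
    config: QGAConfig,
) -> QubitRegister:
    """Rotate a register's genes toward the stored best individual.

    Rotations apply only where the observed individual disagrees with the
    best *and* does not beat it; an individual strictly fitter than the
    stored best leaves its register untouched (it will become the new best).
    """
    if individual.bits.shape != best.bits.shape or register.m != best.bits.shape[0]:
        raise ValueError("register, individual and best must share length m")
    if individual.fitness > best.fitness:
        return QubitRegister(amplitudes=register.amplitudes.copy())
    dtheta = _signed_angles(
        register,
        individual.bits,
        best.bits,
        config.rotation_magnitude,
        config.saturation,
    )
    c, s = np.cos(dtheta), np.sin(dtheta)
    a, b = register.amplitudes[:, 0], register.amplitudes[:, 1]
    out = np.column_stack((c * a - s * b, s * a + c * b))
    return QubitRegister(amplitudes=out)


def quantum_mutate(
    register: QubitRegister, rate: float, rng: np.random.Generator
) -> QubitRegister:
    """Amplitude-swap mutation: each gene flips (alpha, beta) with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    amp = register.amplitudes.copy()
    if rate > 0.0:
        flip = rng.random(register.m) < rate
        amp[flip] = amp[flip][:, ::-1]
    return QubitRegister(amplitudes=amp)


def _evaluate(
    fitness: Callable[[np.ndarray], float], bits: np.ndarray, generation: int
) -> Individual:
    value = float(fitness(bits))
    if not np.isfinite(value):
        bitstring = "".join(str(int(b)) for b in bits)
        raise RuntimeError(
            f"fitness returned non-finite value {value!r} for bitstring {bitstring}"
        )
    return Individual(bits=bits.copy(), fitness=value, generation_born=generation)


def run(
    fitness: Callable[[np.ndarray], float],
    m: int,
    config: QGAConfig | None = None,
) -> RunState:
    """Execute the full QGA loop and return the final :class:`RunState`.

    The loop follows the classical quantum-inspired EA skeleton: initialize
    registers in uniform superposition, observe and evaluate an initial
    population, store the best individual B, then repeat {observe from the
    previous registers, evaluate, rotate registers toward B, mutate, update
    B} until ``max_generations`` or the stall criterion fires.  Ties on
    fitness keep the earlier individual, so runs are fully deterministic
    given the seed.
    """
    config = config or QGAConfig()
    if m < 1:
        raise ValueError("gene count m must be >= 1")
    rng = np.random.default_rng(config.seed)

    registers = [initialize_register(m) for _ in range(config.population_size)]
    population = [
        _evaluate(fitness, observe(reg, rng), 0) for reg in registers
    ]
    n_evals = len(population)
    best = max(population, key=lambda ind: ind.fitness)
    # max() returns the first maximum, which is the tie-break we want.
    best_history = [best.fitness]
    mean_history = [float(np.mean([ind.fitness for ind in population]))]

    t = 0
    stall = 0
    patience = config.stall_patience
    while t < config.max_generations:
        t += 1
        bits_batch = [observe(reg, rng) for reg in registers]
        population = [_evaluate(fitness, bits, t) for bits in bits_batch]
        n_evals += len(population)
        registers = [
            update_register(reg, ind, best, config)
            for reg, ind in zip(registers, population)
        ]
        if config.mutation_rate > 0.0:
            registers = [
                quantum_mutate(reg, config.mutation_rate, rng) for reg in registers
            ]
        for reg in registers:
            reg.validate(_NORM_TOL)

        gen_best = max(population, key=lambda ind: ind.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
            stall = 0
        else:
            stall += 1
        best_history.append(best.fitness)
        mean_history.append(float(np.mean([ind.fitness for ind in population])))
        if patience is not None and stall >= patience:
            break

    return RunState(
        generation=t,
        registers=registers,
        population=population,
        best=best,
        best_history=np.asarray(best_history),
        mean_history=np.asarray(mean_history),
        config=config,
        n_evaluations=n_evals,
    )


class QuantumGeneticAlgorithm:
    """Thin object-oriented front end over :func:`run`.

    Mirrors the scikit-learn parameter idiom (constructor stores
    hyperparameters; ``optimize`` performs the work and sets trailing
    underscore attributes) so the optimizer composes naturally with the
    rest of the package.
    """

    def __init__(
        self,
        population_size: int = 20,
        max_generations: int = 50,
        mutation_rate: float = 0.01,
        rotation_magnitude: float = 0.05 * np.pi,
        stall_patience: int | None = None,
        saturation: float = 1e-4,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.max_generations = max_generations
        self.mutation_rate = mutation_rate
        self.rotation_magnitude = rotation_magnitude
        self.stall_patience = stall_patience
        self.saturation = saturation
        self.random_state = random_state

    def _config(self) -> QGAConfig:
        return QGAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            mutation_rate=self.mutation_rate,
            rotation_magnitude=self.rotation_magnitude,
            stall_patience=self.stall_patience,
            saturation=self.saturation,
            seed=self.random_state,
        )

    def optimize(self, fitness: Callable[[np.ndarray], float], m: int) -> RunState:
        state = run(fitness, m, self._config())
        self.state_ = state
        self.best_bits_ = state.best.bits.copy()
        self.best_fitness_ = state.best.fitness
        self.best_history_ = state.best_history.copy()
        return state
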