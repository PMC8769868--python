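"""Multiobjective binary cuckoo search for channel selection.

Cuckoo search keeps a population of N "nests" (candidate solutions).  Each
iteration:

1. **Global walk (Lévy flight).**  Every nest proposes a move
   x' = x + alpha * L(beta) ⊙ (x - x_best), where L(beta) is a heavy-tailed
   Lévy step drawn with Mantegna's algorithm; the incumbent best nest takes a
   pure alpha * L(beta) perturbation instead (its direction term vanishes).
   The proposal is binarized through a sigmoid transfer function, scored, and
   replaces a *randomly chosen* nest if it is strictly better.
2. **Local walk (abandonment).**  With per-coordinate probability p_a a
   coordinate is displaced along the difference of two other randomly chosen
   nests, x' = x + u ⊙ H(p_a - eps) ⊙ (x_j - x_k); the result replaces its own
   nest if strictly better (greedy).
3. **Elitism.**  The best-ever solution is re-inserted if both walks lost it,
   so the best-fitness trace never decreases.

Positions are continuous; the channel mask is obtained per coordinate by
setting bit = 1 iff a fresh uniform draw phi < sigma(s) = 1/(1+exp(-s)).
A compatibility flag flips the inequality for strict reproduction of the
inverted rule that appears in parts of the binary-metaheuristic literature.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special

from .features import FeatureTable
from .objective import ChannelMask, FitnessEvaluator, FitnessReport, ObjectiveConfig

__all__ = [
    "CSConfig",
    "Solution",
    "SelectionResult",
    "levy_step",
    "global_walk",
    "local_walk",
    "binarize",
    "init_population",
    "run",
]

POSITION_RANGE = (-1.0, 1.0)


@dataclass(frozen=True)
class CSConfig:
    """Cuckoo-search control parameters.

    Defaults follow the standard EEG-selection setup: 30 nests, 100
    iterations, abandonment probability p_a = 0.25, Lévy exponent beta = 1.5.
    The step scale alpha defaults to 1.0: positions live on the logit scale
    of the sigmoid transfer (unit scale), and a much smaller alpha makes the
    Lévy walk numerically inert relative to position magnitudes, collapsing
    the search into random mask sampling.
    """

    n_nests: int = 30
    max_iter: int = 100
    p_a: float = 0.25
    beta: float = 1.5
    alpha: float = 1.0
    seed: int = 0
    printed_transfer_rule: bool = False
    replacement: str = "random"  # "random" (classic) or "greedy" (per-index)

    def __post_init__(self) -> None:
        if self.n_nests < 2:
            raise ValueError("n_nests must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.p_a < 1.0:
            raise ValueError("p_a must be in (0, 1)")
        if not 1.0 < self.beta <= 2.0:
            raise ValueError("beta must be in (1, 2]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.replacement not in ("random", "greedy"):
            raise ValueError("replacement must be 'random' or 'greedy'")


@dataclass
class Solution:
    """One nest: continuous position, its binary mask and cached report."""

    position: np.ndarray
    mask: ChannelMask
    report: FitnessReport | None = None

    @property
    def fit(self) -> float:
        if self.report is None:
            raise ValueError("solution has not been evaluated")
        return self.report.fit


@dataclass
class SelectionResult:
    """Outcome of one optimizer run."""

    best_mask: ChannelMask
    best_report: FitnessReport
    trace: np.ndarray  # best-so-far fitness per iteration
    trace_acc: np.ndarray
    trace_len: np.ndarray
    n_evaluations: int
    config: dict
    seed: int

    def save(self, out_dir: str | Path, prefix: str = "run") -> None:
        """Write mask (1-based channel names), trace and metadata files."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{prefix}_mask.csv", "w") as fh:
            fh.write("channel,selected\n")
            for c, b in enumerate(self.best_mask.bits, start=1):
                fh.write(f"ch{c},{b}\n")
        with open(out_dir / f"{prefix}_trace.csv", "w") as fh:
            fh.write("iteration,best_fit,best_acc,best_len\n")
            for t in range(len(self.trace)):
                fh.write(
                    f"{t + 1},{self.trace[t]:.6f},{self.trace_acc[t]:.6f},"
                    f"{int(self.trace_len[t])}\n"
                )
        meta = dict(self.config)
        meta.update(
            seed=self.seed,
            n_evaluations=self.n_evaluations,
            best_fit=self.best_report.fit,
            best_acc=self.best_report.acc,
            best_len=self.best_report.n_selected,
        )
        with open(out_dir / f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def sigmoid(s: np.ndarray) -> np.ndarray:
    return special.expit(np.asarray(s, dtype=float))


def levy_step(beta: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric heavy-tailed Lévy steps via Mantegna's algorithm.

    step = u / |v|^(1/beta) with u ~ N(0, sigma_u^2), v ~ N(0, 1) and

        sigma_u = [ Gamma(1+beta) sin(pi beta / 2)
                    / (Gamma((1+beta)/2) beta 2^((beta-1)/2)) ]^(1/beta).
    """
    if not 1.0 < beta <= 2.0:
        raise ValueError(f"beta must be in (1, 2], got {beta}")
    sigma_u = (
        math.gamma(1.0 + beta)
        * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.standard_normal(size) * sigma_u
    v = rng.standard_normal(size)
    return u / np.abs(v) ** (1.0 / beta)


def global_walk(
    position: np.ndarray,
    best_position: np.ndarray,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    is_best: bool = False,
) -> np.ndarray:
    """Lévy-flight move toward (and beyond) the best nest.

    Non-best nests move by alpha * L(beta) ⊙ (x - x_best), so a nest sitting
    exactly on the best position does not move; the best nest itself takes a
    pure alpha * L(beta) perturbation to keep exploring.
    """
    position = np.asarray(position, dtype=float)
    best_position = np.asarray(best_position, dtype=float)
    if position.shape != best_position.shape:
        raise ValueError("position vectors must have equal length")
    step = levy_step(beta, position.size, rng)
    if is_best:
        return position + alpha * step
    return position + alpha * step * (position - best_position)


def local_walk(
    positions: np.ndarray, p_a: float, rng: np.random.Generator
) -> np.ndarray:
    """Abandonment walk: mix in the difference of two other random nests.

    Coordinate-wise: x_i += u * H(p_a - eps) * (x_j - x_k) with j != k != i,
    eps ~ U(0,1) and u ~ U(0,1) fresh per coordinate, H the Heaviside step.
    On average a fraction p_a of coordinates move.
    """
    positions = np.asarray(positions, dtype=float)
    n, d = positions.shape
    if n < 3:
        raise ValueError("local walk needs a population of at least 3 nests")
    new = positions.copy()
    for i in range(n):
        others = [x for x in range(n) if x != i]
        j, k = rng.choice(others, size=2, replace=False)
        eps = rng.uniform(size=d)
        scale = rng.uniform(size=d)
        gate = (eps < p_a).astype(float)
        new[i] = positions[i] + scale * gate * (positions[j] - positions[k])
    return new


def binarize(
    position: np.ndarray, rng: np.random.Generator, printed_rule: bool = False
) -> ChannelMask:
    """Sigmoid transfer binarization with empty-mask repair.

    bit_c = 1 iff phi_c < sigma(position_c), phi_c ~ U(0,1).  If no bit comes
    up, one uniformly chosen bit is set (an empty channel set cannot be
    scored).  ``printed_rule=True`` flips the inequality (bit = 1 iff
    phi > sigma), for compatibility with the inverted published form.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position contains non-finite coordinates")
    phi = rng.uniform(size=position.size)
    prob = sigmoid(position)
    bits = (phi > prob) if printed_rule else (phi < prob)
    bits = bits.astype(int)
    if bits.sum() == 0:
        bits[rng.integers(position.size)] = 1
    return ChannelMask(tuple(bits))


def init_population(
    n_nests: int,
    d: int,
    rng: np.random.Generator,
    printed_rule: bool = False,
) -> list[Solution]:
    """Uniformly random positions on the init range, binarized and repaired."""
    if n_nests < 2:
        raise ValueError("n_nests must be >= 2")
    if d < 1:
        raise ValueError("d must be >= 1")
    lo, hi = POSITION_RANGE
    sols = []
    for _ in range(n_nests):
        pos = rng.uniform(lo, hi, size=d)
        sols.append(Solution(position=pos, mask=binarize(pos, rng, printed_rule)))
    return sols


def run(
    features: FeatureTable,
    obj_config: ObjectiveConfig,
    cs_config: CSConfig,
    evaluator: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Run the binary cuckoo search over the channel-blocked feature table."""
    if evaluator is None:
        evaluator = FitnessEvaluator(features, obj_config)
    rng = np.random.default_rng(cs_config.seed)
    d = features.n_channels
    printed = cs_config.printed_transfer_rule

    pop = init_population(cs_config.n_nests, d, rng, printed)
    for sol in pop:
        sol.report = evaluator.evaluate(sol.mask)

    def best_index() -> int:
        return max(range(len(pop)), key=lambda i: pop[i].fit)

    bi = best_index()
    best_ever = Solution(pop[bi].position.copy(), pop[bi].mask, pop[bi].report)

    trace, trace_acc, trace_len = [], [], []
    n = cs_config.n_nests
    for _ in range(cs_config.max_iter):
        # global Lévy-flight walk
        bi = best_index()
        for i in range(n):
            new_pos = global_walk(
                pop[i].position,
                pop[bi].position,
                cs_config.alpha,
                cs_config.beta,
                rng,
                is_best=(i == bi),
            )
            mask = binarize(new_pos, rng, printed)
            report = evaluator.evaluate(mask)
            if cs_config.replacement == "random":
                j = int(rng.integers(n - 1))
                if j >= i:
                    j += 1
            else:
                j = i
            if report.fit > pop[j].fit:
                pop[j] = Solution(new_pos, mask, report)
                bi = best_index()

        # local abandonment walk
        positions = np.vstack([s.position for s in pop])
        new_positions = local_walk(positions, cs_config.p_a, rng)
        for i in range(n):
            mask = binarize(new_positions[i], rng, printed)
            report = evaluator.evaluate(mask)
            if report.fit > pop[i].fit:
                pop[i] = Solution(new_positions[i], mask, report)

        # elitism: keep the best-ever solution alive
        bi = best_index()
        if pop[bi].fit > best_ever.fit:
            best_ever = Solution(pop[bi].position.copy(), pop[bi].mask, pop[bi].report)
        else:
            wi = min(range(n), key=lambda i: pop[i].fit)
            if best_ever.fit > pop[bi].fit:
                pop[wi] = Solution(best_ever.position.copy(), best_ever.mask, best_ever.report)
        trace.append(best_ever.fit)
        trace_acc.append(best_ever.report.acc)
        trace_len.append(best_ever.report.n_selected)

    return SelectionResult(
        best_mask=best_ever.mask,
        best_report=best_ever.report,
        trace=np.asarray(trace),
        trace_acc=np.asarray(trace_acc),
        trace_len=np.asarray(trace_len),
        n_evaluations=evaluator.n_evaluations,
        config=dataclasses.asdict(cs_config),
        seed=cs_config.seed,
    )
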