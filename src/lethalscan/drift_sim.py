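"""Wright-Fisher allele-frequency simulation with viability selection.

The model is the classical Wright sampling scheme: each generation the
allele frequency is updated deterministically by viability selection and
then resampled as a binomial draw of ``two_N`` haploid copies. For a
recessive lethal (homozygote fitness 0, others 1) the post-selection
update has the closed form p* = p/(1+p), so the allele can never fix and
a drift-selection trade-off caps the frequency it can reach. The module
also covers the de-novo mutation arithmetic (mutations per individual and
per generation from genome size, mutation rate and replacement count) and
the persistence of new mutations entering at one copy in the census
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LETHAL_FITNESS = (0.0, 1.0, 1.0)
NEUTRAL_FITNESS = (1.0, 1.0, 1.0)


@dataclass
class DriftConfig:
    """Wright-Fisher simulation settings.

    ``two_N`` is the number of haploid draws per generation (300 = an
    effective population size of 150). ``fitness`` is the viability of
    (focal homozygote, heterozygote, other homozygote); the lethal
    parameterization is (0, 1, 1).
    """

    p0: float
    two_N: int = 300
    fitness: tuple[float, float, float] = LETHAL_FITNESS
    generations: int = 25
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p0 <= 1):
            raise ValueError("p0 must lie in [0, 1]")
        if self.two_N < 2:
            raise ValueError("two_N must be >= 2")
        w = self.fitness
        if len(w) != 3 or any(not (0 <= wi <= 1) for wi in w):
            raise ValueError("fitness values must lie in [0, 1]")
        if max(w) == 0:
            raise ValueError("fitness cannot be all zero")


@dataclass
class DriftResult:
    """Replicate trajectories and per-generation summaries."""

    trajectories: np.ndarray          # (replicates, generations+1)
    summaries: pd.DataFrame           # per-generation stats
    config: DriftConfig

    def __post_init__(self) -> None:
        t = self.trajectories
        if np.any((t < 0) | (t > 1)):
            raise ValueError("frequencies must lie in [0, 1]")


def post_selection_freq(p, fitness=LETHAL_FITNESS):
    """Expected focal-allele frequency after viability selection.

    Standard single-locus update: with focal allele A at frequency p and
    genotype fitnesses (w_AA, w_Aa, w_aa),

        p* = (p² w_AA + p(1-p) w_Aa) / (p² w_AA + 2p(1-p) w_Aa + (1-p)² w_aa)

    which reduces to p* = p/(1+p) for the recessive lethal (0, 1, 1).
    """
    p = np.asarray(p, dtype=float)
    w_aa_focal, w_het, w_other = fitness
    num = p * p * w_aa_focal + p * (1 - p) * w_het
    den = p * p * w_aa_focal + 2 * p * (1 - p) * w_het + (1 - p) ** 2 * w_other
    sing = den == 0
    if np.any(sing):
        # removable singularities at the boundaries: a lethal homozygote
        # class contributes nothing, so take the p -> boundary limit
        at_one = sing & (p == 1.0)
        at_zero = sing & (p == 0.0)
        if np.any(sing & ~at_one & ~at_zero):
            raise ZeroDivisionError("mean fitness is zero")
        if np.any(at_one):
            if w_het == 0:
                raise ZeroDivisionError("mean fitness is zero at fixation")
            num = np.where(at_one, 0.5, num)
            den = np.where(at_one, 1.0, den)
        if np.any(at_zero):
            if w_het == 0:
                raise ZeroDivisionError("mean fitness is zero at loss")
            num = np.where(at_zero, 0.5, num)
            den = np.where(at_zero, 1.0, den)
    out = num / den
    return float(out) if out.ndim == 0 else out


def wf_step(p, config: DriftConfig, rng: np.random.Generator):
    """One Wright-Fisher generation: binomial draw at the post-selection
    expected frequency."""
    p_star = post_selection_freq(p, config.fitness)
    draws = rng.binomial(config.two_N, p_star)
    out = draws / config.two_N
    return float(out) if np.ndim(out) == 0 else out


def _summaries(traj: np.ndarray) -> pd.DataFrame:
    lost = traj == 0.0
    fixed = traj == 1.0
    seg = ~(lost | fixed)
    return pd.DataFrame({
        "generation": np.arange(traj.shape[1]),
        "median": np.median(traj, axis=0),
        "q05": np.quantile(traj, 0.05, axis=0),
        "q95": np.quantile(traj, 0.95, axis=0),
        "mean": traj.mean(axis=0),
        "frac_segregating": seg.mean(axis=0),
        "frac_lost": lost.mean(axis=0),
        "frac_fixed": fixed.mean(axis=0),
    })


def simulate_trajectories(config: DriftConfig,
                          rng: np.random.Generator | None = None) -> DriftResult:
    """Simulate independent replicate allele-frequency trajectories."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    traj = np.empty((config.replicates, config.generations + 1))
    traj[:, 0] = config.p0
    p = np.full(config.replicates, config.p0)
    for g in range(1, config.generations + 1):
        p = wf_step(p, config, rng)
        traj[:, g] = p
    return DriftResult(traj, _summaries(traj), config)


def de_novo_persistence(config: DriftConfig, horizon: int,
                        rng: np.random.Generator | None = None) -> float:
    """Fraction of replicates still segregating (0 < p < 1) at ``horizon``."""
    if config.p0 <= 0:
        raise ValueError("de novo start frequency must be positive")
    if horizon == 0:
        return 1.0 if 0 < config.p0 < 1 else 0.0
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p = np.full(config.replicates, config.p0)
    for _ in range(horizon):
        p = wf_step(p, config, rng)
    return float(((p > 0) & (p < 1)).mean())


def de_novo_count(genome_size_bp: float, mu_per_bp: float,
                  n_replacements: int) -> tuple[int, int]:
    """De-novo mutation arithmetic.

    Per individual: round(genome size x per-bp mutation rate). Per
    generation: replacements entering the population x per-individual
    count.
    """
    if min(genome_size_bp, mu_per_bp, n_replacements) < 0:
        raise ValueError("inputs must be non-negative")
    per_individual = int(round(genome_size_bp * mu_per_bp))
    return per_individual, n_replacements * per_individual


def equilibrium_segregating(u_lethal: float, config: DriftConfig,
                            detection_freq: float = 0.01,
                            census_size: int = 2050,
                            generations: int = 400, burn_in: int = 200,
                            rng: np.random.Generator | None = None
                            ) -> tuple[float, float]:
    """Mutation-drift-selection balance for a class of lethal loci.

    Each generation Poisson(2 x census x u_lethal) new independent lethal
    loci enter at one copy in the census population (frequency
    1/(2 x census)); every active locus evolves by :func:`wf_step`. After
    burn-in, reports the time-averaged number of loci segregating at or
    above ``detection_freq`` and their mean frequency.
    """
    if u_lethal < 0:
        raise ValueError("u_lethal must be >= 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p = np.empty(0)
    counts, freqs = [], []
    p_new = 1.0 / (2 * census_size)
    for g in range(generations):
        n_new = rng.poisson(2 * census_size * u_lethal)
        p = np.concatenate([p, np.full(n_new, p_new)])
        if len(p):
            p = wf_step(p, config, rng)
            p = p[(p > 0) & (p < 1)]
        if g >= burn_in:
            above = p[p >= detection_freq]
            counts.append(len(above))
            freqs.append(above.mean() if len(above) else np.nan)
    mean_count = float(np.mean(counts)) if counts else 0.0
    finite = [f for f in freqs if np.isfinite(f)]
    mean_freq = float(np.mean(finite)) if finite else 0.0
    return mean_count, mean_freq
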