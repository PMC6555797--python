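"""Multi-generation allele-frequency dynamics of the killer-protector drive.

A gamete killer-protector element is an ultra-selfish locus: in
heterozygotes it aborts gametes that do not carry the protector, so the
driver allele is over-transmitted generation after generation.  This
module iterates the single-generation viability model over genotype-class
frequencies, either deterministically (infinite population) or with
finite-population multinomial sampling (a Wright-Fisher-style scheme).

Two mating systems are supported.  Under *selfing* (the default — the
study's F2 populations are selfed F1s) each individual unites its own
surviving gamete pools; under *random mating* all individuals shed their
surviving gametes into common male and female clouds which then unite at
random.  In both systems a genotype's contribution is weighted by its
viable gamete fraction: a semi-sterile plant sires and sets
proportionally fewer offspring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ConfigError,
    _canonical_pair,
    KillerProtectorSpec,
    Locus,
    SporophyteGenotype,
    cross_progeny,
    gamete_pool,
    pair_label,
)

__all__ = [
    "PopulationState",
    "Trajectory",
    "deterministic_step",
    "run_trajectory",
    "wright_fisher_sim",
]

MATING_SYSTEMS = ("selfing", "random_mating")

#: genotype-class key: per-locus canonical allele pair, ordered as loci
GenotypeKey = tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class PopulationState:
    """Genotype-class frequencies at one generation.

    ``freqs`` maps genotype keys (tuples of per-locus canonical allele
    pairs, in ``loci`` order) to frequencies summing to 1.  ``N`` is the
    census size in stochastic mode (None for the deterministic
    recursion).
    """

    generation: int
    loci: tuple[Locus, ...]
    freqs: tuple[tuple[GenotypeKey, float], ...]
    N: int | None = None

    @classmethod
    def monomorphic(
        cls, genotype: SporophyteGenotype, N: int | None = None
    ) -> "PopulationState":
        """Generation-0 state in which every individual has one genotype."""
        key = tuple(pair for _, pair in genotype.pairs)
        return cls(generation=0, loci=genotype.loci, freqs=((key, 1.0),), N=N)

    @property
    def freq_dict(self) -> dict[GenotypeKey, float]:
        return dict(self.freqs)

    def genotype(self, key: GenotypeKey) -> SporophyteGenotype:
        pairs = {l.name: pair for l, pair in zip(self.loci, key)}
        return SporophyteGenotype.from_pairs(self.loci, pairs)

    def allele_frequency(self, locus: str, allele: str) -> float:
        idx = next(
            (i for i, l in enumerate(self.loci) if l.name == locus), None
        )
        if idx is None:
            raise ConfigError(f"unknown locus {locus!r}")
        self.loci[idx].allele(allele)
        return sum(
            f * sum(1 for a in key[idx] if a == allele) / 2.0
            for key, f in self.freqs
        )

    def class_labels(self) -> dict[GenotypeKey, str]:
        return {
            key: " ".join(
                f"{l.name}:{pair_label(pair)}" for l, pair in zip(self.loci, key)
            )
            for key, _ in self.freqs
        }


@dataclass(frozen=True)
class Trajectory:
    states: tuple[PopulationState, ...]
    mating_system: str

    def frequencies(self, locus: str, allele: str) -> list[float]:
        return [s.allele_frequency(locus, allele) for s in self.states]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state in self.states:
            labels = state.class_labels()
            for key, f in state.freqs:
                rows.append(
                    {
                        "generation": state.generation,
                        "class": labels[key],
                        "frequency": f,
                    }
                )
        return pd.DataFrame(rows, columns=["generation", "class", "frequency"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_mating(mating_system: str) -> None:
    if mating_system not in MATING_SYSTEMS:
        raise ValueError(
            f"mating_system must be one of {MATING_SYSTEMS}, got {mating_system!r}"
        )


def _next_freqs(
    state: PopulationState, spec: KillerProtectorSpec, mating_system: str
) -> dict[GenotypeKey, float]:
    """Expected next-generation genotype-class frequencies."""
    _check_mating(mating_system)
    out: dict[GenotypeKey, float] = {}
    if mating_system == "selfing":
        # each parent selfs; offspring contribution proportional to its
        # female viable fraction (seed set)
        total = 0.0
        for key, f in state.freqs:
            if f == 0.0:
                continue
            parent = state.genotype(key)
            w = f * gamete_pool(parent, spec, "female").viable_fraction
            if w == 0.0:
                continue
            progeny = cross_progeny(parent, parent, spec)
            for pkey, p in progeny.probs:
                out[pkey] = out.get(pkey, 0.0) + w * p
            total += w
        if total == 0.0:
            raise ValueError("population produced no offspring (all sterile)")
        return {k: v / total for k, v in out.items()}

    # random mating: pooled gamete clouds, one per sex, weighted by each
    # genotype's frequency times its viable gamete fraction for that sex
    pools: dict[str, dict[tuple[str, ...], float]] = {}
    for sex in ("female", "male"):
        cloud: dict[tuple[str, ...], float] = {}
        for key, f in state.freqs:
            if f == 0.0:
                continue
            gp = gamete_pool(state.genotype(key), spec, sex)
            for g in gp.gametes:
                w = f * gp.viable_fraction * g.weight
                cloud[g.alleles] = cloud.get(g.alleles, 0.0) + w
        mass = sum(cloud.values())
        if mass == 0.0:
            raise ValueError("no viable gametes in the population")
        pools[sex] = {k: v / mass for k, v in cloud.items()}
    for egg, we in pools["female"].items():
        for sperm, wm in pools["male"].items():
            key = tuple(
                _canonical_pair((e, s)) for e, s in zip(egg, sperm)
            )
            out[key] = out.get(key, 0.0) + we * wm
    return out


def deterministic_step(
    state: PopulationState,
    spec: KillerProtectorSpec,
    mating_system: str = "selfing",
) -> PopulationState:
    """One infinite-population generation of the update rule."""
    freqs = _next_freqs(state, spec, mating_system)
    return PopulationState(
        generation=state.generation + 1,
        loci=state.loci,
        freqs=tuple(sorted(freqs.items())),
        N=state.N,
    )


def run_trajectory(
    initial: PopulationState,
    spec: KillerProtectorSpec,
    generations: int,
    mating_system: str = "selfing",
) -> Trajectory:
    """Iterate :func:`deterministic_step` for the requested generations."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    _check_mating(mating_system)
    states = [initial]
    for _ in range(generations):
        states.append(deterministic_step(states[-1], spec, mating_system))
    return Trajectory(states=tuple(states), mating_system=mating_system)


def wright_fisher_sim(
    initial: PopulationState,
    spec: KillerProtectorSpec,
    generations: int,
    N: int,
    seed: int,
    replicates: int = 1,
    mating_system: str = "selfing",
) -> list[Trajectory]:
    """Finite-population stochastic counterpart of :func:`run_trajectory`.

    Each generation, N individuals are sampled multinomially from the
    deterministic expectation given the current (empirical) state.
    Replicate r uses its own generator seeded with seed + r, so
    replicates are independent yet the whole set is reproducible.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    _check_mating(mating_system)
    out = []
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        state = PopulationState(
            generation=initial.generation,
            loci=initial.loci,
            freqs=initial.freqs,
            N=N,
        )
        states = [state]
        for _ in range(generations):
            expected = _next_freqs(states[-1], spec, mating_system)
            keys = sorted(expected)
            probs = np.array([expected[k] for k in keys], dtype=float)
            probs = probs / probs.sum()
            draws = rng.multinomial(N, probs)
            freqs = tuple(
                (k, c / N) for k, c in zip(keys, draws) if c > 0
            )
            states.append(
                PopulationState(
                    generation=states[-1].generation + 1,
                    loci=initial.loci,
                    freqs=freqs,
                    N=N,
                )
            )
        out.append(Trajectory(states=tuple(states), mating_system=mating_system))
    return out
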