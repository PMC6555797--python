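"""Core genetic model of the S1 gamete killer-protector system.

The S1 locus of African rice (*Oryza glaberrima*) carries three closely
linked genes (S1A4, S1TPR, S1A6) that together act as a selfish
killer-protector element in hybrids with Asian rice (*O. sativa*).  The
killer arms *sporophytically*: whenever the diploid parent plant carries
the full killer component set (by default {A4, TPR, A6}, possibly spread
across unlinked transgene loci), a sterility signal is produced.
Protection is *gametophytic*: a haploid gamete survives the signal only
if it itself carries the protector component set (by default {TPR});
unprotected gametes abort with a sex-specific probability.

This module represents alleles as named sets of functional components,
diploid genotypes over one or more independently assorting loci, and the
pipeline of computations: killer arming, gamete enumeration, viability
selection, fertility prediction, and cross (progeny distribution)
prediction.  Each linked gene block is one locus — there is no
recombination within an allele's component set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "NULL_ALLELE",
    "ConfigError",
    "Allele",
    "Locus",
    "KillerProtectorSpec",
    "SporophyteGenotype",
    "Gamete",
    "GameteDistribution",
    "ProgenyDistribution",
    "FertilityPrediction",
    "arm_killer",
    "enumerate_gametes",
    "apply_viability",
    "predict_fertility",
    "cross_progeny",
    "allele_frequency",
    "pair_label",
    "ModelConfig",
    "default_model",
    "load_model",
    "save_model",
]

#: Canonical name of a null (empty) allele, e.g. the absent transgene "-".
NULL_ALLELE = "-"

#: Canonical component identifiers of the native S1 system.
S1_COMPONENTS = ("A4", "TPR", "A6", "TP")


class ConfigError(ValueError):
    """Invalid model configuration (unknown allele, malformed catalog, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Allele:
    """A named allele: a set of functional component ids at one locus.

    The African S1-g allele is ``Allele("g", {"A4", "TPR", "A6"})``, the
    Asian S1-s allele is ``Allele("s", {"TP"})`` (S1TP is truncated by a
    premature stop codon and functionally inert), and a protector
    transgene insertion is ``Allele("T", {"TPR"})``.  The empty set is a
    valid component set (null transgene allele).
    """

    name: str
    components: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("allele name must be non-empty")
        object.__setattr__(self, "components", frozenset(self.components))


@dataclass(frozen=True)
class Locus:
    """One independently assorting linkage unit with its allele catalog."""

    name: str
    alleles: tuple[Allele, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ConfigError(f"locus {self.name!r} needs at least one allele")
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate allele names at locus {self.name!r}")
        object.__setattr__(self, "alleles", tuple(self.alleles))

    def allele(self, name: str) -> Allele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise ConfigError(f"unknown allele {name!r} at locus {self.name!r}")

    @property
    def allele_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.alleles)


@dataclass(frozen=True)
class KillerProtectorSpec:
    """Component requirements for arming and protection, plus abortion rates.

    Parameters
    ----------
    killer_components
        Components whose joint presence anywhere in the sporophyte arms
        the killer (default the tripartite set {A4, TPR, A6}).
    protector_components
        Components a gamete must itself carry to be protected
        (default {TPR}; protection is strictly gametophytic).
    abort_prob_male, abort_prob_female
        Probability that an unprotected gamete of the given sex aborts
        when the killer is armed.  1.0 reproduces the idealised
        "expected ratio" predictions; values < 1 model incomplete
        killing penetrance.
    """

    killer_components: frozenset[str] = frozenset({"A4", "TPR", "A6"})
    protector_components: frozenset[str] = frozenset({"TPR"})
    abort_prob_male: float = 1.0
    abort_prob_female: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "killer_components", frozenset(self.killer_components))
        object.__setattr__(
            self, "protector_components", frozenset(self.protector_components)
        )
        if not self.killer_components or not self.protector_components:
            raise ConfigError("killer and protector component sets must be non-empty")
        for label, p in (
            ("abort_prob_male", self.abort_prob_male),
            ("abort_prob_female", self.abort_prob_female),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{label} must be in [0, 1], got {p}")

    def abort_prob(self, sex: str) -> float:
        if sex == "male":
            return self.abort_prob_male
        if sex == "female":
            return self.abort_prob_female
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    def with_abort(self, k: float) -> "KillerProtectorSpec":
        """Copy of this spec with both sexes' abortion probability set to *k*."""
        return replace(self, abort_prob_male=k, abort_prob_female=k)


def pair_label(pair: Sequence[str]) -> str:
    """Canonical diploid class label: lexicographic, null allele last.

    ``("s", "g") -> "gs"``; ``("-", "T") -> "T-"`` (matching the field's
    "T–" hemizygote notation with an ASCII hyphen for the null allele).
    """
    a, b = sorted(pair, key=lambda x: (x == NULL_ALLELE, x))
    return a + b


def _canonical_pair(pair: Sequence[str]) -> tuple[str, str]:
    a, b = sorted(pair, key=lambda x: (x == NULL_ALLELE, x))
    return (a, b)


@dataclass(frozen=True)
class SporophyteGenotype:
    """Diploid genotype over one or more unlinked loci.

    ``pairs`` maps locus name to an (unordered) pair of allele names;
    the pair is canonicalised on construction, so genotype (a, b)
    equals genotype (b, a).
    """

    loci: tuple[Locus, ...]
    pairs: tuple[tuple[str, tuple[str, str]], ...]

    @classmethod
    def from_pairs(
        cls, loci: Sequence[Locus], pairs: Mapping[str, Sequence[str]]
    ) -> "SporophyteGenotype":
        by_name = {l.name: l for l in loci}
        if set(pairs) != set(by_name):
            raise ConfigError(
                f"genotype loci {sorted(pairs)} do not match locus definitions "
                f"{sorted(by_name)}"
            )
        canon = []
        for locus in loci:
            pair = tuple(pairs[locus.name])
            if len(pair) != 2:
                raise ConfigError(f"locus {locus.name!r}: a diploid pair is required")
            for name in pair:
                locus.allele(name)  # raises ConfigError if unknown
            canon.append((locus.name, _canonical_pair(pair)))
        return cls(loci=tuple(loci), pairs=tuple(canon))

    @property
    def pair_dict(self) -> dict[str, tuple[str, str]]:
        return dict(self.pairs)

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise ConfigError(f"unknown locus {name!r}")

    def component_union(self) -> frozenset[str]:
        """Union of components over both allele copies at every locus."""
        out: set[str] = set()
        for locus in self.loci:
            for allele_name in self.pair_dict[locus.name]:
                out |= locus.allele(allele_name).components
        return frozenset(out)

    def label(self) -> str:
        return " ".join(
            f"{name}:{pair_label(pair)}" for name, pair in self.pairs
        )


@dataclass(frozen=True)
class Gamete:
    """A haploid locus->allele assignment with a probability weight."""

    alleles: tuple[str, ...]  # ordered as the genotype's loci
    weight: float

    def components(self, loci: Sequence[Locus]) -> frozenset[str]:
        out: set[str] = set()
        for locus, name in zip(loci, self.alleles):
            out |= locus.allele(name).components
        return frozenset(out)


@dataclass(frozen=True)
class GameteDistribution:
    """Weighted gamete classes, before or after viability selection."""

    loci: tuple[Locus, ...]
    gametes: tuple[Gamete, ...]
    stage: str  # "pre_selection" | "post_selection"
    viable_fraction: float = 1.0

    def weight_of(self, alleles: Sequence[str]) -> float:
        key = tuple(alleles)
        for g in self.gametes:
            if g.alleles == key:
                return g.weight
        return 0.0

    def as_dict(self) -> dict[tuple[str, ...], float]:
        return {g.alleles: g.weight for g in self.gametes}


@dataclass(frozen=True)
class ProgenyDistribution:
    """Probability distribution over diploid genotype classes.

    Keys are tuples of canonical per-locus allele pairs, ordered as
    ``loci``.  ``marginal`` projects onto one locus's genotype classes
    with conventional labels ("gg", "gs", "T-", ...).
    """

    loci: tuple[Locus, ...]
    probs: tuple[tuple[tuple[tuple[str, str], ...], float], ...]

    def as_dict(self) -> dict[tuple[tuple[str, str], ...], float]:
        return dict(self.probs)

    def marginal(self, locus: str) -> dict[str, float]:
        idx = self._locus_index(locus)
        out: dict[str, float] = {}
        for key, p in self.probs:
            label = pair_label(key[idx])
            out[label] = out.get(label, 0.0) + p
        return out

    def _locus_index(self, locus: str) -> int:
        for i, l in enumerate(self.loci):
            if l.name == locus:
                return i
        raise ConfigError(f"unknown locus {locus!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (locus, class, probability)."""
        rows = []
        for locus in self.loci:
            for label, p in sorted(self.marginal(locus.name).items()):
                rows.append({"locus": locus.name, "class": label, "probability": p})
        return pd.DataFrame(rows, columns=["locus", "class", "probability"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FertilityPrediction:
    """Viable gamete fractions per sex.

    Spikelet fertility is taken to equal the female viable fraction
    (pollen assumed in excess), matching the convention that pollen and
    spikelet semi-sterility co-occur in S1 hybrids.
    """

    pollen_fertility: float
    female_fertility: float

    @property
    def spikelet_fertility(self) -> float:
        return self.female_fertility

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"quantity": "pollen_fertility", "value": self.pollen_fertility},
                {"quantity": "female_fertility", "value": self.female_fertility},
                {"quantity": "spikelet_fertility", "value": self.spikelet_fertility},
            ]
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def arm_killer(genotype: SporophyteGenotype, spec: KillerProtectorSpec) -> bool:
    """Is the sterility signal produced in this sporophyte?

    The killer arms iff the union of components over *all* alleles at
    *all* loci of the diploid plant contains the killer component set.
    Trans-complementation across unlinked loci is deliberate: three
    hemizygous transgenes spread over two insertion sites arm the killer
    just as the native linked S1-g block does.
    """
    return spec.killer_components <= genotype.component_union()


def enumerate_gametes(genotype: SporophyteGenotype) -> GameteDistribution:
    """All gamete classes under independent assortment, 1/2 per allele per locus.

    Identical gamete classes (same allele name at every locus, e.g. from
    a homozygous locus) are merged.  Weights sum to 1.
    """
    per_locus = [genotype.pair_dict[l.name] for l in genotype.loci]
    n_combos = 2 ** len(genotype.loci)
    merged: dict[tuple[str, ...], float] = {}
    for combo in product(*per_locus):
        merged[combo] = merged.get(combo, 0.0) + 1.0 / n_combos
    gametes = tuple(Gamete(k, w) for k, w in merged.items())
    return GameteDistribution(genotype.loci, gametes, stage="pre_selection")


def apply_viability(
    gametes: GameteDistribution,
    killer_armed: bool,
    spec: KillerProtectorSpec,
    sex: str,
) -> GameteDistribution:
    """Apply gametophytic viability selection to a pre-selection pool.

    If the killer is not armed the pool is returned unchanged
    (viable_fraction 1).  If armed, gametes whose own component union
    contains the protector set keep full weight; every other gamete
    keeps weight * (1 - abort_prob) for the given sex.  Weights are
    renormalised and the surviving mass recorded as viable_fraction.
    """
    if gametes.stage != "pre_selection":
        raise ValueError("apply_viability expects a pre_selection distribution")
    k = spec.abort_prob(sex)  # validates sex
    if not killer_armed:
        return GameteDistribution(
            gametes.loci, gametes.gametes, "post_selection", viable_fraction=1.0
        )
    surviving: list[tuple[tuple[str, ...], float]] = []
    for g in gametes.gametes:
        protected = spec.protector_components <= g.components(gametes.loci)
        w = g.weight if protected else g.weight * (1.0 - k)
        if w > 0.0:
            surviving.append((g.alleles, w))
    viable = sum(w for _, w in surviving)
    if viable == 0.0:
        raise ValueError("no viable gametes: every gamete class fully aborted")
    out = tuple(Gamete(a, w / viable) for a, w in surviving)
    return GameteDistribution(gametes.loci, out, "post_selection", viable_fraction=viable)


def gamete_pool(
    genotype: SporophyteGenotype, spec: KillerProtectorSpec, sex: str
) -> GameteDistribution:
    """Post-selection gamete pool of one parent: enumerate, arm, select."""
    armed = arm_killer(genotype, spec)
    return apply_viability(enumerate_gametes(genotype), armed, spec, sex)


def predict_fertility(
    genotype: SporophyteGenotype, spec: KillerProtectorSpec
) -> FertilityPrediction:
    """Pollen and female (spikelet) fertility = viable gamete fraction per sex."""
    male = gamete_pool(genotype, spec, "male")
    female = gamete_pool(genotype, spec, "female")
    return FertilityPrediction(
        pollen_fertility=male.viable_fraction,
        female_fertility=female.viable_fraction,
    )


def cross_progeny(
    mother: SporophyteGenotype,
    father: SporophyteGenotype,
    spec: KillerProtectorSpec,
) -> ProgenyDistribution:
    """Progeny genotype distribution: random union of surviving gamete pools.

    The mother contributes her post-selection female pool, the father
    his post-selection male pool; each diploid class's probability is
    the sum over ordered gamete pairs producing it.  Selfing is
    ``cross_progeny(g, g, spec)``.
    """
    if [l.name for l in mother.loci] != [l.name for l in father.loci]:
        raise ConfigError("mother and father must share the same locus definitions")
    eggs = gamete_pool(mother, spec, "female")
    sperm = gamete_pool(father, spec, "male")
    probs: dict[tuple[tuple[str, str], ...], float] = {}
    for egg in eggs.gametes:
        for sp in sperm.gametes:
            key = tuple(
                _canonical_pair((e, s)) for e, s in zip(egg.alleles, sp.alleles)
            )
            probs[key] = probs.get(key, 0.0) + egg.weight * sp.weight
    return ProgenyDistribution(mother.loci, tuple(sorted(probs.items())))


def allele_frequency(dist: ProgenyDistribution, locus: str, allele: str) -> float:
    """Frequency of *allele* at *locus*: sum of dosage/2 over genotype classes."""
    locus_def = next((l for l in dist.loci if l.name == locus), None)
    if locus_def is None:
        raise ConfigError(f"unknown locus {locus!r}")
    locus_def.allele(allele)  # raises if unknown
    idx = dist._locus_index(locus)
    freq = 0.0
    for key, p in dist.probs:
        dosage = sum(1 for a in key[idx] if a == allele)
        freq += p * dosage / 2.0
    return freq


# ---------------------------------------------------------------------------
# Model configuration I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """A complete model document: loci, killer/protector spec, named genotypes."""

    loci: tuple[Locus, ...]
    spec: KillerProtectorSpec
    genotypes: tuple[tuple[str, tuple[tuple[str, tuple[str, str]], ...]], ...] = ()

    def genotype(self, name: str, loci: Iterable[str] | None = None) -> SporophyteGenotype:
        """Instantiate a named genotype, optionally restricted to a locus subset.

        Restriction drops loci at which the genotype is homozygous null,
        which is how a design such as "S1 heterozygote without the
        transgene" coexists with transgenic designs in one document.
        """
        for gname, pairs in self.genotypes:
            if gname == name:
                pair_map = dict(pairs)
                names = list(loci) if loci is not None else [
                    l.name for l in self.loci if l.name in pair_map
                ]
                use = [l for l in self.loci if l.name in names]
                return SporophyteGenotype.from_pairs(
                    use, {n: pair_map[n] for n in names}
                )
        raise ConfigError(f"unknown genotype {name!r}")

    def to_dict(self) -> dict:
        return {
            "loci": {
                l.name: {a.name: sorted(a.components) for a in l.alleles}
                for l in self.loci
            },
            "spec": {
                "killer_components": sorted(self.spec.killer_components),
                "protector_components": sorted(self.spec.protector_components),
                "abort_prob_male": self.spec.abort_prob_male,
                "abort_prob_female": self.spec.abort_prob_female,
            },
            "genotypes": {
                name: {locus: list(pair) for locus, pair in pairs}
                for name, pairs in self.genotypes
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelConfig":
        try:
            loci = tuple(
                Locus(
                    name,
                    tuple(
                        Allele(a, frozenset(comps)) for a, comps in alleles.items()
                    ),
                )
                for name, alleles in doc["loci"].items()
            )
            s = doc.get("spec", {})
            spec = KillerProtectorSpec(
                killer_components=frozenset(s.get("killer_components", {"A4", "TPR", "A6"})),
                protector_components=frozenset(s.get("protector_components", {"TPR"})),
                abort_prob_male=float(s.get("abort_prob_male", 1.0)),
                abort_prob_female=float(s.get("abort_prob_female", 1.0)),
            )
        except (KeyError, TypeError, AttributeError) as exc:
            raise ConfigError(f"malformed model document: {exc}") from exc
        genotypes = tuple(
            (
                name,
                tuple(
                    (locus, _canonical_pair(pair)) for locus, pair in pairs.items()
                ),
            )
            for name, pairs in doc.get("genotypes", {}).items()
        )
        cfg = cls(loci=loci, spec=spec, genotypes=genotypes)
        # validate every named genotype against the catalogs
        by_name = {l.name: l for l in loci}
        for name, pairs in genotypes:
            for locus, pair in pairs:
                if locus not in by_name:
                    raise ConfigError(f"genotype {name!r}: unknown locus {locus!r}")
                for a in pair:
                    by_name[locus].allele(a)
        return cfg


def load_model(path) -> ModelConfig:
    """Read a model document from YAML (.yml/.yaml) or JSON (.json)."""
    text = open(path).read()
    if str(path).endswith(".json"):
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return ModelConfig.from_dict(doc)


def save_model(cfg: ModelConfig, path) -> None:
    doc = cfg.to_dict()
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(doc, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(doc, fh, sort_keys=True)


def default_model() -> ModelConfig:
    """The S1 system with the genotypes used throughout the study designs.

    Loci
    ----
    S1
        Native locus.  ``g`` = S1-g {A4, TPR, A6}; ``s`` = S1-s {TP};
        ``gm`` = killer-knockout S1-g^m lacking TPR {A4, A6};
        ``gm4`` = S1A4-knockout {TPR, A6}.
    TPRt
        Unlinked protector transgene insertion: ``T`` = {TPR}, ``-`` empty.
    A4A6t
        Unlinked linked-pair transgene insertion: ``46`` = {A4, A6},
        ``-`` empty.
    """
    doc = {
        "loci": {
            "S1": {
                "g": ["A4", "TPR", "A6"],
                "s": ["TP"],
                "gm": ["A4", "A6"],
                "gm4": ["TPR", "A6"],
            },
            "TPRt": {"T": ["TPR"], NULL_ALLELE: []},
            "A4A6t": {"46": ["A4", "A6"], NULL_ALLELE: []},
        },
        "spec": {
            "killer_components": ["A4", "TPR", "A6"],
            "protector_components": ["TPR"],
            "abort_prob_male": 1.0,
            "abort_prob_female": 1.0,
        },
        "genotypes": {
            # F1 of TPR^t line x NIL-g: S1 het + hemizygous protector
            "f1_protected": {"S1": ["g", "s"], "TPRt": ["T", NULL_ALLELE]},
            # F1 of RP-s x NIL-g: S1 het, no transgene
            "f1_plain": {"S1": ["g", "s"]},
            # S1 het, homozygous protector
            "f1_TT": {"S1": ["g", "s"], "TPRt": ["T", "T"]},
            # F1 of A4-A6^t x TPR^t: triple-hemizygous transgenic, ss background
            "f1_transgenic": {
                "S1": ["s", "s"],
                "A4A6t": ["46", NULL_ALLELE],
                "TPRt": ["T", NULL_ALLELE],
            },
            # F1 of TPR^t (homozygous) x s1tpr knockout: dual-role design
            "f1_knockout": {"S1": ["gm", "s"], "TPRt": ["T", NULL_ALLELE]},
        },
    }
    return ModelConfig.from_dict(doc)
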