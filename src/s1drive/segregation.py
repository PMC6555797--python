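"""Segregation analysis: goodness-of-fit, distortion, and killing efficiency.

Observed genotype-class counts from a cross progeny are compared against
the killer-protector model's expected class probabilities with a Pearson
chi-square goodness-of-fit test (no continuity correction, single planned
tests).  Transmission ratio distortion is summarised as an allele
frequency with a Wilson 95% interval.  The abortion probability k — the
penetrance of gamete killing — is estimated by maximising the multinomial
likelihood of the observed counts over k in [0, 1], with a
profile-likelihood 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .model import (
    ConfigError,
    KillerProtectorSpec,
    SporophyteGenotype,
    cross_progeny,
)

__all__ = [
    "ObservedCounts",
    "GofResult",
    "KillingEstimate",
    "CrossDesign",
    "ModelContradictionError",
    "NonIdentifiableError",
    "expected_class_probs",
    "chi_square_gof",
    "transmission_ratio",
    "estimate_killing_efficiency",
    "estimate_k_from_fertility",
    "read_counts_tsv",
    "write_counts_tsv",
]


class ModelContradictionError(ValueError):
    """Observed counts in a class the model assigns zero probability."""


class NonIdentifiableError(ValueError):
    """Class probabilities do not depend on the abortion probability."""


@dataclass(frozen=True)
class ObservedCounts:
    """Genotype-class counts at one locus from a scored progeny."""

    locus: str
    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, locus: str, counts: Mapping[str, int]) -> "ObservedCounts":
        for cls_label, c in counts.items():
            if c < 0 or c != int(c):
                raise ValueError(f"count for class {cls_label!r} must be a non-negative integer")
        if sum(counts.values()) <= 0:
            raise ValueError("total count must be positive")
        return cls(locus, tuple((k, int(v)) for k, v in counts.items()))

    @property
    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def n(self) -> int:
        return sum(c for _, c in self.counts)


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float
    expected_counts: tuple[tuple[str, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"class": k, "expected": e}
                for k, e in self.expected_counts
            ]
        ).assign(statistic=self.statistic, df=self.df, p_value=self.p_value)

    def __str__(self) -> str:  # human-readable log line
        return (
            f"chi-square GOF: X2 = {self.statistic:.4g}, df = {self.df}, "
            f"P = {self.p_value:.4g}"
        )


@dataclass(frozen=True)
class KillingEstimate:
    """Maximum-likelihood abortion probability with profile 95% CI."""

    k_hat: float
    log_likelihood: float
    ci_95: tuple[float, float]

    def __str__(self) -> str:
        lo, hi = self.ci_95
        return f"k_hat = {self.k_hat:.4f} (95% CI {lo:.4f}-{hi:.4f})"


@dataclass(frozen=True)
class CrossDesign:
    """A cross whose class probabilities at one locus are a function of k.

    ``pooling`` optionally maps an observed category to the model
    classes it lumps together, for scoring schemes that cannot resolve
    every genotype (e.g. a dominant marker scores carriers "T_" =
    TT + T-, or only the homozygote fraction "TT" vs "not_TT" is
    reported).  Model classes not covered by any pool keep their own
    label.
    """

    mother: SporophyteGenotype
    father: SporophyteGenotype
    spec: KillerProtectorSpec
    locus: str
    pooling: tuple[tuple[str, tuple[str, ...]], ...] = ()

    @classmethod
    def with_pooling(
        cls,
        mother: SporophyteGenotype,
        father: SporophyteGenotype,
        spec: KillerProtectorSpec,
        locus: str,
        pooling: Mapping[str, Sequence[str]],
    ) -> "CrossDesign":
        return cls(
            mother, father, spec, locus,
            tuple((k, tuple(v)) for k, v in pooling.items()),
        )

    def class_probs(self, k: float | None = None) -> dict[str, float]:
        spec = self.spec if k is None else self.spec.with_abort(k)
        probs = expected_class_probs(self.mother, self.father, spec, self.locus)
        if not self.pooling:
            return probs
        pooled: dict[str, float] = {}
        used: set[str] = set()
        for label, members in self.pooling:
            pooled[label] = sum(probs.get(m, 0.0) for m in members)
            used.update(members)
        for label, p in probs.items():
            if label not in used:
                pooled[label] = pooled.get(label, 0.0) + p
        return pooled


def expected_class_probs(
    mother: SporophyteGenotype,
    father: SporophyteGenotype,
    spec: KillerProtectorSpec,
    locus: str,
) -> dict[str, float]:
    """Model-expected genotype-class probabilities at one locus of a cross."""
    return cross_progeny(mother, father, spec).marginal(locus)


def chi_square_gof(
    observed: ObservedCounts, expected_probs: Mapping[str, float]
) -> GofResult:
    """Pearson chi-square goodness-of-fit of counts against model probabilities.

    Classes with expected probability 0 and observed count 0 are dropped
    before computing degrees of freedom; an observed count > 0 in a
    zero-probability class contradicts the model outright (rather than
    inflating the statistic to infinity) and raises
    :class:`ModelContradictionError` — the usual remedy is to fit k < 1.
    """
    obs = observed.as_dict
    classes = list(dict.fromkeys(list(expected_probs) + list(obs)))
    n = observed.n
    kept: list[tuple[str, int, float]] = []
    for c in classes:
        e_prob = float(expected_probs.get(c, 0.0))
        o = int(obs.get(c, 0))
        if e_prob <= 0.0:
            if o > 0:
                raise ModelContradictionError(
                    f"class {c!r} observed {o} times but has expected probability 0 "
                    "under this model"
                )
            continue
        kept.append((c, o, e_prob * n))
    if not kept:
        raise ValueError("no classes with positive expected probability")
    o_arr = np.array([o for _, o, _ in kept], dtype=float)
    e_arr = np.array([e for _, _, e in kept], dtype=float)
    statistic = float(np.sum((o_arr - e_arr) ** 2 / e_arr))
    df = len(kept) - 1
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return GofResult(
        statistic=statistic,
        df=df,
        p_value=p,
        expected_counts=tuple((c, e) for c, _, e in kept),
    )


def _dosage(label: str, allele: str) -> int:
    """Copies of *allele* in a concatenated diploid class label.

    Labels are the canonical pair labels produced by the model ("gg",
    "gs", "TT", "T-", "--").  The label is split as allele+rest, with
    the homozygous case checked first so multi-character allele names
    (e.g. "46") parse correctly.
    """
    if label == allele + allele:
        return 2
    if label.startswith(allele) or label.endswith(allele):
        return 1
    return 0


def transmission_ratio(
    observed: ObservedCounts,
    allele: str,
    dosage: Mapping[str, int] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Observed allele frequency with a Wilson 95% binomial interval.

    Frequency = sum(dosage * count) / (2n), treating the 2n transmitted
    allele copies as Bernoulli trials.  Dosage per class is parsed from
    the pair label unless an explicit ``dosage`` map is given.
    """
    copies = 0
    for label, count in observed.counts:
        d = dosage[label] if dosage is not None else _dosage(label, allele)
        if not 0 <= d <= 2:
            raise ValueError(f"dosage for class {label!r} must be 0, 1 or 2")
        copies += d * count
    trials = 2 * observed.n
    freq = copies / trials
    lo, hi = proportion_confint(copies, trials, alpha=0.05, method="wilson")
    return freq, (float(lo), float(hi))


def _log_likelihood(counts: dict[str, int], probs: Mapping[str, float]) -> float:
    ll = 0.0
    for c, o in counts.items():
        if o == 0:
            continue
        p = float(probs.get(c, 0.0))
        if p <= 0.0:
            return -np.inf
        ll += o * np.log(p)
    return ll


def estimate_killing_efficiency(
    observed: ObservedCounts,
    design: CrossDesign,
    conf_level: float = 0.95,
) -> KillingEstimate:
    """ML estimate of the abortion probability k from observed segregation.

    Maximises the multinomial log-likelihood of the observed class
    counts over k in [0, 1] (Brent's method, tolerance 1e-8,
    deterministic), with the boundary values compared explicitly so a
    boundary maximum (e.g. complete killing) is found exactly.  The 95%
    interval is the profile-likelihood set {k : 2*(ll(k_hat) - ll(k))
    <= chi2_{1,0.95}}, clipped to [0, 1].

    Raises :class:`NonIdentifiableError` if the class probabilities do
    not vary with k under the given design.
    """
    counts = observed.as_dict

    def probe(k: float) -> tuple[tuple[str, float], ...]:
        return tuple(sorted(design.class_probs(k).items()))

    ref = probe(0.0)
    if all(
        np.allclose([p for _, p in probe(k)], [p for _, p in ref], atol=1e-9)
        and [c for c, _ in probe(k)] == [c for c, _ in ref]
        for k in (0.5, 1.0)
    ):
        raise NonIdentifiableError(
            "class probabilities at this locus do not depend on the abortion "
            "probability under this cross design"
        )

    def ll(k: float) -> float:
        return _log_likelihood(counts, design.class_probs(k))

    res = optimize.minimize_scalar(
        lambda k: -ll(k), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(ll(0.0), 0.0), (ll(1.0), 1.0)]
    if np.isfinite(res.fun):
        candidates.append((-res.fun, float(res.x)))
    best_ll, k_hat = max(candidates, key=lambda t: t[0])
    if not np.isfinite(best_ll):
        raise ValueError("likelihood is degenerate for every k in [0, 1]")

    cutoff = best_ll - stats.chi2.ppf(conf_level, df=1) / 2.0

    def drop(k: float) -> float:
        # finite floor keeps brentq's interpolation well-behaved when a
        # boundary k puts zero mass on an observed class
        return max(ll(k), best_ll - 1e12) - cutoff

    lo = 0.0 if drop(0.0) >= 0 else float(
        optimize.brentq(drop, 0.0, k_hat, xtol=1e-8)
    )
    hi = 1.0 if drop(1.0) >= 0 else float(
        optimize.brentq(drop, k_hat, 1.0, xtol=1e-8)
    )
    return KillingEstimate(k_hat=k_hat, log_likelihood=best_ll, ci_95=(lo, hi))


def estimate_k_from_fertility(
    genotype: SporophyteGenotype,
    spec: KillerProtectorSpec,
    observed_fertility: float,
    sex: str = "female",
    tol: float = 1e-8,
) -> float:
    """Invert the fertility prediction: find k with predicted fertility = observed.

    Fertility is monotonically non-increasing in k for a fixed genotype,
    so the solution on [0, 1] is unique when it exists.  Raises
    :class:`NonIdentifiableError` when fertility does not depend on k
    (killer unarmed, or every gamete protected) and ``ValueError`` when
    the observed value lies outside the attainable range.
    """
    from .model import gamete_pool, predict_fertility  # local to avoid cycle noise

    def fert(k: float) -> float:
        pred = predict_fertility(genotype, spec.with_abort(k))
        return pred.pollen_fertility if sex == "male" else pred.female_fertility

    hi_f, lo_f = fert(0.0), fert(1.0)
    if abs(hi_f - lo_f) < 1e-12:
        raise NonIdentifiableError(
            "fertility of this genotype does not depend on the abortion probability"
        )
    if not (lo_f - 1e-9 <= observed_fertility <= hi_f + 1e-9):
        raise ValueError(
            f"observed fertility {observed_fertility} outside attainable range "
            f"[{lo_f}, {hi_f}]"
        )
    target = min(max(observed_fertility, lo_f), hi_f)
    if target == hi_f:
        return 0.0
    if target == lo_f:
        return 1.0
    return float(optimize.brentq(lambda k: fert(k) - target, 0.0, 1.0, xtol=tol))


# ---------------------------------------------------------------------------
# TSV I/O (columns: locus, class, count)
# ---------------------------------------------------------------------------


def read_counts_tsv(path) -> dict[str, ObservedCounts]:
    """Read observed counts; returns one ObservedCounts per locus."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "class": str})
    required = {"locus", "class", "count"}
    if not required <= set(df.columns):
        raise ConfigError(f"counts table must have columns {sorted(required)}")
    out = {}
    for locus, grp in df.groupby("locus", sort=False):
        out[str(locus)] = ObservedCounts.from_dict(
            str(locus), dict(zip(grp["class"], grp["count"].astype(int)))
        )
    return out


def write_counts_tsv(counts: Sequence[ObservedCounts], path) -> None:
    rows = [
        {"locus": oc.locus, "class": label, "count": c}
        for oc in counts
        for label, c in oc.counts
    ]
    pd.DataFrame(rows, columns=["locus", "class", "count"]).to_csv(
        path, sep="\t", index=False
    )
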