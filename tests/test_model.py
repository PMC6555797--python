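"""Core killer-protector model: arming, gametes, viability, crosses."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from s1drive import (
    Allele,
    ConfigError,
    KillerProtectorSpec,
    Locus,
    ModelConfig,
    SporophyteGenotype,
    allele_frequency,
    apply_viability,
    arm_killer,
    cross_progeny,
    enumerate_gametes,
    load_model,
    predict_fertility,
    save_model,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerates every ordered gamete pair with
# plain dicts and loops, sharing no code with the implementation under test.
# ---------------------------------------------------------------------------


def brute_force_cross(loci, mother_pairs, father_pairs, killer, protector, km, kf):
    """loci: ordered dict locus -> {allele: set(components)}."""
    locus_names = list(loci)

    def gametes(pairs, k):
        # all 2^L gamete tuples, each 1/2^L; survival applied per gamete
        choices = [pairs[l] for l in locus_names]
        out = {}
        for combo in itertools.product(*choices):
            out[combo] = out.get(combo, 0.0) + 0.5 ** len(locus_names)
        union = set()
        for l in locus_names:
            for a in pairs[l]:
                union |= loci[l][a]
        armed = killer <= union
        weighted = {}
        for combo, w in out.items():
            comps = set()
            for l, a in zip(locus_names, combo):
                comps |= loci[l][a]
            if armed and not (protector <= comps):
                w *= 1.0 - k
            if w > 0:
                weighted[combo] = weighted.get(combo, 0.0) + w
        total = sum(weighted.values())
        return {c: w / total for c, w in weighted.items()}

    eggs = gametes(mother_pairs, kf)
    sperm = gametes(father_pairs, km)
    progeny = {}
    for e, we in eggs.items():
        for s, ws in sperm.items():
            key = tuple(
                tuple(sorted((a, b), key=lambda x: (x == "-", x)))
                for a, b in zip(e, s)
            )
            progeny[key] = progeny.get(key, 0.0) + we * ws
    return progeny


def random_case(rng):
    """A random <=3-locus genotype pair plus killer/protector spec."""
    n_loci = rng.randint(1, 3)
    components = ["A4", "TPR", "A6", "TP", "X1", "X2"]
    loci = {}
    for i in range(n_loci):
        alleles = {}
        for j in range(rng.randint(1, 3)):
            name = f"a{i}{j}" if rng.random() < 0.8 else "-"
            alleles[name] = set(rng.sample(components, rng.randint(0, 3)))
        if not alleles:
            alleles["a"] = set()
        loci[f"L{i}"] = alleles
    killer = set(rng.sample(components, rng.randint(1, 3)))
    protector = set(rng.sample(components, rng.randint(1, 2)))
    km, kf = rng.random(), rng.random()
    pairs = lambda: {l: tuple(rng.choices(list(loci[l]), k=2)) for l in loci}
    return loci, pairs(), pairs(), killer, protector, km, kf


def build_genotype(loci, pairs):
    locus_objs = [
        Locus(name, tuple(Allele(a, frozenset(c)) for a, c in alleles.items()))
        for name, alleles in loci.items()
    ]
    return SporophyteGenotype.from_pairs(locus_objs, pairs)


# ---------------------------------------------------------------------------
# Killer arming
# ---------------------------------------------------------------------------


class TestArmKiller:
    def test_native_heterozygote_arms(self, model, spec):
        assert arm_killer(model.genotype("f1_plain"), spec)

    def test_single_transgene_does_not_arm(self, model, spec):
        g = model.genotype("f1_transgenic", loci=["S1", "TPRt"])
        assert not arm_killer(g, spec)

    def test_unlinked_transgenes_arm_in_trans(self, model, spec):
        assert arm_killer(model.genotype("f1_transgenic"), spec)

    def test_killer_knockout_does_not_arm(self, model, spec):
        # S1-g^m4 lacks A4: no complete killer set anywhere in the sporophyte
        g = model.genotype("f1_plain")
        loci = [g.locus("S1")]
        gm4 = SporophyteGenotype.from_pairs(loci, {"S1": ("gm4", "s")})
        assert not arm_killer(gm4, spec)

    def test_unknown_allele_is_config_error(self, model, spec):
        loci = [model.genotype("f1_plain").locus("S1")]
        with pytest.raises(ConfigError, match="S1"):
            SporophyteGenotype.from_pairs(loci, {"S1": ("g", "nonexistent")})


# ---------------------------------------------------------------------------
# Gamete enumeration and viability selection
# ---------------------------------------------------------------------------


class TestGametes:
    def test_single_heterozygous_locus(self, model):
        dist = enumerate_gametes(model.genotype("f1_plain"))
        assert dist.as_dict() == {("g",): 0.5, ("s",): 0.5}

    def test_two_loci_four_classes(self, model):
        dist = enumerate_gametes(model.genotype("f1_protected"))
        weights = dist.as_dict()
        assert len(weights) == 4
        assert all(w == pytest.approx(0.25) for w in weights.values())

    def test_homozygote_merges_to_one_class(self, model):
        g = model.genotype("f1_plain")
        hom = SporophyteGenotype.from_pairs(list(g.loci), {"S1": ("g", "g")})
        assert enumerate_gametes(hom).as_dict() == {("g",): 1.0}

    def test_unprotected_gametes_removed_at_full_abortion(self, model, spec):
        g = model.genotype("f1_protected")
        post = apply_viability(enumerate_gametes(g), True, spec, "male")
        d = post.as_dict()
        # the (s, -) gamete carries no TPR and dies; survivors renormalised
        assert ("s", "-") not in d
        assert post.viable_fraction == pytest.approx(0.75)
        assert all(w == pytest.approx(1 / 3) for w in d.values())

    def test_unarmed_killer_changes_nothing(self, model, spec):
        g = model.genotype("f1_plain")
        pre = enumerate_gametes(g)
        post = apply_viability(pre, False, spec, "female")
        assert post.as_dict() == pre.as_dict()
        assert post.viable_fraction == 1.0

    def test_partial_abortion_hand_arithmetic(self, model):
        # k = 0.851: survivors T: 0.5/(0.5 + 0.5*0.149), -: the rest
        g = model.genotype("f1_transgenic", loci=["TPRt"])
        loci = list(g.loci)
        het = SporophyteGenotype.from_pairs(loci, {"TPRt": ("T", "-")})
        spec = KillerProtectorSpec(
            killer_components={"TPR"}, abort_prob_male=0.851, abort_prob_female=0.851
        )
        post = apply_viability(enumerate_gametes(het), True, spec, "male")
        assert post.viable_fraction == pytest.approx(0.5745)
        assert post.weight_of(("T",)) == pytest.approx(0.5 / 0.5745)
        assert post.weight_of(("-",)) == pytest.approx(0.0745 / 0.5745)

    def test_invalid_sex_rejected(self, model, spec):
        pre = enumerate_gametes(model.genotype("f1_plain"))
        with pytest.raises(ValueError, match="sex"):
            apply_viability(pre, True, spec, "neuter")


# ---------------------------------------------------------------------------
# Fertility prediction
# ---------------------------------------------------------------------------


class TestFertility:
    @pytest.mark.parametrize(
        "genotype, expected",
        [
            ("f1_plain", 0.5),        # S1 het, no protector transgene
            ("f1_protected", 0.75),   # one hemizygous protector copy
            ("f1_TT", 1.0),           # homozygous protector
            ("f1_transgenic", 0.5),   # triple-hemizygous transgenic
        ],
    )
    def test_printed_fertilities(self, model, spec, genotype, expected):
        f = predict_fertility(model.genotype(genotype), spec)
        assert f.pollen_fertility == pytest.approx(expected)
        assert f.spikelet_fertility == pytest.approx(expected)

    def test_homozygous_driver_fully_fertile(self, model, spec):
        # armed, but every gamete carries the protector
        g = model.genotype("f1_plain")
        hom = SporophyteGenotype.from_pairs(list(g.loci), {"S1": ("g", "g")})
        f = predict_fertility(hom, spec)
        assert f.pollen_fertility == 1.0 and f.female_fertility == 1.0

    def test_zero_abortion_means_full_fertility(self, model, spec):
        f = predict_fertility(model.genotype("f1_plain"), spec.with_abort(0.0))
        assert f.pollen_fertility == 1.0

    @given(k=st.floats(min_value=0, max_value=1, allow_nan=False))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fertility_monotone_in_abortion_probability(self, k):
        model = ModelConfig.from_dict(default_doc())
        g = model.genotype("f1_protected")
        f_k = predict_fertility(g, model.spec.with_abort(k)).pollen_fertility
        f_1 = predict_fertility(g, model.spec.with_abort(1.0)).pollen_fertility
        assert f_k >= f_1 - 1e-12


def default_doc():
    from s1drive import default_model

    return default_model().to_dict()


# ---------------------------------------------------------------------------
# Cross prediction and allele frequency
# ---------------------------------------------------------------------------


class TestCrossProgeny:
    def test_protected_selfing_gives_4_4_1_both_loci(self, model, spec):
        g = model.genotype("f1_protected")
        dist = cross_progeny(g, g, spec)
        s1 = dist.marginal("S1")
        tpr = dist.marginal("TPRt")
        assert s1["gg"] == pytest.approx(4 / 9)
        assert s1["gs"] == pytest.approx(4 / 9)
        assert s1["ss"] == pytest.approx(1 / 9)
        assert tpr["TT"] == pytest.approx(4 / 9)
        assert tpr["T-"] == pytest.approx(4 / 9)
        assert tpr["--"] == pytest.approx(1 / 9)

    def test_knockout_selfing_mendelian_s1_distorted_transgene(self, model, spec):
        g = model.genotype("f1_knockout")
        dist = cross_progeny(g, g, spec)
        assert dist.marginal("S1") == pytest.approx(
            {"gmgm": 0.25, "gms": 0.5, "ss": 0.25}
        )
        assert dist.marginal("TPRt") == pytest.approx({"TT": 1.0})

    def test_transgenic_selfing_mendelian_a4a6_distorted_tpr(self, model, spec):
        g = model.genotype("f1_transgenic")
        dist = cross_progeny(g, g, spec)
        assert dist.marginal("A4A6t") == pytest.approx(
            {"4646": 0.25, "46-": 0.5, "--": 0.25}
        )
        assert dist.marginal("TPRt") == pytest.approx({"TT": 1.0})

    def test_no_abortion_recovers_mendelian_everywhere(self, model, spec):
        g = model.genotype("f1_protected")
        dist = cross_progeny(g, g, spec.with_abort(0.0))
        for locus, het in [("S1", "gs"), ("TPRt", "T-")]:
            m = dist.marginal(locus)
            assert m[het] == pytest.approx(0.5)
            assert sum(m.values()) == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, model, spec):
        g = model.genotype("f1_transgenic")
        dist = cross_progeny(g, g, spec.with_abort(0.7))
        assert sum(p for _, p in dist.probs) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_loci_rejected(self, model, spec):
        a = model.genotype("f1_plain")
        b = model.genotype("f1_protected")
        with pytest.raises(ConfigError, match="locus"):
            cross_progeny(a, b, spec)

    def test_allele_frequency_examples(self, model, spec):
        g = model.genotype("f1_protected")
        dist = cross_progeny(g, g, spec)
        assert allele_frequency(dist, "S1", "g") == pytest.approx(2 / 3)
        mendel = cross_progeny(g, g, spec.with_abort(0.0))
        assert allele_frequency(mendel, "S1", "g") == pytest.approx(0.5)
        hom = SporophyteGenotype.from_pairs(
            [g.locus("S1")], {"S1": ("g", "g")}
        )
        fixed = cross_progeny(hom, hom, spec)
        assert allele_frequency(fixed, "S1", "g") == 1.0

    def test_symmetry_with_equal_sex_abortion(self, model):
        spec = KillerProtectorSpec(abort_prob_male=0.6, abort_prob_female=0.6)
        a = model.genotype("f1_protected")
        g = model.genotype("f1_protected")
        loci = list(g.loci)
        b = SporophyteGenotype.from_pairs(loci, {"S1": ("g", "g"), "TPRt": ("-", "-")})
        ab = cross_progeny(a, b, spec).as_dict()
        ba = cross_progeny(b, a, spec).as_dict()
        assert set(ab) == set(ba)
        for key in ab:
            assert ab[key] == pytest.approx(ba[key], abs=1e-12)

    def test_matches_brute_force_oracle_on_randomized_genotypes(self):
        rng = random.Random(20240917)
        for _ in range(30):
            loci, mp, fp, killer, prot, km, kf = random_case(rng)
            spec = KillerProtectorSpec(
                killer_components=killer,
                protector_components=prot,
                abort_prob_male=km,
                abort_prob_female=kf,
            )
            mother = build_genotype(loci, mp)
            father = build_genotype(loci, fp)
            try:
                expected = brute_force_cross(loci, mp, fp, killer, prot, km, kf)
            except ZeroDivisionError:
                with pytest.raises(ValueError):
                    cross_progeny(mother, father, spec)
                continue
            got = cross_progeny(mother, father, spec).as_dict()
            assert set(got) == set(expected)
            for key in got:
                assert got[key] == pytest.approx(expected[key], abs=1e-12)


# ---------------------------------------------------------------------------
# Configuration round trip
# ---------------------------------------------------------------------------


class TestModelConfigIO:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip_is_exact(self, model, tmp_path, suffix):
        path = tmp_path / f"model{suffix}"
        save_model(model, path)
        again = load_model(path)
        assert again.to_dict() == model.to_dict()

    def test_spec_probability_validation(self):
        with pytest.raises(ConfigError, match="abort_prob"):
            KillerProtectorSpec(abort_prob_male=1.5)

    def test_empty_component_set_rejected_for_killer(self):
        with pytest.raises(ConfigError, match="non-empty"):
            KillerProtectorSpec(killer_components=frozenset())
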