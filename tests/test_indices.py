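import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cubkit import (
    ConfigurationError,
    InsufficientDataError,
    StatisticUndefinedError,
    SyntheticSpec,
    cai,
    cbi,
    default_at_planted,
    enc,
    family_homozygosity,
    filter_cds,
    generate_genome,
    high_frequency_codons,
    optimal_codons,
    reference_w_from_high_set,
    rscu,
)
from cubkit.cds_io import GeneRecord

from conftest import make_cds


# ---------------------------------------------------------------- RSCU

def test_rscu_phe_example(space):
    table = rscu({"TTT": 3, "TTC": 1}, space)
    assert table.rscu["TTT"] == pytest.approx(1.5)
    assert table.rscu["TTC"] == pytest.approx(0.5)


def test_rscu_uniform_family_is_one(space):
    fam = next(f for f in space.families if f.k == 4)
    table = rscu({c: 5 for c in fam.codons}, space)
    assert all(table.rscu[c] == pytest.approx(1.0) for c in fam.codons)


def test_rscu_single_codon_extreme_and_zero_flag(space):
    table = rscu({"AAA": 2}, space)
    assert table.rscu["AAA"] == pytest.approx(2.0)
    assert table.rscu["AAG"] == 0.0
    assert "F" in table.zero_families  # Phe unobserved
    assert table.rscu["TTT"] == 0.0


def test_rscu_family_sum_conservation_property(space):
    @given(
        st.dictionaries(
            st.sampled_from(list(space.analysis_codons)),
            st.integers(min_value=0, max_value=60),
            min_size=1,
            max_size=59,
        )
    )
    def check(counts):
        if not any(v > 0 for v in counts.values()):
            return
        table = rscu(counts, space)
        for fam in space.families:
            total = sum(counts.get(c, 0) for c in fam.codons)
            fam_sum = sum(table.rscu[c] for c in fam.codons)
            if total > 0:
                assert fam_sum == pytest.approx(fam.k, abs=1e-9)
            else:
                assert fam_sum == 0.0

    check()


# ---------------------------------------------------------------- ENC

def test_family_homozygosity_hand_case():
    assert family_homozygosity([3, 1]) == pytest.approx(0.5)
    assert family_homozygosity([1]) is None  # n < 2 unusable
    assert family_homozygosity([1, 1]) is None  # F == 0 unusable


def test_enc_minimum_one_codon_per_family(space):
    counts = {f.codons[0]: 10 for f in space.families}
    assert enc(counts, space).enc_obs == pytest.approx(20.0)


def test_enc_maximum_uniform_capped(space):
    counts = {c: 30 for c in space.analysis_codons}
    res = enc(counts, space)
    assert res.enc_raw > 61.0
    assert res.enc_obs == 61.0


def test_enc_undefined_without_usable_family(space):
    with pytest.raises(StatisticUndefinedError):
        enc({"TTT": 1}, space)  # single observation, no family usable


def test_enc_imputes_missing_three_fold_class(space):
    # Use only 2- and 4-fold families: Ile must be imputed as (F2+F4)/2.
    counts = {"TTT": 6, "TTC": 2, "GGT": 4, "GGC": 4}
    res = enc(counts, space)
    assert res.n_classes_imputed >= 1
    f2, f4 = res.f_bar[2], res.f_bar[4]
    assert res.f_bar[3] == pytest.approx((f2 + f4) / 2)


def test_enc_bounds_on_random_vectors(space):
    rng = np.random.default_rng(0)
    codons = list(space.analysis_codons)
    for _ in range(200):
        k = rng.integers(2, 59)
        chosen = rng.choice(codons, size=k, replace=False)
        counts = {c: int(n) for c, n in zip(chosen, rng.integers(1, 50, size=k))}
        try:
            res = enc(counts, space)
        except StatisticUndefinedError:
            continue
        assert 20.0 - 1e-9 <= res.enc_obs <= 61.0
        assert res.enc_obs <= res.enc_raw


def test_enc_decreases_with_planted_bias(space):
    """Stronger within-family preference never raises mean ENC (paired seeds)."""
    planted = default_at_planted(space)
    means = []
    for bias in (0.0, 1.0, 2.0, 4.0, 8.0):
        spec = SyntheticSpec(
            seed=11, n_genes=12, length_range=(600, 900), gc3_target=0.4,
            gc12_target=0.4, class_mixture=1.0, bias_strength=bias,
            planted_optimal=planted,
        )
        genes, _ = generate_genome(spec, space)
        recs, _ = filter_cds(genes, space)
        means.append(np.mean([enc(g.codon_counts, space).enc_obs for g in recs]))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------- CAI

def test_cai_unit_reference(space):
    w = {c: 1.0 for c in space.analysis_codons}
    assert cai({"TTT": 5, "GGG": 3}, w, space) == pytest.approx(1.0)


def test_cai_geometric_mean(space):
    w = dict.fromkeys(space.analysis_codons, 1.0)
    w["TTC"] = 0.25
    assert cai({"TTT": 1, "TTC": 1}, w, space) == pytest.approx(0.5)


def test_cai_order_invariance_and_errors(space):
    w = {c: 0.5 for c in space.analysis_codons}
    a = cai({"TTT": 2, "GGG": 1}, w, space)
    b = cai({"GGG": 1, "TTT": 2}, w, space)
    assert a == b
    with pytest.raises(ConfigurationError):
        cai({"TTT": 1}, {}, space)
    with pytest.raises(StatisticUndefinedError):
        cai({"ATG": 3}, w, space)  # no analysis codons


def test_reference_w_construction(space):
    g_uniform = GeneRecord("u", "x", make_cds([c for f in space.families for c in f.codons]))
    w = reference_w_from_high_set([g_uniform], space)
    fam = next(f for f in space.families if f.k == 2 and f.codons[0] not in ("AAA", "GAA"))
    # uniform usage: every observed codon is its family's max
    assert all(w[c] == pytest.approx(1.0) for c in fam.codons)

    g_biased = GeneRecord("b", "x", make_cds(["TTT"] * 9 + ["TTC"] * 1, pad_to=303))
    w = reference_w_from_high_set([g_biased], space)
    assert w["TTT"] == pytest.approx(1.0)
    assert w["TTC"] == pytest.approx(1 / 9)


def test_cai_own_reference_beats_permuted_reference(space):
    """Misassigning which codon is preferred can only lower CAI: the gene's
    own w vector beats any within-family permutation of it."""
    gene = GeneRecord("g", "x", make_cds(["TTT"] * 8 + ["TTC"] * 2 + ["GGA"] * 6 + ["GGC"] * 2, pad_to=303))
    w_own = reference_w_from_high_set([gene], space)
    base = cai(gene.codon_counts, w_own, space)
    rng = np.random.default_rng(3)
    for _ in range(20):
        w_perm = dict(w_own)
        for fam in space.families:
            vals = [w_own[c] for c in fam.codons]
            rng.shuffle(vals)
            for c, v in zip(fam.codons, vals):
                w_perm[c] = v
        assert cai(gene.codon_counts, w_perm, space) <= base + 1e-12


# ---------------------------------------------------------------- CBI

def test_cbi_extremes_and_random_expectation(space):
    fam = next(f for f in space.families if f.k == 2)
    optimal = {fam.codons[0]}
    # only optimal codons used
    assert cbi({fam.codons[0]: 7}, optimal, space) == pytest.approx(1.0)
    # 50/50 usage in a two-fold family is exactly random expectation
    assert cbi({fam.codons[0]: 5, fam.codons[1]: 5}, optimal, space) == pytest.approx(0.0)
    # total avoidance in two-fold families
    assert cbi({fam.codons[1]: 8}, optimal, space) == pytest.approx(-1.0)
    with pytest.raises(ConfigurationError):
        cbi({fam.codons[0]: 1}, set(), space)


# ------------------------------------------------- optimal codons & HF

def test_high_frequency_codons(space):
    uniform = rscu({c: 3 for c in space.analysis_codons}, space)
    assert high_frequency_codons(uniform) == frozenset()
    exclusive = rscu({f.codons[0]: 10 for f in space.families}, space)
    assert len(high_frequency_codons(exclusive)) == 18


def test_optimal_codons_requires_ten_genes(space):
    genes, _ = filter_cds([make_cds(["GGT"])] * 9, space)
    with pytest.raises(InsufficientDataError):
        optimal_codons(genes, space)


def test_optimal_codons_identical_genes_empty(space):
    genes, _ = filter_cds([make_cds(["GGT", "GGC", "TTA"])] * 12, space)
    res = optimal_codons(genes, space)
    assert all(abs(d) < 1e-12 for d in res.delta_rscu.values())
    assert res.optimal_codons == frozenset()


def test_optimal_codons_decile_size_and_subset(space):
    genes, _ = filter_cds([make_cds(["GGT"])] * 44, space)
    res = optimal_codons(genes, space)
    assert len(res.high_group) == len(res.low_group) == math.ceil(0.1 * 44) == 5
    assert res.optimal_codons <= res.high_frequency_codons


def test_optimal_codons_recover_planted_set(space):
    planted = default_at_planted(space)
    spec = SyntheticSpec(
        seed=4, n_genes=44, length_range=(900, 1500), gc3_target=0.30,
        gc12_target=0.40, class_mixture=0.2, bias_strength=8.0,
        planted_optimal=planted,
    )
    genes, truth = generate_genome(spec, space)
    recs, _ = filter_cds(genes, space)
    res = optimal_codons(recs, space)
    assert set(res.optimal_codons) == set(planted)
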