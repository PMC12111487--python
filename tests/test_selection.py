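import numpy as np
import pytest
import sympy
from hypothesis import given
from hypothesis import strategies as st

from cubkit import (
    InsufficientDataError,
    StatisticUndefinedError,
    SyntheticSpec,
    enc,
    enc_expected,
    enc_ratio,
    enc_ratio_histogram,
    filter_cds,
    gc3s,
    generate_genome,
    neutrality_fit,
    pr2_point,
    selection_diagnostics,
)


def test_enc_expected_anchors_match_symbolic_evaluation():
    """Analytic anchors of the mutation-only ENC curve, cross-checked with
    an independent symbolic evaluation of 2 + s + 29/(s^2 + (1-s)^2)."""
    s = sympy.Symbol("s")
    expr = 2 + s + 29 / (s**2 + (1 - s) ** 2)
    for val, expected in [(0, 31.0), (sympy.Rational(1, 2), 60.5), (1, 32.0)]:
        assert float(expr.subs(s, val)) == expected
        assert enc_expected(float(val)) == pytest.approx(expected, abs=1e-12)


def test_enc_expected_domain():
    with pytest.raises(ValueError):
        enc_expected(-0.01)
    with pytest.raises(ValueError):
        enc_expected(1.01)


@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_enc_expected_symmetry_up_to_linear_term(s):
    assert enc_expected(s) - s == pytest.approx(
        enc_expected(1 - s) - (1 - s), abs=1e-9
    )


def test_enc_ratio_arithmetic():
    assert enc_ratio(40.0, 36.0) == pytest.approx(0.1)
    assert enc_ratio(57.3, 57.3) == 0.0
    assert enc_ratio(60.5, 30.25) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        enc_ratio(0.0, 1.0)


def test_enc_ratio_histogram_bins_and_conservation():
    hist = enc_ratio_histogram([0.12, 0.13, 0.44], bin_width=0.1)
    lookup = {
        (round(l, 10), round(r, 10)): c
        for l, r, c in hist.itertuples(index=False)
    }
    assert lookup[(0.1, 0.2)] == 2
    assert lookup[(0.4, 0.5)] == 1
    assert lookup[(0.2, 0.3)] == 0  # interior empties reported as zero
    assert hist["count"].sum() == 3
    with pytest.raises(ValueError):
        enc_ratio_histogram([])


def test_enc_ratio_histogram_half_open_bins():
    hist = enc_ratio_histogram([0.0, 0.05, 0.1], bin_width=0.05)
    assert hist["count"].sum() == 3
    # each value starts its own [a, a+w) bin
    assert (hist["count"] == 1).all()


def test_pr2_points():
    assert pr2_point(0.3, 0.3, 0.2, 0.2) == (0.5, 0.5)
    x, y = pr2_point(0.6, 0.3, 0.08, 0.02)
    assert x == pytest.approx(0.2)
    assert y == pytest.approx(2 / 3)
    with pytest.raises(StatisticUndefinedError):
        pr2_point(1.0, 0.0, 0.0, 0.0)


def test_neutrality_identity_line_and_constant_gc3():
    pts = [(x, x) for x in (0.2, 0.3, 0.4, 0.5)]
    fit = neutrality_fit(pts)
    assert fit.slope == pytest.approx(1.0)
    assert fit.mutation_pct == pytest.approx(100.0)

    pts = [(x, 0.25) for x in (0.2, 0.3, 0.4, 0.5)]
    fit = neutrality_fit(pts)
    assert fit.slope == pytest.approx(0.0)
    assert fit.selection_pct == pytest.approx(100.0)
    assert fit.mutation_pct + fit.selection_pct == pytest.approx(100.0)


def test_neutrality_orientation_switch():
    pts = [(0.2, 0.3), (0.3, 0.35), (0.4, 0.5), (0.5, 0.52)]
    a = neutrality_fit(pts, orientation="gc12_x")
    b = neutrality_fit(pts, orientation="gc3_x")
    assert a.slope != pytest.approx(b.slope)
    assert a.r == pytest.approx(b.r)  # correlation is orientation-free


def test_neutrality_degenerate_inputs():
    with pytest.raises(InsufficientDataError):
        neutrality_fit([(0.3, 0.4), (0.3, 0.5), (0.3, 0.6)])
    with pytest.raises(InsufficientDataError):
        neutrality_fit([(0.1, 0.2)])


def test_null_genes_track_expected_enc_curve(space):
    """Without selection, mean observed ENC stays near the mutation-only
    curve at the realized GC3s (small Monte-Carlo version)."""
    for tgt in (0.2, 0.5, 0.8):
        spec = SyntheticSpec(
            seed=int(tgt * 10), n_genes=20, length_range=(600, 1200),
            gc3_target=tgt, gc12_target=0.4, gc12_spread=0.0,
        )
        genes, _ = generate_genome(spec, space)
        recs, _ = filter_cds(genes, space)
        mean_enc = np.mean([enc(g.codon_counts, space).enc_obs for g in recs])
        mean_s = np.mean([gc3s(g.codon_counts, space) for g in recs])
        assert abs(mean_enc - enc_expected(mean_s)) < 2.5


def test_pr2_concentrates_at_center_with_length(space):
    """Strand-symmetric usage (GC3 = 0.5, equal AT/GC third-base weights)
    drives PR2 points toward (0.5, 0.5) as genes grow."""
    dists = []
    for lo, hi in ((300, 303), (3000, 3003)):
        spec = SyntheticSpec(
            seed=9, n_genes=15, length_range=(lo, hi), gc3_target=0.5,
            gc12_target=0.4, gc12_spread=0.0,
        )
        genes, _ = generate_genome(spec, space)
        recs, _ = filter_cds(genes, space)
        diag = selection_diagnostics(recs, space, pr2_dialect="fourfold")
        d = np.hypot(diag["pr2_x"] - 0.5, diag["pr2_y"] - 0.5)
        dists.append(float(d.mean()))
    # distance shrinks roughly with 1/sqrt(length); at ~1000 codons the
    # multinomial floor for the mean distance is ~0.05
    assert dists[1] < dists[0] / 1.8
    assert dists[1] < 0.07


def test_selection_diagnostics_table(space):
    spec = SyntheticSpec(seed=2, n_genes=12)
    genes, _ = generate_genome(spec, space)
    recs, _ = filter_cds(genes, space)
    diag = selection_diagnostics(recs, space)
    assert len(diag) == 12
    np.testing.assert_allclose(
        diag["enc_ratio"],
        (diag["enc_exp"] - diag["enc_obs"]) / diag["enc_exp"],
        atol=1e-12,
    )
    assert diag["pr2_defined"].all()
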