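"""Hit filtering, RPK profiles, the motility index and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flagmet.errors import InsufficientMarkerSignalError, ValidationError
from flagmet.io import HitRecord, ProteinEntry, ProteinRegistry, \
    ROLE_FLAGELLAR, ROLE_MARKER
from flagmet.quant import (
    CalibrationCurve,
    HitFilterConfig,
    apply_calibration,
    dedupe_best_hit,
    filter_hits,
    fit_calibration,
    motility_index,
    quantify_metagenome,
    rpk_profile,
)


def _hit(read="r1", prot="m1_v1", pid=90.0, bits=80.0, e=1e-10, aln=50):
    return HitRecord(read, prot, pid, aln, bits, e)


# ---------------------------------------------------------------------------
# filter_hits
# ---------------------------------------------------------------------------

def test_filter_boundary_values_kept():
    # thresholds remove strictly-below / strictly-above; boundary hits stay
    h = _hit(bits=50.0, pid=60.0, e=0.001)
    assert filter_hits([h], {"r1": 101}) == [h]


@pytest.mark.parametrize("kwargs,read_len", [
    (dict(bits=49.9, pid=99.0, e=1e-20), 150),   # bit score below 50
    (dict(bits=80.0, pid=59.9, e=1e-20), 150),   # identity below 60
    (dict(bits=80.0, pid=99.0, e=0.0011), 150),  # e-value above 0.001
    (dict(bits=80.0, pid=99.0, e=1e-20), 100),   # read not above 100 bp
])
def test_filter_removes_failing_hits(kwargs, read_len):
    h = _hit(bits=kwargs["bits"], pid=kwargs["pid"], e=kwargs["e"])
    assert filter_hits([h], {"r1": read_len}) == []


def test_filter_without_read_lengths_skips_length_rule(caplog):
    h = _hit()
    assert filter_hits([h], None) == [h]


# ---------------------------------------------------------------------------
# rpk_profile
# ---------------------------------------------------------------------------

def test_rpk_hand_calculation(lengths_registry):
    # marker genes of 900, 450, 1800 nt with 9, 0, 18 hits ->
    # rpk 10.0, 0.0, 10.0; median 10.0
    hits = [_hit(read=f"r{i}", prot="m1_v1") for i in range(9)]
    hits += [_hit(read=f"s{i}", prot="m3_v1") for i in range(18)]
    prof = rpk_profile(hits, lengths_registry, ROLE_MARKER)
    assert prof.table.loc["m1", "rpk"] == pytest.approx(10.0)
    assert prof.table.loc["m2", "rpk"] == 0.0
    assert prof.table.loc["m3", "rpk"] == pytest.approx(10.0)
    assert prof.median_rpk == pytest.approx(10.0)


def test_rpk_zero_hits_and_homogeneity(lengths_registry):
    assert rpk_profile([], lengths_registry, ROLE_MARKER).median_rpk == 0.0
    hits = [_hit(read=f"r{i}", prot="m1_v1") for i in range(4)]
    base = rpk_profile(hits, lengths_registry, ROLE_MARKER).median_rpk
    doubled_hits = hits + [_hit(read=f"d{i}", prot="m1_v1") for i in range(4)]
    doubled = rpk_profile(doubled_hits, lengths_registry, ROLE_MARKER).median_rpk
    assert doubled == pytest.approx(2 * base)


def test_rpk_requires_genes_for_role(lengths_registry):
    reg = ProteinRegistry([ProteinEntry("p", "g", ROLE_MARKER, 100)])
    with pytest.raises(ValidationError):
        rpk_profile([], reg, ROLE_FLAGELLAR)


@st.composite
def hit_tables(draw):
    n_genes = draw(st.integers(1, 6))
    genes = [f"g{j}" for j in range(n_genes)]
    lengths = draw(st.lists(st.integers(50, 700), min_size=n_genes,
                            max_size=n_genes))
    counts = draw(st.lists(st.integers(0, 15), min_size=n_genes,
                           max_size=n_genes))
    return genes, lengths, counts


@given(hit_tables())
@settings(max_examples=50, deadline=None)
def test_rpk_matches_bruteforce_tally(data):
    genes, lengths, counts = data
    reg = ProteinRegistry([
        ProteinEntry(f"{g}_v1", g, ROLE_MARKER, aa)
        for g, aa in zip(genes, lengths)
    ])
    hits = []
    for g, c in zip(genes, counts):
        hits += [_hit(read=f"{g}_r{i}", prot=f"{g}_v1") for i in range(c)]
    prof = rpk_profile(hits, reg, ROLE_MARKER)
    # independent oracle: plain python tally + sorted-middle median
    expected_rpks = sorted(
        c / (3 * aa / 1000) for c, aa in zip(counts, lengths)
    )
    n = len(expected_rpks)
    mid = (expected_rpks[n // 2] if n % 2 else
           (expected_rpks[n // 2 - 1] + expected_rpks[n // 2]) / 2)
    assert prof.median_rpk == pytest.approx(mid)


def test_dedupe_best_hit_tiebreaks():
    hits = [
        _hit(read="r1", prot="b", bits=80.0, e=1e-10),
        _hit(read="r1", prot="a", bits=90.0, e=1e-10),   # higher bits wins
        _hit(read="r2", prot="b", bits=80.0, e=1e-12),
        _hit(read="r2", prot="a", bits=80.0, e=1e-10),   # lower e wins
        _hit(read="r3", prot="b", bits=80.0, e=1e-10),
        _hit(read="r3", prot="a", bits=80.0, e=1e-10),   # lexicographic wins
    ]
    best = {h.read_id: h.protein_id for h in dedupe_best_hit(hits)}
    assert best == {"r1": "a", "r2": "b", "r3": "a"}


# ---------------------------------------------------------------------------
# motility_index and calibration
# ---------------------------------------------------------------------------

def _profile(median, role=ROLE_MARKER, registry=None):
    import pandas as pd
    from flagmet.quant import GeneSetProfile
    table = pd.DataFrame({"hit_count": [0], "length_kb": [1.0], "rpk": [median]},
                         index=["g"])
    return GeneSetProfile(role=role, table=table, median_rpk=median)


def test_index_ratio_cases():
    assert motility_index(_profile(0.5), _profile(50.0)).index == pytest.approx(0.01)
    assert motility_index(_profile(0.0), _profile(50.0)).index == 0.0
    assert motility_index(_profile(3.0), _profile(3.0)).index == pytest.approx(1.0)
    with pytest.raises(InsufficientMarkerSignalError):
        motility_index(_profile(1.0), _profile(0.0))


def test_reference_calibration_evaluations():
    curve = CalibrationCurve()
    assert apply_calibration(curve, 0.0) == -0.321
    assert apply_calibration(curve, 0.01) == pytest.approx(36.179)
    assert apply_calibration(curve, 0.03) == pytest.approx(109.179)
    assert apply_calibration(curve, 0.03, clamp=True) == 100.0
    with pytest.raises(ValidationError):
        apply_calibration(curve, -0.1)
    with pytest.raises(ValidationError):
        apply_calibration(curve, float("nan"))


def test_fit_calibration_exact_collinear_points():
    curve = fit_calibration([(0.0, 0.0), (0.01, 36.5), (0.02, 73.0)])
    assert curve.slope == pytest.approx(3650.0)
    assert curve.intercept == pytest.approx(0.0, abs=1e-9)
    assert curve.pearson_r == pytest.approx(1.0)
    assert curve.n_points == 3


def test_fit_calibration_two_points_and_degenerate():
    curve = fit_calibration([(0.0, 0.0), (0.02, 73.0)])
    assert curve.slope == pytest.approx(3650.0)
    assert curve.pearson_r == 1.0
    with pytest.raises(ValidationError):
        fit_calibration([(0.01, 10.0), (0.01, 20.0)])
    with pytest.raises(ValidationError):
        fit_calibration([(0.01, 10.0)])


def test_fit_calibration_outlier_shrinks_r():
    clean = [(0.0, 0.0), (0.01, 36.5), (0.02, 73.0), (0.03, 109.5)]
    noisy = clean + [(0.04, 60.0)]
    curve = fit_calibration(noisy)
    # independent closed-form OLS on the same points
    x = np.array([p[0] for p in noisy])
    y = np.array([p[1] for p in noisy])
    slope_hand = (np.mean(x * y) - x.mean() * y.mean()) / (np.mean(x * x) - x.mean() ** 2)
    assert curve.slope == pytest.approx(slope_hand)
    clean_slope = fit_calibration(clean).slope
    # the low outlier drags the slope below the outlier-free fit
    assert curve.slope < clean_slope
    assert curve.pearson_r < 1.0


# ---------------------------------------------------------------------------
# End-to-end quantification
# ---------------------------------------------------------------------------

def test_quantify_gradient_endpoints(small_gradient_quant):
    """A curve fitted on a synthetic gradient reproduces its own endpoints."""
    points = [(res.index, 100 * p) for p, res in small_gradient_quant]
    curve = fit_calibration(points)
    bottom = apply_calibration(curve, small_gradient_quant[0][1].index)
    top = apply_calibration(curve, small_gradient_quant[-1][1].index)
    assert abs(bottom - 0.0) <= 5.0
    assert abs(top - 100.0) <= 5.0


def test_gradient_linearity(small_gradient_quant):
    props = [p for p, _ in small_gradient_quant]
    idx = [res.index for _, res in small_gradient_quant]
    r = np.corrcoef(props, idx)[0, 1]
    assert r >= 0.99


def test_library_size_invariance(small_registry, small_pool):
    from flagmet.simulate import MockMixtureSpec, simulate_reads

    genome = next(g for g in small_pool if g.motile)
    mix = MockMixtureSpec("m", [(genome.genome_id, 1.0)], 1.0,
                          coverage_fold=0.4, seed=21)
    reads = simulate_reads(mix, {genome.genome_id: genome})
    res = quantify_metagenome(reads=reads, registry=small_registry)
    doubled = reads + [(f"{rid}_dup", seq, q) for rid, seq, q in reads]
    res2 = quantify_metagenome(reads=doubled, registry=small_registry)
    assert res2.index == pytest.approx(res.index)
    assert res2.percent_flagellated == pytest.approx(res.percent_flagellated)
    assert res2.flagellar_median_rpk == pytest.approx(2 * res.flagellar_median_rpk)


def test_quantify_empty_input_raises_marker_error(small_registry):
    with pytest.raises(InsufficientMarkerSignalError):
        quantify_metagenome(reads=[], registry=small_registry)


def test_quantify_requires_exactly_one_input(small_registry):
    with pytest.raises(ValidationError):
        quantify_metagenome(registry=small_registry)
    with pytest.raises(ValidationError):
        quantify_metagenome(hits=[], reads=[], registry=small_registry)
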