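import numpy as np
import pandas as pd
import pytest

from irpipe import (
    IRScenario,
    build_sets_with_overlap,
    simulate_expression,
    simulate_interactome,
    simulate_ir_counts,
    venn3,
)
from irpipe.deg import tmm_factors


def test_scenario_validation():
    with pytest.raises(ValueError):
        IRScenario(frac_inc=0.7, frac_dec=0.5)
    with pytest.raises(ValueError):
        IRScenario(overdispersion_rho=1.0)
    with pytest.raises(ValueError):
        IRScenario(delta_psi=1.5)
    with pytest.raises(ValueError):
        IRScenario(groups=(("A", 5),))


def test_ir_counts_deterministic_and_conserved():
    sc = IRScenario(n_events=50, frac_inc=0.1, frac_dec=0.1, seed=99)
    t1, tr1 = simulate_ir_counts(sc)
    t2, tr2 = simulate_ir_counts(sc)
    pd.testing.assert_frame_equal(t1.inclusion, t2.inclusion)
    pd.testing.assert_frame_equal(t1.skipping, t2.skipping)
    pd.testing.assert_series_equal(tr1.event_labels, tr2.event_labels)
    t3, _ = simulate_ir_counts(IRScenario(n_events=50, frac_inc=0.1, frac_dec=0.1, seed=100))
    assert not t1.inclusion.equals(t3.inclusion)
    # conservation: I, S non-negative integers
    assert (t1.inclusion.to_numpy() >= 0).all()
    assert (t1.skipping.to_numpy() >= 0).all()
    assert np.issubdtype(t1.inclusion.to_numpy().dtype, np.integer)


def test_truth_labels_partition_and_match_fractions():
    sc = IRScenario(n_events=200, frac_inc=0.15, frac_dec=0.25, seed=2)
    _, truth = simulate_ir_counts(sc)
    counts = truth.event_labels.value_counts()
    assert counts.get("IncIR", 0) == 30
    assert counts.get("DecIR", 0) == 50
    assert counts.get("null", 0) == 120
    # planted psi clamped to [0.01, 0.99]
    psi = truth.psi_by_group.to_numpy()
    assert psi.min() >= 0.01 and psi.max() <= 0.99


def test_no_planted_effects_means_empty_truth():
    _, truth = simulate_ir_counts(IRScenario(n_events=30, seed=0))
    assert truth.inc_events == []
    assert truth.dec_events == []


def test_rho_zero_reduces_to_binomial_variance():
    """At rho=0 the variance of I/n across replicate draws matches the
    binomial expectation within Monte-Carlo error; positive rho inflates it."""
    base = dict(
        n_events=10000,
        groups=(("A", 2), ("B", 2)),
        baseline_psi_dist=(500.0, 500.0),  # psi pinned near 0.5
        depth_mean=50.0,
        depth_dispersion=0.0,  # Poisson depth, tight around 50
    )
    table0, truth0 = simulate_ir_counts(IRScenario(**base, overdispersion_rho=0.0, seed=8))
    n = table0.total().to_numpy()[:, 0].astype(float)
    ratio = table0.inclusion.to_numpy()[:, 0] / n
    psi0 = truth0.psi_by_group["A"].to_numpy()
    observed_var = ratio.var()
    binom_var = np.mean(psi0 * (1 - psi0) / n) + psi0.var()
    assert observed_var == pytest.approx(binom_var, rel=0.05)

    table1, _ = simulate_ir_counts(IRScenario(**base, overdispersion_rho=0.2, seed=8))
    n1 = table1.total().to_numpy()[:, 0].astype(float)
    var1 = (table1.inclusion.to_numpy()[:, 0] / n1).var()
    assert var1 > 2 * observed_var


def test_expression_null_has_unit_tmm_factors():
    matrix, truth = simulate_expression(800, (("A", 4), ("B", 4)), frac_de=0.0, seed=5)
    f = tmm_factors(matrix.counts)
    assert np.abs(f.to_numpy() - 1.0).max() < 0.05
    assert (truth.gene_log2fc == 0).all()


def test_expression_planted_split_even():
    _, truth = simulate_expression(100, frac_de=0.1, log2fc=1.5, seed=4)
    lfc = truth.gene_log2fc
    assert (lfc == 1.5).sum() == 5
    assert (lfc == -1.5).sum() == 5


def test_expression_validation():
    with pytest.raises(ValueError):
        simulate_expression(10, dispersion=0.0)
    with pytest.raises(ValueError):
        simulate_expression(10, lib_sizes=[1.0, -1.0])


def test_interactome_saturated_bipartite():
    """edge_prob=0, excess=1 gives the complete bipartite query-target graph."""
    net, truth = simulate_interactome(10, 0.0, 4, 5, excess_edge_prob=1.0, seed=1)
    assert net.n_edges == 4 * 5
    for u, v, d in net.graph.edges(data=True):
        assert 0.7 <= d["score"] <= 1.0
        assert (u in truth.query_set) != (v in truth.query_set)
    assert not (truth.query_set & truth.target_set)


def test_interactome_validation():
    with pytest.raises(ValueError):
        simulate_interactome(10, 1.5, 2, 2)
    with pytest.raises(ValueError):
        simulate_interactome(10, 0.1, 6, 6)


def test_build_sets_two_way_printed_example():
    """The cross-study worked example: 403/252/94 regions on a 4,546 universe
    give |A|=497, |B|=346 and overlap 94."""
    (a, b), universe = build_sets_with_overlap(4546, (403, 252, 94), seed=0)
    assert len(universe) == 4546
    assert len(a) == 497
    assert len(b) == 346
    assert len(a & b) == 94


def test_build_sets_empty_and_infeasible():
    (a, b), _ = build_sets_with_overlap(100, (0, 0, 0), seed=0)
    assert a == set() and b == set()
    with pytest.raises(ValueError):
        build_sets_with_overlap(5, (3, 3, 3))
    with pytest.raises(ValueError):
        build_sets_with_overlap(10, (1, 1))


def test_build_sets_three_way_roundtrip():
    regions_in = (1, 1, 1, 1, 1, 1, 1)
    (a, b, c), _ = build_sets_with_overlap(10, regions_in, seed=3)
    v = venn3(a, b, c)
    assert v["ab"] == v["ac"] == v["bc"] == 2
    assert v["abc"] == 1
    assert tuple(
        v[k] for k in ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc")
    ) == regions_in
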