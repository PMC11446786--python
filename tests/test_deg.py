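import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from irpipe import CountMatrix, call_degs, deg_test, simulate_expression, tmm_factors


def _matrix(counts, groups):
    sample_ids, labels = [], []
    for label, n in groups:
        for j in range(n):
            sample_ids.append(f"{label}_{j + 1}")
            labels.append(label)
    counts = pd.DataFrame(
        np.asarray(counts),
        index=[f"g{i}" for i in range(len(counts))],
        columns=sample_ids,
    )
    gs = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="group")
    return CountMatrix(counts=counts, groups=gs)


def test_tmm_identical_columns_unit_factors():
    m = np.tile(np.array([[10], [10], [10], [10]]), (1, 2))
    f = tmm_factors(pd.DataFrame(m, columns=["a", "b"]))
    np.testing.assert_allclose(f, [1.0, 1.0])
    rng = np.random.default_rng(0)
    col = rng.integers(1, 200, 300)
    f2 = tmm_factors(pd.DataFrame(np.column_stack([col] * 4)))
    np.testing.assert_allclose(f2, 1.0)


def test_tmm_invariant_to_global_scaling(rng):
    y = rng.integers(1, 500, size=(400, 5))
    f1 = tmm_factors(pd.DataFrame(y))
    f2 = tmm_factors(pd.DataFrame(y * 7))
    np.testing.assert_allclose(f1, f2, atol=1e-9)


def test_tmm_recovers_library_scaling():
    """A 2x-scaled library with no DE: against equal nominal library sizes the
    TMM factor absorbs the scale (within 10%); against default column-sum
    library sizes the factor stays near 1."""
    lib = [1, 1, 1, 1, 1, 2, 1, 1, 1, 1]
    m, _ = simulate_expression(2000, (("A", 5), ("B", 5)), frac_de=0.0, lib_sizes=lib, seed=7)
    f = tmm_factors(m.counts, lib_sizes=np.ones(10))
    others = np.exp(np.mean(np.log(np.delete(f.to_numpy(), 5))))
    assert f.iloc[5] / others == pytest.approx(2.0, rel=0.10)
    f_default = tmm_factors(m.counts)
    assert f_default.iloc[5] == pytest.approx(1.0, abs=0.05)


def test_tmm_all_zero_column_raises():
    y = np.array([[1, 0], [2, 0]])
    with pytest.raises(ValueError):
        tmm_factors(pd.DataFrame(y))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_tmm_matches_edger(tmp_path, rng):
    """Cross-check TMM factors against edgeR::calcNormFactors on random counts."""
    y = rng.negative_binomial(5, 0.05, size=(300, 6))
    counts_path = tmp_path / "counts.tsv"
    pd.DataFrame(y).to_csv(counts_path, sep="\t", index=False, header=False)
    script = tmp_path / "tmm.R"
    script.write_text(
        "suppressMessages(library(edgeR))\n"
        f'y <- as.matrix(read.delim("{counts_path}", header=FALSE))\n'
        "cat(calcNormFactors(y, method='TMM'), sep='\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    ref = np.array([float(x) for x in out.stdout.split()])
    ours = tmm_factors(pd.DataFrame(y)).to_numpy()
    np.testing.assert_allclose(ours, ref, rtol=0.05)


def test_deg_identical_groups_null():
    rng = np.random.default_rng(3)
    block = rng.integers(5, 400, size=(200, 4))
    m = _matrix(np.hstack([block, block]), [("A", 4), ("B", 4)])
    res = deg_test(m, "A", "B")
    assert (res["p"] >= 0.5).all()
    np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-6)


def test_deg_group_swap_symmetry():
    m, _ = simulate_expression(300, (("A", 4), ("B", 4)), frac_de=0.2, log2fc=1.0, seed=9)
    fwd = deg_test(m, "A", "B").set_index("gene")
    rev = deg_test(m, "B", "A").set_index("gene")
    np.testing.assert_allclose(fwd["p"], rev.loc[fwd.index, "p"], rtol=1e-5, atol=1e-8)
    np.testing.assert_allclose(fwd["log2fc"], -rev.loc[fwd.index, "log2fc"], atol=1e-5)


def test_deg_power_on_planted_genes():
    m, truth = simulate_expression(
        2000, (("A", 8), ("B", 6)), frac_de=0.1, log2fc=1.0, dispersion=0.1, seed=12
    )
    res = deg_test(m, "A", "B").set_index("gene")
    planted = truth.gene_log2fc[truth.gene_log2fc != 0].index.intersection(res.index)
    assert (res.loc[planted, "q"] < 0.1).mean() >= 0.8
    # recovered effect direction matches the planted sign
    sign_ok = np.sign(res.loc[planted, "log2fc"]) == np.sign(truth.gene_log2fc[planted])
    assert sign_ok.mean() > 0.95


@pytest.mark.parametrize(
    "log2fc,p,q,expected",
    [
        (np.log2(1.2), 0.001, 0.001, "NS"),  # FC exactly 1.2: strict inequality
        (0.30, 0.04, 0.5, "up"),  # 0.30 > log2(1.2) = 0.263
        (-0.30, 0.2, 0.08, "down"),  # FDR branch
        (0.30, 0.2, 0.5, "NS"),
    ],
)
def test_call_degs_rule(log2fc, p, q, expected):
    rec = pd.DataFrame({"gene": ["g"], "log2fc": [log2fc], "p": [p], "q": [q]})
    up, down = call_degs(rec)
    got = "up" if len(up) else ("down" if len(down) else "NS")
    assert got == expected


def test_call_degs_matches_bruteforce(rng):
    rec = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(300)],
            "log2fc": rng.normal(0, 0.5, 300),
            "p": rng.uniform(0, 1, 300),
            "q": rng.uniform(0, 1, 300),
        }
    )
    up, down = call_degs(rec)
    sig = (rec["p"] < 0.05) | (rec["q"] < 0.1)
    assert set(up["gene"]) == set(rec.loc[sig & (rec["log2fc"] > np.log2(1.2)), "gene"])
    assert set(down["gene"]) == set(rec.loc[sig & (rec["log2fc"] < -np.log2(1.2)), "gene"])
    empty_up, empty_down = call_degs(rec.iloc[:0])
    assert empty_up.empty and empty_down.empty
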