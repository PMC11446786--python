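import numpy as np
import pandas as pd
import pytest

from irpipe import anova_trajectory, recovery_summary, venn_recovery
from _oracles import anova_f_oracle


def _diff_frame(calls: dict) -> pd.DataFrame:
    return pd.DataFrame({"event_id": list(calls), "call": list(calls.values())})


def _flip(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    out["call"] = out["call"].map({"IncIR": "DecIR", "DecIR": "IncIR", "NS": "NS"})
    return out


def test_venn_recovery_patterns():
    leg1 = _diff_frame({"e1": "IncIR", "e2": "IncIR", "e3": "DecIR", "e4": "NS", "e5": "DecIR"})
    leg2 = _diff_frame({"e1": "DecIR", "e2": "NS", "e3": "IncIR", "e4": "DecIR", "e5": "DecIR"})
    calls = venn_recovery(leg1, leg2).set_index("event_id")["pattern"]
    assert calls["e1"] == "reverse_V"  # up then back down
    assert calls["e3"] == "V"  # down then back up
    assert calls["e2"] == calls["e4"] == calls["e5"] == "none"
    # patterns are mutually exclusive: exactly one per event
    assert calls.isin(["reverse_V", "V", "none"]).all()


def test_venn_recovery_direction_symmetries():
    """Flipping the comparison direction of both legs (swapping case and
    control within each two-group test) turns every reverse_V into a V and
    vice versa; reversing the timeline (control <-> post relabel, i.e.
    venn(flip(leg2), flip(leg1))) preserves the patterns, since an
    up-then-down trajectory read backwards is still up-then-down."""
    rng = np.random.default_rng(6)
    ids = [f"e{i}" for i in range(50)]
    states = ["IncIR", "DecIR", "NS"]
    leg1 = _diff_frame(dict(zip(ids, rng.choice(states, 50))))
    leg2 = _diff_frame(dict(zip(ids, rng.choice(states, 50))))
    fwd = venn_recovery(leg1, leg2).set_index("event_id")["pattern"]
    swap = {"reverse_V": "V", "V": "reverse_V", "none": "none"}
    flipped = venn_recovery(_flip(leg1), _flip(leg2)).set_index("event_id")["pattern"]
    assert (flipped == fwd.map(swap)).all()
    reversed_time = venn_recovery(_flip(leg2), _flip(leg1)).set_index("event_id")["pattern"]
    assert (reversed_time == fwd).all()


def test_venn_recovery_warns_on_disjoint_universes():
    leg1 = _diff_frame({"e1": "IncIR", "e2": "IncIR"})
    leg2 = _diff_frame({"e1": "DecIR", "e9": "DecIR"})
    with pytest.warns(UserWarning, match="universes differ"):
        calls = venn_recovery(leg1, leg2)
    assert list(calls["event_id"]) == ["e1"]


def test_anova_flat_trajectory_is_null():
    res = anova_trajectory(
        [0.3, 0.5, 0.4, 0.3, 0.5, 0.4, 0.3, 0.5, 0.4],
        ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
    )
    assert res.p > 0.9
    assert res.F == pytest.approx(0.0, abs=1e-12)


def test_anova_matches_sum_of_squares_oracle():
    groups = ([1, 2, 3], [2, 3, 4], [5, 6, 7])
    vals = np.concatenate(groups).astype(float)
    labels = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
    res = anova_trajectory(vals, labels)
    assert res.F == pytest.approx(anova_f_oracle(*groups), abs=1e-10)
    # Tukey table covers the three pairs with adjusted p in [0, 1]
    assert len(res.tukey) == 3
    assert res.tukey["p_adj"].between(0, 1).all()


def test_anova_missing_group_raises():
    with pytest.raises(ValueError):
        anova_trajectory([0.1, 0.2, np.nan, np.nan, 0.3, 0.4], ["a", "a", "b", "b", "c", "c"])


def test_tukey_dominates_unadjusted_t(rng):
    """Tukey-adjusted pairwise p-values are never below the unadjusted
    pooled-variance pairwise comparison p on the same pair."""
    from scipy.stats import t as t_dist

    for _ in range(20):
        g = [rng.normal(rng.uniform(0, 1), 1, 5) for _ in range(3)]
        vals = np.concatenate(g)
        labels = np.repeat(["a", "b", "c"], 5)
        res = anova_trajectory(vals, labels)
        mse = np.mean([np.var(x, ddof=1) for x in g])  # balanced pooled MSE
        df_w = len(vals) - 3
        pairs = [(0, 1), (0, 2), (1, 2)]
        for (i, j), p_adj in zip(pairs, res.tukey["p_adj"]):
            t_stat = (np.mean(g[i]) - np.mean(g[j])) / np.sqrt(mse * (2 / 5))
            p_raw = 2 * t_dist.sf(abs(t_stat), df_w)
            assert p_adj >= p_raw - 1e-9


def test_anova_p_matches_permutation_null():
    """The F-distribution p agrees with a 10,000-draw permutation p within
    Monte-Carlo error on a small balanced example."""
    rng = np.random.default_rng(11)
    g = [rng.normal(0.3, 0.1, 4), rng.normal(0.45, 0.1, 4), rng.normal(0.35, 0.1, 4)]
    vals = np.concatenate(g)
    labels = np.repeat(["a", "b", "c"], 4)
    res = anova_trajectory(vals, labels)
    n_perm, hits = 10000, 0
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        f_perm = anova_f_oracle(perm[:4], perm[4:8], perm[8:])
        hits += f_perm >= res.F - 1e-12
    assert abs(hits / n_perm - res.p) < 0.02


def test_recovery_summary_counts():
    calls = pd.DataFrame(
        {"event_id": [f"e{i}" for i in range(10)],
         "pattern": ["reverse_V"] * 3 + ["V"] * 2 + ["none"] * 5}
    )
    s = recovery_summary(calls)
    assert s["counts"] == {"reverse_V": 3, "V": 2, "none": 5}
    assert sum(s["counts"].values()) == s["n_events"] == 10
    all_none = calls.assign(pattern="none")
    s0 = recovery_summary(all_none)
    assert (s0["fractions"]["reverse_V"], s0["fractions"]["V"], s0["fractions"]["none"]) == (0, 0, 1)
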