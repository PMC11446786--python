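"""Cross-study gene-set overlap: fold enrichment and Fisher/hypergeometric p.

With sets of sizes n_a and n_b drawn from a background universe of N genes,
the expected overlap under independence is n_a n_b / N; fold enrichment is
the observed overlap k divided by that expectation.  The one-sided
significance of the overlap is the upper-tail hypergeometric probability
P(X >= k), equivalently a one-sided Fisher exact test on the 2x2 table.
"""

from __future__ import annotations

from scipy.stats import fisher_exact, hypergeom

from .containers import OverlapResult

__all__ = ["fold_enrichment", "fisher_overlap", "overlap_result", "venn3"]


def _check_table(n_a: int, n_b: int, k: int, background_n: int) -> None:
    if k < 0 or k > min(n_a, n_b):
        raise ValueError("overlap k must lie in [0, min(n_a, n_b)]")
    if n_a > background_n or n_b > background_n:
        raise ValueError("set sizes cannot exceed the background")
    if background_n - n_a - n_b + k < 0:
        raise ValueError("contingency table has a negative cell")


def fold_enrichment(n_a: int, n_b: int, k: int, background_n: int) -> float:
    """Observed / expected overlap: k * N / (n_a * n_b)."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("set sizes must be positive")
    _check_table(n_a, n_b, k, background_n)
    return k * background_n / (n_a * n_b)


def fisher_overlap(n_a: int, n_b: int, k: int, background_n: int, sided: str = "greater") -> float:
    """Fisher exact / hypergeometric p for the overlap of two sets.

    ``greater`` is the upper-tail hypergeometric P(X >= k) (enrichment);
    ``two`` sums the probabilities of all tables at most as likely as the
    observed one.
    """
    _check_table(n_a, n_b, k, background_n)
    if sided == "greater":
        return float(hypergeom.sf(k - 1, background_n, n_a, n_b))
    if sided == "two":
        table = [[k, n_a - k], [n_b - k, background_n - n_a - n_b + k]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"sided must be 'greater' or 'two', got {sided!r}")


def overlap_result(set_a, set_b, background_n: int, sided: str = "greater") -> OverlapResult:
    """Full overlap statistics for two explicit gene sets."""
    a, b = set(set_a), set(set_b)
    k = len(a & b)
    expected = len(a) * len(b) / background_n
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        k=k,
        background_n=background_n,
        expected=expected,
        fold_enrichment=fold_enrichment(len(a), len(b), k, background_n),
        fisher_p=fisher_overlap(len(a), len(b), k, background_n, sided=sided),
    )


def venn3(set_a, set_b, set_c) -> dict:
    """Exact counts of the 7 exclusive Venn regions of three sets.

    Returns a dict with keys ``a_only, b_only, c_only, ab_only, ac_only,
    bc_only, abc`` plus derived totals: per-set sizes, pairwise and triple
    overlaps, and per-set counts of members shared with at least one other
    set.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    regions = {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(abc),
    }
    regions["n_a"], regions["n_b"], regions["n_c"] = len(a), len(b), len(c)
    regions["ab"] = len(a & b)
    regions["ac"] = len(a & c)
    regions["bc"] = len(b & c)
    regions["shared_a"] = len(a & (b | c))
    regions["shared_b"] = len(b & (a | c))
    regions["shared_c"] = len(c & (a | b))
    return regions
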