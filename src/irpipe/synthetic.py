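"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is seeded and deterministic: the same scenario and seed
produce bit-identical tables.  Ground truth (planted psi values, effect
labels, fold changes, excess edges, exact Venn regions) is returned
alongside the data so parameter-recovery tests can score the pipeline.

The default IR scenario mirrors a small case/control blood-transcriptome
design: 6 control and 8 case subjects, with an optional third post-treatment
arm of 8 paired with the cases.  Inclusion counts are beta-binomially
overdispersed around group psi (intra-class correlation rho), junction depth
is negative-binomial, and planted events shift psi in the case group only —
so in a three-arm scenario planted increases trace a reverse-V trajectory
(baseline, up, back) and planted decreases a V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountMatrix, Interactome, IRCountTable

__all__ = [
    "IRScenario",
    "SimulatedTruth",
    "simulate_ir_counts",
    "simulate_expression",
    "simulate_interactome",
    "build_sets_with_overlap",
]


@dataclass(frozen=True)
class IRScenario:
    """Parameters of a simulated intron-retention experiment.

    Planted effects apply to the second group; any later groups revert to
    baseline psi (the drug-recovery shape). ``overdispersion_rho`` is the
    intra-class correlation of the beta-binomial; 0 gives pure binomial
    sampling. ``subject_effect_sd`` adds a shared logit-scale random effect
    to paired samples of groups 2 and 3 when those arms have equal size.
    """

    n_events: int = 2000
    groups: tuple = (("CON", 6), ("BMT", 8))
    baseline_psi_dist: tuple = (2.0, 6.0)
    frac_inc: float = 0.0
    frac_dec: float = 0.0
    delta_psi: float = 0.3
    overdispersion_rho: float = 0.01
    depth_mean: float = 50.0
    depth_dispersion: float = 0.3
    inclusion_form_len: int = 1
    skip_form_len: int = 1
    subject_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be positive")
        if not (0 <= self.frac_inc and 0 <= self.frac_dec and self.frac_inc + self.frac_dec <= 1):
            raise ValueError("need frac_inc, frac_dec >= 0 with frac_inc + frac_dec <= 1")
        if not (0 <= self.overdispersion_rho < 1):
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if not (0 <= self.delta_psi <= 1):
            raise ValueError("delta_psi must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion < 0:
            raise ValueError("depth parameters must be positive")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        a, b = self.baseline_psi_dist
        if a <= 0 or b <= 0:
            raise ValueError("baseline Beta parameters must be positive")


@dataclass
class SimulatedTruth:
    """Ground truth attached to a simulated dataset."""

    psi_by_group: pd.DataFrame | None = None
    event_labels: pd.Series | None = None
    gene_log2fc: pd.Series | None = None
    planted_edges: list = field(default_factory=list)
    query_set: set = field(default_factory=set)
    target_set: set = field(default_factory=set)

    @property
    def inc_events(self) -> list[str]:
        if self.event_labels is None:
            return []
        return list(self.event_labels.index[self.event_labels == "IncIR"])

    @property
    def dec_events(self) -> list[str]:
        if self.event_labels is None:
            return []
        return list(self.event_labels.index[self.event_labels == "DecIR"])


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_ir_counts(scenario: IRScenario) -> tuple[IRCountTable, SimulatedTruth]:
    """Draw an inclusion/skipping count table under a scenario.

    Per cell, total junction depth n is negative-binomial; inclusion reads
    are beta-binomial(n, theta, rho) with theta the length-adjusted image of
    the group psi. Planted psi shifts are clamped to [0.01, 0.99].
    """
    rng = np.random.default_rng(scenario.seed)
    sc = scenario
    n_ev = sc.n_events
    a0, b0 = sc.baseline_psi_dist
    psi0 = np.clip(rng.beta(a0, b0, n_ev), 0.01, 0.99)

    n_inc = int(round(sc.frac_inc * n_ev))
    n_dec = int(round(sc.frac_dec * n_ev))
    perm = rng.permutation(n_ev)
    inc_idx = perm[:n_inc]
    dec_idx = perm[n_inc : n_inc + n_dec]
    labels = np.array(["null"] * n_ev, dtype=object)
    labels[inc_idx] = "IncIR"
    labels[dec_idx] = "DecIR"

    group_labels = [g for g, _ in sc.groups]
    psi_groups = np.tile(psi0[:, None], (1, len(sc.groups)))
    psi_case = psi0.copy()
    psi_case[inc_idx] = np.clip(psi0[inc_idx] + sc.delta_psi, 0.01, 0.99)
    psi_case[dec_idx] = np.clip(psi0[dec_idx] - sc.delta_psi, 0.01, 0.99)
    psi_groups[:, 1] = psi_case

    event_ids = [f"EV{i + 1:06d}" for i in range(n_ev)]
    events = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:06d}" for i in range(n_ev)],
            "gene_symbol": [f"GENE{i + 1:06d}" for i in range(n_ev)],
            "chrom": "chr1",
            "strand": "+",
            "intron_start": np.arange(n_ev) * 1000,
            "intron_end": np.arange(n_ev) * 1000 + 500,
            "inclusion_form_len": sc.inclusion_form_len,
            "skip_form_len": sc.skip_form_len,
        },
        index=pd.Index(event_ids, name="event_id"),
    )

    paired = (
        sc.subject_effect_sd > 0
        and len(sc.groups) >= 3
        and sc.groups[1][1] == sc.groups[2][1]
    )
    subject_u = (
        rng.normal(0.0, sc.subject_effect_sd, size=sc.groups[1][1]) if paired else None
    )

    li, ls = sc.inclusion_form_len, sc.skip_form_len
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    inc_cols = []
    skip_cols = []
    for gi, (label, n_samp) in enumerate(sc.groups):
        psi_g = psi_groups[:, gi]
        for j in range(n_samp):
            sample_ids.append(f"{label}_{j + 1}")
            sample_groups.append(label)
            psi_cell = psi_g
            if paired and gi in (1, 2):
                psi_cell = _expit(_logit(psi_g) + subject_u[j])
            theta = psi_cell * li / (psi_cell * li + (1 - psi_cell) * ls)
            n = _draw_depth(rng, sc.depth_mean, sc.depth_dispersion, n_ev)
            rho = sc.overdispersion_rho
            if rho < 1e-12:
                I = rng.binomial(n, theta)
            else:
                c = (1 - rho) / rho
                p = rng.beta(theta * c, (1 - theta) * c)
                I = rng.binomial(n, p)
            inc_cols.append(I)
            skip_cols.append(n - I)

    inclusion = pd.DataFrame(
        np.column_stack(inc_cols), index=events.index, columns=sample_ids
    )
    skipping = pd.DataFrame(
        np.column_stack(skip_cols), index=events.index, columns=sample_ids
    )
    samples = pd.Series(sample_groups, index=pd.Index(sample_ids, name="sample_id"), name="group")
    table = IRCountTable(events=events, samples=samples, inclusion=inclusion, skipping=skipping)
    truth = SimulatedTruth(
        psi_by_group=pd.DataFrame(psi_groups, index=events.index, columns=group_labels),
        event_labels=pd.Series(labels, index=events.index, name="label"),
    )
    return table, truth


def simulate_expression(
    n_genes: int,
    groups=(("CON", 6), ("BMT", 8)),
    frac_de: float = 0.0,
    log2fc: float = 1.0,
    dispersion: float = 0.1,
    lib_sizes=None,
    seed: int = 0,
    mean_expression: float = 100.0,
) -> tuple[CountMatrix, SimulatedTruth]:
    """Negative-binomial gene counts with library-size and fold-change structure.

    Gene base means are lognormal with median ``mean_expression``; planted DE
    genes (fraction ``frac_de``) are split evenly up/down by ``log2fc`` in
    the second group. ``lib_sizes`` are relative sequencing-depth multipliers,
    one per sample (default all 1).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_samples = sum(n for _, n in groups)
    if lib_sizes is None:
        lib_sizes = np.ones(n_samples)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if len(lib_sizes) != n_samples or (lib_sizes <= 0).any():
        raise ValueError("need one positive lib_size per sample")

    base = rng.lognormal(np.log(mean_expression), 1.0, n_genes)
    n_de = int(round(frac_de * n_genes))
    n_up = n_de // 2 + (n_de % 2)
    perm = rng.permutation(n_genes)
    up_idx, dn_idx = perm[:n_up], perm[n_up:n_de]
    true_lfc = np.zeros(n_genes)
    true_lfc[up_idx] = log2fc
    true_lfc[dn_idx] = -log2fc

    gene_ids = [f"GENE{i + 1:06d}" for i in range(n_genes)]
    r = 1.0 / dispersion
    cols = {}
    sample_groups = []
    si = 0
    for gi, (label, n_samp) in enumerate(groups):
        mean_g = base * (2.0**true_lfc) if gi == 1 else base
        for j in range(n_samp):
            mu = mean_g * lib_sizes[si]
            cols[f"{label}_{j + 1}"] = rng.negative_binomial(r, r / (r + mu))
            sample_groups.append(label)
            si += 1
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    groups_s = pd.Series(sample_groups, index=pd.Index(counts.columns, name="sample_id"), name="group")
    truth = SimulatedTruth(gene_log2fc=pd.Series(true_lfc, index=counts.index, name="log2fc"))
    return CountMatrix(counts=counts, groups=groups_s), truth


def simulate_interactome(
    n_genes: int,
    edge_prob: float,
    query_set_size: int,
    target_set_size: int,
    excess_edge_prob: float = 0.0,
    seed: int = 0,
) -> tuple[Interactome, SimulatedTruth]:
    """Erdos-Renyi interactome with planted query-target excess connectivity.

    Background edges appear independently at ``edge_prob`` over all node
    pairs; additional query-target edges are layered in at
    ``excess_edge_prob``. Every retained edge carries a confidence score
    drawn uniformly on [0.7, 1.0], so the default 0.7 cutoff keeps all.
    """
    for p in (edge_prob, excess_edge_prob):
        if not 0 <= p <= 1:
            raise ValueError("edge probabilities must lie in [0, 1]")
    if query_set_size + target_set_size > n_genes:
        raise ValueError("query and target sets must fit disjointly in the gene universe")
    rng = np.random.default_rng(seed)
    nodes = [f"P{i + 1:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    query = {nodes[i] for i in perm[:query_set_size]}
    target = {nodes[i] for i in perm[query_set_size : query_set_size + target_set_size]}

    iu, ju = np.triu_indices(n_genes, k=1)
    present = rng.random(iu.size) < edge_prob
    edges = {(min(nodes[i], nodes[j]), max(nodes[i], nodes[j])) for i, j in zip(iu[present], ju[present])}

    planted = []
    if excess_edge_prob > 0:
        q_sorted, t_sorted = sorted(query), sorted(target)
        draws = rng.random((len(q_sorted), len(t_sorted)))
        for qi, q in enumerate(q_sorted):
            for ti, t in enumerate(t_sorted):
                if draws[qi, ti] < excess_edge_prob:
                    e = (min(q, t), max(q, t))
                    if e not in edges:
                        planted.append(e)
                    edges.add(e)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in sorted(edges):
        g.add_edge(u, v, score=float(rng.uniform(0.7, 1.0)))
    truth = SimulatedTruth(planted_edges=planted, query_set=query, target_set=target)
    return Interactome(graph=g, score_cutoff=0.7), truth


def build_sets_with_overlap(background_n: int, region_counts, seed: int = 0):
    """Gene sets over a synthetic universe hitting exact Venn region counts.

    ``region_counts`` is a 3-tuple ``(a_only, b_only, ab)`` for two sets or a
    7-tuple ``(a_only, b_only, c_only, ab_only, ac_only, bc_only, abc)`` for
    three. Returns ``(sets, universe)`` where ``sets`` is a tuple of 2 or 3
    gene sets realizing the requested regions exactly.
    """
    region_counts = tuple(int(c) for c in region_counts)
    if len(region_counts) not in (3, 7):
        raise ValueError("region_counts must have 3 (two sets) or 7 (three sets) entries")
    if any(c < 0 for c in region_counts):
        raise ValueError("region counts must be non-negative")
    if sum(region_counts) > background_n:
        raise ValueError("regions exceed the background universe")
    rng = np.random.default_rng(seed)
    universe = [f"BG{i + 1:06d}" for i in range(background_n)]
    order = rng.permutation(background_n)
    pools = []
    pos = 0
    for c in region_counts:
        pools.append({universe[i] for i in order[pos : pos + c]})
        pos += c
    if len(region_counts) == 3:
        a_only, b_only, ab = pools
        sets = (a_only | ab, b_only | ab)
    else:
        a_, b_, c_, ab_, ac_, bc_, abc_ = pools
        sets = (
            a_ | ab_ | ac_ | abc_,
            b_ | ab_ | bc_ | abc_,
            c_ | ac_ | bc_ | abc_,
        )
    return sets, universe
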