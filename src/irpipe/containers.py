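"""Core in-memory containers shared across the pipeline stages.

The pipeline moves junction counts (inclusion/skipping reads per retained
intron, per sample) through psi quantification, differential testing and
downstream enrichment.  Containers are thin dataclasses around pandas
objects so every stage can be inspected, written to TSV and read back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntronEvent",
    "IRCountTable",
    "PsiMatrix",
    "CountMatrix",
    "Interactome",
    "OverlapResult",
]


@dataclass(frozen=True)
class IntronEvent:
    """One retained-intron event with its effective form lengths.

    ``inclusion_form_len`` (LI) and ``skip_form_len`` (LS) are the effective
    lengths of the intron-retaining and intron-spliced isoform segments that
    a junction read can map to; psi is length-adjusted by their ratio.
    Coordinates are 0-based half-open.
    """

    event_id: str
    gene_id: str = ""
    gene_symbol: str = ""
    chrom: str = ""
    strand: str = "+"
    intron_start: int = 0
    intron_end: int = 1
    inclusion_form_len: int = 1
    skip_form_len: int = 1

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError(f"{self.event_id}: intron_end must exceed intron_start")
        if not (self.inclusion_form_len >= self.skip_form_len >= 1):
            raise ValueError(f"{self.event_id}: need LI >= LS >= 1")


@dataclass
class IRCountTable:
    """Inclusion/skipping junction counts for retained-intron events.

    Attributes
    ----------
    events : pd.DataFrame
        Indexed by ``event_id`` with columns ``gene_id, gene_symbol, chrom,
        strand, intron_start, intron_end, inclusion_form_len, skip_form_len``.
    samples : pd.Series
        Group label per sample_id, in sample order.
    inclusion, skipping : pd.DataFrame
        events x samples integer count matrices (I and S).
    """

    events: pd.DataFrame
    samples: pd.Series
    inclusion: pd.DataFrame
    skipping: pd.DataFrame

    def __post_init__(self) -> None:
        for name, mat in (("inclusion", self.inclusion), ("skipping", self.skipping)):
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"{name} counts must be non-negative")
            if not mat.index.equals(self.events.index):
                raise ValueError(f"{name} rows do not match events")
            if list(mat.columns) != list(self.samples.index):
                raise ValueError(f"{name} columns do not match samples")
        if self.samples.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.samples:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        ids = [s for s, g in self.samples.items() if g == group]
        if not ids:
            raise ValueError(f"unknown group label: {group!r}")
        return ids

    def total(self) -> pd.DataFrame:
        """Junction coverage I + S per cell."""
        return self.inclusion + self.skipping


@dataclass
class PsiMatrix:
    """events x samples intron ratios with coverage-filtered missingness.

    A cell is NaN exactly when its junction coverage I + S was at or below
    ``coverage_min`` (strictly more reads than the threshold are required).
    """

    values: pd.DataFrame
    coverage_min: int
    groups: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("psi values must lie in [0, 1]")

    @property
    def n_events(self) -> int:
        return len(self.values)


@dataclass
class CountMatrix:
    """Gene-level raw counts (genes x samples) with group labels.

    ``tmm_factors`` is filled in by normalization; effective library size is
    column sum (or user-stated library size) times the factor.
    """

    counts: pd.DataFrame
    groups: pd.Series
    tmm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.groups.index):
            raise ValueError("count columns do not match sample groups")

    def samples_in_group(self, group: str) -> list[str]:
        ids = [s for s, g in self.groups.items() if g == group]
        if not ids:
            raise ValueError(f"unknown group label: {group!r}")
        return ids

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class Interactome:
    """Score-filtered, canonicalized PPI graph.

    Backed by a :class:`networkx.Graph`; edges carry a ``score`` attribute in
    [0, 1], all at or above ``score_cutoff``.
    """

    graph: "object"
    score_cutoff: float = 0.7

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


@dataclass(frozen=True)
class OverlapResult:
    """Two-set overlap against a finite background universe."""

    n_a: int
    n_b: int
    k: int
    background_n: int
    expected: float
    fold_enrichment: float
    fisher_p: float

    def as_contingency(self) -> np.ndarray:
        """2x2 table (in A? x in B?) over the background."""
        a, b, k, n = self.n_a, self.n_b, self.k, self.background_n
        return np.array([[k, a - k], [b - k, n - a - b + k]])
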