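"""Intron-ratio (psi) quantification, coverage filtering and ordination.

psi is the length-adjusted fraction of transcripts retaining an intron,

    psi = (I / LI) / (I / LI + S / LS)

with I inclusion-supporting junction reads, S skipping-junction reads and
LI / LS the effective form lengths of the retaining / spliced isoforms.
Cells need strictly more than ``coverage_min`` junction reads to yield a
psi estimate; under-covered cells are missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import IRCountTable, PsiMatrix

logger = logging.getLogger(__name__)

__all__ = ["compute_psi", "psi_matrix", "ordinate"]


def compute_psi(I, S, inclusion_form_len=1, skip_form_len=1):
    """Length-adjusted intron ratio; NaN where I + S = 0.

    Accepts scalars or aligned arrays. With LI = LS this reduces to the
    plain read ratio I / (I + S).
    """
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    if (I < 0).any() or (S < 0).any():
        raise ValueError("junction counts must be non-negative")
    li = np.asarray(inclusion_form_len, dtype=float)
    ls = np.asarray(skip_form_len, dtype=float)
    if (li < 1).any() or (ls < 1).any():
        raise ValueError("form lengths must be >= 1")
    inc = I / li
    skip = S / ls
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = inc / (inc + skip)
    psi = np.where(I + S == 0, np.nan, psi)
    if psi.ndim == 0:
        return float(psi)
    return psi


def psi_matrix(table: IRCountTable, coverage_min: int = 10) -> PsiMatrix:
    """Per-cell psi with the coverage filter applied.

    A cell is kept only when I + S > ``coverage_min`` (strict). Events that
    are missing in every sample are dropped from the output.
    """
    if table.n_events == 0:
        raise ValueError("empty count table")
    I = table.inclusion.to_numpy(dtype=float)
    S = table.skipping.to_numpy(dtype=float)
    li = table.events["inclusion_form_len"].to_numpy(dtype=float)[:, None]
    ls = table.events["skip_form_len"].to_numpy(dtype=float)[:, None]
    psi = compute_psi(I, S, li, ls)
    psi = np.where(I + S > coverage_min, psi, np.nan)
    values = pd.DataFrame(psi, index=table.events.index, columns=table.inclusion.columns)
    keep = ~values.isna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("psi_matrix: dropped %d events missing in all samples", n_dropped)
    return PsiMatrix(values=values.loc[keep], coverage_min=coverage_min, groups=table.samples.copy())


def _complete_sample_matrix(matrix: PsiMatrix) -> np.ndarray:
    """samples x events array of the events observed in every sample."""
    complete = matrix.values.dropna(axis=0, how="any")
    return complete.to_numpy().T, list(matrix.values.columns)


def ordinate(matrix: PsiMatrix, method: str = "pca", n_components: int = 2):
    """Sample ordination on the complete-event psi matrix.

    PCA projects samples onto the top principal components of the
    column-centered psi profile matrix (via :class:`sklearn.decomposition.PCA`);
    MDS is classical scaling (principal coordinates) of the pairwise Euclidean
    distances between sample profiles. Events with any missing psi are
    dropped rather than imputed.

    Returns
    -------
    coords : pd.DataFrame
        samples x components.
    explained : np.ndarray or None
        Explained-variance fractions (PCA only).
    """
    X, sample_ids = _complete_sample_matrix(matrix)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for ordination")
    if X.shape[1] < n_components:
        raise ValueError(
            f"only {X.shape[1]} complete events for {n_components} components"
        )
    method = method.lower()
    if method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=n_components, svd_solver="full")
        coords = pca.fit_transform(X)
        explained = pca.explained_variance_ratio_
    elif method == "mds":
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa

        dm = DistanceMatrix(squareform(pdist(X)), ids=sample_ids)
        res = pcoa(dm, number_of_dimensions=n_components)
        coords = res.samples.to_numpy()[:, :n_components]
        explained = None
    else:
        raise ValueError(f"unknown ordination method: {method!r}")
    cols = [f"{method.upper()}{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=pd.Index(sample_ids, name="sample_id"), columns=cols), explained
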