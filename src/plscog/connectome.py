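"""Connectome construction and edge vectorization.

A connectome here is a region-by-region matrix of Pearson correlations
between ROI time series, one matrix per subject and imaging modality
(hemodynamic for BOLD-fMRI, metabolic for FDG-fPET). For multivariate
analysis the upper triangle of each matrix is flattened into a fixed-order
edge vector; the edge order is strict row-major upper triangle (i < j,
0-based) and is identical across subjects and modalities, which is the
alignment the cross-modality comparisons rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import ParcellationSpec

SYMMETRY_TOL = 1e-10


def n_edges_for(n_regions: int) -> int:
    """Number of distinct region pairs, R(R-1)/2."""
    return n_regions * (n_regions - 1) // 2


def edge_index_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Upper-triangle (i, j) pairs, i < j, in row-major order."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def compute_connectivity(ts: pd.DataFrame) -> np.ndarray:
    """Pearson correlation matrix between region time series.

    Parameters
    ----------
    ts : pandas.DataFrame
        Rows are timepoints, columns are regions (header = region labels).

    Returns
    -------
    numpy.ndarray
        Symmetric R x R matrix with unit diagonal.

    Raises
    ------
    ValueError
        If fewer than 3 timepoints, any missing value (no silent
        imputation), or any region has zero temporal variance (its
        correlations are undefined); the error names the region.
    """
    values = np.asarray(ts, dtype=float)
    if values.shape[0] < 3:
        raise ValueError(f"need >= 3 timepoints, got {values.shape[0]}")
    if np.isnan(values).any():
        bad = [str(c) for c, has in zip(ts.columns, np.isnan(values).any(axis=0)) if has]
        raise ValueError(f"missing values in region(s) {bad}; impute or drop first")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [str(c) for c, s in zip(ts.columns, sd) if s == 0]
        raise ValueError(
            f"region(s) {bad} have zero temporal variance; correlation undefined"
        )
    if values.shape[1] == 1:
        return np.ones((1, 1))
    mat = np.corrcoef(values, rowvar=False)
    # enforce exact symmetry / unit diagonal against float round-off
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return mat


@dataclass
class ConnectomeStack:
    """Per-subject connectivity matrices for one modality.

    Parameters
    ----------
    modality : str
        ``hemodynamic``, ``metabolic`` or any other tag.
    matrices : numpy.ndarray
        Shape (n_subjects, R, R); each slice symmetric with unit diagonal.
    subject_ids : list
        Ordered subject identifiers, one per slice.
    strict : bool
        When True (default) the off-diagonal entries must lie in [-1, 1]
        and diagonals equal 1 — the contract for genuine correlation
        matrices. Synthetic edge data on an unbounded correlation-like
        scale may use ``strict=False``.
    """

    modality: str
    matrices: np.ndarray
    subject_ids: list = field(default_factory=list)
    strict: bool = True

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError(
                f"matrices must be (n_subjects, R, R), got {self.matrices.shape}"
            )
        if not self.subject_ids:
            self.subject_ids = list(range(self.matrices.shape[0]))
        if len(self.subject_ids) != self.matrices.shape[0]:
            raise ValueError("subject_ids length does not match matrices")
        asym = np.abs(self.matrices - self.matrices.transpose(0, 2, 1)).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrices asymmetric beyond tolerance: {asym:.3g}")
        if self.strict:
            diag = np.diagonal(self.matrices, axis1=1, axis2=2)
            if np.abs(diag - 1.0).max() > SYMMETRY_TOL:
                raise ValueError("diagonals must equal 1")
            off = self.matrices.copy()
            for m in off:
                np.fill_diagonal(m, 0.0)
            if np.abs(off).max() > 1.0 + 1e-12:
                raise ValueError("off-diagonal entries must lie in [-1, 1]")

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


@dataclass
class EdgeVectorSet:
    """Subjects-by-edges matrix with its column-to-region-pair map."""

    values: np.ndarray
    edge_index: list[tuple[int, int]]
    subject_ids: list = field(default_factory=list)
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x edges)")
        if self.values.shape[1] != len(self.edge_index):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.edge_index)} edges indexed"
            )
        if not self.subject_ids:
            self.subject_ids = list(range(self.values.shape[0]))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def n_regions(self) -> int:
        return max(j for _, j in self.edge_index) + 1 if self.edge_index else 0


def vectorize(stack: ConnectomeStack) -> EdgeVectorSet:
    """Flatten each subject's upper triangle into an edge row.

    82 regions give 3,321 edge columns. The inverse is :func:`devectorize`.
    """
    r = stack.n_regions
    iu, ju = np.triu_indices(r, k=1)
    values = stack.matrices[:, iu, ju]
    return EdgeVectorSet(
        values=values,
        edge_index=list(zip(iu.tolist(), ju.tolist())),
        subject_ids=list(stack.subject_ids),
        modality=stack.modality,
    )


def devectorize(edges: np.ndarray, n_regions: int) -> np.ndarray:
    """Rebuild a symmetric matrix from one edge vector.

    The diagonal is set to 0 and is undefined for edge-level quantities
    such as loadings (a region has no self-edge).
    """
    edges = np.asarray(edges, dtype=float).ravel()
    expected = n_edges_for(n_regions)
    if edges.size != expected:
        raise ValueError(
            f"edge vector length {edges.size}, expected {expected} for {n_regions} regions"
        )
    mat = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    mat[iu, ju] = edges
    mat[ju, iu] = edges
    return mat


def lobe_of_edge(edge: tuple[int, int], parcellation: ParcellationSpec) -> tuple[str, str]:
    """Lobes of an edge's two endpoints, in stored order."""
    i, j = edge
    return parcellation.lobe_of(i), parcellation.lobe_of(j)


def stack_from_timeseries(
    tables: list[pd.DataFrame],
    modality: str,
    subject_ids: list | None = None,
) -> ConnectomeStack:
    """Compute per-subject connectivity matrices from ROI time-series tables."""
    if not tables:
        raise ValueError("no time-series tables supplied")
    cols = list(tables[0].columns)
    for k, t in enumerate(tables[1:], start=1):
        if list(t.columns) != cols:
            raise ValueError(f"subject {k} region columns differ from subject 0")
    matrices = np.stack([compute_connectivity(t) for t in tables])
    return ConnectomeStack(
        modality=modality,
        matrices=matrices,
        subject_ids=subject_ids or list(range(len(tables))),
    )


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform, arctanh(r). Off by default in the pipeline;
    the analysis z-scores edge columns across subjects instead."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("|r| >= 1 maps to infinity under the Fisher transform")
    return np.arctanh(r)
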