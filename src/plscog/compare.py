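"""Cross-modality comparison of PLS solutions.

Quantifies how two modality-specific connectome-cognition mappings agree:
the cosine (unit-normalized scalar product) between their saliences, a
region-by-region Pearson similarity matrix between their devectorized
loading matrices, top-percentile edge selection and anatomical (lobe)
attribution of the strongest loadings, and a concatenated-modality PLS in
which both edge blocks enter a single decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import devectorize, n_edges_for
from .parcellation import LOBES, ParcellationSpec
from .pls import PLSCorrelation, PLSCorrelationResults


def salience_cosine(a, b, normalize: bool = True) -> float:
    """Scalar product of two salience vectors, unit-normalized by default.

    1 means identical direction, 0 orthogonality, -1 opposition. With
    ``normalize=False`` the raw dot product is returned (equal to the
    cosine when both inputs are exact singular vectors, which have unit
    norm already).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("salience vectors must be nonzero")
    dot = float(a @ b)
    if not normalize:
        return dot
    # the true cosine lies in [-1, 1]; clamp float round-off at the endpoints
    return float(np.clip(dot / (na * nb), -1.0, 1.0))


def region_loading_similarity(
    loadings_a: np.ndarray,
    loadings_b: np.ndarray,
    parcellation: ParcellationSpec | int,
) -> np.ndarray:
    """Region-by-region Pearson similarity between two edge-loading maps.

    Each modality's edge-loading vector is devectorized to its symmetric
    R x R loading matrix; entry (i, j) of the output correlates region i's
    loading profile in modality A with region j's profile in modality B.
    The undefined diagonal entries are masked: positions i and j are
    excluded from both profiles (for i = j just the diagonal position), so
    the compared profiles cover the same region pairs.

    similarity(A, A) has unit diagonal; similarity(A, B) = similarity(B, A)'.
    """
    r = parcellation if isinstance(parcellation, int) else parcellation.n_regions
    a = np.asarray(loadings_a, dtype=float).ravel()
    b = np.asarray(loadings_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"edge-index mismatch: {a.size} vs {b.size} edges")
    if a.size != n_edges_for(r):
        raise ValueError(f"expected {n_edges_for(r)} edges for {r} regions, got {a.size}")
    mat_a = devectorize(a, r)
    mat_b = devectorize(b, r)
    out = np.empty((r, r))
    for i in range(r):
        for j in range(r):
            mask = np.ones(r, dtype=bool)
            mask[[i, j]] = False
            pa = mat_a[i, mask]
            pb = mat_b[j, mask]
            pa = pa - pa.mean()
            pb = pb - pb.mean()
            denom = np.linalg.norm(pa) * np.linalg.norm(pb)
            out[i, j] = float(pa @ pb) / denom if denom > 0 else np.nan
    return out


def coefficient_histogram(similarity: np.ndarray, n_bins: int = 20) -> tuple:
    """Histogram of similarity coefficients over [-1, 1]: (edges, counts)."""
    vals = np.asarray(similarity, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    counts, edges = np.histogram(vals, bins=n_bins, range=(-1.0, 1.0))
    return edges, counts


def top_percentile_edges(
    loadings: np.ndarray, percentile: float = 99.0, absolute: bool = False
) -> np.ndarray:
    """Indices of edges at or above the given loading percentile.

    Operates on signed loadings by default (the strongest positive
    contributors); ``absolute=True`` ranks by magnitude. Ties at the cutoff
    are all included. ``percentile=0`` selects every edge.
    """
    vals = np.asarray(loadings, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty loading vector")
    if not 0 <= percentile < 100:
        raise ValueError("percentile must lie in [0, 100)")
    ranked = np.abs(vals) if absolute else vals
    cutoff = np.percentile(ranked, percentile)
    return np.flatnonzero(ranked >= cutoff)


def lobe_attribution(
    edge_subset: list[tuple[int, int]],
    parcellation: ParcellationSpec,
    mode: str = "regions",
) -> dict[str, float]:
    """Fraction of an edge subset attributable to each anatomical lobe.

    ``mode="regions"`` (default): the fraction of *distinct regions*
    incident to the subset that fall in each lobe — the reading consistent
    with published attribution percentages. ``mode="endpoints"``: the
    fraction of edge endpoints per lobe. Fractions sum to 1 either way.
    """
    if not edge_subset:
        raise ValueError("empty edge subset")
    if mode not in ("regions", "endpoints"):
        raise ValueError(f"unknown mode {mode!r}")
    lobes = parcellation.lobes
    counts = dict.fromkeys(LOBES, 0)
    if mode == "regions":
        regions = sorted({idx for edge in edge_subset for idx in edge})
        for idx in regions:
            counts[lobes[idx]] += 1
        total = len(regions)
    else:
        for i, j in edge_subset:
            counts[lobes[i]] += 1
            counts[lobes[j]] += 1
        total = 2 * len(edge_subset)
    return {lobe: counts[lobe] / total for lobe in LOBES}


@dataclass
class SimilarityResult:
    """Cross-modality agreement summary for one LV pair."""

    brain_salience_cosine: float
    behavior_salience_cosine: float
    behavior_salience_dot: float
    region_similarity: np.ndarray
    histogram_bin_edges: np.ndarray
    histogram_counts: np.ndarray


def compare_modalities(
    results_a: PLSCorrelationResults,
    results_b: PLSCorrelationResults,
    parcellation: ParcellationSpec | int,
    lv: int = 0,
) -> SimilarityResult:
    """Full similarity report between two fitted modality solutions."""
    u_a = results_a.brain_saliences[:, lv]
    u_b = results_b.brain_saliences[:, lv]
    v_a = results_a.behavior_saliences[:, lv]
    v_b = results_b.behavior_saliences[:, lv]
    sim = region_loading_similarity(
        results_a.brain_loadings[:, lv], results_b.brain_loadings[:, lv], parcellation
    )
    edges, counts = coefficient_histogram(sim)
    return SimilarityResult(
        brain_salience_cosine=salience_cosine(u_a, u_b),
        behavior_salience_cosine=salience_cosine(v_a, v_b),
        behavior_salience_dot=salience_cosine(v_a, v_b, normalize=False),
        region_similarity=sim,
        histogram_bin_edges=edges,
        histogram_counts=counts,
    )


@dataclass
class ConcatenatedPLS:
    """PLS of two column-concatenated modality blocks against cognition."""

    results: PLSCorrelationResults
    modality_of_column: np.ndarray  # 0 for block A, 1 for block B
    modality_names: tuple[str, str]

    def salience_mass_by_modality(self, lv: int = 0) -> dict[str, float]:
        """Squared-salience mass of an LV in each modality's half."""
        u = self.results.brain_saliences[:, lv]
        total = float(np.sum(u**2))
        out = {}
        for tag, name in enumerate(self.modality_names):
            out[name] = float(np.sum(u[self.modality_of_column == tag] ** 2)) / total
        return out


def concatenated_pls(
    edges_a,
    edges_b,
    cognition,
    scale: str = "correlation",
    modality_names: tuple[str, str] = ("A", "B"),
) -> ConcatenatedPLS:
    """Fit one PLS on the column-wise concatenation of two edge blocks.

    Both blocks must hold the same subjects in the same order and share an
    edge index; the fitted brain saliences carry a modality tag per column.
    """
    a = np.asarray(getattr(edges_a, "values", edges_a), dtype=float)
    b = np.asarray(getattr(edges_b, "values", edges_b), dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"subject mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"edge-index mismatch: {a.shape[1]} vs {b.shape[1]} edges")
    idx_a = getattr(edges_a, "edge_index", None)
    idx_b = getattr(edges_b, "edge_index", None)
    if idx_a is not None and idx_b is not None and list(idx_a) != list(idx_b):
        raise ValueError("edge indices differ between modalities")
    stacked = np.hstack([a, b])
    model = PLSCorrelation(brain=stacked, cognition=cognition, scale=scale)
    tags = np.repeat([0, 1], a.shape[1])
    return ConcatenatedPLS(
        results=model.fit(), modality_of_column=tags, modality_names=modality_names
    )
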