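"""Resampling inference for PLS correlation.

Two procedures, both seeded and chunk-invariant:

* permutation test — Y rows are re-paired with X rows uniformly at random
  and the singular values of the recomputed cross-block matrix form the
  null distribution; each LV's p-value is the add-one exceedance fraction
  (1 + #{s_perm >= s_obs}) / (1 + n_iterations).
* bootstrap — subjects are resampled with replacement jointly in X and Y,
  the PLS refit, resampled LVs aligned to the original solution, and the
  loadings recomputed; percentile confidence intervals that exclude zero
  flag a loading as reliable.

Per-iteration random generators are derived from a spawned seed sequence,
so results are identical whether iterations run serially or in chunks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pls import (
    column_score_correlations,
    cross_block,
    decompose,
    zscore_columns,
)

_MAX_REDRAWS = 10


def _iteration_rngs(seed: Optional[int], n_iterations: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_iterations)]


def _procrustes_rotation(basis: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal W minimizing ||target - basis @ W||_F."""
    a, _, bt = np.linalg.svd(basis.T @ target, full_matrices=False)
    return a @ bt


@dataclass
class PermutationResult:
    p_values: np.ndarray
    null_singular_values: np.ndarray  # n_iterations x n_lv
    observed_singular_values: np.ndarray
    n_iterations: int
    seed: Optional[int]
    alignment: str


def permutation_test(
    x,
    y,
    n_iterations: int = 5000,
    seed: Optional[int] = None,
    alignment: str = "none",
    chunk_size: Optional[int] = None,
    scale: str = "correlation",
    observed_singular_values: Optional[np.ndarray] = None,
    observed_v: Optional[np.ndarray] = None,
) -> PermutationResult:
    """Permutation significance of each latent variable.

    ``alignment="none"`` (default) compares the k-th permuted singular value
    with the k-th observed one; ``"procrustes"`` first rotates each permuted
    solution onto the observed behavior-salience basis, which guards against
    axis swapping among near-degenerate LVs.
    """
    if alignment not in ("none", "procrustes"):
        raise ValueError(f"unknown alignment {alignment!r}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need >= 4 subjects")
    x_z = zscore_columns(x)
    y_z = zscore_columns(y)  # raises on constant column
    if n <= 12 and n_iterations > math.factorial(n):
        warnings.warn(
            f"n_iterations={n_iterations} exceeds the {math.factorial(n)} distinct "
            "permutations of {n} subjects; the null distribution will repeat"
        )
    if observed_singular_values is None or (
        alignment == "procrustes" and observed_v is None
    ):
        s_obs, _, v_obs = decompose(cross_block(x_z, y_z, scale=scale))
        observed_singular_values = s_obs
        if observed_v is None:
            observed_v = v_obs
    s_obs = np.asarray(observed_singular_values, dtype=float)
    n_lv = len(s_obs)

    null = np.empty((n_iterations, n_lv))
    rngs = _iteration_rngs(seed, n_iterations)
    step = chunk_size or n_iterations
    for start in range(0, n_iterations, step):
        for it in range(start, min(start + step, n_iterations)):
            perm = rngs[it].permutation(n)
            r_perm = cross_block(x_z, y_z[perm], scale=scale)
            if alignment == "none":
                null[it] = np.linalg.svd(r_perm, compute_uv=False)[:n_lv]
            else:
                u_p, s_p, vt_p = np.linalg.svd(r_perm, full_matrices=False)
                w = _procrustes_rotation(vt_p.T, observed_v)
                rotated = (u_p * s_p) @ w
                null[it] = np.linalg.norm(rotated, axis=0)[:n_lv]
    exceed = (null >= s_obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_iterations)
    return PermutationResult(
        p_values=p,
        null_singular_values=null,
        observed_singular_values=s_obs,
        n_iterations=n_iterations,
        seed=seed,
        alignment=alignment,
    )


@dataclass
class BootstrapResult:
    behavior_loadings: np.ndarray  # original-sample loadings, variables x LVs
    behavior_ci_low: np.ndarray
    behavior_ci_high: np.ndarray
    behavior_reliable: np.ndarray
    behavior_se: np.ndarray
    behavior_ratio: np.ndarray
    brain_loadings: np.ndarray  # original-sample loadings, edges x LVs
    brain_ci_low: np.ndarray
    brain_ci_high: np.ndarray
    brain_reliable: np.ndarray
    brain_se: np.ndarray
    brain_ratio: np.ndarray
    n_iterations: int
    seed: Optional[int]
    ci_level: float
    alignment: str
    n_redraws: int


def _resample_indices(rng: np.random.Generator, x: np.ndarray, y: np.ndarray) -> tuple:
    """Draw a joint bootstrap resample, redrawing if a column degenerates."""
    n = x.shape[0]
    redraws = 0
    for _ in range(_MAX_REDRAWS + 1):
        idx = rng.integers(0, n, size=n)
        if np.all(x[idx].std(axis=0) > 0) and np.all(y[idx].std(axis=0) > 0):
            return idx, redraws
        redraws += 1
    raise RuntimeError(
        f"bootstrap resample still contains a constant column after {_MAX_REDRAWS} redraws"
    )


def bootstrap_loadings(
    x,
    y,
    n_iterations: int = 5000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
    alignment: str = "sign",
    chunk_size: Optional[int] = None,
    scale: str = "correlation",
    reference_u: Optional[np.ndarray] = None,
    reference_v: Optional[np.ndarray] = None,
    brain_lvs: Optional[Sequence[int]] = None,
) -> BootstrapResult:
    """Bootstrap percentile CIs and reliability flags for PLS loadings.

    ``alignment="sign"`` flips resample LV k when its brain salience points
    away from the original (u_k . u_k^boot < 0); ``"procrustes"`` applies a
    joint orthogonal rotation of the resampled saliences onto the original
    basis. ``brain_lvs`` restricts the LVs for which full brain-loading
    distributions (hence CIs) are kept — edge blocks are large, and
    interpretation usually concerns the significant LV only; SEs and
    bootstrap ratios are kept for every LV regardless.
    """
    if alignment not in ("sign", "procrustes"):
        raise ValueError(f"unknown alignment {alignment!r}")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need >= 4 subjects")

    x_z = zscore_columns(x)
    y_z = zscore_columns(y)
    s0, u0, v0 = decompose(cross_block(x_z, y_z, scale=scale))
    if reference_u is None:
        reference_u = u0
    if reference_v is None:
        reference_v = v0
    lx0 = x_z @ reference_u
    ly0 = y_z @ reference_v
    brain_loadings0 = column_score_correlations(x, lx0)
    behavior_loadings0 = column_score_correlations(y, ly0)

    n_lv = len(s0)
    kept_lvs = list(range(n_lv)) if brain_lvs is None else sorted(set(brain_lvs))
    p_edges, q_vars = x.shape[1], y.shape[1]

    beh_draws = np.empty((n_iterations, q_vars, n_lv))
    brain_draws = np.empty((n_iterations, p_edges, len(kept_lvs)))
    brain_sum = np.zeros((p_edges, n_lv))
    brain_sumsq = np.zeros((p_edges, n_lv))

    rngs = _iteration_rngs(seed, n_iterations)
    total_redraws = 0
    step = chunk_size or n_iterations
    for start in range(0, n_iterations, step):
        for it in range(start, min(start + step, n_iterations)):
            idx, redraws = _resample_indices(rngs[it], x, y)
            total_redraws += redraws
            xb, yb = x[idx], y[idx]
            xb_z = zscore_columns(xb)
            yb_z = zscore_columns(yb)
            _, ub, vb = decompose(cross_block(xb_z, yb_z, scale=scale))
            if alignment == "sign":
                flip = np.sign(np.einsum("ij,ij->j", ub, reference_u))
                flip[flip == 0] = 1.0
                ub = ub * flip
                vb = vb * flip
            else:
                stacked_b = np.vstack([ub, vb])
                stacked_ref = np.vstack([reference_u, reference_v])
                w = _procrustes_rotation(stacked_b, stacked_ref)
                ub = ub @ w
                vb = vb @ w
            lxb = xb_z @ ub
            lyb = yb_z @ vb
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bl = column_score_correlations(xb, lxb)
                vl = column_score_correlations(yb, lyb)
            beh_draws[it] = vl
            brain_draws[it] = bl[:, kept_lvs]
            brain_sum += bl
            brain_sumsq += bl**2

    alpha = 1.0 - ci_level
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)

    beh_lo = np.nanpercentile(beh_draws, lo_q, axis=0)
    beh_hi = np.nanpercentile(beh_draws, hi_q, axis=0)
    beh_se = np.nanstd(beh_draws, axis=0, ddof=1)

    brain_lo = np.full((p_edges, n_lv), np.nan)
    brain_hi = np.full((p_edges, n_lv), np.nan)
    brain_lo[:, kept_lvs] = np.nanpercentile(brain_draws, lo_q, axis=0)
    brain_hi[:, kept_lvs] = np.nanpercentile(brain_draws, hi_q, axis=0)
    brain_mean = brain_sum / n_iterations
    brain_var = (brain_sumsq - n_iterations * brain_mean**2) / (n_iterations - 1) \
        if n_iterations > 1 else np.full_like(brain_mean, np.nan)
    brain_se = np.sqrt(np.clip(brain_var, 0, None))

    with np.errstate(invalid="ignore", divide="ignore"):
        beh_ratio = behavior_loadings0 / beh_se
        brain_ratio = brain_loadings0 / brain_se

    return BootstrapResult(
        behavior_loadings=behavior_loadings0,
        behavior_ci_low=beh_lo,
        behavior_ci_high=beh_hi,
        behavior_reliable=(beh_lo > 0) | (beh_hi < 0),
        behavior_se=beh_se,
        behavior_ratio=beh_ratio,
        brain_loadings=brain_loadings0,
        brain_ci_low=brain_lo,
        brain_ci_high=brain_hi,
        brain_reliable=(brain_lo > 0) | (brain_hi < 0),
        brain_se=brain_se,
        brain_ratio=brain_ratio,
        n_iterations=n_iterations,
        seed=seed,
        ci_level=ci_level,
        alignment=alignment,
        n_redraws=total_redraws,
    )
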