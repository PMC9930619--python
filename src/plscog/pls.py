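"""Partial least squares correlation (PLSC) between a brain block and a
behavior block.

The model: with X the subjects-by-edges connectivity block and Y the
subjects-by-variables cognition block, both z-scored column-wise, the
cross-block matrix R = X'Y (scaled by 1/(n-1) so entries are Pearson r)
is decomposed as R = U S V'. Each latent variable (LV) pairs a brain
salience u_k (weights over edges), a behavior salience v_k (weights over
cognitive variables) and a singular value s_k; s_k^2 over the total gives
the fraction of cross-block covariance the LV explains. Subject scores are
the projections Lx = XU and Ly = YV, and loadings are the Pearson
correlations between original columns and scores — the quantity that is
interpreted and bootstrapped.

This module is deterministic; resampling inference lives in
:mod:`plscog.inference` and is reached through
:meth:`PLSCorrelationResults.permutation_test` and
:meth:`PLSCorrelationResults.bootstrap_loadings`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .battery import CognitiveMatrix
from .connectome import EdgeVectorSet

__all__ = [
    "zscore_columns",
    "cross_block",
    "decompose",
    "covariance_explained",
    "column_score_correlations",
    "PLSCorrelation",
    "PLSCorrelationResults",
]


def zscore_columns(matrix) -> np.ndarray:
    """Column-wise z-score with sample SD (n-1 denominator).

    Raises if any column is constant — run zero-variance screening first.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects-by-variables matrix")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant column(s) at index {bad}; z-score undefined")
    return (x - x.mean(axis=0)) / sd


def cross_block(x_z: np.ndarray, y_z: np.ndarray, scale: str = "correlation") -> np.ndarray:
    """Cross-block matrix R = X'Y between two column-z-scored blocks.

    With ``scale="correlation"`` the product is divided by n-1 so each
    entry is the Pearson r between one X column and one Y column;
    ``scale="unscaled"`` returns the raw product. Singular vectors and
    permutation p-values are identical under either scaling.
    """
    x_z = np.asarray(x_z, dtype=float)
    y_z = np.asarray(y_z, dtype=float)
    if x_z.shape[0] != y_z.shape[0]:
        raise ValueError(
            f"subject counts differ: X has {x_z.shape[0]}, Y has {y_z.shape[0]}"
        )
    r = x_z.T @ y_z
    if scale == "correlation":
        r = r / (x_z.shape[0] - 1)
    elif scale != "unscaled":
        raise ValueError(f"unknown scale {scale!r}")
    return r


def _apply_sign_convention(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Joint flip per LV so the largest-|.| element of v is positive.
    # Joint flipping preserves R = U S V'; SVD signs are otherwise arbitrary.
    u = u.copy()
    v = v.copy()
    for k in range(v.shape[1]):
        anchor = np.argmax(np.abs(v[:, k]))
        if v[anchor, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    return u, v


def decompose(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of the cross-block matrix with a deterministic sign convention.

    Returns (singular_values, U, V) with singular values descending and
    each (u_k, v_k) pair flipped jointly so the element of v_k with the
    largest absolute value is positive.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("cross-block matrix contains NaN or Inf")
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    u, v = _apply_sign_convention(u, vt.T)
    return s, u, v


def covariance_explained(singular_values) -> np.ndarray:
    """Fraction of cross-block covariance per LV: s_k^2 / sum_j s_j^2."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    total = np.sum(s**2)
    if total == 0:
        raise ValueError("all singular values are zero")
    return s**2 / total


def column_score_correlations(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r between every column of ``block`` and every score column.

    This is the loading matrix: entry (j, k) correlates block column j with
    LV k's score. Score columns with zero variance (degenerate LVs) yield
    NaN loadings with a warning.
    """
    x = np.asarray(block, dtype=float)
    sc = np.asarray(scores, dtype=float)
    xc = x - x.mean(axis=0)
    sc_c = sc - sc.mean(axis=0)
    x_sd = xc.std(axis=0, ddof=1)
    s_sd = sc_c.std(axis=0, ddof=1)
    degenerate = s_sd == 0
    if degenerate.any():
        warnings.warn(
            f"LV score column(s) {np.flatnonzero(degenerate).tolist()} have zero "
            "variance; their loadings are undefined (NaN)"
        )
        s_sd = np.where(degenerate, np.nan, s_sd)
    n = x.shape[0]
    cov = xc.T @ sc_c / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cov / np.outer(x_sd, s_sd)
    return out


@dataclass
class PLSCorrelation:
    """PLS correlation model between brain connectivity and cognition.

    Parameters
    ----------
    brain : array-like, pandas.DataFrame or EdgeVectorSet
        Subjects x edges connectivity block (X).
    cognition : array-like, pandas.DataFrame or CognitiveMatrix
        Subjects x variables cognition block (Y).
    scale : {"correlation", "unscaled"}
        Scaling of R = X'Y; ``correlation`` (default) divides by n-1 so
        entries are Pearson r. Saliences and p-values are identical under
        either.

    Examples
    --------
    >>> model = PLSCorrelation(edges.values, cognition.values())
    >>> res = model.fit()
    >>> res.permutation_test(n_iterations=5000, seed=11)
    >>> res.bootstrap_loadings(n_iterations=5000, seed=11)
    >>> print(res.summary(lv=0))
    """

    brain: object
    cognition: object
    scale: str = "correlation"
    edge_index: Optional[list] = None
    edge_names: Optional[Sequence[str]] = None
    variable_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        x, self.edge_index, self.edge_names = self._coerce_brain(self.brain)
        y, self.variable_names = self._coerce_cognition(self.cognition)
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"subject counts differ: brain {x.shape[0]}, cognition {y.shape[0]}"
            )
        if x.shape[0] < 4:
            raise ValueError("need >= 4 subjects")
        self.x = x
        self.y = y

    def _coerce_brain(self, brain):
        if isinstance(brain, EdgeVectorSet):
            names = [f"{i}-{j}" for i, j in brain.edge_index]
            return brain.values.astype(float), list(brain.edge_index), names
        if isinstance(brain, pd.DataFrame):
            return brain.to_numpy(dtype=float), self.edge_index, list(brain.columns)
        arr = np.asarray(brain, dtype=float)
        names = (
            list(self.edge_names)
            if self.edge_names is not None
            else [f"e{k}" for k in range(arr.shape[1])]
        )
        return arr, self.edge_index, names

    def _coerce_cognition(self, cognition):
        if isinstance(cognition, CognitiveMatrix):
            return cognition.values(), cognition.names
        if isinstance(cognition, pd.DataFrame):
            return cognition.to_numpy(dtype=float), list(cognition.columns)
        arr = np.asarray(cognition, dtype=float)
        names = (
            list(self.variable_names)
            if self.variable_names is not None
            else [f"v{k}" for k in range(arr.shape[1])]
        )
        return arr, names

    @classmethod
    def from_dataframes(
        cls, brain: pd.DataFrame, cognition: pd.DataFrame, scale: str = "correlation"
    ) -> "PLSCorrelation":
        return cls(brain=brain, cognition=cognition, scale=scale)

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    def fit(self) -> "PLSCorrelationResults":
        """Z-score both blocks, decompose R = X'Y, project scores, compute
        loadings and covariance explained."""
        x_z = zscore_columns(self.x)
        y_z = zscore_columns(self.y)
        r = cross_block(x_z, y_z, scale=self.scale)
        s, u, v = decompose(r)
        lx = x_z @ u
        ly = y_z @ v
        return PLSCorrelationResults(
            model=self,
            cross_block_matrix=r,
            singular_values=s,
            brain_saliences=u,
            behavior_saliences=v,
            brain_scores=lx,
            behavior_scores=ly,
            brain_loadings=column_score_correlations(self.x, lx),
            behavior_loadings=column_score_correlations(self.y, ly),
            covariance_explained=covariance_explained(s),
        )


@dataclass
class PLSCorrelationResults:
    """Fitted PLS correlation solution plus (optional) resampling inference.

    All LV-indexed arrays are ordered by descending singular value.
    ``p_values`` and the bootstrap fields are None until
    :meth:`permutation_test` / :meth:`bootstrap_loadings` are called.
    """

    model: PLSCorrelation
    cross_block_matrix: np.ndarray
    singular_values: np.ndarray
    brain_saliences: np.ndarray
    behavior_saliences: np.ndarray
    brain_scores: np.ndarray
    behavior_scores: np.ndarray
    brain_loadings: np.ndarray
    behavior_loadings: np.ndarray
    covariance_explained: np.ndarray
    p_values: Optional[np.ndarray] = None
    permutation_null: Optional[np.ndarray] = None
    bootstrap: Optional[object] = field(default=None, repr=False)

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)

    def permutation_test(
        self,
        n_iterations: int = 5000,
        seed: Optional[int] = None,
        alignment: str = "none",
        chunk_size: Optional[int] = None,
    ):
        """Permutation significance of each LV's singular value.

        Y rows are re-paired with X rows uniformly at random; the PLS is
        recomputed per permutation and p(LV_k) is the add-one fraction
        (1 + #{s_k^perm >= s_k}) / (1 + n_iterations). Stores ``p_values``
        and ``permutation_null`` on the results object.
        """
        from .inference import permutation_test as _perm

        out = _perm(
            self.model.x,
            self.model.y,
            n_iterations=n_iterations,
            seed=seed,
            alignment=alignment,
            chunk_size=chunk_size,
            scale=self.model.scale,
            observed_singular_values=self.singular_values,
            observed_v=self.behavior_saliences,
        )
        self.p_values = out.p_values
        self.permutation_null = out.null_singular_values
        return out

    def bootstrap_loadings(
        self,
        n_iterations: int = 5000,
        seed: Optional[int] = None,
        ci_level: float = 0.95,
        alignment: str = "sign",
        chunk_size: Optional[int] = None,
        brain_lvs: Optional[Sequence[int]] = None,
    ):
        """Bootstrap reliability of loadings with percentile CIs.

        Subjects are resampled with replacement jointly in X and Y, the PLS
        is refit, resample LVs are aligned to the original solution, and
        loadings are recomputed. A loading is flagged reliable when its CI
        excludes zero. Stores the result on ``self.bootstrap``.
        """
        from .inference import bootstrap_loadings as _boot

        out = _boot(
            self.model.x,
            self.model.y,
            n_iterations=n_iterations,
            seed=seed,
            ci_level=ci_level,
            alignment=alignment,
            chunk_size=chunk_size,
            scale=self.model.scale,
            reference_u=self.brain_saliences,
            reference_v=self.behavior_saliences,
            brain_lvs=brain_lvs,
        )
        self.bootstrap = out
        return out

    def summarize_lv(self, lv_index: int = 0, alpha: float = 0.05) -> dict:
        """JSON-serializable report for one latent variable."""
        if not 0 <= lv_index < self.n_lv:
            raise IndexError(f"LV index {lv_index} out of range ({self.n_lv} LVs)")
        report = {
            "lv": lv_index,
            "singular_value": float(self.singular_values[lv_index]),
            "covariance_explained": float(self.covariance_explained[lv_index]),
            "p_value": None,
            "significant": None,
            "behavior_variables": list(self.model.variable_names),
            "behavior_loadings": [float(b) for b in self.behavior_loadings[:, lv_index]],
            "behavior_saliences": [float(b) for b in self.behavior_saliences[:, lv_index]],
            "brain_loadings": [float(b) for b in self.brain_loadings[:, lv_index]],
        }
        if self.p_values is not None:
            p = float(self.p_values[lv_index])
            report["p_value"] = p
            report["significant"] = bool(p < alpha)
        if self.bootstrap is not None:
            report["behavior_loading_ci"] = [
                [float(lo), float(hi)]
                for lo, hi in zip(
                    self.bootstrap.behavior_ci_low[:, lv_index],
                    self.bootstrap.behavior_ci_high[:, lv_index],
                )
            ]
            report["behavior_reliable"] = [
                bool(b) for b in self.bootstrap.behavior_reliable[:, lv_index]
            ]
        return report

    def summary(self, lv: int = 0, alpha: float = 0.05) -> str:
        """Human-readable summary table for one latent variable."""
        rep = self.summarize_lv(lv, alpha=alpha)
        lines = [
            "PLS correlation results",
            "=" * 58,
            f"subjects: {self.model.n_subjects}   edges: {self.model.x.shape[1]}   "
            f"variables: {self.model.y.shape[1]}   LVs: {self.n_lv}",
            f"LV {lv}: singular value = {rep['singular_value']:.4f}, "
            f"covariance explained = {100 * rep['covariance_explained']:.2f}%",
        ]
        if rep["p_value"] is not None:
            tag = "significant" if rep["significant"] else "not significant"
            lines.append(f"permutation P = {rep['p_value']:.4f} ({tag} at alpha={alpha})")
        lines.append("-" * 58)
        header = f"{'variable':<28}{'loading':>9}"
        if "behavior_loading_ci" in rep:
            header += f"{'95% CI':>18}{'rel.':>5}"
        lines.append(header)
        for i, name in enumerate(rep["behavior_variables"]):
            row = f"{name:<28}{rep['behavior_loadings'][i]:>9.3f}"
            if "behavior_loading_ci" in rep:
                lo, hi = rep["behavior_loading_ci"][i]
                row += f"{f'[{lo:.2f}, {hi:.2f}]':>18}{'*' if rep['behavior_reliable'][i] else '':>5}"
            lines.append(row)
        return "\n".join(lines)
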