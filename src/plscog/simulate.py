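"""Synthetic study data with planted latent brain-behavior structure.

The generator emulates the shape of a simultaneous MR-PET cognition study:
26 subjects, an 82-region parcellation (3,321 edges per modality), and a
neuropsychological battery scored into 14 outcome variables. Its central
model is a rank-k latent factor: each subject carries standard-normal
latent scores z, the edge block is X = Z diag(effect) U' + noise and the
cognition block is Y = Z diag(effect) V' + noise with unit-norm planted
saliences U, V. This is exactly the data-generating process PLS correlation
assumes, so recovered saliences can be validated against ground truth and
the permutation test can be calibrated at effect = 0.

A simplified tracer-accumulation model (monotone linear + quadratic trend
added per region, removed by polynomial detrending) stands in for the
cumulative glucose-uptake component of fPET time series. It is a polynomial
stand-in, not a spatiotemporal gradient filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .battery import CognitiveMatrix
from .connectome import ConnectomeStack, EdgeVectorSet, devectorize, n_edges_for, edge_index_pairs

_UNIT_TOL = 1e-10


@dataclass(frozen=True)
class LatentGroundTruth:
    """Planted latent structure: the truth PLS estimates are judged against.

    ``u_true`` (edges x rank) and ``v_true`` (variables x rank) have
    unit-norm, mutually orthogonal columns; ``effect`` holds one coupling
    strength per component (>= 0). Rank 1 is the canonical fixture — the
    analysis this emulates found a single significant latent variable per
    modality.
    """

    u_true: np.ndarray
    v_true: np.ndarray
    effect: np.ndarray
    noise_sd_brain: float
    noise_sd_cog: float
    n_subjects: int
    n_regions: int
    n_variables: int
    seed: int

    def __post_init__(self) -> None:
        u = np.atleast_2d(np.asarray(self.u_true, dtype=float))
        v = np.atleast_2d(np.asarray(self.v_true, dtype=float))
        if u.shape[0] == 1:
            u = u.T
        if v.shape[0] == 1:
            v = v.T
        eff = np.atleast_1d(np.asarray(self.effect, dtype=float))
        object.__setattr__(self, "u_true", u)
        object.__setattr__(self, "v_true", v)
        object.__setattr__(self, "effect", eff)
        n_edges = n_edges_for(self.n_regions)
        if u.shape[0] != n_edges:
            raise ValueError(
                f"u_true has {u.shape[0]} rows, expected {n_edges} edges "
                f"for {self.n_regions} regions"
            )
        if v.shape[0] != self.n_variables:
            raise ValueError(
                f"v_true has {v.shape[0]} rows, expected {self.n_variables} variables"
            )
        if u.shape[1] != v.shape[1] or u.shape[1] != len(eff):
            raise ValueError("u_true, v_true and effect disagree on rank")
        if np.any(eff < 0):
            raise ValueError("effect must be >= 0")
        if self.noise_sd_brain <= 0 or self.noise_sd_cog <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.n_subjects < 4:
            raise ValueError("need n_subjects >= 4")
        for mat, name in ((u, "u_true"), (v, "v_true")):
            gram = mat.T @ mat
            if np.abs(np.diag(gram) - 1.0).max() > _UNIT_TOL:
                raise ValueError(f"{name} columns must be unit-norm")
            off = gram - np.diag(np.diag(gram))
            if np.abs(off).max() > 1e-8:
                raise ValueError(f"{name} columns must be mutually orthogonal")

    @property
    def rank(self) -> int:
        return self.u_true.shape[1]

    @property
    def n_edges(self) -> int:
        return self.u_true.shape[0]


@dataclass
class SyntheticDataset:
    """A generated study: edge-level brain block, cognition block, truth."""

    edges: EdgeVectorSet
    cognition: CognitiveMatrix
    truth: LatentGroundTruth
    latent_scores: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.edges.n_subjects != self.cognition.n_subjects:
            raise ValueError(
                f"edges have {self.edges.n_subjects} subjects but cognition "
                f"has {self.cognition.n_subjects}"
            )

    def connectomes(self) -> ConnectomeStack:
        """Devectorized per-subject matrices (diagonal 1).

        The latent Gaussian model is on an unbounded correlation-like
        scale, so the stack is built with relaxed range validation.
        """
        mats = np.stack(
            [devectorize(row, self.truth.n_regions) for row in self.edges.values]
        )
        for m in mats:
            np.fill_diagonal(m, 1.0)
        return ConnectomeStack(
            modality=self.edges.modality or "synthetic",
            matrices=mats,
            subject_ids=list(self.edges.subject_ids),
            strict=False,
        )


def _random_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q[:, :k]


def random_ground_truth(
    n_subjects: int = 26,
    n_regions: int = 82,
    n_variables: int = 13,
    effect: float | np.ndarray = 3.0,
    noise_sd_brain: float = 1.0,
    noise_sd_cog: float = 1.0,
    rank: int = 1,
    seed: int = 0,
) -> LatentGroundTruth:
    """Draw random orthonormal planted saliences for a study of given size.

    Defaults mirror the emulated study: 26 subjects, 82 regions, 13
    cognitive variables after QA, one latent component.
    """
    rng = np.random.default_rng(seed)
    eff = np.broadcast_to(np.atleast_1d(np.asarray(effect, dtype=float)), (rank,)).copy()
    u = _random_orthonormal(rng, n_edges_for(n_regions), rank)
    v = _random_orthonormal(rng, n_variables, rank)
    return LatentGroundTruth(
        u_true=u,
        v_true=v,
        effect=eff,
        noise_sd_brain=noise_sd_brain,
        noise_sd_cog=noise_sd_cog,
        n_subjects=n_subjects,
        n_regions=n_regions,
        n_variables=n_variables,
        seed=seed,
    )


def generate_latent_dataset(
    truth: LatentGroundTruth, modality: str = "hemodynamic"
) -> SyntheticDataset:
    """Sample one dataset from the planted latent model.

    X = Z diag(effect) U' + E and Y = Z diag(effect) V' + F with Z
    standard-normal subject scores and i.i.d. Gaussian noise; fully
    reproducible from ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n, k = truth.n_subjects, truth.rank
    z = rng.standard_normal((n, k))
    x = z @ (truth.effect[:, None] * truth.u_true.T) + truth.noise_sd_brain * \
        rng.standard_normal((n, truth.n_edges))
    y = z @ (truth.effect[:, None] * truth.v_true.T) + truth.noise_sd_cog * \
        rng.standard_normal((n, truth.n_variables))
    edges = EdgeVectorSet(
        values=x,
        edge_index=edge_index_pairs(truth.n_regions),
        subject_ids=[f"sub-{i + 1:02d}" for i in range(n)],
        modality=modality,
    )
    names = [f"cog_{j + 1:02d}" for j in range(truth.n_variables)]
    cognition = CognitiveMatrix(
        scores=pd.DataFrame(y, columns=names),
        variables=pd.DataFrame(
            {
                "name": names,
                "test": "synthetic",
                "domain": "synthetic",
                "scale": "continuous",
                "higher_is_better": True,
            }
        ),
    )
    return SyntheticDataset(edges=edges, cognition=cognition, truth=truth, latent_scores=z)


@dataclass(frozen=True)
class PopulationPLS:
    """Closed-form population PLS solution implied by a planted truth.

    Computed from the model's population moments, not from any sample:
    the population cross-block correlation matrix is decomposed and the
    population loadings are the correlations each variable would have with
    the population scores. This is the estimand that sample PLS solutions
    converge to, and the ground truth for coverage studies.
    """

    cross_block: np.ndarray
    singular_values: np.ndarray
    brain_saliences: np.ndarray
    behavior_saliences: np.ndarray
    brain_loadings: np.ndarray
    behavior_loadings: np.ndarray


def population_pls_solution(truth: LatentGroundTruth) -> PopulationPLS:
    """Population cross-block correlation, saliences and loadings.

    Under the latent model, Cov(X) = U diag(e^2) U' + sd_b^2 I,
    Cov(Y) = V diag(e^2) V' + sd_c^2 I and Cov(X, Y) = U diag(e^2) V'.
    Column z-scoring turns covariances into correlations; the population
    cross-block matrix is the element-wise-normalized cross-covariance,
    and its SVD (same sign convention as the estimator) gives the
    population saliences. Population loadings correlate each variable with
    the population score built from those saliences.
    """
    from .pls import _apply_sign_convention

    e2 = truth.effect**2
    u, v = truth.u_true, truth.v_true
    cov_x = (u * e2) @ u.T + truth.noise_sd_brain**2 * np.eye(truth.n_edges)
    cov_y = (v * e2) @ v.T + truth.noise_sd_cog**2 * np.eye(truth.n_variables)
    cov_xy = (u * e2) @ v.T
    sd_x = np.sqrt(np.diag(cov_x))
    sd_y = np.sqrt(np.diag(cov_y))
    r_pop = cov_xy / np.outer(sd_x, sd_y)
    uu, ss, vvt = np.linalg.svd(r_pop, full_matrices=False)
    u_pop, v_pop = _apply_sign_convention(uu, vvt.T)
    corr_x = cov_x / np.outer(sd_x, sd_x)
    corr_y = cov_y / np.outer(sd_y, sd_y)
    # loading_{j,k} = corr(block_j, score_k) with score variance w' C w
    brain_load = (corr_x @ u_pop) / np.sqrt(np.einsum("jk,jk->k", u_pop, corr_x @ u_pop))
    beh_load = (corr_y @ v_pop) / np.sqrt(np.einsum("jk,jk->k", v_pop, corr_y @ v_pop))
    return PopulationPLS(
        cross_block=r_pop,
        singular_values=ss,
        brain_saliences=u_pop,
        behavior_saliences=v_pop,
        brain_loadings=brain_load,
        behavior_loadings=beh_load,
    )


def generate_roi_timeseries(
    n_regions: int,
    n_timepoints: int,
    community_assignment: Optional[np.ndarray] = None,
    within_r: float = 0.3,
    between_r: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Multivariate Gaussian ROI series with block-community correlation.

    The population correlation is ``within_r`` for pairs inside a community
    and ``between_r`` across communities. Raises if the implied correlation
    matrix is not positive definite, naming the offending parameters.
    """
    if not (-1 < between_r <= within_r < 1):
        raise ValueError(
            f"require -1 < between_r <= within_r < 1, got between_r={between_r}, "
            f"within_r={within_r}"
        )
    if n_timepoints < 10:
        raise ValueError("need n_timepoints >= 10")
    if community_assignment is None:
        community_assignment = np.zeros(n_regions, dtype=int)
    comm = np.asarray(community_assignment)
    if comm.shape != (n_regions,):
        raise ValueError("community_assignment must have one entry per region")
    same = comm[:, None] == comm[None, :]
    corr = np.where(same, within_r, between_r)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"implied correlation matrix is not positive definite "
            f"(within_r={within_r}, between_r={between_r}, "
            f"{len(np.unique(comm))} communities)"
        ) from err
    rng = np.random.default_rng(seed)
    series = rng.standard_normal((n_timepoints, n_regions)) @ chol.T
    cols = [f"roi_{i + 1:03d}" for i in range(n_regions)]
    return pd.DataFrame(series, columns=cols)


def add_accumulation_trend(
    ts: pd.DataFrame, uptake_rate: float, curvature: float = 0.0
) -> pd.DataFrame:
    """Add a monotone non-decreasing linear+quadratic trend per region.

    Mimics cumulative radiotracer uptake: over normalized time t in [0, 1]
    the added trend is uptake_rate * t + curvature * t^2, required to be
    non-decreasing on the interval.
    """
    if uptake_rate < 0:
        raise ValueError("uptake_rate must be >= 0")
    if curvature < -uptake_rate / 2:
        raise ValueError(
            f"curvature={curvature} makes the trend decreasing "
            f"(need curvature >= -uptake_rate/2 = {-uptake_rate / 2})"
        )
    t = np.linspace(0.0, 1.0, len(ts))
    trend = uptake_rate * t + curvature * t**2
    out = ts.copy()
    out.iloc[:, :] = ts.to_numpy(dtype=float) + trend[:, None]
    return out


def remove_accumulation_trend(ts: pd.DataFrame, poly_order: int = 2) -> pd.DataFrame:
    """Per-region least-squares polynomial detrend.

    Residuals have zero mean and are orthogonal to the fitted polynomial
    basis. This is a simplified stand-in for dedicated fPET filtering, not
    a spatiotemporal gradient filter.
    """
    if poly_order not in (1, 2, 3):
        raise ValueError("poly_order must be 1, 2 or 3")
    n_t = len(ts)
    if n_t <= poly_order + 1:
        raise ValueError(
            f"need more than poly_order + 1 = {poly_order + 1} timepoints, got {n_t}"
        )
    t = np.linspace(0.0, 1.0, n_t)
    basis = np.vander(t, poly_order + 1, increasing=True)
    values = ts.to_numpy(dtype=float)
    coeff, *_ = np.linalg.lstsq(basis, values, rcond=None)
    resid = values - basis @ coeff
    out = ts.copy()
    out.iloc[:, :] = resid
    return out


#: Outcome-variable metadata for the emulated battery: (name, test, domain,
#: scale, mean, SD). One constant at-ceiling score (Stroop congruent total,
#: every subject at the 112 maximum) is included so the zero-variance QA
#: path is exercised; the remaining moments follow the published battery
#: descriptives. Score-capped recall/recognition variables are marked
#: ordinal.
BATTERY_VARIABLES = [
    ("HVLT_total_recall", "HVLT-R", "verbal episodic memory", "continuous", 26.96, 3.72),
    ("HVLT_delayed_recall", "HVLT-R", "verbal episodic memory", "continuous", 9.73, 1.61),
    ("HVLT_retention_rate", "HVLT-R", "verbal episodic memory", "ordinal", 93.46, 10.93),
    ("HVLT_recognition", "HVLT-R", "verbal episodic memory", "ordinal", 11.19, 1.02),
    ("SDMT_total", "SDMT", "processing speed", "continuous", 56.19, 5.72),
    ("Stroop_congruent_score", "Stroop", "executive function", "ordinal", 112.0, 0.0),
    ("Stroop_incongruent_score", "Stroop", "executive function", "ordinal", 109.42, 5.22),
    ("Stroop_incongruent_rt", "Stroop", "executive function", "continuous", 102.50, 19.67),
    ("Stroop_congruent_rt", "Stroop", "executive function", "continuous", 53.58, 10.11),
    ("COWAT_total", "COWAT", "verbal fluency", "continuous", 42.50, 11.92),
    ("CT1_score", "ColorTrails", "cognitive flexibility", "continuous", 30.88, 8.59),
    ("CT2_score", "ColorTrails", "cognitive flexibility", "continuous", 56.88, 8.77),
    ("CT_interference", "ColorTrails", "cognitive flexibility", "continuous", 0.96, 0.54),
    ("CESDR_total", "CESD-R", "depression", "continuous", 9.12, 8.54),
]


def generate_battery(
    n_subjects: int = 26, seed: int = 0, within_test_r: float = 0.5
) -> CognitiveMatrix:
    """Score a synthetic neuropsychological battery (14 outcome variables).

    Variables within the same test share a latent factor with correlation
    ``within_test_r``; across tests they are independent. The Stroop
    congruent total is constant at its 112 ceiling and should be removed by
    :func:`plscog.battery.drop_zero_variance` before multivariate analysis.
    """
    if not 0 <= within_test_r < 1:
        raise ValueError("within_test_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    tests = {}
    cols = {}
    for name, test, _, _, mean, sd in BATTERY_VARIABLES:
        if sd == 0:
            cols[name] = np.full(n_subjects, mean)
            continue
        if test not in tests:
            tests[test] = rng.standard_normal(n_subjects)
        shared = tests[test]
        item = np.sqrt(within_test_r) * shared + np.sqrt(1 - within_test_r) * \
            rng.standard_normal(n_subjects)
        cols[name] = mean + sd * item
    scores = pd.DataFrame(cols)
    variables = pd.DataFrame(
        [
            {
                "name": name,
                "test": test,
                "domain": domain,
                "scale": scale,
                "higher_is_better": name not in
                ("Stroop_incongruent_rt", "Stroop_congruent_rt", "CT_interference",
                 "CESDR_total", "CT1_score", "CT2_score"),
            }
            for name, test, domain, scale, _, _ in BATTERY_VARIABLES
        ]
    )
    return CognitiveMatrix(scores=scores, variables=variables)


def generate_cohort(n_recruited: int = 28, seed: int = 0) -> pd.DataFrame:
    """A recruited cohort table with the study's two exclusions planted.

    One subject is flagged for an incomplete scan and one for an infusion
    pump failure; applying :func:`plscog.battery.apply_exclusions` leaves
    n_recruited - 2 analyzable subjects.
    """
    if n_recruited < 3:
        raise ValueError("need at least 3 recruited subjects")
    rng = np.random.default_rng(seed)
    ages = rng.integers(18, 24, size=n_recruited)
    sex = rng.choice(["F", "M"], size=n_recruited, p=[0.77, 0.23])
    reasons = [""] * n_recruited
    flagged = rng.choice(n_recruited, size=2, replace=False)
    reasons[flagged[0]] = "incomplete scan"
    reasons[flagged[1]] = "infusion pump failure"
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(n_recruited)],
            "age": ages,
            "sex": sex,
            "exclusion_reason": reasons,
        }
    )
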