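"""Neuropsychological battery statistics and score-table QA.

Covers the descriptive stage of the analysis: a mixed-type pairwise
correlation matrix (Pearson for continuous, Spearman when either variable
is ordinal) with Benjamini-Hochberg false-discovery-rate control, Cronbach's
alpha for within-test internal consistency, removal of zero-variance
variables (scores at ceiling carry no information and break column
z-scoring), and the recruitment exclusions that define the analyzed cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SCALE_TYPES = ("continuous", "ordinal")


@dataclass
class CognitiveMatrix:
    """Subjects-by-variables score table with per-variable metadata.

    Parameters
    ----------
    scores : pandas.DataFrame
        One row per subject, one column per outcome variable.
    variables : pandas.DataFrame
        One row per variable with columns ``name``, ``test``, ``domain``,
        ``scale`` (``continuous`` or ``ordinal``) and ``higher_is_better``.
        Row order matches the columns of ``scores``.
    """

    scores: pd.DataFrame
    variables: pd.DataFrame

    def __post_init__(self) -> None:
        names = self.variables["name"].tolist()
        if list(self.scores.columns) != names:
            raise ValueError("variables metadata order must match score columns")
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if self.scores.isna().any().any():
            bad = self.scores.columns[self.scores.isna().any()].tolist()
            raise ValueError(f"missing values in variable(s) {bad}")
        bad_scale = set(self.variables["scale"]) - set(SCALE_TYPES)
        if bad_scale:
            raise ValueError(f"unknown scale type(s): {sorted(bad_scale)}")

    @property
    def n_subjects(self) -> int:
        return len(self.scores)

    @property
    def n_variables(self) -> int:
        return self.scores.shape[1]

    @property
    def names(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def is_ordinal(self) -> np.ndarray:
        return (self.variables["scale"] == "ordinal").to_numpy()


@dataclass
class BatteryCorrelations:
    """Pairwise coefficients, p-values and the method used per pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (tiny n only)."""
    rx = stats.rankdata(x)
    obs = abs(stats.spearmanr(x, y).statistic)
    count = 0
    total = 0
    for perm in _perms(range(len(y))):
        rho = stats.spearmanr(rx, stats.rankdata(y)[list(perm)]).statistic
        count += abs(rho) >= obs - 1e-12
        total += 1
    return count / total


def correlation_matrix(cog: CognitiveMatrix, exact: bool = False) -> BatteryCorrelations:
    """Mixed-type correlation matrix of a cognitive battery.

    A pair is correlated with Spearman's rho if either variable is ordinal,
    otherwise with Pearson's r. P-values are two-sided; Spearman p-values
    use the t-approximation on rho unless ``exact`` is set (exact
    permutation enumeration, feasible only for n <= 8).

    Zero-variance variables must be removed first (:func:`drop_zero_variance`);
    their correlations are undefined.
    """
    if cog.n_subjects < 4:
        raise ValueError("need >= 4 subjects for pairwise correlation testing")
    x = cog.values()
    if np.any(x.std(axis=0, ddof=1) == 0):
        bad = [n for n, s in zip(cog.names, x.std(axis=0, ddof=1)) if s == 0]
        raise ValueError(f"zero-variance variable(s) {bad}; run drop_zero_variance first")
    if exact and cog.n_subjects > 8:
        raise ValueError("exact permutation p-values are limited to n <= 8")
    k = cog.n_variables
    ordinal = cog.is_ordinal()
    r = np.eye(k)
    p = np.zeros((k, k))
    method = np.full((k, k), "", dtype=object)
    for i in range(k):
        method[i, i] = "spearman" if ordinal[i] else "pearson"
        for j in range(i + 1, k):
            if ordinal[i] or ordinal[j]:
                res = stats.spearmanr(x[:, i], x[:, j])
                rij = res.statistic
                pij = _exact_spearman_p(x[:, i], x[:, j]) if exact else res.pvalue
                method[i, j] = method[j, i] = "spearman"
            else:
                res = stats.pearsonr(x[:, i], x[:, j])
                rij, pij = res.statistic, res.pvalue
                method[i, j] = method[j, i] = "pearson"
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    names = cog.names
    return BatteryCorrelations(
        r=pd.DataFrame(r, index=names, columns=names),
        p=pd.DataFrame(p, index=names, columns=names),
        method=pd.DataFrame(method, index=names, columns=names),
    )


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns
    -------
    flags : numpy.ndarray of bool
        Significance flag per input p-value.
    critical_p : float
        The largest p-value that passes (nan when none do). On the study's
        own data this is a realization, not a constant of the method.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    flags = multipletests(p, alpha=q, method="fdr_bh")[0]
    critical_p = float(p[flags].max()) if flags.any() else float("nan")
    return flags, critical_p


def cronbach_alpha(item_scores) -> float:
    """Cronbach's alpha, k/(k-1) * (1 - sum of item variances / total variance).

    ``item_scores`` is subjects x items; sample variances (ddof=1). May be
    negative for incoherent item sets.
    """
    x = np.asarray(item_scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 items")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def drop_zero_variance(cog: CognitiveMatrix) -> tuple[CognitiveMatrix, list[str]]:
    """Remove variables with zero sample variance.

    Mirrors the removal of at-ceiling scores (every subject at the maximum)
    before multivariate analysis. Returns the reduced matrix and the removed
    names in input order; raises if nothing would remain.
    """
    x = cog.values()
    sd = x.std(axis=0, ddof=1)
    removed = [n for n, s in zip(cog.names, sd) if s == 0]
    if len(removed) == cog.n_variables:
        raise ValueError("all variables have zero variance")
    if not removed:
        return cog, []
    keep = [n for n in cog.names if n not in removed]
    reduced = CognitiveMatrix(
        scores=cog.scores[keep].copy(),
        variables=cog.variables[cog.variables["name"].isin(keep)].reset_index(drop=True),
    )
    return reduced, removed


def apply_exclusions(
    cohort: pd.DataFrame, reason_column: str = "exclusion_reason"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects carrying an exclusion reason.

    ``cohort`` has one row per recruited subject; a non-empty value in
    ``reason_column`` excludes the row. Returns (retained, excluded report).
    """
    if reason_column not in cohort.columns:
        raise ValueError(f"cohort table has no column {reason_column!r}")
    reasons = cohort[reason_column].fillna("")
    excluded = cohort[reasons != ""].copy()
    retained = cohort[reasons == ""].drop(columns=[reason_column]).reset_index(drop=True)
    if retained.empty:
        raise ValueError("every subject excluded")
    return retained, excluded


def read_cognition_tsv(scores_path, metadata_path=None) -> CognitiveMatrix:
    """Read a cognition score TSV plus an optional sidecar metadata TSV.

    Without a sidecar all variables default to continuous.
    """
    scores = pd.read_csv(scores_path, sep="\t")
    if metadata_path is not None:
        variables = pd.read_csv(metadata_path, sep="\t")
    else:
        variables = pd.DataFrame(
            {
                "name": list(scores.columns),
                "test": "",
                "domain": "",
                "scale": "continuous",
                "higher_is_better": True,
            }
        )
    return CognitiveMatrix(scores=scores, variables=variables)


def write_cognition_tsv(cog: CognitiveMatrix, scores_path, metadata_path) -> None:
    cog.scores.to_csv(scores_path, sep="\t", index=False)
    cog.variables.to_csv(metadata_path, sep="\t", index=False)
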