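"""Permutation inference, network-based statistics, and clinical correlations.

Group comparisons use label-permutation tests on a pooled-variance t
statistic. Nuisance covariates (age, sex, IQ) are handled by the
Freedman-Lane scheme: the outcome is residualized on the covariates and
group labels are permuted over the residuals, preserving group sizes.
The network-based statistic (NBS) controls family-wise error over the 406
channel-pair comparisons by permuting the null distribution of the
maximal suprathreshold connected-component size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PermutationResult",
    "NBSResult",
    "CorrelationResult",
    "permutation_test",
    "critical_t",
    "nbs",
    "partial_correlation",
    "demographic_tests",
]


@dataclass
class PermutationResult:
    observed_t: float
    p_value: float
    n_perm: int
    seed: int | None
    alternative: str = "two-sided"


@dataclass
class NBSResult:
    """Suprathreshold components and their permutation-corrected p-values.

    ``components`` lists each connected component (>= 1 link) as a list of
    ``(i, j)`` node-index pairs, largest first; ``corrected_p[i]`` is the
    proportion of permutations whose maximal component is at least as
    large (in link count) as component ``i``.
    """

    t_threshold: float
    suprathreshold_edges: list[tuple[int, int]]
    components: list[list[tuple[int, int]]]
    component_sizes: list[int]
    corrected_p: list[float]
    n_perm: int
    seed: int | None
    edge_t: np.ndarray = field(repr=False, default=None)

    @property
    def max_component_links(self) -> int:
        return max(self.component_sizes, default=0)

    def significant_components(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.corrected_p) if p < alpha]


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    covariates: list[str]


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y after OLS on covariates plus an intercept."""
    if covariates is None:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _covariate_array(covariates, n: int) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        num = covariates.copy()
        for col in num.columns:
            if not np.issubdtype(num[col].dtype, np.number):
                num[col] = pd.factorize(num[col])[0]
        arr = num.to_numpy(dtype=float)
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError("covariate rows do not match number of subjects")
    return arr


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def _two_group_masks(groups) -> tuple[np.ndarray, np.ndarray, list]:
    labels = np.asarray(groups)
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    g0 = labels == uniq[0]
    g1 = labels == uniq[1]
    if g0.sum() < 2 or g1.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    return g0, g1, uniq


def permutation_test(
    values,
    groups,
    covariates=None,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Two-group permutation test on a per-subject scalar.

    The observed statistic is the pooled-variance t between groups on
    covariate-adjusted values (first sorted group label minus second).
    Group labels are permuted ``n_perm`` times preserving group sizes;
    the p-value uses the add-one estimator, so it is bounded below by
    1/(n_perm+1). ``alternative`` is ``"two-sided"`` (default),
    ``"greater"`` or ``"less"``; the one-sided variants reproduce the
    literal exceedance-proportion rule.
    """
    y = np.asarray(values, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("values must be finite")
    g0, g1, _ = _two_group_masks(groups)
    resid = _residualize(y, _covariate_array(covariates, len(y)))
    t_obs = _pooled_t(resid[g0], resid[g1])

    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    n = len(y)
    n0 = int(g0.sum())
    n1 = n - n0
    s_tot = resid.sum()
    ss_tot = (resid**2).sum()
    sq = resid**2
    exceed = 0
    chunk = 2048
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        # first n0 positions of each random permutation form the permuted group
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :n0]
        s0 = resid[idx].sum(axis=1)
        ss0 = sq[idx].sum(axis=1)
        m0 = s0 / n0
        m1 = (s_tot - s0) / n1
        sp2 = (ss_tot - n0 * m0**2 - n1 * m1**2) / (n - 2)
        denom = np.sqrt(np.maximum(sp2, 0) * (1 / n0 + 1 / n1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = np.where(denom > 0, (m0 - m1) / denom, 0.0)
        if alternative == "two-sided":
            exceed += int((np.abs(t_p) >= abs(t_obs)).sum())
        elif alternative == "greater":
            exceed += int((t_p >= t_obs).sum())
        else:
            exceed += int((t_p <= t_obs).sum())
    p = (exceed + 1) / (n_perm + 1)
    return PermutationResult(observed_t=t_obs, p_value=float(p), n_perm=n_perm,
                             seed=seed, alternative=alternative)


def critical_t(tail_p: float, df: int) -> float:
    """Upper one-tailed critical value of the central t distribution."""
    if not 0 < tail_p < 0.5:
        raise ValueError(f"tail probability must lie in (0, 0.5), got {tail_p}")
    if df < 1:
        raise ValueError("degrees of freedom must be at least 1")
    return float(sps.t.ppf(1.0 - tail_p, df))


def _edge_t_stats(X: np.ndarray, g0: np.ndarray) -> np.ndarray:
    """Pooled t per column (edge) for group mask g0 vs its complement."""
    n0 = g0.sum()
    n1 = (~g0).sum()
    s0 = X[g0].sum(axis=0)
    s1 = X[~g0].sum(axis=0)
    ss0 = (X[g0] ** 2).sum(axis=0)
    ss1 = (X[~g0] ** 2).sum(axis=0)
    m0, m1 = s0 / n0, s1 / n1
    sp2 = (ss0 - n0 * m0**2 + ss1 - n1 * m1**2) / (n0 + n1 - 2)
    denom = np.sqrt(np.maximum(sp2, 0) * (1 / n0 + 1 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m0 - m1) / denom, 0.0)
    return t


def _components_from_edges(
    n_nodes: int, iu: np.ndarray, ju: np.ndarray, mask: np.ndarray
) -> tuple[list[list[tuple[int, int]]], list[int]]:
    ei, ej = iu[mask], ju[mask]
    if ei.size == 0:
        return [], []
    adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    adj[ei, ej] = 1
    _, labels = connected_components(csr_array(adj), directed=False)
    comp_of_edge = labels[ei]
    comps: dict[int, list[tuple[int, int]]] = {}
    for a, b, c in zip(ei, ej, comp_of_edge):
        comps.setdefault(int(c), []).append((int(a), int(b)))
    ordered = sorted(comps.values(), key=len, reverse=True)
    return ordered, [len(c) for c in ordered]


def _max_component_size(n_nodes: int, iu, ju, mask) -> int:
    _, sizes = _components_from_edges(n_nodes, iu, ju, mask)
    return max(sizes, default=0)


def nbs(
    matrices: np.ndarray,
    groups,
    t_threshold: float = 2.61,
    n_perm: int = 10_000,
    seed: int | None = None,
    direction: str = "greater",
) -> NBSResult:
    """Network-based statistic over a stack of per-subject matrices.

    Parameters
    ----------
    matrices
        ``(n_subjects, n_nodes, n_nodes)`` symmetric connectivity stack.
    groups
        Two-level group labels; edge t statistics are first-sorted-label
        minus second (e.g. ``"control" - "patient"`` for the default
        string labels).
    t_threshold
        Uncorrected primary threshold on the edge t statistic
        (2.61 corresponds to one-tailed p = 0.005 at df = 142).
    direction
        ``"greater"`` keeps edges with ``t > threshold``, ``"less"`` with
        ``t < -threshold``, ``"two-sided"`` with ``|t| > threshold``.

    A finding of zero suprathreshold edges is reported as an empty result,
    not an error.
    """
    M = np.asarray(matrices, dtype=float)
    if M.ndim != 3 or M.shape[1] != M.shape[2]:
        raise ValueError("matrices must be a (subjects, nodes, nodes) stack")
    n_sub, n_nodes, _ = M.shape
    g0, g1, _ = _two_group_masks(groups)
    iu, ju = np.triu_indices(n_nodes, k=1)
    X = M[:, iu, ju]

    def supra(t: np.ndarray) -> np.ndarray:
        if direction == "greater":
            return t > t_threshold
        if direction == "less":
            return t < -t_threshold
        if direction == "two-sided":
            return np.abs(t) > t_threshold
        raise ValueError(f"unknown direction {direction!r}")

    t_obs = _edge_t_stats(X, g0)
    obs_mask = supra(t_obs)
    components, sizes = _components_from_edges(n_nodes, iu, ju, obs_mask)
    edges = [(int(a), int(b)) for a, b in zip(iu[obs_mask], ju[obs_mask])]

    rng = np.random.default_rng(seed)
    n0 = int(g0.sum())
    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(n_sub)
        pg0 = np.zeros(n_sub, dtype=bool)
        pg0[perm[:n0]] = True
        null_max[b] = _max_component_size(n_nodes, iu, ju, supra(_edge_t_stats(X, pg0)))

    corrected = [float((1 + (null_max >= s).sum()) / (n_perm + 1)) for s in sizes]
    return NBSResult(t_threshold=t_threshold, suprathreshold_edges=edges,
                     components=components, component_sizes=sizes,
                     corrected_p=corrected, n_perm=n_perm, seed=seed, edge_t=t_obs)


def partial_correlation(
    metric, score, covariates
) -> CorrelationResult:
    """Partial Pearson correlation controlling for covariates.

    Both variables are residualized on the covariates (plus intercept);
    the p-value uses the t transform with df = n - n_covariates - 2.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(score, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("metric or score is constant; correlation undefined")
    cov_names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                 else [f"c{i}" for i in range(np.atleast_2d(covariates).shape[1])])
    cov = _covariate_array(covariates, len(x))
    k = 0 if cov is None else cov.shape[1]
    n = len(x)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, p_value=p, n=n, covariates=cov_names)


def demographic_tests(meta: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of the demographic table.

    Sex uses a 2x2 chi-square with 1 df and no continuity correction;
    age, education and IQ use pooled-variance two-sample t tests
    (patient minus control). Returns a tidy table with one row per test.
    """
    groups = meta["group"].unique().tolist()
    if not {"patient", "control"} <= set(groups):
        raise ValueError("metadata must contain both 'patient' and 'control' rows")
    pat = meta[meta["group"] == "patient"]
    ctl = meta[meta["group"] == "control"]

    table = pd.crosstab(meta["group"], meta["sex"])
    if (table.to_numpy() == 0).any() or table.shape != (2, 2):
        raise ValueError(f"sex contingency table has empty cells:\n{table}")
    chi2, chi_p, chi_df, _ = sps.chi2_contingency(table.to_numpy(), correction=False)

    rows = [{"variable": "sex", "test": "chi2", "statistic": float(chi2),
             "df": int(chi_df), "p_value": float(chi_p)}]
    for var in ("age", "education", "iq"):
        t, p = sps.ttest_ind(pat[var], ctl[var], equal_var=True)
        rows.append({"variable": var, "test": "t", "statistic": float(t),
                     "df": len(pat) + len(ctl) - 2, "p_value": float(p)})
    return pd.DataFrame(rows)
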