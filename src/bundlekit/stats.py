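"""Cohort statistics: ICV matching, GLM, permutation inference, TFCE, FDR.

The statistical layer mirrors a standard population neuroimaging workflow:

* construction of ICV-matched man/woman pairs (|delta ICV| below a tolerance,
  maximum-cardinality matching on sorted ICVs);
* mean-centered multiple linear regression of a DTI index on ICV, age and a
  sex indicator (coded female = 1, so the sex beta is women minus men);
* permutation inference over many units (voxels or tracts) with
  family-wise-error control by the max-statistic distribution, optionally
  enhanced by threshold-free cluster enhancement (TFCE);
* Benjamini-Hochberg step-up correction within predefined variable families;
* Cohen's d and partial eta squared effect sizes.

Permutations follow the Freedman-Lane scheme: residuals of the reduced model
(the design without the term under test) are permuted, and the full-model
statistic is recomputed. Two-sided tests operate on |t|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

GroupSummary = Tuple[int, float, float]  # (n, mean, sd)


# ---------------------------------------------------------------------------
# ICV matching
# ---------------------------------------------------------------------------


@dataclass
class MatchedPairs:
    pairs: List[Tuple[str, str]]  # (man_id, woman_id)
    tolerance: float  # ml

    def __len__(self) -> int:
        return len(self.pairs)


def match_by_icv(
    men: pd.DataFrame,
    women: pd.DataFrame,
    tolerance: float = 10.0,
    id_col: str = "subject_id",
    icv_col: str = "icv_ml",
) -> MatchedPairs:
    """Maximum-cardinality man/woman pairs with |delta ICV| < tolerance.

    Solved as a rectangular assignment problem: the cost of a compatible
    pair is its |delta ICV|, an incompatible pair costs a penalty larger
    than any feasible total, and the Hungarian solution therefore maximizes
    the pair count first and, among maximum matchings, minimizes the total
    ICV discrepancy (which drives the matched-group ICV difference toward
    zero). Each subject is used at most once; deterministic.
    """
    if (men[icv_col] <= 0).any() or (women[icv_col] <= 0).any():
        raise ValueError("ICVs must be positive")
    if len(men) == 0 or len(women) == 0:
        return MatchedPairs(pairs=[], tolerance=tolerance)
    from scipy.optimize import linear_sum_assignment

    m_icv = men[icv_col].to_numpy(dtype=float)
    w_icv = women[icv_col].to_numpy(dtype=float)
    diff = np.abs(m_icv[:, None] - w_icv[None, :])
    compatible = diff < tolerance
    penalty = tolerance * (min(len(m_icv), len(w_icv)) + 1)
    cost = np.where(compatible, diff, penalty)
    rows, cols = linear_sum_assignment(cost)
    pairs: List[Tuple[str, str]] = [
        (str(men[id_col].iloc[i]), str(women[id_col].iloc[j]))
        for i, j in zip(rows, cols)
        if compatible[i, j]
    ]
    return MatchedPairs(pairs=pairs, tolerance=tolerance)


# ---------------------------------------------------------------------------
# t tests and effect sizes
# ---------------------------------------------------------------------------


def _as_summary(group: Union[Sequence[float], GroupSummary]) -> GroupSummary:
    if isinstance(group, tuple) and len(group) == 3 and np.isscalar(group[0]):
        n, mean, sd = group
        return int(n), float(mean), float(sd)
    arr = np.asarray(group, dtype=float)
    return len(arr), float(arr.mean()), float(arr.std(ddof=1))


def two_sample_t(
    group1: Union[Sequence[float], GroupSummary],
    group2: Union[Sequence[float], GroupSummary],
    variant: str = "pooled",
) -> float:
    """Two-sample t statistic from raw groups or (n, mean, sd) summaries.

    The pooled (Student) variant uses
    ``t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2))`` with the pooled variance
    ``s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)``; Welch uses the
    separate-variance form. Equal means with zero pooled SD give t = 0.
    """
    n1, m1, s1 = _as_summary(group1)
    n2, m2, s2 = _as_summary(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        if sp2 == 0:
            if m1 == m2:
                return 0.0
            raise ValueError("zero pooled SD with unequal means")
        return float((m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    if variant == "welch":
        denom = np.sqrt(s1**2 / n1 + s2**2 / n2)
        if denom == 0:
            if m1 == m2:
                return 0.0
            raise ValueError("zero variance with unequal means")
        return float((m1 - m2) / denom)
    raise ValueError("variant must be 'pooled' or 'welch'")


def cohen_d(
    group1: Union[Sequence[float], GroupSummary],
    group2: Union[Sequence[float], GroupSummary],
) -> float:
    """Cohen's d: (mean1 - mean2) / pooled SD (pooled as in the t test)."""
    n1, m1, s1 = _as_summary(group1)
    n2, m2, s2 = _as_summary(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("Cohen's d undefined for zero pooled SD")
    return float((m1 - m2) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# Design matrices and OLS
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Regression design with a centering record.

    ``matrix`` holds the intercept plus one column per term; continuous
    covariates are mean-centered (the record keeps the subtracted means so
    predictions stay interpretable). Interaction terms are written
    ``a:b`` and built as products of the (centered) component columns.
    """

    matrix: pd.DataFrame
    terms: List[str]
    centering: Dict[str, float] = field(default_factory=dict)


def build_design(
    table: pd.DataFrame,
    terms: Sequence[str] = ("icv", "age", "sex"),
    center: bool = True,
) -> DesignMatrix:
    """Build a design matrix from a subject table.

    Base terms: ``icv`` (ml, column ``icv_ml``), ``age`` (years), ``sex``
    (indicator, female = 1 from column ``sex`` coded M/F). Interactions are
    colon-joined (e.g. ``icv:sex``) and are products of component columns.
    """
    cols: Dict[str, np.ndarray] = {}
    centering: Dict[str, float] = {}

    def base_column(name: str) -> np.ndarray:
        if name in cols:
            return cols[name]
        if name == "sex":
            col = (table["sex"].to_numpy() == "F").astype(float)
        elif name == "icv":
            col = table["icv_ml"].to_numpy(dtype=float)
        elif name in table.columns:
            col = table[name].to_numpy(dtype=float)
        else:
            raise KeyError(f"unknown design term {name!r}")
        if center and name != "sex":
            centering[name] = float(col.mean())
            col = col - col.mean()
        return col

    out = {"intercept": np.ones(len(table))}
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            col = np.ones(len(table))
            for p in parts:
                col = col * base_column(p)
        else:
            col = base_column(term)
        cols[term] = col
        out[term] = col
    return DesignMatrix(
        matrix=pd.DataFrame(out), terms=list(terms), centering=centering
    )


@dataclass
class RegressionFit:
    """OLS results: per-term beta/SE/t/p plus partial eta squared."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    partial_eta_sq: pd.Series
    ssr: float
    df_resid: float
    nobs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "partial_eta_sq": self.partial_eta_sq,
            }
        )


def fit_glm(y: Sequence[float], design: DesignMatrix) -> RegressionFit:
    """Fit OLS of ``y`` on the design; reject rank-deficient designs.

    Partial eta squared per single-df term is ``t^2 / (t^2 + df_resid)``,
    which equals the Type-III SS ratio ``SS_term / (SS_term + SS_resid)``.
    """
    X = design.matrix.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [design.matrix.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    names = list(design.matrix.columns)
    t = pd.Series(res.tvalues, index=names)
    eta = t**2 / (t**2 + res.df_resid)
    return RegressionFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=t,
        pvalues=pd.Series(res.pvalues, index=names),
        partial_eta_sq=eta,
        ssr=float(res.ssr),
        df_resid=float(res.df_resid),
        nobs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_correct(
    pvalues: Sequence[float],
    alpha: float = 0.05,
    families: Optional[Sequence] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """BH step-up rejections and adjusted p, independently per family.

    Returns ``(reject, p_adjusted)`` aligned with the input order. With no
    ``families``, all p-values form one family.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(len(p), dtype=bool)
    adjusted = np.ones(len(p))
    fam = np.zeros(len(p)) if families is None else np.asarray(families)
    for f in pd.unique(fam):
        idx = np.where(fam == f)[0]
        rej, adj, _, _ = multipletests(p[idx], alpha=alpha, method="fdr_bh")
        reject[idx] = rej
        adjusted[idx] = adj
    return reject, adjusted


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


def grid_adjacency(mask: np.ndarray, connectivity: int = 1) -> csr_matrix:
    """Sparse adjacency of the True voxels of a 3D mask (face connectivity)."""
    from scipy.ndimage import generate_binary_structure

    mask = np.asarray(mask, dtype=bool)
    idx = -np.ones(mask.shape, dtype=int)
    coords = np.argwhere(mask)
    idx[mask] = np.arange(len(coords))
    struct = generate_binary_structure(3, connectivity)
    offsets = np.argwhere(struct) - 1
    rows, cols = [], []
    for off in offsets:
        if not off.any():
            continue
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < np.array(mask.shape)), axis=1)
        src = idx[tuple(coords[ok].T)]
        dst = idx[tuple(shifted[ok].T)]
        good = dst >= 0
        rows.extend(src[good])
        cols.extend(dst[good])
    n = len(coords)
    data = np.ones(len(rows), dtype=np.int8)
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def tfce_enhance(
    statistic: np.ndarray,
    adjacency: csr_matrix,
    H: float = 2.0,
    E: float = 0.5,
    dh: Optional[float] = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative statistic vector.

    For each threshold ``h`` in steps of ``dh`` up to the maximum, every
    suprathreshold unit accrues ``extent^E * h^H * dh`` where extent is the
    size of its connected component among suprathreshold units (components
    from the supplied adjacency). ``dh`` defaults to max/n_steps. Negative
    contrasts should be enhanced separately on the negated map.
    """
    stat = np.asarray(statistic, dtype=float)
    if (stat < 0).any():
        raise ValueError("TFCE input must be non-negative")
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    peak = stat.max()
    if peak == 0:
        return np.zeros_like(stat)
    step = dh if dh is not None else peak / n_steps
    out = np.zeros_like(stat)
    n = int(np.floor(peak / step + 1e-9))
    for m in range(1, n + 1):
        h = m * step
        above = stat >= h
        if not above.any():
            break
        sub = adjacency[above][:, above]
        n_comp, comp = connected_components(sub, directed=False)
        sizes = np.bincount(comp)
        out[above] += sizes[comp] ** E * h**H * step
    return out


# ---------------------------------------------------------------------------
# Permutation inference (Freedman-Lane)
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed statistic per unit with permutation-corrected p-values."""

    statistic: np.ndarray  # observed |t| (or TFCE-enhanced |t|) per unit
    corrected_p: np.ndarray
    uncorrected_p: np.ndarray
    n_permutations: int
    method: str
    seed: int

    def __post_init__(self) -> None:
        floor = 1.0 / (self.n_permutations + 1)
        if ((self.corrected_p < floor - 1e-12) | (self.corrected_p > 1)).any():
            raise ValueError("corrected p outside [1/(n_perm+1), 1]")


def permutation_inference(
    responses: np.ndarray,
    design: DesignMatrix,
    term: str,
    n_perm: int = 5000,
    method: str = "maxstat",
    seed: int = 0,
    adjacency: Optional[csr_matrix] = None,
    tfce_kwargs: Optional[dict] = None,
    chunk: int = 100,
) -> PermutationResult:
    """Family-wise-corrected permutation test for one design term.

    ``responses`` is (units, subjects). The reduced model excludes ``term``;
    its residuals are row-permuted (Freedman-Lane) and the full-model |t|
    for the term recomputed per unit. Correction uses the distribution of
    the maximum |t| over units (``method='maxstat'``) or of the maximum
    TFCE-enhanced |t| (``method='tfce'``, requires ``adjacency``). Corrected
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if term not in design.matrix.columns:
        raise ValueError(f"term {term!r} not in design")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("maxstat", "tfce"):
        raise ValueError("method must be 'maxstat' or 'tfce'")
    if method == "tfce" and adjacency is None:
        raise ValueError("TFCE needs a neighborhood adjacency")

    Y = np.asarray(responses, dtype=float).T  # (n_subjects, units)
    X = design.matrix.to_numpy(dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("responses and design disagree on subject count")
    j = list(design.matrix.columns).index(term)

    Z = np.delete(X, j, axis=1)
    Hz = Z @ np.linalg.pinv(Z)
    Yres = Y - Hz @ Y  # reduced-model residuals

    pinvX = np.linalg.pinv(X)
    w = pinvX[j]  # beta_j = w @ y
    Q, _ = np.linalg.qr(X)
    var_j = np.linalg.inv(X.T @ X)[j, j]
    dof = n - p
    css = (Yres**2).sum(axis=0)  # invariant under row permutation

    def tmap(Yp: np.ndarray) -> np.ndarray:
        # Yp: (n, units) or (P, n, units)
        beta = np.einsum("n,...nu->...u", w, Yp)
        fitted = np.einsum("nk,...nu->...ku", Q, Yp)
        rss = np.maximum(css - (fitted**2).sum(axis=-2), 0.0)
        sigma2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / np.sqrt(np.maximum(sigma2 * var_j, 1e-300))
        return np.abs(t)

    def enhance(absmap: np.ndarray) -> np.ndarray:
        if method == "maxstat":
            return absmap
        return tfce_enhance(absmap, adjacency, **(tfce_kwargs or {}))

    observed_t = tmap(Yres)  # identical to full-model |t| on Y
    observed = enhance(observed_t)

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    exceed_unit = np.zeros(observed_t.shape)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(m)])
        Yp = Yres[perms]  # (m, n, units)
        tp = tmap(Yp)
        if method == "tfce":
            enhanced = np.stack([enhance(row) for row in tp])
            max_null[done : done + m] = enhanced.max(axis=1)
            exceed_unit += (tp >= observed_t[None]).sum(axis=0)
        else:
            max_null[done : done + m] = tp.max(axis=1)
            exceed_unit += (tp >= observed_t[None]).sum(axis=0)
        done += m

    corrected = (1 + (max_null[:, None] >= observed[None]).sum(axis=0)) / (n_perm + 1)
    uncorrected = (1 + exceed_unit) / (n_perm + 1)
    return PermutationResult(
        statistic=observed,
        corrected_p=corrected,
        uncorrected_p=uncorrected,
        n_permutations=n_perm,
        method=method,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Interaction screening
# ---------------------------------------------------------------------------


def interaction_screen(
    y: Sequence[float],
    table: pd.DataFrame,
    base_terms: Sequence[str] = ("icv", "age", "sex"),
    interaction_terms: Sequence[str] = ("icv:sex", "icv:age", "icv:sex:age"),
    alpha: float = 0.05,
) -> Tuple[DesignMatrix, Dict[str, dict]]:
    """Fit the full model with interactions; drop the non-significant ones.

    The interaction p-values are BH-corrected as one family; every
    interaction whose corrected p is >= alpha is removed. Returns the
    reduced design plus a report of each interaction's p, corrected p, and
    whether it was dropped.
    """
    full = build_design(table, tuple(base_terms) + tuple(interaction_terms))
    fit = fit_glm(y, full)
    p_int = np.array([fit.pvalues[t] for t in interaction_terms])
    reject, adjusted = bh_correct(p_int, alpha=alpha)
    kept = [t for t, r in zip(interaction_terms, reject) if r]
    report = {
        t: {
            "p": float(p_int[i]),
            "p_corrected": float(adjusted[i]),
            "dropped": not reject[i],
        }
        for i, t in enumerate(interaction_terms)
    }
    reduced = build_design(table, tuple(base_terms) + tuple(kept))
    return reduced, report
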