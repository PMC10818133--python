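"""Genotype-environment association by partial redundancy analysis (pRDA).

The response is a Hellinger-transformed individual allele-frequency
matrix; explanatory variables are standardised environmental measurements
and the conditioning matrix holds distance-based Moran's eigenvector maps
(dbMEM), the spatial eigenfunctions that absorb spatial autocorrelation
so environment effects are not confounded with geography.  Significance
comes from permutation of the reduced-model residuals; model
simplification uses forward selection with the classic double stopping
rule (permutation alpha and the full-model adjusted R-squared ceiling);
variance partitioning decomposes adjusted R-squared into pure
environment, pure space, shared and unexplained fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# response and explanatory matrices
# ---------------------------------------------------------------------

def genotype_freq_matrix(gm: GenotypeMatrix,
                         max_missing: float = 0.0) -> pd.DataFrame:
    """Individual allele-frequency table (dosage / 2) on complete-case
    sites (``max_missing`` raises the per-site missingness allowance;
    remaining missing values are mean-imputed)."""
    miss = gm.missing_fraction_per_site()
    keep = np.flatnonzero(miss <= max_missing)
    if keep.size == 0:
        raise ValueError("no sites pass the missingness threshold")
    d = gm.dosages[:, keep].astype(float)
    d[gm.dosages[:, keep] == MISSING] = np.nan
    col = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col[None, :], d) / 2.0
    names = [f"{c}:{p}" for c, p in
             zip(gm.site_meta["contig"].to_numpy()[keep],
                 gm.site_meta["pos"].to_numpy()[keep])]
    return pd.DataFrame(d, index=gm.ind_meta["id"].to_numpy(), columns=names)


def hellinger(freqs) -> pd.DataFrame | np.ndarray:
    """Hellinger transformation: entry -> sqrt(entry / row sum)."""
    arr = np.asarray(freqs, dtype=float)
    if np.any(arr < 0):
        raise ValueError("Hellinger transform requires non-negative entries")
    rs = arr.sum(axis=1)
    if np.any(rs == 0):
        raise ValueError("rows with zero sum cannot be transformed")
    out = np.sqrt(arr / rs[:, None])
    if isinstance(freqs, pd.DataFrame):
        return pd.DataFrame(out, index=freqs.index, columns=freqs.columns)
    return out


@dataclass
class EnvMatrix:
    """Centred/standardised environmental variables with a collinearity
    report (pairwise Pearson r)."""

    data: pd.DataFrame
    correlations: pd.DataFrame
    dropped: list = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def names(self) -> list:
        return list(self.data.columns)


def build_env_matrix(env: pd.DataFrame, max_abs_r: float = 0.70) -> EnvMatrix:
    """Standardise environment columns and drop collinear variables
    (|r| >= ``max_abs_r``; the later column of each offending pair goes,
    with a log message)."""
    num = env.select_dtypes("number")
    z = (num - num.mean()) / num.std(ddof=1)
    corr = z.corr()
    dropped = []
    cols = list(z.columns)
    for i, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[i + 1:]:
            if b in dropped:
                continue
            if abs(corr.loc[a, b]) >= max_abs_r:
                dropped.append(b)
                logger.info("dropping %s (|r|=%.2f with %s)", b,
                            abs(corr.loc[a, b]), a)
    kept = z.drop(columns=dropped)
    return EnvMatrix(kept, corr, dropped)


# ---------------------------------------------------------------------
# dbMEM spatial eigenfunctions
# ---------------------------------------------------------------------

@dataclass
class MEMBasis:
    """Distance-based Moran's eigenvector maps."""

    vectors: np.ndarray      # individuals x retained vectors (orthonormal)
    eigenvalues: np.ndarray
    truncation: float

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    def take(self, k: int | None) -> np.ndarray:
        if k is None or k >= self.n_vectors:
            return self.vectors
        return self.vectors[:, :k]


def dbmem(coords: np.ndarray, jitter_seed: int = 0,
          eig_tol: float = 1e-10) -> MEMBasis:
    """dbMEM basis from 2-D coordinates.

    The Euclidean distance matrix is truncated at the longest edge of its
    minimum spanning tree (distances beyond it replaced by four times the
    truncation); principal-coordinate decomposition of the double-centred
    truncated matrix yields eigenvectors, of which those with positive
    eigenvalues are retained (orthonormal columns, sorted by decreasing
    eigenvalue).  Exact duplicate coordinates get an infinitesimal seeded
    jitter.
    """
    xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    n = xy.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    uniq = {tuple(row) for row in xy}
    if len(uniq) < n:
        logger.warning("duplicate coordinates: applying infinitesimal jitter")
        rng = np.random.default_rng(jitter_seed)
        xy = xy + rng.normal(0, 1e-9, size=xy.shape)
    d = squareform(pdist(xy))
    mst = minimum_spanning_tree(d).toarray()
    trunc = float(mst.max())
    dt = np.where(d > trunc, 4.0 * trunc, d)
    np.fill_diagonal(dt, 0.0)
    # Gower double-centring of -0.5 * D^2
    a = -0.5 * dt**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eig_tol * max(vals.max(), 1.0)
    return MEMBasis(vecs[:, keep], vals[keep], trunc)


# ---------------------------------------------------------------------
# redundancy analysis
# ---------------------------------------------------------------------

def _centre(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _residualise(a: np.ndarray, z: np.ndarray | None) -> np.ndarray:
    """Residuals of (centred) ``a`` on (centred) ``z`` by least squares."""
    a = _centre(np.asarray(a, float))
    if z is None or z.size == 0 or z.shape[1] == 0:
        return a
    z = _centre(np.asarray(z, float))
    coef, *_ = np.linalg.lstsq(z, a, rcond=None)
    return a - z @ coef


def _rank(a: np.ndarray) -> int:
    if a is None or a.size == 0:
        return 0
    return int(np.linalg.matrix_rank(_centre(np.asarray(a, float))))


def _fit_ss(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(fitted values, SS fitted, SS total) for centred Y on centred X."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    return fitted, float((fitted**2).sum()), float((Y**2).sum())


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel correction with n observations and p predictors."""
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class RDAResult:
    """Outputs of a (partial) redundancy analysis."""

    r2: float
    adj_r2: float
    F: float
    p_value: float | None
    axis_variance: np.ndarray      # fraction of constrained variance per axis
    sample_scores: np.ndarray      # individuals x axes
    biplot_scores: pd.DataFrame    # predictor loadings on the axes
    selected: list
    n_perm: int = 0
    axis_F: np.ndarray | None = None
    axis_p: np.ndarray | None = None


class PartialRDA:
    """Partial redundancy analysis, scikit-learn style.

    ``fit(Y, X, Z)`` residualises the response ``Y`` and predictors ``X``
    on the conditioning matrix ``Z``, regresses, and eigen-decomposes the
    fitted values.  Fitted attributes carry trailing underscores
    (``r2_``, ``adj_r2_``, ``F_``, ``p_value_``, ``sample_scores_`` ...).
    ``transform`` projects (residualised) data onto the canonical axes.
    """

    def __init__(self, n_perm: int = 999, seed: int = 0,
                 scope: str = "global"):
        self.n_perm = n_perm
        self.seed = seed
        self.scope = scope

    def get_params(self, deep: bool = True) -> dict:
        return {"n_perm": self.n_perm, "seed": self.seed, "scope": self.scope}

    def set_params(self, **kw) -> "PartialRDA":
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------

    def fit(self, Y, X, Z=None) -> "PartialRDA":
        Y = np.asarray(Y, float)
        Xnames = list(X.columns) if isinstance(X, pd.DataFrame) else \
            [f"x{i}" for i in range(np.asarray(X).shape[1])]
        X = np.asarray(X, float)
        Z = None if Z is None else np.asarray(Z, float)
        if X.ndim != 2 or Y.ndim != 2 or len(Y) != len(X):
            raise ValueError("Y and X must be aligned 2-D arrays")
        if Z is not None and len(Z) != len(Y):
            raise ValueError("Z rows must align with Y")
        n = len(Y)
        Yr = _residualise(Y, Z)
        Xr = _residualise(X, Z)
        # drop aliased predictors (rank-deficient after conditioning)
        keep = _independent_columns(Xr)
        if len(keep) < X.shape[1]:
            logger.warning("dropping %d aliased predictor(s)",
                           X.shape[1] - len(keep))
        Xr = Xr[:, keep]
        names = [Xnames[i] for i in keep]
        fitted, ss_fit, ss_tot = _fit_ss(Yr, Xr)
        p = _rank(Xr)
        q = _rank(Z) if Z is not None else 0
        r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        nax = min(p, fitted.shape[1])
        s = s[:nax]
        self.r2_ = float(r2)
        self.adj_r2_ = float(adjusted_r2(r2, n, p))
        df_res = n - 1 - p - q
        ss_res = ss_tot - ss_fit
        self.F_ = float((ss_fit / p) / (ss_res / df_res)) \
            if p > 0 and df_res > 0 and ss_res > 0 else np.inf
        self.axis_variance_ = (s**2) / ss_fit if ss_fit > 0 else s[:0]
        self.sample_scores_ = u[:, :nax] * s[None, :]
        bip = np.zeros((len(names), nax))
        for a in range(nax):
            ax = self.sample_scores_[:, a]
            sd = ax.std(ddof=0)
            for i in range(len(names)):
                xs = Xr[:, i].std(ddof=0)
                bip[i, a] = float(np.mean(_centre(Xr[:, i][:, None]).ravel()
                                          * _centre(ax[:, None]).ravel())
                                  / (xs * sd)) if xs > 0 and sd > 0 else 0.0
        self.biplot_scores_ = pd.DataFrame(
            bip, index=names, columns=[f"RDA{a + 1}" for a in range(nax)])
        self.selected_ = names
        self._Yr, self._Xr, self._Z, self._n, self._p, self._q = \
            Yr, Xr, Z, n, p, q
        if self.n_perm > 0:
            perm = permutation_test(Y, X[:, keep], Z, n_perm=self.n_perm,
                                    seed=self.seed, scope=self.scope)
            self.p_value_ = perm["p_value"]
            self.perm_ = perm
        else:
            self.p_value_ = None
        self.result_ = RDAResult(
            self.r2_, self.adj_r2_, self.F_, self.p_value_,
            self.axis_variance_, self.sample_scores_, self.biplot_scores_,
            self.selected_, self.n_perm)
        return self

    def transform(self, Y) -> np.ndarray:
        if not hasattr(self, "sample_scores_"):
            raise RuntimeError("not fitted")
        Yr = _residualise(np.asarray(Y, float), self._Z)
        fitted, _, _ = _fit_ss(Yr, self._Xr)
        u, s, vt = np.linalg.svd(self._fitted_cache(), full_matrices=False)
        return fitted @ vt.T[:, :self.sample_scores_.shape[1]]

    def _fitted_cache(self) -> np.ndarray:
        fitted, _, _ = _fit_ss(self._Yr, self._Xr)
        return fitted

    def fit_transform(self, Y, X, Z=None) -> np.ndarray:
        return self.fit(Y, X, Z).sample_scores_


def _independent_columns(a: np.ndarray, tol: float = 1e-9) -> list[int]:
    keep: list[int] = []
    for i in range(a.shape[1]):
        cand = a[:, keep + [i]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(a).max())) \
                == len(keep) + 1:
            keep.append(i)
    return keep


def partial_rda(Y, X, Z=None, n_perm: int = 0, seed: int = 0) -> RDAResult:
    """Functional wrapper over :class:`PartialRDA`."""
    return PartialRDA(n_perm=n_perm, seed=seed).fit(Y, X, Z).result_


# ---------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------

def _global_F(Yr: np.ndarray, Xr: np.ndarray, p: int, q: int) -> float:
    _, ss_fit, ss_tot = _fit_ss(Yr, Xr)
    n = len(Yr)
    df_res = n - 1 - p - q
    ss_res = ss_tot - ss_fit
    if df_res <= 0 or ss_res <= 0:
        return np.inf
    return (ss_fit / p) / (ss_res / df_res)


def permutation_test(Y, X, Z=None, n_perm: int = 999, seed: int = 0,
                     scope: str = "global") -> dict:
    """Permutation F-test for a (partial) RDA.

    Rows of the *residualised* response are permuted while the
    conditioning structure stays fixed (reduced-model residual
    permutation); ``p = (exceedances + 1) / (n_perm + 1)``, so the
    smallest attainable p-value is ``1 / (n_perm + 1)``.
    """
    if scope not in ("global", "axis", "term"):
        raise ValueError("scope must be global, axis or term")
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    Z = None if Z is None else np.asarray(Z, float)
    Yr = _residualise(Y, Z)
    Xr = _residualise(X, Z)
    p = _rank(Xr)
    q = _rank(Z) if Z is not None else 0
    F_obs = _global_F(Yr, Xr, p, q)
    if scope == "global":
        exceed = 0
        n = len(Yr)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _global_F(Yr[perm], Xr, p, q) >= F_obs:
                exceed += 1
        pval = (exceed + 1) / (n_perm + 1)
        return {"F": float(F_obs), "p_value": float(pval),
                "n_perm": n_perm, "scope": scope}
    if scope == "axis":
        fitted, ss_fit, ss_tot = _fit_ss(Yr, Xr)
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        nax = min(p, fitted.shape[1])
        n = len(Yr)
        df_res = n - 1 - p - q
        ss_res = ss_tot - ss_fit
        F_axes = (s[:nax]**2) / (ss_res / df_res)
        exceed = np.zeros(nax)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            fp, sfp, stp = _fit_ss(Yr[perm], Xr)
            sp = np.linalg.svd(fp, compute_uv=False)[:nax]
            Fp = (sp**2) / ((stp - sfp) / df_res)
            exceed += Fp >= F_axes
        pvals = (exceed + 1) / (n_perm + 1)
        return {"F": F_axes, "p_value": pvals, "n_perm": n_perm,
                "scope": scope}
    raise NotImplementedError("term scope: test each predictor marginally "
                              "via forward_select")


# ---------------------------------------------------------------------
# forward selection and variance partitioning
# ---------------------------------------------------------------------

def forward_select(Y, X, Z=None, alpha: float = 0.05,
                   r2_stop: bool = True, n_perm: int = 199,
                   seed: int = 0) -> list:
    """Forward selection of predictors with double stopping.

    Adds the predictor with the largest gain in constrained variance,
    one at a time, while (a) its marginal permutation p-value is below
    ``alpha`` and (b) the cumulative adjusted R-squared stays below the
    full-model adjusted R-squared (disable with ``r2_stop=False``).
    A global permutation pretest guards the whole procedure, and the
    adjusted-R-squared ceiling is enforced from the second variable
    onward: a single strong predictor legitimately exceeds the global
    adjusted R-squared when the remaining candidates are noise (noise
    predictors only lower the Ezekiel correction), so applying the
    ceiling to the first pick would veto exactly the variables the
    procedure exists to find.  Returns the selected column names in
    selection order.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{i}" for i in range(np.asarray(X).shape[1])]
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Z = None if Z is None else np.asarray(Z, float)
    rng = np.random.default_rng(seed)
    n = len(Y)
    Yr = _residualise(Y, Z)
    Xr = _residualise(X, Z)
    q = _rank(Z) if Z is not None else 0
    _, ss_full, ss_tot = _fit_ss(Yr, Xr)
    p_full = _rank(Xr)
    adj_full = adjusted_r2(ss_full / ss_tot, n, p_full)
    if alpha <= 1.0:
        global_p = permutation_test(Y, X, Z, n_perm=n_perm,
                                    seed=seed)["p_value"]
        if global_p >= alpha:
            return []
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    while remaining:
        gains = []
        for j in remaining:
            cols = Xr[:, selected + [j]]
            _, ss_fit, _ = _fit_ss(Yr, cols)
            gains.append(ss_fit)
        j_best = remaining[int(np.argmax(gains))]
        cols = Xr[:, selected + [j_best]]
        # marginal test of the added variable given those already in
        base = Xr[:, selected] if selected else None
        Yb = _residualise(Yr, base)
        xb = _residualise(Xr[:, [j_best]], base)
        F_obs = _global_F(Yb, xb, 1, q + len(selected))
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _global_F(Yb[perm], xb, 1, q + len(selected)) >= F_obs:
                exceed += 1
        pval = (exceed + 1) / (n_perm + 1)
        if pval >= alpha:
            break
        _, ss_fit, _ = _fit_ss(Yr, cols)
        adj_cum = adjusted_r2(ss_fit / ss_tot, n, len(selected) + 1)
        if r2_stop and selected and adj_cum > adj_full:
            break
        selected.append(j_best)
        remaining.remove(j_best)
    return [names[j] for j in selected]


def variance_partition(Y, X, Z) -> dict:
    """Adjusted-R-squared partition into pure-environment, pure-space,
    shared and unexplained fractions via the three nested models."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    n = len(Y)

    def _adj(pred: np.ndarray) -> float:
        Yc = _centre(Y)
        pc = _centre(pred)
        _, ss_fit, ss_tot = _fit_ss(Yc, pc)
        return adjusted_r2(ss_fit / ss_tot, n, _rank(pc))

    adj_x = _adj(X)
    adj_z = _adj(Z)
    adj_joint = _adj(np.hstack([X, Z]))
    pure_env = adj_joint - adj_z
    pure_space = adj_joint - adj_x
    shared = adj_x + adj_z - adj_joint
    return {
        "pure_env": pure_env,
        "pure_space": pure_space,
        "shared": shared,
        "unexplained": 1.0 - adj_joint,
        "adj_r2_env": adj_x,
        "adj_r2_space": adj_z,
        "adj_r2_joint": adj_joint,
    }
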