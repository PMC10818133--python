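"""Divergence and clustering statistics for two-population comparisons.

Implements the classic Weir & Cockerham (1984) three-component F_ST
estimator for diploids (ratio-of-sums across loci for the genome-wide
value; negative per-locus values retained), squared-Euclidean individual
distances with a kernel-density "barcode gap" heuristic for detecting
sympatric taxa, pixy-style windowed absolute divergence D_XY that
accounts for invariant sites and missing genotypes, and PCA + K-means
taxon assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------

def wc_fst_components(gm: GenotypeMatrix, pops: tuple[str, str]
                      ) -> pd.DataFrame:
    """Per-site Weir-Cockerham variance components a, b, c.

    a = among populations, b = among individuals within populations,
    c = within individuals (heterozygosity).  Sites with fewer than two
    genotyped diploids in either population get NaN components.
    """
    pop_labels = gm.ind_meta["population"].to_numpy()
    rows = []
    for pop in pops:
        idx = np.flatnonzero(pop_labels == pop)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} absent from genotype matrix")
        rows.append(idx)
    r = 2
    comp = np.full((gm.n_sites, 3), np.nan)
    d = gm.dosages
    n_i = np.zeros((2, gm.n_sites))
    p_i = np.zeros((2, gm.n_sites))
    h_i = np.zeros((2, gm.n_sites))
    for k, idx in enumerate(rows):
        sub = d[idx, :]
        called = sub != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, sub, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h = ((sub == 1) & called).sum(axis=0) / np.maximum(n, 1)
        n_i[k] = n
        p_i[k] = p
        h_i[k] = h
    ok = (n_i >= 2).all(axis=0)
    n1, n2 = n_i[0, ok], n_i[1, ok]
    p1, p2 = p_i[0, ok], p_i[1, ok]
    h1, h2 = h_i[0, ok], h_i[1, ok]
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    comp[ok, 0] = a
    comp[ok, 1] = b
    comp[ok, 2] = c
    out = gm.site_meta[["contig", "pos"]].copy()
    out["a"] = comp[:, 0]
    out["b"] = comp[:, 1]
    out["c"] = comp[:, 2]
    return out


def wc_fst(gm: GenotypeMatrix, pops: tuple[str, str],
           per_locus: bool = False):
    """Weir-Cockerham F_ST between two populations.

    Genome-wide value is the ratio of sums ``sum(a) / sum(a+b+c)``;
    ``per_locus=True`` additionally returns per-site ``a/(a+b+c)``
    (negative values retained, NaN where undefined).
    """
    comp = wc_fst_components(gm, pops)
    a = comp["a"].to_numpy()
    tot = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
    valid = ~np.isnan(tot)
    denom = np.nansum(tot[valid])
    global_fst = float(np.nansum(a[valid]) / denom) if denom != 0 else np.nan
    if not per_locus:
        return global_fst
    with np.errstate(invalid="ignore", divide="ignore"):
        site_fst = np.where(tot != 0, a / tot, np.nan)
    per_site = comp[["contig", "pos"]].copy()
    per_site["fst"] = site_fst
    return global_fst, per_site


def pairwise_fst_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Genome-wide W&C F_ST for every population pair in the matrix."""
    pops = list(pd.unique(gm.ind_meta["population"]))
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        out.loc[p1, p1] = 0.0
        for p2 in pops[i + 1:]:
            f = wc_fst(gm, (p1, p2))
            out.loc[p1, p2] = out.loc[p2, p1] = f
    return out


# ---------------------------------------------------------------------
# individual distances and the multi-peak gap heuristic
# ---------------------------------------------------------------------

@dataclass
class PairDistanceSet:
    """Pairwise squared Euclidean distances among individuals at a reef."""

    reef: str
    pairs: pd.DataFrame  # columns ind_i, ind_j, distance
    field_names: tuple = ("ind_i", "ind_j", "distance")

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["distance"].to_numpy()


def pair_distances(gm: GenotypeMatrix, reef: str) -> PairDistanceSet:
    """Squared Euclidean dosage distances between all individuals at a
    reef, computed over co-called sites and rescaled by
    ``total sites / co-called sites`` so missingness does not shrink
    distances."""
    idx = np.flatnonzero(gm.ind_meta["reef"].to_numpy() == reef)
    if idx.size < 2:
        raise ValueError(f"fewer than 2 individuals at reef {reef!r}")
    ids = gm.ind_meta["id"].to_numpy()[idx]
    d = gm.dosages[idx, :].astype(float)
    called = gm.dosages[idx, :] != MISSING
    n_sites = gm.n_sites
    rows = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            both = called[i] & called[j]
            n_co = int(both.sum())
            if n_co == 0:
                logger.warning("pair (%s, %s) shares no called sites",
                               ids[i], ids[j])
                dist = np.nan
            else:
                diff = d[i, both] - d[j, both]
                dist = float(diff @ diff) * n_sites / n_co
            rows.append((ids[i], ids[j], dist))
    return PairDistanceSet(reef, pd.DataFrame(
        rows, columns=["ind_i", "ind_j", "distance"]))


@dataclass
class GapPeaks:
    """Peaks and gaps of a distance distribution."""

    n_peaks: int
    peak_locations: np.ndarray
    gap_locations: np.ndarray
    assignments: pd.DataFrame | None = None
    grid: np.ndarray | None = None
    density: np.ndarray | None = None


def distance_gap_peaks(dset: PairDistanceSet,
                       gap_depth: float = 0.1,
                       grid_points: int = 512) -> GapPeaks:
    """Detect multimodality in the pairwise-distance distribution.

    A Gaussian kernel density (Silverman bandwidth) is evaluated over the
    distances; peaks are local maxima, and a *gap* is a local minimum
    whose density falls below ``gap_depth`` times the smaller of its two
    flanking peaks — the analogue of the DNA-barcoding gap separating
    within-taxon from between-taxon comparisons.  Pairs below the first
    gap are classified conspecific.
    """
    x = dset.distances
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("need at least 3 pairwise distances")
    if np.allclose(x, x[0]):
        return GapPeaks(1, np.array([x[0]]), np.array([]),
                        _assign(dset, np.inf))
    kde = gaussian_kde(x, bw_method="silverman")
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_points)
    dens = kde(grid)
    d1 = np.diff(dens)
    peaks = np.flatnonzero((d1[:-1] > 0) & (d1[1:] <= 0)) + 1
    minima = np.flatnonzero((d1[:-1] < 0) & (d1[1:] >= 0)) + 1
    gaps = []
    for m in minima:
        left = peaks[peaks < m]
        right = peaks[peaks > m]
        if len(left) == 0 or len(right) == 0:
            continue
        flank = min(dens[left[-1]], dens[right[0]])
        if dens[m] < gap_depth * flank:
            gaps.append(grid[m])
    gaps = np.array(gaps)
    first_gap = gaps[0] if len(gaps) else np.inf
    return GapPeaks(len(peaks), grid[peaks], gaps, _assign(dset, first_gap),
                    grid, dens)


def _assign(dset: PairDistanceSet, first_gap: float) -> pd.DataFrame:
    out = dset.pairs.copy()
    out["conspecific"] = out["distance"] < first_gap
    return out


# ---------------------------------------------------------------------
# windowed D_XY
# ---------------------------------------------------------------------

@dataclass
class WindowStat:
    """One 1000 bp window's D_XY tallies."""

    contig: str
    start: int  # 1-based inclusive
    end: int    # exclusive
    diff_sum: float
    comparison_sum: float

    @property
    def dxy(self) -> float:
        if self.comparison_sum > 0:
            return self.diff_sum / self.comparison_sum
        return np.nan


def dxy_windows(gm: GenotypeMatrix, pops: tuple[str, str],
                window: int = 1000, tag_length: int | None = None,
                assume_invariant_called: bool = True) -> list[WindowStat]:
    """Windowed absolute divergence D_XY in the pixy accounting.

    Per site, the between-population difference count is
    ``c1 (a2 - c2) + (a1 - c1) c2`` and the comparison count ``a1 a2``,
    with ``c_k`` the alternate-allele count and ``a_k`` the called allele
    number in population k; the window statistic is the ratio of sums.

    SNP matrices usually omit invariant sites; with
    ``assume_invariant_called`` every position of each tag (length
    ``tag_length``, default the maximum SNP position) not present in the
    matrix contributes ``a1_full * a2_full`` comparisons and zero
    differences.  Pass an all-sites matrix and set it False to use only
    explicit records.
    """
    from .jafs import site_allele_counts

    c1, a1, c2, a2 = site_allele_counts(gm, pops)
    pop_labels = gm.ind_meta["population"].to_numpy()
    full1 = 2 * int((pop_labels == pops[0]).sum())
    full2 = 2 * int((pop_labels == pops[1]).sum())
    diffs = c1 * (a2 - c2) + (a1 - c1) * c2
    comps = a1 * a2
    out: list[WindowStat] = []
    sm = gm.site_meta
    for contig, grp in sm.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        sidx = grp.index.to_numpy()
        length = tag_length if tag_length is not None else int(pos.max())
        for start in range(1, length + 1, window):
            end = start + window
            in_win = (pos >= start) & (pos < end)
            ds = float(diffs[sidx[in_win]].sum())
            cs = float(comps[sidx[in_win]].sum())
            if assume_invariant_called:
                n_invariant = min(end - 1, length) - (start - 1) \
                    - int(in_win.sum())
                cs += n_invariant * full1 * full2
            out.append(WindowStat(str(contig), start, end, ds, cs))
    return out


def dxy_genomewide(windows: list[WindowStat]) -> float:
    """Count-weighted genome-wide D_XY: total differences over total
    comparisons (windows without comparisons are excluded)."""
    ds = sum(w.diff_sum for w in windows if w.comparison_sum > 0)
    cs = sum(w.comparison_sum for w in windows if w.comparison_sum > 0)
    return ds / cs if cs > 0 else np.nan


# ---------------------------------------------------------------------
# PCA + K-means taxon assignment
# ---------------------------------------------------------------------

class TaxonClusterer:
    """PCA of mean-imputed dosages followed by K-means on the leading
    axes (sklearn-style estimator).

    Attributes set by :meth:`fit`: ``labels_``, ``coords_`` (individual
    scores on the retained axes), ``explained_variance_ratio_``,
    ``inertia_``.
    """

    def __init__(self, k: int = 2, n_axes: int = 10, seed: int = 0,
                 n_init: int = 10):
        self.k = k
        self.n_axes = n_axes
        self.seed = seed
        self.n_init = n_init

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "n_axes": self.n_axes, "seed": self.seed,
                "n_init": self.n_init}

    def set_params(self, **kw) -> "TaxonClusterer":
        for key, v in kw.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit(self, X: GenotypeMatrix | np.ndarray, y=None) -> "TaxonClusterer":
        from sklearn.cluster import KMeans
        from sklearn.decomposition import PCA

        if isinstance(X, GenotypeMatrix):
            if self.k > X.n_individuals:
                raise ValueError("k exceeds the number of individuals")
            d = X.dosages.astype(float)
            d[X.dosages == MISSING] = np.nan
        else:
            d = np.asarray(X, dtype=float)
            if self.k > d.shape[0]:
                raise ValueError("k exceeds the number of individuals")
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        filled = np.where(np.isnan(d), col_mean[None, :], d)
        n_axes = min(self.n_axes, filled.shape[0] - 1, filled.shape[1])
        pca = PCA(n_components=n_axes, random_state=self.seed)
        coords = pca.fit_transform(filled)
        km = KMeans(n_clusters=self.k, n_init=self.n_init,
                    random_state=self.seed)
        self.labels_ = km.fit_predict(coords)
        self.coords_ = coords
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.inertia_ = float(km.inertia_)
        self._pca = pca
        self._km = km
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def pca_kmeans_assign(gm: GenotypeMatrix, k: int, n_axes: int = 10,
                      seed: int = 0):
    """Cluster individuals on the leading PC axes; returns
    (labels, PC coordinates, explained variance ratio, inertia)."""
    tc = TaxonClusterer(k=k, n_axes=n_axes, seed=seed).fit(gm)
    return tc.labels_, tc.coords_, tc.explained_variance_ratio_, tc.inertia_
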