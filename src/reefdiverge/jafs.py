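"""Two-population joint allele-frequency spectra (JAFS).

A JAFS is an ``(n1+1) x (n2+1)`` table whose cell ``(i, j)`` holds the
number (or expected density) of SNPs with derived/alternate allele count
``i`` in population 1 and ``j`` in population 2, where ``n1``/``n2`` are
haploid sample sizes.  Genotype data here are unpolarised, so spectra are
built on the arbitrary ref/alt orientation and *folded* (indexed by minor
allele) before analysis, which is exact for folded inference.

Sites with missing genotypes are *projected* down to a common sample size
by hypergeometric expectation, the standard trick that lets partially
genotyped sites contribute fractional mass instead of being lost.

The text serialisation is the classic SFS exchange format: a header line
``"<n1+1> <n2+1> folded|unfolded"``, the row-major table, then a 0/1 mask
line (1 = masked).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: folded cells with total minor-allele count 1 or 2
LOW_COUNT_CELLS = ((1, 0), (0, 1), (2, 0), (0, 2), (1, 1))


@dataclass
class JAFS:
    """Joint allele-frequency spectrum with mask and provenance.

    ``mask[i, j]`` True means cell (i, j) is excluded from all sums and
    likelihoods.  The absorbing corners (0, 0) and (n1, n2) are always
    masked.  ``sample_sizes`` are haploid allele-copy counts.
    """

    counts: np.ndarray
    sample_sizes: tuple[int, int]
    mask: np.ndarray | None = None
    folded: bool = False
    provenance: dict = field(default_factory=dict)
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n1, n2 = self.sample_sizes
        if self.counts.shape != (n1 + 1, n2 + 1):
            raise ValueError(
                f"counts shape {self.counts.shape} != {(n1 + 1, n2 + 1)}")
        if self.mask is None:
            self.mask = np.zeros_like(self.counts, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
        self.mask[0, 0] = True
        self.mask[n1, n2] = True

    # ------------------------------------------------------------------

    @property
    def n1(self) -> int:
        return self.sample_sizes[0]

    @property
    def n2(self) -> int:
        return self.sample_sizes[1]

    def unmasked_sum(self) -> float:
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JAFS":
        return JAFS(self.counts.copy(), self.sample_sizes, self.mask.copy(),
                    self.folded, dict(self.provenance),
                    None if self.se is None else self.se.copy())

    def normalised(self) -> "JAFS":
        out = self.copy()
        total = out.unmasked_sum()
        if total > 0:
            out.counts = out.counts / total
            if out.se is not None:
                out.se = out.se / total
        return out

    def transpose(self) -> "JAFS":
        return JAFS(self.counts.T.copy(), (self.n2, self.n1), self.mask.T.copy(),
                    self.folded, dict(self.provenance),
                    None if self.se is None else self.se.T.copy())

    # -- folding -------------------------------------------------------

    def fold(self) -> "JAFS":
        """Fold onto minor-allele orientation.

        Cell (i, j) with ``i + j`` above the hinge ``(n1+n2)/2`` is added
        into its partner ``(n1-i, n2-j)``; hinge cells are symmetrised at
        half weight.  Total unmasked mass is conserved; folded-out cells
        get zero weight and are masked.
        """
        if self.folded:
            logger.warning("fold() on an already folded spectrum: no-op")
            return self.copy()
        n1, n2 = self.sample_sizes
        total = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
        hinge = (n1 + n2) / 2.0
        rev = self.counts[::-1, ::-1]
        folded = np.where(total < hinge, self.counts + rev, 0.0)
        on_hinge = total == hinge
        folded[on_hinge] = 0.5 * (self.counts + rev)[on_hinge]
        # a masked cell poisons its fold partner too
        mask = (self.mask | self.mask[::-1, ::-1]) | (total > hinge)
        prov = dict(self.provenance)
        return JAFS(folded, self.sample_sizes, mask, folded=True,
                    provenance=prov)

    def mask_low_counts(self, include_diagonal_doubleton: bool = True) -> "JAFS":
        """Mask folded singleton/doubleton cells (total minor count <= 2).

        ``include_diagonal_doubleton`` controls whether (1, 1) is masked
        along with (1,0), (0,1), (2,0), (0,2).
        """
        out = self.copy()
        cells = [c for c in LOW_COUNT_CELLS
                 if include_diagonal_doubleton or c != (1, 1)]
        masked_mass = 0.0
        for (i, j) in cells:
            if i <= self.n1 and j <= self.n2:
                if not out.mask[i, j]:
                    masked_mass += out.counts[i, j]
                out.mask[i, j] = True
        out.provenance["masked_low_count_mass"] = masked_mass
        if out.unmasked_sum() == 0:
            logger.warning("mask_low_counts left zero usable mass")
        return out

    # -- serialisation -------------------------------------------------

    def to_file(self, path) -> None:
        n1, n2 = self.sample_sizes
        with open(path, "w") as fh:
            fh.write(f"{n1 + 1} {n2 + 1} {'folded' if self.folded else 'unfolded'}\n")
            fh.write(" ".join(f"{v:.12g}" for v in self.counts.ravel()) + "\n")
            fh.write(" ".join("1" if m else "0" for m in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "JAFS":
        with open(path) as fh:
            header = fh.readline().split()
            d1, d2 = int(header[0]), int(header[1])
            folded = len(header) > 2 and header[2] == "folded"
            counts = np.array(fh.readline().split(), dtype=float).reshape(d1, d2)
            mask_line = fh.readline().split()
            mask = (np.array(mask_line, dtype=int).reshape(d1, d2).astype(bool)
                    if mask_line else None)
        return cls(counts, (d1 - 1, d2 - 1), mask, folded=folded)


# ---------------------------------------------------------------------
# construction from genotypes
# ---------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _projection_weights(a: int, c: int, n_proj: int) -> np.ndarray:
    """P(i of n_proj sampled copies are alt | c alt among a called copies)."""
    i = np.arange(n_proj + 1)
    return hypergeom.pmf(i, a, c, n_proj)


def site_allele_counts(gm: GenotypeMatrix, pops: tuple[str, str]
                       ) -> tuple[np.ndarray, ...]:
    """Per-site (alt count, called allele number) for each population."""
    out = []
    pop_labels = gm.ind_meta["population"].to_numpy()
    for pop in pops:
        rows = np.flatnonzero(pop_labels == pop)
        if rows.size == 0:
            raise ValueError(f"population {pop!r} absent from genotype matrix")
        sub = gm.dosages[rows, :]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0).astype(np.int64)
        an = 2 * called.sum(axis=0).astype(np.int64)
        out.extend([alt, an])
    return tuple(out)


def build_jafs(gm: GenotypeMatrix, pops: tuple[str, str],
               projection: tuple[int, int], fold: bool = True,
               mask_low: bool = True,
               include_diagonal_doubleton: bool = True) -> JAFS:
    """Build the (optionally folded and masked) JAFS from genotypes.

    Each site with called allele numbers ``(a1, a2)`` at least the
    projection sizes in *both* populations contributes its hypergeometric
    projection expectation; other sites are dropped and tallied.
    """
    n1p, n2p = projection
    c1, a1, c2, a2 = site_allele_counts(gm, pops)
    usable = (a1 >= n1p) & (a2 >= n2p)
    counts = np.zeros((n1p + 1, n2p + 1))
    for s in np.flatnonzero(usable):
        w1 = _projection_weights(int(a1[s]), int(c1[s]), n1p)
        w2 = _projection_weights(int(a2[s]), int(c2[s]), n2p)
        counts += np.outer(w1, w2)
    spectrum = JAFS(
        counts, (n1p, n2p), folded=False,
        provenance={
            "populations": list(pops),
            "projection": [n1p, n2p],
            "n_sites_used": int(usable.sum()),
            "n_sites_dropped": int((~usable).sum()),
        })
    if fold:
        spectrum = spectrum.fold()
        if mask_low:
            spectrum = spectrum.mask_low_counts(include_diagonal_doubleton)
    return spectrum


def bootstrap_jafs(gm: GenotypeMatrix, pops: tuple[str, str],
                   projection: tuple[int, int], n_boot: int = 100,
                   seed: int = 0, fold: bool = True, mask_low: bool = True,
                   include_diagonal_doubleton: bool = True) -> list[JAFS]:
    """Nonparametric bootstrap over RAD tags (the linkage unit).

    Tags are resampled with replacement and the spectrum rebuilt per
    replicate; 100 replicates by default.
    """
    rng = np.random.default_rng(seed)
    tag_ids = gm.tag_index
    tags = np.unique(tag_ids)
    if tags.size == 1:
        logger.warning("single RAD tag: all bootstrap replicates identical")
    n1p, n2p = projection
    c1, a1, c2, a2 = site_allele_counts(gm, pops)
    usable = (a1 >= n1p) & (a2 >= n2p)
    # per-tag unfolded spectra, so replicates are sums over resampled tags
    tag_spectra = np.zeros((tags.size, n1p + 1, n2p + 1))
    for k, tag in enumerate(tags):
        for s in np.flatnonzero(usable & (tag_ids == tag)):
            w1 = _projection_weights(int(a1[s]), int(c1[s]), n1p)
            w2 = _projection_weights(int(a2[s]), int(c2[s]), n2p)
            tag_spectra[k] += np.outer(w1, w2)
    out = []
    for b in range(n_boot):
        pick = rng.integers(0, tags.size, size=tags.size)
        counts = tag_spectra[pick].sum(axis=0)
        rep = JAFS(counts, (n1p, n2p), folded=False,
                   provenance={"bootstrap_replicate": b})
        if fold:
            rep = rep.fold()
            if mask_low:
                rep = rep.mask_low_counts(include_diagonal_doubleton)
        out.append(rep)
    return out


def fold_jafs(s: JAFS) -> JAFS:
    """Functional alias for :meth:`JAFS.fold`."""
    return s.fold()


def mask_low_counts(s: JAFS, include_diagonal_doubleton: bool = True) -> JAFS:
    """Functional alias for :meth:`JAFS.mask_low_counts`."""
    return s.mask_low_counts(include_diagonal_doubleton)
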