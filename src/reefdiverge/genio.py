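"""Genotype I/O and post-assembly filtering for RAD-seq SNP matrices.

The central container is :class:`GenotypeMatrix`: a diploid dosage matrix
(individuals x biallelic sites, values 0/1/2 with -1 for missing) plus site
and individual metadata.  The filtering cascade mirrors the standard
post-variant-calling workflow for reduced-representation data:

    stage 1 site filters (biallelic, MAC, depth, per-site missingness)
    -> individual missingness filter
    -> clonal-duplicate removal
    -> stage 2 site filters (stricter missingness, MAF)
    -> linkage pruning by variance inflation factor (VIF)

Threshold conventions: missingness removal uses strict ``>``, clone
similarity uses ``>=``, and MAC/MAF removal uses ``<`` (a site *survives*
when its count/frequency is at or above the minimum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with site/individual metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_sites)`` int8 array of alternate-allele counts
        per genotype: 0, 1, 2, or -1 for missing.
    site_meta
        DataFrame with columns ``contig``, ``pos`` (1-based), ``ref``,
        ``alt`` and boolean ``biallelic``; one row per site.
    ind_meta
        DataFrame with columns ``id``, ``population``, ``reef``; one row
        per individual.
    depth
        Optional per-genotype read depth, same shape as ``dosages``.
    """

    dosages: np.ndarray
    site_meta: pd.DataFrame
    ind_meta: pd.DataFrame
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        n_ind, n_sites = self.dosages.shape
        if len(self.ind_meta) != n_ind:
            raise ValueError("ind_meta rows != number of individuals")
        if len(self.site_meta) != n_sites:
            raise ValueError("site_meta rows != number of sites")
        self.site_meta = self.site_meta.reset_index(drop=True)
        self.ind_meta = self.ind_meta.reset_index(drop=True)

    # -- basic queries -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.dosages != MISSING

    @property
    def tag_index(self) -> np.ndarray:
        """Integer RAD-tag id per site (contigs are tags)."""
        return pd.factorize(self.site_meta["contig"])[0]

    def missing_fraction_per_individual(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=1)

    def missing_fraction_per_site(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele number)."""
        called = self.called
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        return alt.astype(np.int64), an.astype(np.int64)

    def minor_allele_counts(self) -> np.ndarray:
        alt, an = self.allele_counts()
        return np.minimum(alt, an - alt)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[:, idx],
            site_meta=self.site_meta.iloc[np.asarray(idx)].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[np.asarray(idx), :],
            ind_meta=self.ind_meta.iloc[np.asarray(idx)].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[idx, :],
        )

    def subset_populations(self, pops: list[str]) -> "GenotypeMatrix":
        keep = np.flatnonzero(self.ind_meta["population"].isin(pops).to_numpy())
        return self.take_individuals(keep)


@dataclass
class FilterConfig:
    """Thresholds for the filtering cascade (defaults follow common
    RAD-seq practice: MAC 3, depth 5-100, 50% then 5% site missingness,
    70% individual missingness, MAF 0.01, 50/5 SNP VIF-2 pruning, 99%
    clone similarity)."""

    mac_min: int = 3
    depth_min: int = 5
    depth_max: int = 100
    site_missing_max_1: float = 0.5
    site_missing_max_2: float = 0.05
    ind_missing_max: float = 0.7
    maf_min: float = 0.01
    ld_window: int = 50
    ld_step: int = 5
    vif_max: float = 2.0
    clone_similarity: float = 0.99

    def __post_init__(self) -> None:
        for name in ("site_missing_max_1", "site_missing_max_2",
                     "ind_missing_max", "maf_min", "clone_similarity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min > depth_max")


@dataclass
class FilterReport:
    """Tally of removals per filter, in application order."""

    rows: list[dict] = field(default_factory=list)

    def add(self, filter_name: str, sites_removed: int = 0,
            individuals_removed: int = 0) -> None:
        self.rows.append({
            "filter": filter_name,
            "sites_removed": int(sites_removed),
            "individuals_removed": int(individuals_removed),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["filter", "sites_removed", "individuals_removed"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when present)."""
    sm = gm.site_meta
    contigs = pd.unique(sm["contig"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=reefdiverge\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        cols = "\t".join(gm.ind_meta["id"].astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT" if gm.depth is None else "GT:DP"
        for j in range(gm.n_sites):
            row = sm.iloc[j]
            fields = [str(row["contig"]), str(int(row["pos"])), ".",
                      str(row["ref"]), str(row["alt"]), ".", "PASS", ".", fmt]
            if gm.depth is None:
                sample_cols = [gt_strings[int(d)] for d in gm.dosages[:, j]]
            else:
                sample_cols = [
                    f"{gt_strings[int(d)]}:{int(dp)}"
                    for d, dp in zip(gm.dosages[:, j], gm.depth[:, j])
                ]
            fh.write("\t".join(fields + sample_cols) + "\n")


def read_vcf(path, populations: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` via cyvcf2.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    populations
        Optional DataFrame mapping ``id`` to ``population`` (and optionally
        ``reef``); unmapped individuals get population ``"NA"``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    has_depth = True
    for var in vcf:
        biallelic = len(var.ALT) == 1
        if biallelic:
            gts = var.gt_types.astype(np.int8)  # 0,1,2; 3=missing
            gts[gts == 3] = MISSING
        else:
            gts = np.full(len(samples), MISSING, dtype=np.int8)
        dosage_rows.append(gts)
        try:
            dp = var.format("DP")
        except Exception:
            dp = None
        if dp is None:
            has_depth = False
        else:
            depth_rows.append(np.where(dp < 0, 0, dp).ravel().astype(np.int32))
        alt = var.ALT[0] if var.ALT else "."
        if len(var.ALT) > 1:
            alt = ",".join(var.ALT)
        meta_rows.append((var.CHROM, var.POS, var.REF, alt, biallelic))
    vcf.close()
    if not meta_rows:
        raise ValueError(f"no records in {path}")
    dosages = np.vstack(dosage_rows).T
    depth = np.vstack(depth_rows).T if (has_depth and depth_rows) else None
    site_meta = pd.DataFrame(
        meta_rows, columns=["contig", "pos", "ref", "alt", "biallelic"]
    )
    ind_meta = pd.DataFrame({"id": samples})
    if populations is not None:
        populations = populations.set_index("id")
        ind_meta["population"] = [
            populations["population"].get(s, "NA") for s in samples
        ]
        if "reef" in populations.columns:
            ind_meta["reef"] = [populations["reef"].get(s, "NA") for s in samples]
    for col in ("population", "reef"):
        if col not in ind_meta.columns:
            ind_meta[col] = "NA"
    return GenotypeMatrix(dosages, site_meta, ind_meta, depth=depth)


# ---------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------

def apply_depth_mask(gm: GenotypeMatrix, cfg: FilterConfig,
                     report: FilterReport | None = None) -> GenotypeMatrix:
    """Set genotypes with depth outside [depth_min, depth_max] to missing.

    Skipped with a warning when no per-genotype depth is available; the
    depth filter then has no effect downstream (missingness is recomputed
    at each stage)."""
    if gm.depth is None:
        logger.warning("no DP field: depth filter skipped")
        return gm
    bad = (gm.depth < cfg.depth_min) | (gm.depth > cfg.depth_max)
    dosages = gm.dosages.copy()
    dosages[bad] = MISSING
    if report is not None:
        report.add("depth_mask", sites_removed=0)
    return replace(gm, dosages=dosages)


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig, stage: int,
                 report: FilterReport | None = None) -> GenotypeMatrix:
    """Site filters; ``stage`` 1 = {biallelic, MAC, depth, loose
    missingness}, stage 2 = {strict missingness, MAF}."""
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    report = report if report is not None else FilterReport()
    keep = np.ones(gm.n_sites, dtype=bool)
    if stage == 1:
        if "biallelic" in gm.site_meta.columns:
            bi = gm.site_meta["biallelic"].to_numpy().astype(bool)
        else:
            bi = np.ones(gm.n_sites, dtype=bool)
        report.add("biallelic", sites_removed=int((~bi).sum()))
        keep &= bi
        gm = apply_depth_mask(gm, cfg, report)
        mac = gm.minor_allele_counts()
        fail_mac = keep & (mac < cfg.mac_min)
        report.add("mac", sites_removed=int(fail_mac.sum()))
        keep &= ~fail_mac
        miss = gm.missing_fraction_per_site()
        fail_miss = keep & (miss > cfg.site_missing_max_1)
        report.add("site_missing_stage1", sites_removed=int(fail_miss.sum()))
        keep &= ~fail_miss
    else:
        miss = gm.missing_fraction_per_site()
        fail_miss = keep & (miss > cfg.site_missing_max_2)
        report.add("site_missing_stage2", sites_removed=int(fail_miss.sum()))
        keep &= ~fail_miss
        alt, an = gm.allele_counts()
        with np.errstate(divide="ignore", invalid="ignore"):
            maf = np.where(an > 0, np.minimum(alt, an - alt) / np.maximum(an, 1), 0.0)
        fail_maf = keep & (maf < cfg.maf_min)
        report.add("maf", sites_removed=int(fail_maf.sum()))
        keep &= ~fail_maf
    return gm.take_sites(np.flatnonzero(keep))


def filter_individuals(gm: GenotypeMatrix, cfg: FilterConfig,
                       report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove individuals with missing fraction strictly above the cap."""
    miss = gm.missing_fraction_per_individual()
    keep = miss <= cfg.ind_missing_max
    if not keep.any():
        raise ValueError("all individuals exceed the missingness cap")
    if report is not None:
        report.add("individual_missing", individuals_removed=int((~keep).sum()))
    return gm.take_individuals(np.flatnonzero(keep))


def pairwise_similarity(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(similarity, n_co_called) matrices: fraction of co-called sites with
    identical dosage.  Pairs with no co-called sites get similarity NaN."""
    called = gm.called
    d = gm.dosages
    n = gm.n_individuals
    sim = np.full((n, n), np.nan)
    co = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = called[i] & called[i + 1:]
        eq = (d[i] == d[i + 1:]) & both
        co_i = both.sum(axis=1)
        co[i, i + 1:] = co_i
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(co_i > 0, eq.sum(axis=1) / np.maximum(co_i, 1), np.nan)
        sim[i, i + 1:] = s
    iu = np.triu_indices(n, 1)
    sim[(iu[1], iu[0])] = sim[iu]
    co[(iu[1], iu[0])] = co[iu]
    np.fill_diagonal(sim, 1.0)
    return sim, co


def detect_clones(gm: GenotypeMatrix, cfg: FilterConfig,
                  report: FilterReport | None = None
                  ) -> tuple[list[tuple[str, str, float]], GenotypeMatrix]:
    """Find clonal pairs (dosage identity >= ``clone_similarity`` over
    co-called sites) and keep the least-missing member of each clonal group.

    Returns the clone pairs (id_i, id_j, similarity) and the reduced matrix.
    """
    if gm.n_individuals < 2:
        raise ValueError("need >= 2 individuals for clone detection")
    sim, co = pairwise_similarity(gm)
    ids = gm.ind_meta["id"].to_numpy()
    n = gm.n_individuals
    pairs: list[tuple[str, str, float]] = []
    # clonal groups via union-find over clone edges
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if co[i, j] == 0:
                logger.warning(
                    "no co-called sites for pair (%s, %s); treated as non-clonal",
                    ids[i], ids[j])
                continue
            if sim[i, j] >= cfg.clone_similarity:
                pairs.append((str(ids[i]), str(ids[j]), float(sim[i, j])))
                parent[find(i)] = find(j)
    miss = gm.missing_fraction_per_individual()
    keep = np.ones(n, dtype=bool)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    for members in groups.values():
        if len(members) > 1:
            best = min(members, key=lambda i: (miss[i], i))
            for i in members:
                if i != best:
                    keep[i] = False
    if report is not None:
        report.add("clones", individuals_removed=int((~keep).sum()))
    return pairs, gm.take_individuals(np.flatnonzero(keep))


def _vif(x: np.ndarray) -> np.ndarray:
    """VIF per column of a (n x p) matrix via R^2 of regressing each column
    on the others (columns centred; zero-variance columns get VIF 1)."""
    n, p = x.shape
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    vifs = np.ones(p)
    if p < 2:
        return vifs
    for j in range(p):
        if sd[j] == 0:
            continue
        others = np.delete(np.arange(p), j)
        a = xc[:, others]
        y = xc[:, j]
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        resid = y - a @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def ld_prune(gm: GenotypeMatrix, cfg: FilterConfig,
             report: FilterReport | None = None) -> GenotypeMatrix:
    """Sliding-window VIF pruning of linked SNPs.

    Dosages are mean-imputed per site for the regression only.  Within each
    window of ``ld_window`` surviving SNPs the site with the highest VIF is
    removed (greedy, VIFs recomputed after each removal) until all
    VIF <= ``vif_max``; the window then shifts by ``ld_step`` SNPs.
    """
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    imputed = np.where(np.isnan(d), col_mean[None, :], d)

    surviving = list(range(gm.n_sites))
    # sliding passes to a fixpoint: removals shrink the list and pull new
    # sites into windows, so sweep again until a pass removes nothing
    changed = True
    while changed:
        changed = False
        start = 0
        while start < len(surviving):
            window = surviving[start:start + cfg.ld_window]
            if len(window) >= 2:
                while True:
                    vifs = _vif(imputed[:, window])
                    worst = int(np.argmax(vifs))
                    if vifs[worst] <= cfg.vif_max:
                        break
                    removed_site = window.pop(worst)
                    surviving.remove(removed_site)
                    changed = True
            if start + cfg.ld_window >= len(surviving):
                break
            start += cfg.ld_step
    if report is not None:
        report.add("ld_prune", sites_removed=gm.n_sites - len(surviving))
    return gm.take_sites(np.array(sorted(surviving), dtype=int))


def run_filter_pipeline(gm: GenotypeMatrix, cfg: FilterConfig
                        ) -> tuple[GenotypeMatrix, FilterReport,
                                   list[tuple[str, str, float]]]:
    """Full cascade: stage-1 sites -> individuals -> clones -> stage-2
    sites -> LD pruning.  Returns (filtered matrix, report, clone pairs)."""
    report = FilterReport()
    gm = filter_sites(gm, cfg, stage=1, report=report)
    gm = filter_individuals(gm, cfg, report=report)
    clones, gm = detect_clones(gm, cfg, report=report)
    gm = filter_sites(gm, cfg, stage=2, report=report)
    gm = ld_prune(gm, cfg, report=report)
    return gm, report, clones
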