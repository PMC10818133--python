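"""Coalescent simulation of RAD-style genotype data under two-population
divergence histories, plus spatially structured environmental covariates.

Five histories are supported, all expressed in the scaled units used by
joint-SFS inference (time in units of ``2 N_ref`` generations, migration as
``M = 2 N_ref m``):

SI
    strict isolation: split at ``T_total``, no gene flow.
IM
    split with constant symmetric migration ``M``.
IM2M
    as IM, but a proportion ``Q`` of RAD tags draws the reduced rate
    ``M_e`` instead of ``M`` (genomic semi-permeability).
SC
    secondary contact: no migration on ``(T_phase, T_total]``, migration
    ``M`` on ``[0, T_phase)`` (recent epoch).
AM
    ancient migration: migration ``M`` on ``(T_phase, T_total]``, none on
    ``[0, T_phase)``.

Each RAD tag is an independent non-recombining locus simulated under the
structured coalescent (exponential waiting times for coalescence and
migration, discrete epoch switches), with infinite-sites mutations dropped
on branches at rate ``theta_per_tag / 2`` per lineage.  Diploid genotypes
pair consecutive haplotypes within a deme (haplotypes are exchangeable, so
this is distributionally identical to random pairing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .genio import MISSING, GenotypeMatrix
from .jafs import JAFS

logger = logging.getLogger(__name__)

MODEL_NAMES = ("SI", "IM", "IM2M", "SC", "AM")


@dataclass
class SimScenario:
    """Parameters of a two-population divergence simulation.

    Sizes ``nu1``/``nu2`` are relative to the ancestral reference size;
    ``T_total`` and ``T_phase`` are in units of ``2 N_ref`` generations;
    ``M`` and ``M_e`` are scaled rates ``2 N_ref m``; ``Q`` is the
    proportion of tags in the reduced-migration class; ``n1``/``n2`` are
    diploid sample sizes.
    """

    model_name: str
    nu1: float = 1.0
    nu2: float = 1.0
    T_total: float = 1.0
    M: float = 0.0
    M_e: float = 0.0
    Q: float = 0.0
    T_phase: float = 0.0
    n1: int = 10
    n2: int = 10
    n_tags: int = 200
    tag_length: int = 110
    theta_per_tag: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.nu1 <= 0 or self.nu2 <= 0:
            raise ValueError("nu1, nu2 must be > 0")
        if self.T_total < 0:
            raise ValueError("T_total must be >= 0")
        if not 0.0 <= self.Q <= 1.0:
            raise ValueError("Q outside [0, 1]")
        if not 0.0 <= self.T_phase <= max(self.T_total, 0.0):
            raise ValueError("T_phase outside [0, T_total]")
        if self.model_name == "IM2M" and self.M_e > self.M:
            raise ValueError("M_e must be <= M")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n1, n2 >= 2 diploids")


@dataclass
class SimulatedDataset:
    """Genotypes plus spatial coordinates, environment and ground truth."""

    genotypes: GenotypeMatrix
    truth: SimScenario
    coords: pd.DataFrame  # columns id, x, y
    env: pd.DataFrame | None = None
    tag_classes: np.ndarray | None = None  # IM2M: 1 = reduced-migration tag

    @property
    def tag_index(self) -> np.ndarray:
        return self.genotypes.tag_index


# ---------------------------------------------------------------------
# structured-coalescent kernel (numba)
# ---------------------------------------------------------------------

@njit(cache=True)
def _simulate_tag(h1, h2, nu1, nu2, nu_anc, T_total, ends, rates,
                  theta, mode, L_out, carriers, B, d1, d2, slot1, slot2):
    """One tag genealogy; haploid samples h1 + h2.

    mode 0: accumulate branch time per descendant configuration in L_out.
    mode 1: drop Poisson(theta/2 * branch length) mutations; carrier leaf
    sets written to ``carriers`` (up to its capacity; the returned count
    may exceed capacity so the caller can re-run with a larger buffer and
    the identical random stream).
    Returns the number of mutations (mode 1) or 0 (mode 0).
    """
    n_leaves = h1 + h2
    B[:, :] = 0
    for i in range(n_leaves):
        B[i, i] = 1
        d1[i] = 1 if i < h1 else 0
        d2[i] = 0 if i < h1 else 1
    k1 = h1
    k2 = h2
    for i in range(h1):
        slot1[i] = i
    for i in range(h2):
        slot2[i] = h1 + i
    t = 0.0
    ep = 0
    n_ep = len(ends)
    n_mut = 0
    merged = T_total <= 0.0
    if merged:
        # panmictic from the start: move deme-2 lineages into deme 1
        for i in range(k2):
            slot1[k1 + i] = slot2[i]
        k1 += k2
        k2 = 0
        nu1 = nu_anc
    while k1 + k2 > 1:
        if not merged:
            m = rates[ep]
            rc1 = 0.5 * k1 * (k1 - 1) / nu1
            rc2 = 0.5 * k2 * (k2 - 1) / nu2
            rm = m * (k1 + k2)
            total = rc1 + rc2 + rm
            boundary = ends[ep]
            if total > 0.0:
                w = np.random.exponential(1.0 / total)
            else:
                w = boundary - t + 1.0
            if t + w >= boundary:
                dt = boundary - t
            else:
                dt = w
        else:
            rc1 = 0.5 * k1 * (k1 - 1) / nu_anc
            rc2 = 0.0
            rm = 0.0
            total = rc1
            dt = np.random.exponential(1.0 / total)
            w = dt
            boundary = 1e300
        # accumulate interval
        if dt > 0.0:
            if mode == 0:
                for i in range(k1):
                    s = slot1[i]
                    L_out[d1[s], d2[s]] += dt
                for i in range(k2):
                    s = slot2[i]
                    L_out[d1[s], d2[s]] += dt
            else:
                lam = 0.5 * theta * (k1 + k2) * dt
                nm = np.random.poisson(lam)
                for _ in range(nm):
                    pick = np.random.randint(0, k1 + k2)
                    s = slot1[pick] if pick < k1 else slot2[pick - k1]
                    if n_mut < carriers.shape[0]:
                        for j in range(n_leaves):
                            carriers[n_mut, j] = B[s, j]
                    n_mut += 1
        if (not merged) and t + w >= boundary:
            t = boundary
            ep += 1
            if ep >= n_ep:
                # crossed T_total: merge demes into the ancestral population
                for i in range(k2):
                    slot1[k1 + i] = slot2[i]
                k1 += k2
                k2 = 0
                merged = True
            continue
        t += dt
        # choose event
        u = np.random.random() * total
        if u < rc1 or merged:
            deme = 1
        elif u < rc1 + rc2:
            deme = 2
        else:
            # migration: uniform lineage switches deme
            pick = np.random.randint(0, k1 + k2)
            if pick < k1:
                s = slot1[pick]
                slot1[pick] = slot1[k1 - 1]
                k1 -= 1
                slot2[k2] = s
                k2 += 1
            else:
                s = slot2[pick - k1]
                slot2[pick - k1] = slot2[k2 - 1]
                k2 -= 1
                slot1[k1] = s
                k1 += 1
            continue
        # coalescence within the chosen deme
        ka = k1 if deme == 1 else k2
        ia = np.random.randint(0, ka)
        ib = np.random.randint(0, ka - 1)
        if ib >= ia:
            ib += 1
        if deme == 1:
            sa = slot1[ia]
            sb = slot1[ib]
        else:
            sa = slot2[ia]
            sb = slot2[ib]
        for j in range(n_leaves):
            B[sa, j] |= B[sb, j]
        d1[sa] += d1[sb]
        d2[sa] += d2[sb]
        # remove sb's entry from the deme list (swap in the last entry)
        if deme == 1:
            slot1[ib] = slot1[k1 - 1]
            k1 -= 1
        else:
            slot2[ib] = slot2[k2 - 1]
            k2 -= 1
    return n_mut


@njit(cache=True)
def _expected_jafs_loop(seed, n_reps, h1, h2, nu1, nu2, nu_anc, T_total,
                        ends_full, rates_full, ends_red, rates_red, q_red,
                        theta, sum_f, sumsq_f):
    """Accumulate folded expected spectra over replicate tags.

    Per replicate the expected (per-tag) unfolded spectrum is
    ``theta/2 * branch length per configuration``; it is folded before
    accumulation so per-cell Monte-Carlo SEs refer to folded cells.
    """
    np.random.seed(seed)
    d1t = h1 + 1
    d2t = h2 + 1
    L = np.zeros((d1t, d2t))
    carriers = np.zeros((1, h1 + h2), dtype=np.uint8)
    B = np.zeros((h1 + h2, h1 + h2), dtype=np.uint8)
    d1 = np.zeros(h1 + h2, dtype=np.int64)
    d2 = np.zeros(h1 + h2, dtype=np.int64)
    slot1 = np.zeros(h1 + h2, dtype=np.int64)
    slot2 = np.zeros(h1 + h2, dtype=np.int64)
    hinge = (h1 + h2) / 2.0
    for _ in range(n_reps):
        L[:, :] = 0.0
        if q_red > 0.0 and np.random.random() < q_red:
            _simulate_tag(h1, h2, nu1, nu2, nu_anc, T_total, ends_red,
                          rates_red, theta, 0, L, carriers, B, d1, d2,
                          slot1, slot2)
        else:
            _simulate_tag(h1, h2, nu1, nu2, nu_anc, T_total, ends_full,
                          rates_full, theta, 0, L, carriers, B, d1, d2,
                          slot1, slot2)
        for i in range(d1t):
            for j in range(d2t):
                tot = i + j
                if tot > hinge:
                    continue
                v = 0.5 * theta * L[i, j]
                ip = h1 - i
                jp = h2 - j
                if tot < hinge:
                    v += 0.5 * theta * L[ip, jp]
                else:  # hinge: symmetrise at half weight
                    v = 0.5 * (v + 0.5 * theta * L[ip, jp])
                sum_f[i, j] += v
                sumsq_f[i, j] += v * v
    return 0


@njit(cache=True)
def _seed_rng(seed):
    # numba's RNG state is separate from NumPy's; must seed in jitted code
    np.random.seed(seed)


def _migration_schedule(sc: SimScenario, reduced: bool
                        ) -> tuple[np.ndarray, np.ndarray]:
    T = max(sc.T_total, 0.0)
    m = sc.M_e if reduced else sc.M
    if sc.model_name == "SI":
        return np.array([T]), np.array([0.0])
    if sc.model_name in ("IM", "IM2M"):
        return np.array([T]), np.array([m])
    if sc.model_name == "SC":
        return np.array([sc.T_phase, T]), np.array([sc.M, 0.0])
    if sc.model_name == "AM":
        return np.array([sc.T_phase, T]), np.array([0.0, sc.M])
    raise ValueError(sc.model_name)


# ---------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------

def simulate_pair(scenario: SimScenario) -> SimulatedDataset:
    """Simulate diploid genotypes for one two-population scenario.

    Deterministic under a fixed ``scenario.seed``.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    h1, h2 = 2 * sc.n1, 2 * sc.n2
    n_leaves = h1 + h2
    ends_full, rates_full = _migration_schedule(sc, reduced=False)
    ends_red, rates_red = _migration_schedule(sc, reduced=True)
    tag_seeds = rng.integers(0, 2**31 - 1, size=sc.n_tags)
    tag_red = (rng.random(sc.n_tags) < sc.Q) if sc.model_name == "IM2M" \
        else np.zeros(sc.n_tags, dtype=bool)
    pos_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    B = np.zeros((n_leaves, n_leaves), dtype=np.uint8)
    d1 = np.zeros(n_leaves, dtype=np.int64)
    d2 = np.zeros(n_leaves, dtype=np.int64)
    slot1 = np.zeros(n_leaves, dtype=np.int64)
    slot2 = np.zeros(n_leaves, dtype=np.int64)
    L_dummy = np.zeros((h1 + 1, h2 + 1))

    dosage_cols: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    width = len(str(sc.n_tags))
    for tag in range(sc.n_tags):
        ends, rates = (ends_red, rates_red) if tag_red[tag] \
            else (ends_full, rates_full)
        cap = max(64, int(20 * sc.theta_per_tag) + 16)
        while True:
            carriers = np.zeros((cap, n_leaves), dtype=np.uint8)
            _seed_rng(tag_seeds[tag])
            nm = _simulate_tag(h1, h2, sc.nu1, sc.nu2, 1.0, sc.T_total,
                               ends, rates, sc.theta_per_tag, 1, L_dummy,
                               carriers, B, d1, d2, slot1, slot2)
            if nm <= cap:
                break
            cap = nm  # deterministic re-run with a larger buffer
        if nm == 0:
            continue
        nm_kept = min(nm, sc.tag_length)
        if nm > sc.tag_length:
            logger.warning("tag %d: %d mutations exceed tag_length; truncated",
                           tag, nm)
        positions = np.sort(pos_rng.choice(
            sc.tag_length, size=nm_kept, replace=False)) + 1
        contig = f"tag{tag:0{width}d}"
        for k in range(nm_kept):
            hap = carriers[k].astype(np.int8)
            dos = hap[0::2] + hap[1::2]  # pair consecutive haplotypes
            dosage_cols.append(dos)
            meta_rows.append((contig, int(positions[k]), "A", "T", True))
    if dosage_cols:
        dosages = np.stack(dosage_cols, axis=1).astype(np.int8)
    else:
        dosages = np.zeros((sc.n1 + sc.n2, 0), dtype=np.int8)
    site_meta = pd.DataFrame(
        meta_rows, columns=["contig", "pos", "ref", "alt", "biallelic"])
    ids = [f"pop1_{i:03d}" for i in range(sc.n1)] + \
          [f"pop2_{i:03d}" for i in range(sc.n2)]
    ind_meta = pd.DataFrame({
        "id": ids,
        "population": ["pop1"] * sc.n1 + ["pop2"] * sc.n2,
        "reef": "R1",
    })
    gm = GenotypeMatrix(dosages, site_meta, ind_meta)
    coord_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    coords = pd.DataFrame({
        "id": ids,
        "x": coord_rng.uniform(0, 10, size=len(ids)),
        "y": coord_rng.uniform(0, 10, size=len(ids)),
    })
    return SimulatedDataset(gm, sc, coords,
                            tag_classes=tag_red.astype(np.int8))


def expected_jafs_mc(scenario: SimScenario, n_reps: int, seed: int,
                     mask_low: bool = False) -> JAFS:
    """Monte-Carlo expected folded JAFS, normalised over unmasked cells.

    Averages ``theta/2 x`` branch length per frequency configuration over
    ``n_reps`` independent tag genealogies; the ``se`` attribute holds the
    per-cell Monte-Carlo standard error on the same (normalised) scale.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sc = scenario
    h1, h2 = 2 * sc.n1, 2 * sc.n2
    ends_full, rates_full = _migration_schedule(sc, reduced=False)
    ends_red, rates_red = _migration_schedule(sc, reduced=True)
    q_red = sc.Q if sc.model_name == "IM2M" else 0.0
    sum_f = np.zeros((h1 + 1, h2 + 1))
    sumsq_f = np.zeros((h1 + 1, h2 + 1))
    _expected_jafs_loop(seed % (2**31 - 1), n_reps, h1, h2, sc.nu1, sc.nu2,
                        1.0, sc.T_total, ends_full, rates_full, ends_red,
                        rates_red, q_red, sc.theta_per_tag, sum_f, sumsq_f)
    mean = sum_f / n_reps
    var = np.maximum(sumsq_f / n_reps - mean**2, 0.0)
    se = np.sqrt(var / n_reps)
    total_idx = np.add.outer(np.arange(h1 + 1), np.arange(h2 + 1))
    mask = total_idx > (h1 + h2) / 2.0
    spec = JAFS(mean, (h1, h2), mask=mask, folded=True,
                provenance={"mc_reps": n_reps, "seed": seed})
    spec.se = se
    if mask_low:
        se_saved = spec.se
        spec = spec.mask_low_counts()
        spec.se = se_saved
    total = spec.unmasked_sum()
    if total > 0:
        spec.counts = spec.counts / total
        spec.se = spec.se / total
    return spec


def inject_missing_and_clones(data: SimulatedDataset, miss_rate: float,
                              n_clones: int, seed: int) -> SimulatedDataset:
    """Degrade a simulated dataset with missing genotypes and clonal copies.

    Missingness is independent per genotype at ``miss_rate``; ``n_clones``
    individuals are duplicated with missingness redrawn per copy.
    """
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError("miss_rate outside [0, 1)")
    gm = data.genotypes
    if n_clones >= gm.n_individuals:
        raise ValueError("n_clones must be < number of individuals")
    rng = np.random.default_rng(seed)
    dosages = gm.dosages.copy()
    ind_meta = gm.ind_meta.copy()
    coords = data.coords.copy()
    if n_clones > 0:
        donors = rng.choice(gm.n_individuals, size=n_clones, replace=False)
        clone_rows = gm.dosages[donors].copy()
        clone_meta = ind_meta.iloc[donors].copy()
        clone_meta["id"] = [f"{s}_cl" for s in clone_meta["id"]]
        clone_coords = coords.iloc[donors].copy()
        clone_coords["id"] = clone_meta["id"].to_numpy()
        dosages = np.vstack([dosages, clone_rows])
        ind_meta = pd.concat([ind_meta, clone_meta], ignore_index=True)
        coords = pd.concat([coords, clone_coords], ignore_index=True)
    if miss_rate > 0:
        drop = rng.random(dosages.shape) < miss_rate
        dosages = dosages.copy()
        dosages[drop] = MISSING
    gm_out = GenotypeMatrix(dosages, gm.site_meta.copy(), ind_meta)
    return replace(data, genotypes=gm_out, coords=coords)


def simulate_env(data: SimulatedDataset, effect_sizes, n_vars: int,
                 spatial_range: float, seed: int,
                 loci_per_var: int = 20) -> SimulatedDataset:
    """Attach spatially autocorrelated environmental variables and
    (optionally) genotype-environment associations.

    Variables are zero-mean unit-variance Gaussian fields over individual
    coordinates with exponential covariance ``exp(-d / spatial_range)``
    (``spatial_range -> 0`` gives i.i.d. noise).  For each variable ``v``
    with nonzero ``effect_sizes[v]``, a block of ``loci_per_var`` SNPs has
    its per-individual alternate-allele probability shifted by
    ``beta * env`` and its genotypes redrawn binomially, so downstream
    association methods can recover a known signal.  Zero effect sizes
    leave genotypes untouched.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    effect = np.zeros(n_vars)
    eff_in = np.asarray(effect_sizes, dtype=float).ravel()
    effect[:min(len(eff_in), n_vars)] = eff_in[:n_vars]
    rng = np.random.default_rng(seed)
    xy = data.coords[["x", "y"]].to_numpy(float)
    n = xy.shape[0]
    if spatial_range > 0:
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        cov = np.exp(-d / spatial_range) + 1e-9 * np.eye(n)
        chol = np.linalg.cholesky(cov)
    else:
        chol = np.eye(n)
    env = chol @ rng.standard_normal((n, n_vars))
    env = (env - env.mean(axis=0)) / env.std(axis=0)
    env_df = pd.DataFrame(env, columns=[f"env{v + 1}" for v in range(n_vars)])
    env_df.insert(0, "id", data.coords["id"].to_numpy())

    gm = data.genotypes
    dosages = gm.dosages.copy()
    n_sites = gm.n_sites
    affected: dict[int, np.ndarray] = {}
    cursor = 0
    for v in range(n_vars):
        lo = cursor
        hi = min(cursor + loci_per_var, n_sites)
        affected[v] = np.arange(lo, hi)
        cursor = hi
    for v in range(n_vars):
        if effect[v] == 0 or affected[v].size == 0:
            continue
        for s in affected[v]:
            called = gm.dosages[:, s] != MISSING
            if called.sum() == 0:
                continue
            p0 = gm.dosages[called, s].mean() / 2.0
            p = np.clip(p0 + effect[v] * env[:, v], 0.0, 1.0)
            new = rng.binomial(2, p).astype(np.int8)
            new[~called] = MISSING
            dosages[:, s] = new
    gm_out = GenotypeMatrix(dosages, gm.site_meta.copy(), gm.ind_meta.copy())
    return replace(data, genotypes=gm_out, env=env_df)


def write_dataset(data: SimulatedDataset, prefix) -> None:
    """Write VCF + metadata/coords/env TSVs with a common path prefix."""
    from . import genio

    genio.write_vcf(data.genotypes, f"{prefix}.vcf")
    meta = data.genotypes.ind_meta.merge(data.coords, on="id", how="left")
    meta.to_csv(f"{prefix}.popmap.tsv", sep="\t", index=False)
    if data.env is not None:
        data.env.to_csv(f"{prefix}.env.tsv", sep="\t", index=False)
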