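"""Conversion of scaled joint-SFS fit parameters into demographic units.

The fitted quantities (theta, nu1_scaled, nu2_scaled, M_scaled, T_scaled)
live in coalescent units relative to an unknown ancestral size.  With a
per-base mutation rate ``mu``, a generation time ``T_gen`` and the total
callable sequence length ``L`` they convert to individuals, years and
migrants per generation:

    N_ref = theta / (4 mu L)
    nu_k  = nu_k_scaled * N_ref            (individuals)
    m     = M_scaled / (2 N_ref)           (migrant fraction / generation)
    T     = T_scaled * 2 N_ref * T_gen     (years)
    M21   = m * nu1,   M12 = m * nu2       (migrants / generation)

``L`` accounts for the SNP loss between discovery and analysis:
``L = SNP_used * (n_tags * tag_length) / SNP_discovered``.

Defaults ``mu = 1.2e-8`` per base per generation (an Acroporidae coral
estimate) and ``T_gen = 3`` years are explicit, configurable and recorded
in the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

logger = logging.getLogger(__name__)

DEFAULT_MU = 1.2e-8
DEFAULT_TGEN = 3.0


@dataclass
class SeqLengthSpec:
    """Inputs to the effective sequence-length calculation."""

    snp_dadi: int        # SNPs retained for the SFS analysis (post projection)
    snp_original: int    # SNPs originally detected
    n_rad_tags: int
    rad_tag_length: int

    def __post_init__(self) -> None:
        if self.snp_original <= 0:
            raise ValueError("snp_original must be > 0")
        if self.snp_dadi < 0 or self.n_rad_tags <= 0 or self.rad_tag_length <= 0:
            raise ValueError("counts must be positive")
        if self.snp_dadi > self.snp_original:
            raise ValueError("snp_dadi cannot exceed snp_original")


@dataclass
class ConvertedParams:
    """Demographic-unit parameters (full precision; see
    :func:`round_sig` for Table-style reporting)."""

    N_ref: float         # individuals
    nu1: float           # individuals
    nu2: float           # individuals
    m: float             # migrant fraction per generation
    m_e: float           # reduced migrant fraction (two-class models)
    M21: float           # migrants per generation into population 1
    M12: float           # migrants per generation into population 2
    T_years: float
    mu: float = DEFAULT_MU
    T_gen: float = DEFAULT_TGEN

    def to_dict(self) -> dict:
        return asdict(self)


def total_seq_length(spec: SeqLengthSpec) -> float:
    """Effective sequence length L in bases."""
    L = spec.snp_dadi * (spec.n_rad_tags * spec.rad_tag_length) \
        / spec.snp_original
    if L == 0:
        logger.warning("snp_dadi = 0 gives zero sequence length")
    return float(L)


def convert(params, theta: float, L: float, mu: float = DEFAULT_MU,
            T_gen: float = DEFAULT_TGEN) -> ConvertedParams:
    """Convert scaled parameters to demographic units.

    ``params`` may be a :class:`reefdiverge.demography.DadiParams` or any
    object with attributes ``nu1``, ``nu2``, ``T``, ``M`` (and optionally
    ``M_e``).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if L <= 0 or mu <= 0 or T_gen <= 0:
        raise ValueError("L, mu, T_gen must be > 0")
    N_ref = theta / (4.0 * mu * L)
    nu1 = params.nu1 * N_ref
    nu2 = params.nu2 * N_ref
    m = params.M / (2.0 * N_ref)
    m_e = getattr(params, "M_e", 0.0) / (2.0 * N_ref)
    T_years = params.T * 2.0 * N_ref * T_gen
    return ConvertedParams(N_ref=N_ref, nu1=nu1, nu2=nu2, m=m, m_e=m_e,
                           M21=m * nu1, M12=m * nu2, T_years=T_years,
                           mu=mu, T_gen=T_gen)


def deconvert(cp: ConvertedParams, L: float):
    """Algebraic inverse of :func:`convert` (scaled-unit dict); used to
    verify the conversion identities round-trip."""
    theta = cp.N_ref * 4.0 * cp.mu * L
    return {
        "theta": theta,
        "nu1": cp.nu1 / cp.N_ref,
        "nu2": cp.nu2 / cp.N_ref,
        "M": cp.m * 2.0 * cp.N_ref,
        "M_e": cp.m_e * 2.0 * cp.N_ref,
        "T": cp.T_years / (2.0 * cp.N_ref * cp.T_gen),
    }


def migrants_per_generation(m: float, nu_recipient_individuals: float) -> float:
    """Gene flow in migrants per generation: M = m * nu."""
    if m < 0 or nu_recipient_individuals < 0:
        raise ValueError("m and nu must be >= 0")
    return m * nu_recipient_individuals


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting style used for
    demographic tables)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
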