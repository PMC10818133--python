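"""Two-population demographic inference on the folded joint SFS.

The expected spectrum under each divergence model is computed with a
diffusion approximation: the ancestral population's equilibrium allele
frequency density is split onto the diagonal of a 2-D density
``phi(x, y)``, which is then integrated forward through the model's
epochs with an alternating-direction implicit (ADI) scheme — genetic
drift as diffusion ``d^2[x(1-x) phi / nu] / dx^2 / 2``, symmetric
migration as advection ``M (y - x)``, and a constant influx of new
mutations at the low-frequency corners.  The density is evaluated on
three nonuniform grids and Richardson-extrapolated to zero spacing, then
integrated against binomial sampling kernels to give the
``(n1+1) x (n2+1)`` expected spectrum.

Units follow the standard scaled parameterisation: time in ``2 N_ref``
generations, sizes relative to ``N_ref``, migration ``M = 2 N_ref m``.

Model menu (see :mod:`reefdiverge.simdata` for the epoch conventions):
SI (strict isolation), IM (constant symmetric migration), IM2M (an IM
mixture in which a proportion ``Q`` of loci migrates at the reduced rate
``M_e``), SC (secondary contact) and AM (ancient migration).

Fitting maximises a Poisson composite likelihood over unmasked cells
with the scaling ``theta`` profiled analytically; the search runs
multiple rounds of log-uniform fold perturbations around the incumbent
followed by Nelder-Mead refinement, the standard SFS optimisation
recipe.  Uncertainty comes from the Fisher Information Matrix and from
tag-bootstrap spectra; likelihood-ratio tests between nested models are
Godambe-adjusted for the composite (linked-site) likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize, stats
from scipy.special import gammaln

from .jafs import JAFS

logger = logging.getLogger(__name__)

MODEL_FREE_PARAMS = {
    "SI": ("nu1", "nu2", "T"),
    "IM": ("nu1", "nu2", "T", "M"),
    "IM2M": ("nu1", "nu2", "T", "M", "M_e", "Q"),
    "SC": ("nu1", "nu2", "T", "M", "phase_frac"),
    "AM": ("nu1", "nu2", "T", "M", "phase_frac"),
}

#: nested -> allowed full models for likelihood-ratio testing
NESTINGS = {
    ("SI", "IM"), ("SI", "IM2M"), ("SI", "SC"), ("SI", "AM"),
    ("IM", "IM2M"), ("IM", "SC"), ("IM", "AM"),
}

DEFAULT_BOUNDS = {
    "nu1": (1e-2, 50.0),
    "nu2": (1e-2, 50.0),
    "T": (1e-3, 10.0),
    "M": (1e-3, 20.0),
    "M_e": (1e-5, 20.0),
    "Q": (1e-3, 0.999),
    "phase_frac": (1e-3, 0.999),
}


@dataclass
class DadiParams:
    """Scaled parameters of one divergence model.

    ``phase_frac`` is the internal SC/AM parameterisation
    ``T_phase = phase_frac * T`` (one total time plus an epoch fraction).
    """

    model_name: str
    nu1: float = 1.0
    nu2: float = 1.0
    T: float = 1.0
    M: float = 0.0
    M_e: float = 0.0
    Q: float = 0.0
    phase_frac: float = 0.5
    theta_hat: float | None = None

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_FREE_PARAMS:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.nu1 <= 0 or self.nu2 <= 0 or self.T <= 0:
            raise ValueError("nu1, nu2, T must be > 0")
        if self.M < 0 or self.M_e < 0:
            raise ValueError("M, M_e must be >= 0")
        if not 0 <= self.Q <= 1:
            raise ValueError("Q outside [0, 1]")

    @property
    def T_phase(self) -> float:
        return self.phase_frac * self.T

    @property
    def free_names(self) -> tuple[str, ...]:
        return MODEL_FREE_PARAMS[self.model_name]

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names])

    def with_free(self, values) -> "DadiParams":
        return replace(self, **dict(zip(self.free_names, values)))

    @property
    def n_free(self) -> int:
        """Free parameter count including the profiled theta."""
        return len(self.free_names) + 1

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name, "nu1": self.nu1, "nu2": self.nu2,
            "T": self.T, "M": self.M, "M_e": self.M_e, "Q": self.Q,
            "phase_frac": self.phase_frac, "T_phase": self.T_phase,
            "theta_hat": self.theta_hat,
        }


@dataclass
class FitResult:
    """Optimised parameters with likelihood, AIC and uncertainty."""

    params: DadiParams
    loglik: float
    aic: float
    n_free_params: int
    trace: list = field(default_factory=list)
    bootstrap_params: list = field(default_factory=list)
    fim_sd: dict | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_free_params": self.n_free_params,
            "trace": self.trace,
            "bootstrap_params": self.bootstrap_params,
            "fim_sd": self.fim_sd,
        }


# ---------------------------------------------------------------------
# diffusion engine
# ---------------------------------------------------------------------

@njit(cache=True)
def _tridiag_coeffs(xx, nu, mrate, other_freq, dt, a, b, c, absorb):
    """Implicit-step tridiagonal matrix (I/dt + A) for one 1-D operator.

    Finite-volume flux form on the nonuniform grid ``xx``: diffusion
    ``(1/2) d2[V phi]`` with ``V = x(1-x)/nu`` and advection
    ``M(x) = mrate (other_freq - x)``, with an exponential-fitting
    upwind weight to stay stable when advection dominates near the
    boundaries.

    With ``absorb`` true the boundary rows let density exit the system
    (the pure 1-D problem, where loss and fixation end a site's story).
    In the 2-D sweeps ``absorb`` must be false: a site lost or fixed in
    one population is still segregating in the other, so boundary points
    act as conservative traps whose mass keeps evolving in the other
    direction; only the (0,0)/(1,1) corners truly exit, and they are
    masked in the sampled spectrum.
    """
    N = len(xx)
    for j in range(N):
        a[j] = 0.0
        b[j] = 1.0 / dt
        c[j] = 0.0
    for j in range(N - 1):
        dx = xx[j + 1] - xx[j]
        xmid = 0.5 * (xx[j] + xx[j + 1])
        Mmid = mrate * (other_freq - xmid)
        Vmid = xmid * (1.0 - xmid) / nu
        Vj = xx[j] * (1.0 - xx[j]) / nu
        Vj1 = xx[j + 1] * (1.0 - xx[j + 1]) / nu
        # exponential-fitting weight (0.5 = centred) for the advective flux
        wj = 2.0 * Mmid * dx
        if Vmid <= 0.0 or wj == 0.0:
            delj = 0.5
        else:
            r = wj / Vmid
            if r > 40.0:
                delj = 1.0 - Vmid / wj
            elif r < -40.0:
                delj = -Vmid / wj
            else:
                epsj = math.exp(r)
                denom = wj - epsj * wj
                if denom == 0.0:
                    delj = 0.5
                else:
                    delj = (-epsj * wj + epsj * Vmid - Vmid) / denom
        # flux F_{j+1/2} = Mmid (delj phi_j + (1-delj) phi_{j+1})
        #                  - (V_{j+1} phi_{j+1} - V_j phi_j) / (2 dx)
        dfac_j = 2.0 / dx if j == 0 else 2.0 / (dx + (xx[j] - xx[j - 1]))
        if j + 1 == N - 1:
            dfac_j1 = 2.0 / dx
        else:
            dfac_j1 = 2.0 / (dx + (xx[j + 2] - xx[j + 1]))
        f_j = Mmid * delj + Vj / (2.0 * dx)
        f_j1 = Mmid * (1.0 - delj) - Vj1 / (2.0 * dx)
        # Edge interfaces: a boundary node can hold trapped point mass
        # (sites lost/fixed in this population, still segregating in the
        # other), so its flux coefficient may only move that mass inward
        # when advection points inward; the unconstrained fitted value
        # would let an accumulated boundary spike drain its neighbour.
        if j == 0 and f_j < 0.0:
            f_j = 0.0
        if j == N - 2 and f_j1 > 0.0:
            f_j1 = 0.0
        # dphi_j/dt -= dfac_j * F_{j+1/2} ; dphi_{j+1}/dt += dfac_j1 * F_{j+1/2}
        b[j] += dfac_j * f_j
        c[j] += dfac_j * f_j1
        a[j + 1] += -dfac_j1 * f_j
        b[j + 1] += -dfac_j1 * f_j1
    if absorb:
        # loss at x=0 when advection points outward, fixation at x=1
        # likewise (0.5/nu is the one-sided limit of the diffusion flux)
        M0 = mrate * other_freq
        M1 = mrate * (other_freq - 1.0)
        if M0 <= 0.0:
            b[0] += (0.5 / nu - M0) * 2.0 / (xx[1] - xx[0])
        if M1 >= 0.0:
            b[N - 1] += -(-0.5 / nu - M1) * 2.0 / (xx[N - 1] - xx[N - 2])


@njit(cache=True)
def _thomas_factor(a, b, c, cp):
    """Precompute Thomas-algorithm upper-diagonal multipliers."""
    N = len(b)
    denom = b[0]
    cp[0] = c[0] / denom
    for j in range(1, N):
        denom = b[j] - a[j] * cp[j - 1]
        cp[j] = c[j] / denom


@njit(cache=True)
def _thomas_solve(a, b, c, cp, d, out):
    N = len(b)
    out[0] = d[0] / b[0]
    for j in range(1, N):
        denom = b[j] - a[j] * cp[j - 1]
        out[j] = (d[j] - a[j] * out[j - 1]) / denom
    for j in range(N - 2, -1, -1):
        out[j] = out[j] - cp[j] * out[j + 1]


@njit(cache=True)
def _adi_step(phi, dt, ax, bx, cx, cpx, ay, by, cy, cpy, inj, parity,
              col, out):
    """One ADI time step: mutation injection then the two implicit
    sweeps, their order alternating with ``parity`` to cancel the
    leading operator-splitting asymmetry."""
    N = phi.shape[0]
    phi[1, 0] += dt * inj
    phi[0, 1] += dt * inj
    for half in range(2):
        do_x = (half == 0) == (parity == 0)
        if do_x:
            for k in range(N):
                for j in range(N):
                    col[j] = phi[j, k] / dt
                _thomas_solve(ax[k], bx[k], cx[k], cpx[k], col, out)
                for j in range(N):
                    phi[j, k] = out[j]
        else:
            for j in range(N):
                for k in range(N):
                    col[k] = phi[j, k] / dt
                _thomas_solve(ay[j], by[j], cy[j], cpy[j], col, out)
                for k in range(N):
                    phi[j, k] = out[k]


@njit(cache=True)
def _factor_operators(xx, nu1, nu2, mrate, dt, ax, bx, cx, cpx,
                      ay, by, cy, cpy):
    N = len(xx)
    for k in range(N):
        _tridiag_coeffs(xx, nu1, mrate, xx[k], dt, ax[k], bx[k], cx[k],
                        False)
        _thomas_factor(ax[k], bx[k], cx[k], cpx[k])
        _tridiag_coeffs(xx, nu2, mrate, xx[k], dt, ay[k], by[k], cy[k],
                        False)
        _thomas_factor(ay[k], by[k], cy[k], cpy[k])


@njit(cache=True)
def _adi_epoch(phi, xx, nu1, nu2, mrate, T_epoch, dt_target, theta0):
    """Integrate phi(x, y) forward for one epoch of constant parameters.

    Full steps of exactly ``dt_target`` plus one partial remainder step,
    so the result varies continuously with ``T_epoch`` (an integer step
    count re-scaled to the duration would make the likelihood jump at
    step-count boundaries and ruin finite-difference derivatives).
    """
    N = len(xx)
    if T_epoch <= 0.0:
        return
    n_full = int(T_epoch / dt_target)
    rem = T_epoch - n_full * dt_target
    ax = np.zeros((N, N)); bx = np.zeros((N, N)); cx = np.zeros((N, N))
    cpx = np.zeros((N, N))
    ay = np.zeros((N, N)); by = np.zeros((N, N)); cy = np.zeros((N, N))
    cpy = np.zeros((N, N))
    inj = theta0 / 2.0 / xx[1] * 4.0 / ((xx[2] - xx[0]) * xx[1])
    col = np.zeros(N)
    out = np.zeros(N)
    if n_full > 0:
        _factor_operators(xx, nu1, nu2, mrate, dt_target,
                          ax, bx, cx, cpx, ay, by, cy, cpy)
        for step in range(n_full):
            _adi_step(phi, dt_target, ax, bx, cx, cpx, ay, by, cy, cpy,
                      inj, step % 2, col, out)
    if rem > 1e-14 * T_epoch:
        _factor_operators(xx, nu1, nu2, mrate, rem,
                          ax, bx, cx, cpx, ay, by, cy, cpy)
        _adi_step(phi, rem, ax, bx, cx, cpx, ay, by, cy, cpy, inj,
                  n_full % 2, col, out)


def _grid(pts: int) -> np.ndarray:
    """Nonuniform grid on [0, 1], crowded at both boundaries."""
    u = np.linspace(0.0, np.pi, pts)
    return (1.0 - np.cos(u)) / 2.0


def _equilibrium_phi_1d(xx: np.ndarray, nu: float = 1.0,
                        theta0: float = 1.0) -> np.ndarray:
    """Steady state of the 1-D neutral operator with mutation influx.

    Solves ``A phi = s`` for the discrete operator (the discrete analogue
    of ``phi = theta0 / x``).
    """
    N = len(xx)
    a = np.zeros(N); b = np.zeros(N); c = np.zeros(N)
    big_dt = 1e30  # so 1/dt vanishes and (I/dt + A) ~= A
    _tridiag_coeffs(xx, nu, 0.0, 0.0, big_dt, a, b, c, True)
    s = np.zeros(N)
    s[1] = theta0 / 2.0 / xx[1] * 2.0 / (xx[2] - xx[0])
    ab = np.zeros((3, N))
    ab[0, 1:] = c[:-1]
    ab[1, :] = b
    ab[2, :-1] = a[1:]
    from scipy.linalg import solve_banded
    return solve_banded((1, 1), ab, s)


def _quad_weights(xx: np.ndarray) -> np.ndarray:
    w = np.zeros(len(xx))
    w[1:-1] = (xx[2:] - xx[:-2]) / 2.0
    w[0] = (xx[1] - xx[0]) / 2.0
    w[-1] = (xx[-1] - xx[-2]) / 2.0
    return w


def _phi_to_spectrum(phi: np.ndarray, xx: np.ndarray,
                     n1: int, n2: int) -> np.ndarray:
    """Integrate the density against binomial sampling kernels."""
    w = _quad_weights(xx)
    i = np.arange(n1 + 1)[:, None]
    Bx = stats.binom.pmf(i, n1, xx[None, :])
    j = np.arange(n2 + 1)[:, None]
    By = stats.binom.pmf(j, n2, xx[None, :])
    weighted = phi * w[:, None] * w[None, :]
    return Bx @ weighted @ By.T


class ExpectedJAFSEngine:
    """Expected folded JAFS under the five divergence models.

    Parameters
    ----------
    n1, n2
        Haploid sample sizes of the output spectrum.
    pts
        Grid sizes for Richardson extrapolation (default three grids
        scaled to the larger sample size).
    timescale_factor
        Target integration time step in units of ``1 / max rate``;
        smaller is more accurate and slower.
    """

    def __init__(self, n1: int, n2: int, pts: tuple[int, ...] | None = None,
                 timescale_factor: float = 1e-3, fold: bool = True,
                 max_steps_per_epoch: int = 8000):
        self.n1 = int(n1)
        self.n2 = int(n2)
        nmax = max(self.n1, self.n2)
        self.pts = tuple(pts) if pts else (nmax + 20, nmax + 30, nmax + 40)
        self.timescale_factor = timescale_factor
        self.fold = fold
        self.max_steps_per_epoch = int(max_steps_per_epoch)
        self.n_evaluations = 0

    # -- single-grid, single-class expected spectrum -------------------

    def _epochs(self, p: DadiParams, mrate: float
                ) -> list[tuple[float, float]]:
        """(duration, migration) epochs, oldest first."""
        name = p.model_name
        if name == "SI":
            return [(p.T, 0.0)]
        if name in ("IM", "IM2M"):
            return [(p.T, mrate)]
        Tp = p.phase_frac * p.T
        if name == "SC":
            return [(p.T - Tp, 0.0), (Tp, mrate)]
        if name == "AM":
            return [(p.T - Tp, mrate), (Tp, 0.0)]
        raise ValueError(name)

    def _raw_spectrum(self, p: DadiParams, mrate: float,
                      pts: int) -> np.ndarray:
        xx = _grid(pts)
        phi1d = _equilibrium_phi_1d(xx)
        phi = np.zeros((pts, pts))
        # place the ancestral density on the diagonal (a 2-D delta ridge);
        # ancestral fixed/lost boundary states are not segregating sites
        w = _quad_weights(xx)
        for j in range(1, pts - 1):
            phi[j, j] = phi1d[j] / w[j]
        for duration, m in self._epochs(p, mrate):
            # negligible epochs are dropped so degenerate epoch layouts
            # reduce exactly to their nested model's integration
            if duration <= 1e-12 * max(p.T, 1.0):
                continue
            max_rate = max(0.25 / p.nu1, 0.25 / p.nu2, m, 0.25)
            dt_target = self.timescale_factor / max_rate
            # cap the step count so pathological parameter corners (and,
            # when a lower cap is configured, routine fitting) stay
            # affordable
            dt_eff = max(dt_target, duration / self.max_steps_per_epoch)
            _adi_epoch(phi, xx, p.nu1, p.nu2, m, duration, dt_eff, 1.0)
        return _phi_to_spectrum(phi, xx, self.n1, self.n2)

    def _extrapolated(self, p: DadiParams, mrate: float) -> np.ndarray:
        """Richardson extrapolation to zero grid spacing (quadratic in
        the first interior grid point)."""
        specs = []
        hs = []
        for pts in self.pts:
            specs.append(self._raw_spectrum(p, mrate, pts))
            hs.append(_grid(pts)[1])
        if len(specs) == 1:
            return specs[0]
        hs = np.array(hs)
        out = np.zeros_like(specs[0])
        for i in range(len(specs)):
            li = 1.0
            for j in range(len(specs)):
                if j != i:
                    li *= (0.0 - hs[j]) / (hs[i] - hs[j])
            out += li * specs[i]
        return out

    def expected(self, p: DadiParams) -> JAFS:
        """Expected (optionally folded) spectrum, unnormalised
        (theta0 = 1 scale)."""
        self.n_evaluations += 1
        if p.model_name == "IM2M":
            full = self._extrapolated(p, p.M)
            if p.Q > 0:
                red = self._extrapolated(p, p.M_e)
            else:
                red = full
            counts = (1.0 - p.Q) * full + p.Q * red
        else:
            mrate = p.M if p.model_name != "SI" else 0.0
            counts = self._extrapolated(p, mrate)
        counts = np.maximum(counts, 0.0)
        spec = JAFS(counts, (self.n1, self.n2), folded=False,
                    provenance={"model": p.model_name, "engine": "diffusion"})
        if self.fold:
            spec = spec.fold()
        return spec


def expected_jafs(p: DadiParams, sizes: tuple[int, int],
                  pts: tuple[int, ...] | None = None,
                  timescale_factor: float = 1e-3) -> JAFS:
    """Convenience wrapper: folded expected JAFS for one parameter set."""
    engine = ExpectedJAFSEngine(sizes[0], sizes[1], pts=pts,
                                timescale_factor=timescale_factor)
    return engine.expected(p)


# ---------------------------------------------------------------------
# composite likelihood and optimisation
# ---------------------------------------------------------------------

MODEL_EPS = 1e-12


def composite_loglik(model: JAFS, data: JAFS) -> tuple[float, float]:
    """Poisson composite log-likelihood and the profiled theta-hat.

    ``theta_hat = sum(data) / sum(model)`` over jointly unmasked cells is
    the analytic optimum of the Poisson likelihood with intensity
    ``theta * model``.
    """
    if model.counts.shape != data.counts.shape:
        raise ValueError("model/data shape mismatch")
    mask = model.mask | data.mask
    m = model.counts[~mask]
    d = data.counts[~mask]
    if np.any(m <= 0):
        n_floored = int((m <= 0).sum())
        if np.any(d[m <= 0] > 0):
            logger.debug("flooring %d zero model cells with data", n_floored)
        m = np.maximum(m, MODEL_EPS)
    msum = m.sum()
    if msum <= 0:
        raise ValueError("model spectrum has no unmasked mass")
    theta_hat = d.sum() / msum
    lam = theta_hat * m
    ll = float(np.sum(d * np.log(np.maximum(lam, MODEL_EPS)) - lam
                      - gammaln(d + 1.0)))
    return ll, float(theta_hat)


def _transform(values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    """Natural -> optimiser space (log for positive, logit for fractions)."""
    out = np.empty(len(values))
    for i, (v, n) in enumerate(zip(values, names)):
        if n in ("Q", "phase_frac"):
            v = min(max(v, 1e-9), 1 - 1e-9)
            out[i] = math.log(v / (1 - v))
        else:
            out[i] = math.log(max(v, 1e-300))
    return out


def _untransform(z: np.ndarray, names: tuple[str, ...],
                 bounds: dict) -> np.ndarray:
    out = np.empty(len(z))
    for i, (v, n) in enumerate(zip(z, names)):
        if n in ("Q", "phase_frac"):
            x = 1.0 / (1.0 + math.exp(-v))
        else:
            x = math.exp(min(v, 700.0))
        lo, hi = bounds[n]
        out[i] = min(max(x, lo), hi)
    return out


def _loglik_at(engine: ExpectedJAFSEngine, template: DadiParams,
               values: np.ndarray, data: JAFS) -> tuple[float, float]:
    p = template.with_free(values)
    if p.model_name == "IM2M" and p.M_e > p.M:
        p = replace(p, M_e=p.M)
    model = engine.expected(p)
    return composite_loglik(model, data)


def optimize_fit(data: JAFS, model_name: str,
                 start: DadiParams | None = None,
                 bounds: dict | None = None, seed: int = 0,
                 rounds: tuple[int, ...] = (3, 2, 1),
                 runs_per_round: int = 30,
                 maxiter: int = 120,
                 engine: ExpectedJAFSEngine | None = None,
                 pts: tuple[int, ...] | None = None,
                 timescale_factor: float = 1e-3,
                 fatol: float = 1e-8, xatol: float = 1e-4) -> FitResult:
    """Multi-round randomised optimisation of the composite likelihood.

    Each round perturbs the incumbent best parameters by a factor
    ``2**u`` with ``u ~ Uniform(-fold, +fold)`` per parameter (the fold
    sizes are given by ``rounds``, default 3, 2, 1), clips to bounds and
    refines with Nelder-Mead in log/logit space; ``runs_per_round``
    restarts per round.  Deterministic under a fixed seed.
    """
    if model_name not in MODEL_FREE_PARAMS:
        raise ValueError(f"unknown model {model_name!r}")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    rng = np.random.default_rng(seed)
    n1, n2 = data.sample_sizes
    if engine is None:
        engine = ExpectedJAFSEngine(n1, n2, pts=pts,
                                    timescale_factor=timescale_factor)
    if start is None:
        start = DadiParams(model_name, nu1=1.0, nu2=1.0, T=1.0, M=1.0,
                           M_e=0.1, Q=0.2, phase_frac=0.5)
    else:
        start = replace(start, model_name=model_name)
    names = MODEL_FREE_PARAMS[model_name]
    template = start

    def objective(z: np.ndarray) -> float:
        vals = _untransform(z, names, bounds)
        ll, _ = _loglik_at(engine, template, vals, data)
        return -ll

    best_vals = np.array([getattr(start, n) for n in names])
    best_ll, _ = _loglik_at(engine, template, best_vals, data)
    start_ll = best_ll
    trace: list = []
    for fold in rounds:
        round_best_vals = best_vals
        round_best_ll = best_ll
        for run in range(runs_per_round):
            u = rng.uniform(-fold, fold, size=len(names))
            pert = best_vals * (2.0 ** u)
            pert = np.array([min(max(v, bounds[n][0]), bounds[n][1])
                             for v, n in zip(pert, names)])
            z0 = _transform(pert, names)
            res = optimize.minimize(objective, z0, method="Nelder-Mead",
                                    options={"maxiter": maxiter,
                                             "xatol": xatol, "fatol": fatol})
            vals = _untransform(res.x, names, bounds)
            ll = -res.fun
            trace.append({"fold": fold, "run": run,
                          "params": dict(zip(names, map(float, vals))),
                          "loglik": float(ll)})
            if ll > round_best_ll:
                round_best_ll = ll
                round_best_vals = vals
        best_vals, best_ll = round_best_vals, round_best_ll
    if best_ll <= start_ll:
        logger.warning("optimisation did not improve on the start point")
    params = template.with_free(best_vals)
    if params.model_name == "IM2M" and params.M_e > params.M:
        params = replace(params, M_e=params.M)
    model = engine.expected(params)
    ll, theta_hat = composite_loglik(model, data)
    params = replace(params, theta_hat=theta_hat)
    k = params.n_free
    aic = 2.0 * k - 2.0 * ll
    return FitResult(params, ll, aic, k, trace=trace)


def compare_models(fits: list[FitResult], tie_delta: float = 1.0):
    """Rank fits by AIC; flags ties with delta-AIC below ``tie_delta``."""
    import pandas as pd

    rows = []
    best_aic = min(f.aic for f in fits)
    for f in sorted(fits, key=lambda f: f.aic):
        rows.append({
            "model": f.params.model_name,
            "loglik": f.loglik,
            "aic": f.aic,
            "delta_aic": f.aic - best_aic,
            "tie_with_best": f.aic - best_aic < tie_delta,
            "n_free_params": f.n_free_params,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# uncertainty: FIM, Godambe-adjusted LRT
# ---------------------------------------------------------------------

def numeric_hessian(f, z0: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``z0``."""
    z0 = np.asarray(z0, dtype=float)
    d = len(z0)
    h = np.maximum(np.abs(z0) * rel_step, rel_step)
    H = np.zeros((d, d))
    f0 = f(z0)
    for i in range(d):
        for j in range(i, d):
            if i == j:
                zp = z0.copy(); zp[i] += h[i]
                zm = z0.copy(); zm[i] -= h[i]
                H[i, i] = (f(zp) - 2 * f0 + f(zm)) / h[i] ** 2
            else:
                zpp = z0.copy(); zpp[i] += h[i]; zpp[j] += h[j]
                zpm = z0.copy(); zpm[i] += h[i]; zpm[j] -= h[j]
                zmp = z0.copy(); zmp[i] -= h[i]; zmp[j] += h[j]
                zmm = z0.copy(); zmm[i] -= h[i]; zmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(zpp) - f(zpm) - f(zmp) + f(zmm)) \
                    / (4 * h[i] * h[j])
    return H


def _loglik_hessian_log(engine: ExpectedJAFSEngine, params: DadiParams,
                        data: JAFS, names: tuple[str, ...],
                        rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of the composite log-likelihood in
    log-parameter space."""
    z0 = np.log(np.array([getattr(params, n) for n in names]))

    def f(z):
        vals = np.exp(z)
        ll, _ = _loglik_at(engine, params, _clip_to_model(params, vals, names),
                           data)
        return ll

    return numeric_hessian(f, z0, rel_step)


def _clip_to_model(template: DadiParams, vals: np.ndarray,
                   names: tuple[str, ...]) -> np.ndarray:
    out = vals.copy()
    for i, n in enumerate(names):
        if n in ("Q", "phase_frac"):
            out[i] = min(out[i], 0.999999)
    return out


def fim_sd(fit: FitResult, data: JAFS,
           engine: ExpectedJAFSEngine | None = None,
           rel_step: float = 1e-3) -> dict:
    """Per-parameter standard deviations from the observed Fisher
    Information Matrix (numerical Hessian at the optimum).

    The Hessian is taken in log-parameter space (central differences,
    relative step ``rel_step``); natural-scale SDs follow by the delta
    method ``sd_p = p * sd_log_p``.  Parameters at a bound are flagged.
    """
    names = fit.params.free_names
    if engine is None:
        n1, n2 = data.sample_sizes
        engine = ExpectedJAFSEngine(n1, n2)
    H = _loglik_hessian_log(engine, fit.params, data, names, rel_step)
    fim = -H
    cond = np.linalg.cond(fim)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"Fisher information matrix not invertible (cond={cond:.3g})")
    cov = np.linalg.inv(fim)
    diag = np.diag(cov)
    out = {}
    for i, n in enumerate(names):
        v = float(getattr(fit.params, n))
        if diag[i] < 0:
            logger.warning("negative FIM variance for %s", n)
            out[n] = {"sd": float("nan"), "value": v, "at_bound": False}
            continue
        sd_log = math.sqrt(diag[i])
        lo, hi = DEFAULT_BOUNDS.get(n, (0, np.inf))
        at_bound = v <= lo * 1.001 or v >= hi * 0.999
        if at_bound:
            logger.warning("parameter %s at a bound: one-sided uncertainty", n)
        out[n] = {"sd": v * sd_log, "sd_log": sd_log, "value": v,
                  "at_bound": bool(at_bound)}
    out["_condition_number"] = float(cond)
    return out


def _score_at(engine: ExpectedJAFSEngine, params: DadiParams, data: JAFS,
              names: tuple[str, ...], rel_step: float = 1e-3) -> np.ndarray:
    """Gradient of the composite log-likelihood in log-parameter space."""
    z0 = np.log(np.array([getattr(params, n) for n in names]))
    h = np.maximum(np.abs(z0) * rel_step, rel_step)
    g = np.zeros(len(z0))
    for i in range(len(z0)):
        zp = z0.copy(); zp[i] += h[i]
        zm = z0.copy(); zm[i] -= h[i]
        lp, _ = _loglik_at(engine, params,
                           _clip_to_model(params, np.exp(zp), names), data)
        lm, _ = _loglik_at(engine, params,
                           _clip_to_model(params, np.exp(zm), names), data)
        g[i] = (lp - lm) / (2 * h[i])
    return g


def lrt_adjusted(full: FitResult, nested: FitResult, data: JAFS,
                 boots: list[JAFS],
                 engine: ExpectedJAFSEngine | None = None,
                 boundary: bool = True) -> dict:
    """Likelihood-ratio test between nested models, adjusted for the
    composite likelihood.

    The raw statistic ``2 (lnL_full - lnL_nested)`` is rescaled by a
    Godambe-information factor estimated from bootstrap spectra (variance
    of the score of the focal parameters at the nested optimum embedded
    in the full model).  When the nested value lies on a parameter bound
    the null is the boundary mixture ``0.5 chi2_{d-1} + 0.5 chi2_d``.
    """
    pair = (nested.params.model_name, full.params.model_name)
    if pair not in NESTINGS:
        raise ValueError(f"{pair[1]} does not nest {pair[0]}")
    stat_raw = 2.0 * (full.loglik - nested.loglik)
    names_full = full.params.free_names
    names_nested = nested.params.free_names
    focal = tuple(n for n in names_full if n not in names_nested)
    # embed the nested optimum in the full model's parameter space, with
    # focal parameters at their null (boundary) values
    null_embedding = {"M": 1e-3, "M_e": 1e-3, "Q": 1e-3, "phase_frac": 0.999}
    embedded = replace(full.params,
                       **{n: getattr(nested.params, n) for n in names_nested})
    embedded = replace(embedded,
                       **{n: null_embedding.get(n, getattr(embedded, n))
                          for n in focal})
    if engine is None:
        n1, n2 = data.sample_sizes
        engine = ExpectedJAFSEngine(n1, n2)
    d = len(focal)
    if d == 0 or stat_raw <= 0:
        stat_adj = max(stat_raw, 0.0)
        adjust = 1.0
    else:
        H = -_loglik_hessian_log(engine, embedded, data, focal)
        scores = np.array([_score_at(engine, embedded, b, focal)
                           for b in boots])
        J = np.atleast_2d(np.cov(scores.T))
        try:
            godambe = H @ np.linalg.inv(J) @ H
            adjust = d / float(np.trace(H @ np.linalg.inv(godambe)))
        except np.linalg.LinAlgError:
            logger.warning("singular Godambe information; raw LRT used")
            adjust = 1.0
        stat_adj = adjust * stat_raw
    if boundary and d >= 1:
        # point mass at 0 mixed with chi-square(s) for a null on a bound
        p = 0.5 * stats.chi2.sf(stat_adj, df=max(d - 1, 1)) \
            + 0.5 * stats.chi2.sf(stat_adj, df=d)
        if d == 1:
            p = 0.5 * (stat_adj <= 0) + 0.5 * stats.chi2.sf(stat_adj, df=1)
    else:
        p = stats.chi2.sf(stat_adj, df=max(d, 1))
    if stat_adj == 0:
        p = 1.0
    return {"statistic_raw": float(stat_raw),
            "statistic_adjusted": float(stat_adj),
            "adjustment": float(adjust), "df": d, "p_value": float(p),
            "focal_params": list(focal)}


# ---------------------------------------------------------------------
# sklearn-style estimator facade
# ---------------------------------------------------------------------

class DemographicModel:
    """Fit-shaped wrapper around :func:`optimize_fit`.

    Follows the scikit-learn estimator protocol: constructor stores
    hyperparameters, :meth:`fit` takes the data (a folded JAFS) and sets
    trailing-underscore attributes ``params_``, ``loglik_``, ``aic_``,
    ``theta_``, ``result_``.
    """

    def __init__(self, model_name: str = "IM", rounds=(3, 2, 1),
                 runs_per_round: int = 30, seed: int = 0,
                 pts: tuple[int, ...] | None = None,
                 timescale_factor: float = 1e-3,
                 bounds: dict | None = None,
                 start: DadiParams | None = None):
        self.model_name = model_name
        self.rounds = rounds
        self.runs_per_round = runs_per_round
        self.seed = seed
        self.pts = pts
        self.timescale_factor = timescale_factor
        self.bounds = bounds
        self.start = start

    def get_params(self, deep: bool = True) -> dict:
        return {"model_name": self.model_name, "rounds": self.rounds,
                "runs_per_round": self.runs_per_round, "seed": self.seed,
                "pts": self.pts, "timescale_factor": self.timescale_factor,
                "bounds": self.bounds, "start": self.start}

    def set_params(self, **kw) -> "DemographicModel":
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: JAFS, y=None) -> "DemographicModel":
        result = optimize_fit(
            X, self.model_name, start=self.start, bounds=self.bounds,
            seed=self.seed, rounds=tuple(self.rounds),
            runs_per_round=self.runs_per_round, pts=self.pts,
            timescale_factor=self.timescale_factor)
        self.result_ = result
        self.params_ = result.params
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.theta_ = result.params.theta_hat
        return self

    def predict(self, X: JAFS | None = None) -> JAFS:
        """Expected spectrum at the fitted parameters, scaled by theta."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        sizes = X.sample_sizes if X is not None else None
        if sizes is None:
            raise ValueError("pass the data spectrum to size the output")
        engine = ExpectedJAFSEngine(sizes[0], sizes[1], pts=self.pts,
                                    timescale_factor=self.timescale_factor)
        spec = engine.expected(self.params_)
        spec.counts = spec.counts * (self.theta_ or 1.0)
        return spec

    def score(self, X: JAFS, y=None) -> float:
        engine = ExpectedJAFSEngine(X.sample_sizes[0], X.sample_sizes[1],
                                    pts=self.pts,
                                    timescale_factor=self.timescale_factor)
        ll, _ = composite_loglik(engine.expected(self.params_), X)
        return ll
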