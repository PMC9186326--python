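"""SECR conditional likelihood for binary proximity detectors.

Density estimation from spatial capture-recapture data proceeds by
integrating, over a discretized region of possible activity centers (the
habitat mesh), the probability of each individual's observed capture
history under a half-normal detection model:

    p(detect at trap k | activity center x) = g0 * exp(-d(x,k)^2 / (2 sigma^2))

with g0 on the logit scale a function of sex and of prior detection at the
same trap (the "bk" learned response), sigma on the log scale a function of
sex and optionally a latent two-class finite mixture, and per trap-occasion
effort u entering as 1 - (1 - p)^u.  d(x,k) is either Euclidean distance or
a least-cost-path distance through a resistance surface exp(alpha2 * z),
with alpha2 estimated jointly.

The likelihood is conditional on detection: each individual contributes

    Pr(omega_i) / Pr(detected at least once)

where the denominator ("pdot" integrated over the mesh) always refers to a
naive animal (bk = 0).  Density is then the Horvitz-Thompson style derived
parameter D = sum_i 1 / a_i, with a_i the individual's effective sampling
area, and its variance combines a Poisson point-process component with a
delta-method propagation of parameter uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .distance import LcpDistanceCache, euclidean_distance_matrix
from .raster import CostRaster

SEXES = ("F", "M")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class TrapArray:
    """Detector locations with a detector x occasion effort (usage) matrix."""

    ids: list
    xy: np.ndarray          # (K, 2) projected metres
    usage: np.ndarray       # (K, S), entries in [0, 1]

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.usage = np.asarray(self.usage, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate detector ids")
        if self.xy.shape != (len(self.ids), 2):
            raise ValueError("xy must be (n_detectors, 2)")
        if self.usage.shape[0] != len(self.ids):
            raise ValueError("usage rows must match detectors")
        if ((self.usage < 0) | (self.usage > 1)).any():
            raise ValueError("usage entries must lie in [0, 1]")

    @property
    def n_traps(self) -> int:
        return len(self.ids)

    @property
    def n_occasions(self) -> int:
        return self.usage.shape[1]


@dataclass
class CaptureHistories:
    """Binary individual x occasion x detector detections with sex labels."""

    omega: np.ndarray       # (n, S, K) in {0, 1}
    sex: np.ndarray         # (n,) of "F"/"M"
    ids: list | None = None

    def __post_init__(self):
        self.omega = np.asarray(self.omega)
        self.sex = np.asarray(self.sex)
        if self.omega.ndim != 3:
            raise ValueError("omega must be (n, S, K)")
        if len(self.sex) != self.omega.shape[0]:
            raise ValueError("one sex label per individual required")
        if self.omega.shape[0] and not self.omega.any(axis=(1, 2)).all():
            raise ValueError("every individual must have >= 1 detection")
        bad = set(np.unique(self.sex)) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex labels: {bad}")

    @property
    def n_individuals(self) -> int:
        return self.omega.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.omega.shape[1]

    @property
    def n_traps(self) -> int:
        return self.omega.shape[2]


@dataclass
class HabitatMesh:
    """Discretized region of integration: candidate activity-center points."""

    points: np.ndarray      # (M, 2) cell centers, metres
    spacing: float          # metres
    n_water_excluded: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not self.spacing > 0:
            raise ValueError("mesh spacing must be positive")
        if len(self.points) == 0:
            raise ValueError("mesh is empty")

    @property
    def cell_area_km2(self) -> float:
        return self.spacing**2 / 1e6

    @property
    def n_points(self) -> int:
        return len(self.points)


def make_mesh(traps: TrapArray, buffer: float = 15_000.0,
              spacing: float = 1_000.0,
              water: CostRaster | None = None) -> HabitatMesh:
    """Build the habitat mesh: a lattice buffered around the detectors.

    Points further than ``buffer`` from every detector are dropped, as are
    points falling on water cells (value > 0.5 in ``water``).  The lattice
    is anchored at the detector bounding-box corner so detector coordinates
    that sit on the lattice remain mesh points.
    """
    if buffer <= 0 or spacing <= 0:
        raise ValueError("buffer and spacing must be positive")
    xy = traps.xy
    x0, y0 = xy[:, 0].min(), xy[:, 1].min()
    pad = math.ceil(buffer / spacing) * spacing
    xs = np.arange(x0 - pad, xy[:, 0].max() + pad + spacing / 2, spacing)
    ys = np.arange(y0 - pad, xy[:, 1].max() + pad + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = euclidean_distance_matrix(pts, xy).d.min(axis=1)
    pts = pts[d <= buffer]

    n_water = 0
    if water is not None:
        keep = np.ones(len(pts), dtype=bool)
        for i, (px, py) in enumerate(pts):
            try:
                r, c = water.index_of(px, py)
            except ValueError:
                continue
            v = water.values[r, c]
            if np.isfinite(v) and v > 0.5:
                keep[i] = False
        n_water = int((~keep).sum())
        pts = pts[keep]
    if len(pts) == 0:
        raise ValueError("mesh is empty after buffering/water exclusion")
    return HabitatMesh(pts, spacing, n_water_excluded=n_water)


# ---------------------------------------------------------------------------
# Model specification and parameters
# ---------------------------------------------------------------------------

COVARIATES = ("roads", "ruggedness", "water")
RESOLUTIONS = (30, 60, 120, 240, 480, 960)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate detection model.

    All models share sex effects on g0 and sigma and a trap-specific
    learned response (bk) on g0.  On top of that base: ``mixture`` adds a
    two-class sigma mixture (Euclidean only); ``distance_mode='lcp'``
    replaces Euclidean distance with least-cost-path distance through one
    covariate at one resolution, with alpha2 estimated (identity scale for
    roads, log scale i.e. positive-only for ruggedness and water).
    """

    distance_mode: str = "euclidean"
    covariate: str | None = None
    resolution: int | None = None
    mixture: bool = False
    alpha2_constraint: str = "unconstrained"

    def __post_init__(self):
        if self.distance_mode not in ("euclidean", "lcp"):
            raise ValueError("distance_mode must be 'euclidean' or 'lcp'")
        if self.distance_mode == "lcp":
            if self.mixture:
                raise ValueError("mixture models use Euclidean distance only")
            if self.covariate not in COVARIATES:
                raise ValueError(f"unknown covariate {self.covariate!r}")
            if self.resolution is None:
                raise ValueError("lcp models need a resolution")
        else:
            if self.covariate is not None or self.resolution is not None:
                raise ValueError("covariate/resolution only apply to lcp mode")
        if self.alpha2_constraint not in ("unconstrained", "positive"):
            raise ValueError("bad alpha2_constraint")

    @property
    def n_params(self) -> int:
        n = 5  # g0: intercept+sex+bk; sigma: intercept+sex
        if self.mixture:
            n += 2  # sigma class effect + mixing proportion
        if self.distance_mode == "lcp":
            n += 1  # alpha2
        return n

    @property
    def label(self) -> str:
        if self.distance_mode == "euclidean":
            return "euclidean.h2" if self.mixture else "euclidean"
        return f"lcp.{self.covariate}.{self.resolution}m"


@dataclass
class DetectionParams:
    """Detection parameters on their link scales.

    g0 is logit-linear in sex and the bk indicator; sigma is log-linear in
    sex and the latent mixture class; pi is the mixing proportion of class
    1 (logit scale); alpha2 is the resistance coefficient (identity scale;
    models with a positivity constraint optimize log alpha2 and store the
    back-transformed value here).
    """

    beta0: float            # logit g0, female, naive
    beta_male: float = 0.0
    beta_bk: float = 0.0
    gamma0: float = math.log(2000.0)   # log sigma (m), female, class 1
    gamma_male: float = 0.0
    gamma_h2: float = 0.0   # class-2 effect on log sigma
    logit_pi: float = 0.0   # mixing proportion of class 1
    alpha2: float | None = None

    def g0(self, sex: str, bk: int = 0) -> float:
        return float(expit(self.beta0 + self.beta_male * (sex == "M")
                           + self.beta_bk * bk))

    def sigma(self, sex: str, cls: int = 1) -> float:
        return float(np.exp(self.gamma0 + self.gamma_male * (sex == "M")
                            + self.gamma_h2 * (cls == 2)))

    @property
    def pi(self) -> float:
        return float(expit(self.logit_pi))

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        v = [self.beta0, self.beta_male, self.beta_bk,
             self.gamma0, self.gamma_male]
        if spec.mixture:
            v += [self.gamma_h2, self.logit_pi]
        if spec.distance_mode == "lcp":
            a2 = 0.0 if self.alpha2 is None else self.alpha2
            if spec.alpha2_constraint == "positive":
                v.append(math.log(a2) if a2 > 0 else math.log(0.05))
            else:
                v.append(a2)
        return np.array(v, dtype=float)

    @classmethod
    def from_vector(cls, theta: np.ndarray, spec: ModelSpec) -> "DetectionParams":
        theta = np.asarray(theta, dtype=float)
        p = cls(beta0=theta[0], beta_male=theta[1], beta_bk=theta[2],
                gamma0=theta[3], gamma_male=theta[4])
        i = 5
        if spec.mixture:
            p.gamma_h2, p.logit_pi = theta[i], theta[i + 1]
            i += 2
        if spec.distance_mode == "lcp":
            raw = theta[i]
            p.alpha2 = float(np.exp(raw)) if spec.alpha2_constraint == "positive" \
                else float(raw)
        return p


# ---------------------------------------------------------------------------
# Elementary detection quantities
# ---------------------------------------------------------------------------

def halfnormal_p(d, g0, sigma):
    """Half-normal detection probability g0 * exp(-d^2 / (2 sigma^2))."""
    d = np.asarray(d, dtype=float)
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    return g0 * np.exp(-(d**2) / (2.0 * sigma**2))


def usage_adjust(p, u):
    """Effort-adjusted detection probability 1 - (1 - p)^u, u in [0, 1]."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("usage must lie in [0, 1]")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** u

def bk_indicator(omega_i: np.ndarray, trap: int, occasion: int) -> int:
    """1 iff the individual was detected at this trap on an earlier occasion.

    ``omega_i`` is the individual's (S, K) history; ``occasion`` is 0-based.
    """
    return int(np.asarray(omega_i)[:occasion, trap].any())


def encounter_prob(d: float, sex: str, cls: int, bk: int,
                   params: DetectionParams, u: float = 1.0) -> float:
    """Single trap-occasion detection probability for one activity center."""
    if not np.isfinite(d):
        return 0.0
    g0 = params.g0(sex, bk)
    sigma = params.sigma(sex, cls)
    return float(usage_adjust(halfnormal_p(d, g0, sigma), u))


# ---------------------------------------------------------------------------
# Conditional likelihood (vectorized over the mesh)
# ---------------------------------------------------------------------------

class _HistoryStats:
    """Per-individual sufficient statistics for the likelihood.

    Only occasions-by-trap cells where a detection occurred, or where the bk
    indicator is on, differ from the naive animal, so the non-detection part
    of each history collapses to two effort totals per trap:

    - ``A[i, k]``: total effort over occasions with no detection, bk = 0
    - ``B[i, k]``: total effort over occasions with no detection, bk = 1
    - detection events as flat arrays (individual, trap, bk flag, effort)
    """

    def __init__(self, data: CaptureHistories, traps: TrapArray):
        omega = data.omega.astype(bool)       # (n, S, K)
        n, S, K = omega.shape
        u = traps.usage.T[None, :, :]         # (1, S, K)
        if bool(np.any(omega & (traps.usage.T[None] <= 0))):
            raise ValueError("detections recorded at zero-usage trap-occasions")
        # bk[i, s, k] = detected at k on any occasion before s
        cum = np.cumsum(omega, axis=1)
        bk = np.zeros_like(omega)
        bk[:, 1:, :] = cum[:, :-1, :] > 0
        nondet = ~omega
        self.A = (u * (nondet & ~bk)).sum(axis=1)   # (n, K)
        self.B = (u * (nondet & bk)).sum(axis=1)    # (n, K)
        i_idx, s_idx, k_idx = np.nonzero(omega)
        self.det_i = i_idx
        self.det_k = k_idx
        self.det_bk = bk[i_idx, s_idx, k_idx]
        self.det_u = traps.usage[k_idx, s_idx]
        self.male = data.sex == "M"
        self.U_total = traps.usage.sum(axis=1)       # (K,)


def _class_loglik(dmat: np.ndarray, stats: _HistoryStats,
                  params: DetectionParams, cls: int):
    """Per-individual log integral of Pr(history | x) over the mesh, and
    log of the integrated pdot, for one latent class; both per sex.

    Returns (lognum, logpdot_sum) where lognum is (n,) of
    log sum_x Pr(omega_i | x, cls) and logpdot_sum is a dict sex -> log
    sum_x pdot(x, sex, cls).  Cell area is applied by the caller.
    """
    n = len(stats.A)
    lognum = np.empty(n)
    logpdot = {}
    d2 = dmat**2
    for sex, male in (("F", False), ("M", True)):
        # numpy scalar: absurd optimizer excursions give inf, not a raise
        sigma = np.float64(params.sigma(sex, cls))
        logkern = -d2 / (2.0 * sigma**2)             # (M, K)
        kern = np.exp(logkern)
        g0_0 = params.g0(sex, 0)
        g0_1 = params.g0(sex, 1)
        with np.errstate(divide="ignore"):
            log1mq0 = np.log1p(-g0_0 * kern)
            log1mq1 = np.log1p(-g0_1 * kern)
            logg0_0 = np.log(g0_0)
            logg0_1 = np.log(g0_1)

        # naive-animal denominator: log(1 - pdot(x)) = sum_k U_k log(1 - q0)
        log1mpdot = log1mq0 @ stats.U_total
        pdot = -np.expm1(log1mpdot)
        logpdot[sex] = float(np.log(pdot.sum())) if pdot.sum() > 0 else -np.inf

        rows = np.nonzero(stats.male == male)[0]
        if rows.size == 0:
            continue
        # non-detection contribution, all individuals of this sex at once
        contrib = stats.A[rows] @ log1mq0.T + stats.B[rows] @ log1mq1.T  # (n_s, M)
        # detection events, vectorized over (event, mesh)
        local = np.full(stats.A.shape[0], -1)
        local[rows] = np.arange(rows.size)
        sel = np.nonzero(local[stats.det_i] >= 0)[0]
        if sel.size:
            k_e = stats.det_k[sel]
            b_e = stats.det_bk[sel]
            u_e = stats.det_u[sel]
            row_e = local[stats.det_i[sel]]
            logg = np.where(b_e, logg0_1, logg0_0)
            full = u_e >= 1.0
            terms = np.empty((sel.size, dmat.shape[0]))
            if full.any():
                terms[full] = logkern[:, k_e[full]].T + logg[full][:, None]
            if (~full).any():
                # partial effort: log(1 - (1 - q)^u)
                part = np.nonzero(~full)[0]
                l1mq = np.where(b_e[part][:, None], log1mq1[:, k_e[part]].T,
                                log1mq0[:, k_e[part]].T)
                with np.errstate(divide="ignore", invalid="ignore"):
                    terms[part] = np.log(-np.expm1(u_e[part][:, None] * l1mq))
            order = np.argsort(row_e, kind="stable")
            sorted_rows = row_e[order]
            starts = np.nonzero(np.r_[True, sorted_rows[1:] != sorted_rows[:-1]])[0]
            contrib[sorted_rows[starts]] += np.add.reduceat(terms[order], starts,
                                                            axis=0)
        lognum[rows] = logsumexp(contrib, axis=1)
    return lognum, logpdot


def conditional_negloglik(data: CaptureHistories, mesh: HabitatMesh,
                          traps: TrapArray, params: DetectionParams,
                          spec: ModelSpec, distances,
                          stats: "_HistoryStats | None" = None) -> float:
    """Negative log conditional likelihood for proximity detectors.

    ``distances`` is the (M, K) mesh-to-trap matrix for Euclidean models,
    or an :class:`~scrpath.distance.LcpDistanceCache` whose matrix is
    re-evaluated at ``params.alpha2`` for non-Euclidean models.  Mixture
    models sum the numerator and denominator over the two latent classes
    weighted by pi; non-mixture models are the pi = 1 special case.
    Non-finite results (overflow, impossible data) raise.
    """
    if isinstance(distances, LcpDistanceCache):
        if params.alpha2 is None:
            raise ValueError("lcp model requires alpha2")
        dmat = distances.matrix(params.alpha2)
    else:
        dmat = np.asarray(distances, dtype=float)
        if spec.distance_mode == "euclidean" and params.alpha2 is not None:
            raise ValueError("alpha2 given for a Euclidean model")
    if stats is None:
        stats = _HistoryStats(data, traps)
    logA = math.log(mesh.cell_area_km2)

    if spec.mixture:
        pi = params.pi
        ln1, lp1 = _class_loglik(dmat, stats, params, cls=1)
        ln2, lp2 = _class_loglik(dmat, stats, params, cls=2)
        with np.errstate(divide="ignore"):
            lognum = np.logaddexp(math.log(pi) + ln1,
                                  math.log1p(-pi) + ln2)
        logden = {s: np.logaddexp(math.log(pi) + lp1[s],
                                  math.log1p(-pi) + lp2[s]) for s in SEXES}
    else:
        lognum, logden = _class_loglik(dmat, stats, params, cls=1)

    ll = 0.0
    for sex in SEXES:
        rows = np.nonzero(data.sex == sex)[0]
        if rows.size == 0:
            continue
        # logA cancels between numerator and denominator but both are kept
        # on the area scale for interpretability of intermediate values
        ll += float(np.sum(lognum[rows] + logA)) \
            - rows.size * (logden[sex] + logA)
    nll = -ll
    if math.isnan(nll):
        raise FloatingPointError("conditional likelihood evaluated to NaN")
    return nll


def effective_sampling_area(params: DetectionParams, sex: str,
                            mesh: HabitatMesh, traps: TrapArray,
                            distances, mixture: bool = False) -> float:
    """Effective sampling area a(sex) in km^2.

    Integral over the mesh of the probability that a naive animal of the
    given sex is detected at least once; for mixture models the pi-weighted
    average of the class-specific integrals.
    """
    if isinstance(distances, LcpDistanceCache):
        dmat = distances.matrix(params.alpha2)
    else:
        dmat = np.asarray(distances, dtype=float)
    U = traps.usage.sum(axis=1)
    d2 = dmat**2

    def one_class(cls):
        sigma = params.sigma(sex, cls)
        kern = np.exp(-d2 / (2.0 * sigma**2))
        with np.errstate(divide="ignore"):
            log1mq = np.log1p(-params.g0(sex, 0) * kern)
        return float(-np.expm1(log1mq @ U).sum())

    total = one_class(1)
    if mixture:
        total = params.pi * total + (1.0 - params.pi) * one_class(2)
    return total * mesh.cell_area_km2


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class ScrFit:
    """A fitted SECR model with derived density."""

    spec: ModelSpec
    params: DetectionParams
    theta: np.ndarray
    loglik: float
    vcov: np.ndarray | None
    converged: bool
    n_params: int
    density: float | None = None          # animals / km^2
    density_se: float | None = None
    esa_by_sex: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    _ctx: dict = field(default_factory=dict, repr=False)

    @property
    def rse(self) -> float | None:
        """Relative standard error: SE divided by the point estimate."""
        if self.density_se is None or not self.density:
            return None
        return self.density_se / self.density

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label,
            "theta": list(map(float, self.theta)),
            "loglik": float(self.loglik),
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "density": self.density,
            "density_se": self.density_se,
            "rse": self.rse,
            "esa_by_sex": {k: float(v) for k, v in self.esa_by_sex.items()},
            "vcov": None if self.vcov is None
            else [list(map(float, r)) for r in self.vcov],
            "warnings": list(self.warnings),
        }


def _sigma_start(data: CaptureHistories, traps: TrapArray) -> float:
    """Crude sigma starting value from within-individual trap spread."""
    dists = []
    for i in range(data.n_individuals):
        ks = np.unique(np.nonzero(data.omega[i].sum(axis=0))[0])
        if len(ks) > 1:
            xy = traps.xy[ks]
            diff = xy[:, None, :] - xy[None, :, :]
            dists.append(np.sqrt((diff**2).sum(-1)).max())
    if dists:
        return max(float(np.mean(dists)) / math.sqrt(2.0), 200.0)
    return 2000.0


def _numeric_hessian(fun, theta, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                f0 = fun(theta)
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                H[i, i] = (fun(tp) - 2 * f0 + fun(tm)) / h[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += [h[i], h[j]]
                tpm[i] += h[i]; tpm[j] -= h[j]
                tmp[i] -= h[i]; tmp[j] += h[j]
                tmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    fun(tpp) - fun(tpm) - fun(tmp) + fun(tmm)
                ) / (4 * h[i] * h[j])
    return H


def fit_model(spec: ModelSpec, data: CaptureHistories, mesh: HabitatMesh,
              traps: TrapArray, surfaces: dict | None = None,
              start: DetectionParams | None = None,
              directions: int = 16, seed: int = 0,
              maxiter: int = 500, compute_vcov: bool = True) -> ScrFit:
    """Maximize the conditional likelihood for one model specification.

    ``surfaces`` maps (covariate, resolution) to a [1, 10]-scaled
    :class:`CostRaster`; required for lcp models.  ``start`` (typically the
    simple Euclidean fit's parameters) seeds the optimizer; on
    non-convergence up to three jittered restarts are attempted.  The
    parameter covariance is the inverse of the numerically differentiated
    observed information.
    """
    if data.n_individuals == 0:
        raise ValueError("no detected individuals")
    if spec.distance_mode == "lcp":
        if surfaces is None or (spec.covariate, spec.resolution) not in surfaces:
            raise ValueError(
                f"no surface provided for {spec.covariate} at {spec.resolution} m")
        cov_raster = surfaces[(spec.covariate, spec.resolution)]
        distances = LcpDistanceCache(cov_raster, mesh.points, traps.xy,
                                     directions=directions)
    else:
        distances = euclidean_distance_matrix(mesh.points, traps.xy).d

    warnings: list[str] = []
    n_spatial = _count_spatial_recaptures(data)
    if n_spatial == 0:
        warnings.append("no spatial recaptures: sigma weakly identified")

    if start is None:
        start = DetectionParams(
            beta0=float(np.log(0.1 / 0.9)),
            gamma0=math.log(_sigma_start(data, traps)),
        )
    if spec.mixture and start.gamma_h2 == 0.0:
        # break class symmetry so the optimizer can leave the ridge
        start = replace(start, gamma_h2=0.5, logit_pi=0.0)
    theta0 = start.to_vector(spec)

    hstats = _HistoryStats(data, traps)

    def nll(theta):
        p = DetectionParams.from_vector(theta, spec)
        if spec.distance_mode == "euclidean":
            p.alpha2 = None
        try:
            return conditional_negloglik(data, mesh, traps, p, spec, distances,
                                         stats=hstats)
        except (FloatingPointError, OverflowError):
            return np.inf

    rng = np.random.default_rng(seed)
    best = None
    best_ok = False

    def acceptable(res):
        # BFGS with finite-difference gradients often stops with a
        # "precision loss" message at the optimum once the gradient falls
        # below the differencing noise floor; accept such solutions when
        # the gradient is statistically negligible.
        if res.success:
            return True
        return (np.isfinite(res.fun) and res.jac is not None
                and np.max(np.abs(res.jac)) < 0.05)

    for attempt in range(4):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, len(theta0))
        res = minimize(nll, t0, method="BFGS",
                       options={"maxiter": maxiter, "gtol": 1e-4})
        if best is None or res.fun < best.fun - 1e-9:
            best, best_ok = res, acceptable(res)
        if acceptable(res):
            break
    if not best.success:
        warnings.append(f"optimizer message: {best.message}")
    theta_hat = np.asarray(best.x, dtype=float)
    params_hat = DetectionParams.from_vector(theta_hat, spec)

    vcov = None
    if compute_vcov:
        try:
            H = _numeric_hessian(nll, theta_hat)
            vcov = np.linalg.inv(H)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
                vcov = None
                warnings.append("observed information singular or indefinite")
        except np.linalg.LinAlgError:
            warnings.append("observed information not invertible")

    fit = ScrFit(spec=spec, params=params_hat, theta=theta_hat,
                 loglik=-float(best.fun), vcov=vcov,
                 converged=bool(best_ok), n_params=spec.n_params,
                 warnings=warnings,
                 _ctx={"data": data, "mesh": mesh, "traps": traps,
                       "distances": distances})
    derived_density(fit, data)
    return fit


def _count_spatial_recaptures(data: CaptureHistories) -> int:
    total = 0
    for i in range(data.n_individuals):
        s_idx, k_idx = np.nonzero(data.omega[i])
        if len(s_idx) == 0:
            continue
        order = np.lexsort((k_idx, s_idx))
        first_trap = k_idx[order][0]
        total += int((k_idx != first_trap).sum())
    return total


def derived_density(fit: ScrFit, data: CaptureHistories) -> tuple:
    """Derived density D = sum_i 1/a_i with asymptotic Poisson variance.

    a_i is the effective sampling area for individual i's sex (mixture
    weighted).  var(D) combines the Poisson point-process component
    sum a_i^-2 with the delta-method term G' V G, where G differentiates
    D with respect to the detection parameters.  Results are stored on the
    fit and returned as (D, SE, RSE).
    """
    ctx = fit._ctx
    mesh, traps, distances = ctx["mesh"], ctx["traps"], ctx["distances"]
    spec = fit.spec

    def areas(theta):
        p = DetectionParams.from_vector(theta, spec)
        return {s: effective_sampling_area(p, s, mesh, traps, distances,
                                           mixture=spec.mixture)
                for s in SEXES}

    a_hat = areas(fit.theta)
    fit.esa_by_sex = a_hat
    n_by_sex = {s: int((data.sex == s).sum()) for s in SEXES}
    if min(a_hat.values()) <= 0:
        fit.warnings.append("zero effective sampling area")
        return None, None, None
    D = sum(n_by_sex[s] / a_hat[s] for s in SEXES)
    poisson_var = sum(n_by_sex[s] / a_hat[s] ** 2 for s in SEXES)

    se = None
    if fit.vcov is not None:
        k = len(fit.theta)
        G = np.empty(k)
        h = 1e-4 * np.maximum(np.abs(fit.theta), 1.0)
        for t in range(k):
            tp, tm = fit.theta.copy(), fit.theta.copy()
            tp[t] += h[t]
            tm[t] -= h[t]
            ap, am = areas(tp), areas(tm)
            Dp = sum(n_by_sex[s] / ap[s] for s in SEXES)
            Dm = sum(n_by_sex[s] / am[s] for s in SEXES)
            G[t] = (Dp - Dm) / (2 * h[t])
        var = poisson_var + float(G @ fit.vcov @ G)
        se = math.sqrt(var) if var > 0 else None
    fit.density = float(D)
    fit.density_se = se
    return fit.density, se, fit.rse
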