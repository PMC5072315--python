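"""Local edge inference: Bayesian scoring of single-regulator Hill models.

For each target gene the engine enumerates every candidate regulation
(regulator, sign) allowed by the role prior, fits the five kinetic
parameters theta = (alpha, beta, gamma, n, K) of the corresponding ODE by
bounded multi-start minimization of an integral-equation loss, and scores
each candidate by a Gibbs posterior

    p(E | D)  proportional to  integral_{R_E} exp(-l(D,E,theta)/lambda)
                               dtheta / (s * Vol(R_E)),

approximated by Laplace's method at the loss minimizer. The loss compares
the observed trajectory with the running integral of the modeled
derivative, with an additive shift absorbing the unknown integration
constant:

    l = min_c (1/T) sum_j (X(t_j) - Xhat(t_j) - c)^2,
    Xhat(t_j) = cumulative trapezoid of
                F(t) = alpha*hill(Y(t)) - beta*X(t) + gamma.

Working on the integrated equation rather than on estimated derivatives
makes the fit robust to measurement noise. Because each node is scored
separately (the local approximation), the per-node posteriors are
independent work units and the whole inference is embarrassingly parallel.

Expression is min-max normalized per gene to [0, 1] before fitting so the
default parameter box and the Gibbs temperature are meaningful across
datasets; fitted parameters are mapped back to data units for reporting.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import lsq_linear, minimize
from scipy.special import logsumexp
from scipy.stats import qmc

from .model_core import (
    EdgeModel,
    ExpressionDataset,
    NetworkSpec,
    NodeRule,
    PARAM_NAMES,
    ParamVector,
    ParameterDomainError,
    Sign,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterRegion",
    "PriorSpec",
    "CandidateSet",
    "EdgeScore",
    "NodePosterior",
    "InferenceSettings",
    "InferenceResult",
    "FitError",
    "enumerate_candidates",
    "model_prediction",
    "loss",
    "default_region",
    "fit_edge",
    "log_evidence",
    "node_posterior",
    "infer_network",
    "extract_network",
    "assemble_system",
    "normalize_dataset",
    "gibbs_temperature",
]


class FitError(RuntimeError):
    """Optimization failed for an edge; carries the edge id in the message."""


# ---------------------------------------------------------------------------
# Parameter regions and priors
# ---------------------------------------------------------------------------


@dataclass
class ParameterRegion:
    """Axis-aligned box of admissible (alpha, beta, gamma, n, K).

    The maximum-entropy prior over the box is uniform with density
    1 / Vol. An axis may be pinned (lower == upper) to fix a parameter;
    pinned axes do not count toward the volume or the Laplace dimension.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != (5,) or self.upper.shape != (5,):
            raise ValueError("bounds must be length-5 (alpha, beta, gamma, n, K)")
        if np.any(self.upper < self.lower):
            raise ValueError("upper bound below lower bound")
        lo = self.lower
        if lo[0] < 0 or lo[1] < 0 or lo[2] < 0 or lo[3] < 1 or lo[4] <= 0:
            raise ValueError(
                "bounds violate parameter domains (alpha,beta,gamma >= 0, n >= 1, K > 0)"
            )
        if not np.any(self.free_mask):
            raise ValueError("at least one axis must be free")

    @property
    def free_mask(self) -> np.ndarray:
        return self.upper > self.lower

    @property
    def n_free(self) -> int:
        return int(np.sum(self.free_mask))

    @property
    def volume(self) -> float:
        widths = (self.upper - self.lower)[self.free_mask]
        return float(np.prod(widths))

    def contains(self, theta: np.ndarray, rtol: float = 1e-9) -> bool:
        theta = np.asarray(theta, dtype=float)
        slack = rtol * np.maximum(1.0, np.abs(self.upper))
        return bool(
            np.all(theta >= self.lower - slack) and np.all(theta <= self.upper + slack)
        )

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lower, self.upper)

    def override(self, **bounds: tuple[float, float]) -> "ParameterRegion":
        """New region with named axes replaced, e.g. ``override(n=(1, 4))``."""
        lo, hi = self.lower.copy(), self.upper.copy()
        for name, (a, b) in bounds.items():
            i = PARAM_NAMES.index(name)
            lo[i], hi[i] = a, b
        return ParameterRegion(lo, hi)


@dataclass
class PriorSpec:
    """Per-gene regulatory role: 'activator', 'repressor', or 'both'.

    A gene marked activator never appears as a repressor in any candidate
    set (and vice versa); unlisted genes default to 'both'.
    """

    roles: dict[str, str] = field(default_factory=dict)

    _VALID = ("activator", "repressor", "both")

    def __post_init__(self) -> None:
        for g, r in self.roles.items():
            if r not in self._VALID:
                raise ValueError(f"role for {g!r} must be one of {self._VALID}, got {r!r}")

    def role(self, gene: str) -> str:
        return self.roles.get(gene, "both")


@dataclass
class CandidateSet:
    """Ordered candidate edges for one target after prior filtering;
    ``s`` is the number of candidates (the prior mass is 1/s each)."""

    target: str
    edges: list[EdgeModel]

    @property
    def s(self) -> int:
        return len(self.edges)


def enumerate_candidates(
    target: str,
    genes: list[str],
    prior: PriorSpec | None = None,
    include_self: bool = True,
) -> CandidateSet:
    """All candidate regulations of ``target`` allowed by the role prior.

    For every potential regulator Y the activation edge is listed unless Y
    is marked repressor, and the repression edge unless Y is marked
    activator. Order is deterministic: regulator name, then activation
    before repression. An empty candidate set raises ``ValueError``.
    """
    if target not in genes:
        raise ValueError(f"target {target!r} not among genes")
    prior = prior or PriorSpec()
    edges = []
    for reg in sorted(genes):
        if not include_self and reg == target:
            continue
        role = prior.role(reg)
        if role != "repressor":
            edges.append(EdgeModel(target, reg, Sign.ACTIVATION))
        if role != "activator":
            edges.append(EdgeModel(target, reg, Sign.REPRESSION))
    if not edges:
        raise ValueError(
            f"prior excludes every candidate regulation of target {target!r}"
        )
    return CandidateSet(target=target, edges=edges)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def _hill_fast(x: np.ndarray, K: float, n: float, is_activation: bool) -> np.ndarray:
    # Unchecked Hill for optimizer internals: finite-difference probes may
    # step marginally outside the admissible box, so clamp instead of raise.
    K = max(K, 1e-12)
    n = max(n, 1.0)
    r = np.power(np.maximum(x, 0.0) / K, n)
    act = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    return act if is_activation else 1.0 - act


class _EdgeProblem:
    """Precomputed quantities for repeated loss evaluation on one edge."""

    def __init__(self, data: ExpressionDataset, edge: EdgeModel):
        self.edge = edge
        self.t = data.times
        self.xt = data.gene(edge.target)
        self.xr = data.gene(edge.regulator)
        self.is_act = edge.sign is Sign.ACTIVATION
        self.T = self.t.size
        # running integrals of the affine pieces: Xhat is linear in
        # (alpha, beta, gamma) once (n, K) are fixed
        self.int_x = cumulative_trapezoid(self.xt, self.t, initial=0.0)
        self.int_1 = self.t - self.t[0]

    def prediction(self, theta: np.ndarray) -> np.ndarray:
        a, b, g, n, K = theta
        h = _hill_fast(self.xr, K, n, self.is_act)
        F = a * h - b * self.xt + g
        if not np.all(np.isfinite(F)):
            raise ParameterDomainError(
                f"non-finite model derivative for edge {self.edge} at theta={theta}"
            )
        return cumulative_trapezoid(F, self.t, initial=0.0)

    def loss(self, theta: np.ndarray) -> float:
        r = self.xt - self.prediction(theta)
        r = r - r.mean()  # optimal shift c in closed form
        return float(np.mean(r * r))

    def loss_and_shift(self, theta: np.ndarray) -> tuple[float, float]:
        r = self.xt - self.prediction(theta)
        c = float(r.mean())
        r = r - c
        return float(np.mean(r * r)), c


def model_prediction(
    data: ExpressionDataset, edge: EdgeModel, theta: ParamVector
) -> np.ndarray:
    """Integrated model prediction Xhat(t_j).

    Evaluates F(t_j) = alpha*hill(X_reg(t_j)) - beta*X_target(t_j) + gamma,
    extends F by linear interpolation, and integrates from t_1; on the
    sample grid this is exactly the cumulative trapezoid of F, with
    Xhat(t_1) = 0.
    """
    return _EdgeProblem(data, edge).prediction(theta.as_array())


def loss(
    data: ExpressionDataset,
    edge: EdgeModel,
    theta: ParamVector,
    return_shift: bool = False,
):
    """Shift-minimized mean squared error between data and prediction.

    l = min_c (1/T) sum_j (X(t_j) - Xhat(t_j) - c)^2; the minimizing shift
    is the mean residual. With ``return_shift`` the pair (l, c) is
    returned.
    """
    l, c = _EdgeProblem(data, edge).loss_and_shift(theta.as_array())
    return (l, c) if return_shift else l


# ---------------------------------------------------------------------------
# Default parameter region
# ---------------------------------------------------------------------------

#: Floor for the half-saturation interval when the regulator is constant.
_K_EPS = 1e-3


def default_region(data: ExpressionDataset, edge: EdgeModel) -> ParameterRegion:
    """Biologically-reasonable default box for min-max normalized data.

    With each trajectory scaled to [0, 1] and W the window length
    t_T - t_1: alpha and beta in [0.01, 20]/W, gamma in [0, 5]/W, n in
    [1, 8], K spanning the regulator's observed range (floored at 1e-3).
    A constant regulator degenerates the K interval; it is widened to
    [1e-3, max(1, level)] with a warning.
    """
    W = float(data.times[-1] - data.times[0])
    xr = data.gene(edge.regulator)
    k_lo = max(_K_EPS, float(xr.min()))
    k_hi = float(xr.max())
    if not k_hi > k_lo:
        warnings.warn(
            f"regulator {edge.regulator!r} is constant; widening K interval",
            stacklevel=2,
        )
        k_lo, k_hi = _K_EPS, max(1.0, k_hi)
    lower = np.array([0.01 / W, 0.01 / W, 0.0, 1.0, k_lo])
    upper = np.array([20.0 / W, 20.0 / W, 5.0 / W, 8.0, k_hi])
    return ParameterRegion(lower, upper)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _informed_starts(prob: _EdgeProblem, region: ParameterRegion) -> list[np.ndarray]:
    """Cheap deterministic warm starts: on a small (n, K) grid the loss is
    a bounded linear least-squares problem in (alpha, beta, gamma, c),
    solved in closed form; the best few grid points seed the local search."""
    lo, hi = region.lower, region.upper
    n_vals = np.unique(np.clip([1.0, 2.0, 4.0, 8.0], lo[3], hi[3]))
    qs = np.quantile(prob.xr, [0.25, 0.5, 0.75])
    k_vals = np.unique(np.clip(qs, lo[4], hi[4]))
    out = []
    for n in n_vals:
        for K in k_vals:
            h = _hill_fast(prob.xr, float(K), float(n), prob.is_act)
            A = np.column_stack(
                [
                    cumulative_trapezoid(h, prob.t, initial=0.0),
                    -prob.int_x,
                    prob.int_1,
                    np.ones(prob.T),
                ]
            )
            res = lsq_linear(
                A,
                prob.xt,
                bounds=(
                    [lo[0], lo[1], lo[2], -np.inf],
                    [hi[0], hi[1], hi[2], np.inf],
                ),
            )
            a, b, g, _c = res.x
            theta = region.clip(np.array([a, b, g, n, K]))
            out.append((prob.loss(theta), theta))
    out.sort(key=lambda p: p[0])
    return [theta for _, theta in out[:3]]


def fit_edge(
    data: ExpressionDataset,
    edge: EdgeModel,
    region: ParameterRegion | None = None,
    n_starts: int = 20,
    seed: int = 0,
    informed_starts: bool = True,
) -> tuple[ParamVector, float]:
    """Minimize the loss over the region by bounded multi-start local search.

    Starts are ``n_starts`` Latin-hypercube points in the free axes (plus,
    by default, a few warm starts from a closed-form linear solve on an
    (n, K) grid); each is refined with L-BFGS-B under the box bounds.
    Returns the best minimizer, clipped to the region, and its loss.
    Deterministic given ``seed``.
    """
    region = region if region is not None else default_region(data, edge)
    prob = _EdgeProblem(data, edge)
    free = region.free_mask
    idx = np.flatnonzero(free)
    lo, hi = region.lower, region.upper

    starts: list[np.ndarray] = []
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=len(idx), seed=seed)
        unit = sampler.random(n=n_starts)
        for u in unit:
            theta = region.lower.copy()
            theta[idx] = lo[idx] + u * (hi[idx] - lo[idx])
            starts.append(theta)
    if informed_starts and free[0] and free[1] and free[2]:
        starts.extend(_informed_starts(prob, region))
    if not starts:
        raise FitError(f"no start points for edge {edge}")

    def objective(x_free: np.ndarray, base: np.ndarray) -> float:
        theta = base.copy()
        theta[idx] = x_free
        return prob.loss(theta)

    bounds = list(zip(lo[idx], hi[idx]))
    best_theta, best_loss = None, np.inf
    failures = []
    for theta0 in starts:
        try:
            res = minimize(
                objective,
                theta0[idx],
                args=(theta0,),
                method="L-BFGS-B",
                bounds=bounds,
            )
        except (ParameterDomainError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if np.isfinite(res.fun) and res.fun < best_loss:
            best_loss = float(res.fun)
            best_theta = theta0.copy()
            best_theta[idx] = res.x
    if best_theta is None:
        raise FitError(
            f"all {len(starts)} starts failed for edge {edge}: {failures[:3]}"
        )
    best_theta = region.clip(best_theta)
    # final loss at the clipped point (clipping can nudge it)
    best_loss = prob.loss(best_theta)
    return ParamVector.from_array(best_theta), float(best_loss)


# ---------------------------------------------------------------------------
# Laplace evidence
# ---------------------------------------------------------------------------


def gibbs_temperature(target_values: np.ndarray, floor: float = 1e-8) -> float:
    """Plug-in Gibbs temperature lambda = 2 * sigma^2 / T.

    Because the loss is a *mean* squared error over T points, a Gaussian
    likelihood with noise variance sigma^2 reads
    exp(-sum r^2 / (2 sigma^2)) = exp(-T l / (2 sigma^2)), i.e. a Gibbs
    temperature of 2 sigma^2 / T. sigma^2 is estimated from the mean
    squared second difference of the target trajectory divided by 6
    (unbiased for i.i.d. noise on a locally linear signal) and the result
    is floored to keep exp(-l/lambda) well defined on noiseless data.
    """
    x = np.asarray(target_values, dtype=float)
    if x.size < 3:
        return floor
    d2 = np.diff(x, n=2)
    sigma2 = float(np.mean(d2 * d2)) / 6.0
    return max(2.0 * sigma2 / x.size, floor)


def _hessian(
    f, theta: np.ndarray, idx: np.ndarray, steps: np.ndarray
) -> np.ndarray:
    """Central finite-difference Hessian of f over the axes in idx."""
    d = len(idx)
    H = np.empty((d, d))
    f0 = f(theta)

    def at(shift: dict[int, float]) -> float:
        th = theta.copy()
        for k, dv in shift.items():
            th[idx[k]] += dv
        return f(th)

    for a in range(d):
        ha = steps[a]
        H[a, a] = (at({a: ha}) - 2.0 * f0 + at({a: -ha})) / (ha * ha)
        for b in range(a + 1, d):
            hb = steps[b]
            val = (
                at({a: ha, b: hb})
                - at({a: ha, b: -hb})
                - at({a: -ha, b: hb})
                + at({a: -ha, b: -hb})
            ) / (4.0 * ha * hb)
            H[a, b] = H[b, a] = val
    return H


def log_evidence(
    data: ExpressionDataset,
    edge: EdgeModel,
    region: ParameterRegion,
    theta_star: ParamVector,
    loss_star: float,
    s: int = 1,
    lam: float = 1.0,
) -> float:
    """Laplace approximation of the log Gibbs evidence of one edge.

    log [ exp(-l*/lambda) (2 pi)^{d/2} det(H/lambda)^{-1/2} / (s Vol(R_E)) ]

    with d the number of free axes and H the central finite-difference
    Hessian of the loss at theta_star (per-axis step 1e-4 of the interval
    width; eigenvalues floored at 1e-8 of the largest to regularize flat or
    boundary optima). Larger regions and sharper optima are penalized;
    flatter optima — models more robust to parameter perturbation — gain.

    The Gaussian factor is evaluated per eigendirection and each
    direction's width sqrt(2 pi lambda / eig) is capped at the region's
    extent along that direction: the exact integral over the bounded box
    can never exceed the box width, and without the cap exactly-flat
    directions (e.g. n and K at an alpha ~ 0 degenerate optimum) would
    receive unbounded, spurious evidence.
    """
    theta = theta_star.as_array()
    if not region.contains(theta):
        raise ValueError(f"theta_star outside region for edge {edge}")
    prob = _EdgeProblem(data, edge)
    idx = np.flatnonzero(region.free_mask)
    widths = region.upper[idx] - region.lower[idx]
    steps = 1e-4 * widths
    H = _hessian(prob.loss, theta, idx, steps)
    if not np.all(np.isfinite(H)):
        raise FitError(f"non-finite Hessian for edge {edge}")
    eigvals, eigvecs = np.linalg.eigh(H)
    emax = float(eigvals.max())
    floor = 1e-8 * max(emax, 1e-300)
    eigvals = np.maximum(eigvals, floor)
    # support width of the box along each eigendirection
    box_extent = np.abs(eigvecs.T) @ widths
    gauss_width = np.sqrt(2.0 * np.pi * lam / eigvals)
    log_width = np.log(np.minimum(gauss_width, box_extent))
    return float(
        -loss_star / lam + np.sum(log_width) - np.log(s * region.volume)
    )


# ---------------------------------------------------------------------------
# Posteriors and network-level inference
# ---------------------------------------------------------------------------


@dataclass
class EdgeScore:
    """Fit and evidence of one candidate edge (theta in normalized units
    unless stated otherwise by the producing call)."""

    edge: EdgeModel
    theta_star: ParamVector
    loss_star: float
    log_evidence: float
    shift: float = 0.0


@dataclass
class NodePosterior:
    """Gibbs posterior over the candidate regulations of one target."""

    target: str
    probabilities: dict[EdgeModel, float]
    scores: list[EdgeScore] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.array(list(self.probabilities.values()))
        if p.size and (np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9):
            raise ValueError("posterior probabilities must be in [0,1] and sum to 1")

    def top_edge(self) -> EdgeModel:
        """Most probable edge; ties broken by candidate order."""
        best, best_p = None, -np.inf
        for e in self.probabilities:  # insertion order = candidate order
            if self.probabilities[e] > best_p + 1e-15:
                best, best_p = e, self.probabilities[e]
        return best

    def score_for(self, edge: EdgeModel) -> EdgeScore:
        for sc in self.scores:
            if sc.edge == edge:
                return sc
        raise KeyError(f"edge {edge} not scored for target {self.target}")


@dataclass
class InferenceSettings:
    """Knobs of the inference engine.

    n_starts      : Latin-hypercube starts per edge fit (default 20)
    seed          : base seed; per-edge seeds are derived deterministically
    lam           : Gibbs temperature, or None for the plug-in
                    2*sigma_hat^2 estimate per target (default)
    normalize     : min-max scale each gene to [0, 1] before fitting
    include_self  : allow self-regulation candidates
    informed_starts : add closed-form warm starts to the LHS starts
    region_overrides: dict axis name -> (lo, hi), applied to every edge box
    n_jobs        : worker processes for per-target parallelism (targets
                    are independent and individually seeded, so results
                    are identical regardless of scheduling)
    """

    n_starts: int = 20
    seed: int = 0
    lam: float | None = None
    normalize: bool = True
    include_self: bool = True
    informed_starts: bool = True
    region_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_jobs: int = 1


@dataclass
class _GeneScaler:
    offset: float  # trajectory minimum
    span: float  # max - min (1.0 if constant)


@dataclass
class InferenceResult:
    """Posteriors for every target plus the normalization used, so edge
    parameters can be reported in data units and the fitted system can be
    re-simulated."""

    posteriors: list[NodePosterior]
    dataset: ExpressionDataset  # clipped original-unit data
    normalized: ExpressionDataset
    scalers: dict[str, _GeneScaler]
    settings: InferenceSettings
    failures: dict[str, str] = field(default_factory=dict)

    def posterior_for(self, target: str) -> NodePosterior:
        for p in self.posteriors:
            if p.target == target:
                return p
        raise KeyError(f"no posterior for target {target!r}")

    def theta_in_data_units(self, score: EdgeScore) -> ParamVector:
        """Map a normalized-unit fit to data units.

        alpha and gamma scale with the target's span; beta and n are scale
        free; K maps back through the regulator's affine normalization.
        gamma additionally absorbs beta times the target's offset (the
        normalization shifts the basal balance).
        """
        st = self.scalers[score.edge.target]
        sr = self.scalers[score.edge.regulator]
        th = score.theta_star
        return ParamVector(
            alpha=th.alpha * st.span,
            beta=th.beta,
            gamma=max(th.gamma * st.span + th.beta * st.offset, 0.0),
            n=th.n,
            K=sr.offset + th.K * sr.span,
        )


def normalize_dataset(
    data: ExpressionDataset,
) -> tuple[ExpressionDataset, dict[str, _GeneScaler]]:
    """Min-max scale each gene to [0, 1]; constant genes map to 0 with unit
    span. Negative inputs (e.g. from noise pipelines that clamp elsewhere)
    are clipped to 0 first with a warning."""
    values = data.values
    if np.any(values < 0):
        warnings.warn("negative expression values clipped to 0", stacklevel=2)
        values = np.clip(values, 0.0, None)
    scaled = np.empty_like(values)
    scalers: dict[str, _GeneScaler] = {}
    for i, g in enumerate(data.gene_names):
        lo = float(values[i].min())
        span = float(values[i].max()) - lo
        if span <= 0:
            warnings.warn(f"gene {g!r} has a constant trajectory", stacklevel=2)
            span = 1.0
        scaled[i] = (values[i] - lo) / span
        scalers[g] = _GeneScaler(offset=lo, span=span)
    return (
        ExpressionDataset(list(data.gene_names), data.times.copy(), scaled),
        scalers,
    )


def _edge_seed(base_seed: int, target: str, k: int) -> int:
    # stable per-edge seed independent of execution order and of Python's
    # per-process string-hash randomization
    tag = zlib.crc32(f"{target}#{k}".encode()) % 65_536
    return (base_seed * 1_000_003 + tag) % (2**31 - 1)


def node_posterior(
    data: ExpressionDataset,
    target: str,
    candidates: CandidateSet,
    regions: dict[EdgeModel, ParameterRegion] | None = None,
    settings: InferenceSettings | None = None,
    lam: float | None = None,
) -> NodePosterior:
    """Gibbs posterior over one target's candidate edges.

    ``data`` must already be on the scale the regions assume (the
    high-level :func:`infer_network` handles normalization). Probabilities
    are the softmax of per-edge Laplace log-evidences; edges excluded by
    the prior are simply absent (probability 0 by construction).
    """
    settings = settings or InferenceSettings()
    if lam is None:
        lam = settings.lam
    if lam is None:
        lam = gibbs_temperature(data.gene(target))
    if float(np.ptp(data.gene(target))) == 0.0:
        warnings.warn(
            f"target {target!r} trajectory is constant; posterior will be "
            "close to uniform",
            stacklevel=2,
        )
    scores = []
    s = candidates.s
    for k, edge in enumerate(candidates.edges):
        region = (regions or {}).get(edge)
        if region is None:
            region = default_region(data, edge)
            if settings.region_overrides:
                region = region.override(**settings.region_overrides)
        theta_star, loss_star = fit_edge(
            data,
            edge,
            region,
            n_starts=settings.n_starts,
            seed=_edge_seed(settings.seed, target, k),
            informed_starts=settings.informed_starts,
        )
        _, shift = loss(data, edge, theta_star, return_shift=True)
        le = log_evidence(data, edge, region, theta_star, loss_star, s=s, lam=lam)
        scores.append(
            EdgeScore(
                edge=edge,
                theta_star=theta_star,
                loss_star=loss_star,
                log_evidence=le,
                shift=shift,
            )
        )
    le_arr = np.array([sc.log_evidence for sc in scores])
    log_norm = logsumexp(le_arr)
    probs = np.exp(le_arr - log_norm)
    probs = probs / probs.sum()
    return NodePosterior(
        target=target,
        probabilities={sc.edge: float(p) for sc, p in zip(scores, probs)},
        scores=scores,
    )


def _run_target(
    work: ExpressionDataset,
    target: str,
    genes: list[str],
    prior: PriorSpec,
    settings: InferenceSettings,
) -> "tuple[str, NodePosterior | None, str | None]":
    """One independent work unit; exceptions become (target, None, msg)."""
    try:
        candidates = enumerate_candidates(
            target, genes, prior, include_self=settings.include_self
        )
        return target, node_posterior(work, target, candidates, settings=settings), None
    except (FitError, ValueError) as exc:
        return target, None, str(exc)


def infer_network(
    data: ExpressionDataset,
    prior: PriorSpec | None = None,
    settings: InferenceSettings | None = None,
) -> InferenceResult:
    """Run local edge inference for every gene in the dataset.

    Each target is an independent work unit: its posterior depends only on
    the data, the prior, and the per-target seed, never on the other
    targets, so results are identical regardless of execution order.
    Per-target failures are collected in ``result.failures`` and do not
    abort the remaining targets.
    """
    settings = settings or InferenceSettings()
    prior = prior or PriorSpec()

    clipped = data.copy()
    if np.any(clipped.values < 0):
        warnings.warn("negative expression values clipped to 0", stacklevel=2)
        clipped.values = np.clip(clipped.values, 0.0, None)

    if settings.normalize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            work, scalers = normalize_dataset(clipped)
    else:
        work = clipped
        scalers = {g: _GeneScaler(offset=0.0, span=1.0) for g in data.gene_names}

    if settings.n_jobs != 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=settings.n_jobs)(
            delayed(_run_target)(work, target, data.gene_names, prior, settings)
            for target in data.gene_names
        )
    else:
        outcomes = [
            _run_target(work, target, data.gene_names, prior, settings)
            for target in data.gene_names
        ]
    posteriors = [p for _, p, _ in outcomes if p is not None]
    failures = {t: msg for t, p, msg in outcomes if p is None}
    for target, msg in failures.items():
        logger.error("target %s failed: %s", target, msg)
    return InferenceResult(
        posteriors=posteriors,
        dataset=clipped,
        normalized=work,
        scalers=scalers,
        settings=settings,
        failures=failures,
    )


def extract_network(
    posteriors: list[NodePosterior],
    mode: str = "argmax",
    threshold: float = 0.4,
) -> list[EdgeModel]:
    """Collapse per-node posteriors to a single signed edge list.

    ``argmax`` keeps exactly the most probable edge per node (ties broken
    by candidate order); ``threshold`` keeps every edge with posterior
    probability >= ``threshold`` (possibly none or several per node).
    """
    if mode == "argmax":
        return [p.top_edge() for p in posteriors]
    if mode == "threshold":
        out = []
        for p in posteriors:
            out.extend(e for e, pr in p.probabilities.items() if pr >= threshold)
        return out
    raise ValueError(f"unknown extraction mode {mode!r}")


def assemble_system(
    result: InferenceResult,
) -> tuple[NetworkSpec, "ExpressionDataset"]:
    """Build the full fitted ODE system and re-simulate the data.

    Takes each node's most probable edge with its fitted parameters,
    assembles the single-regulator ODE system in normalized units, and
    integrates it on the data's time grid from the data's initial values;
    trajectories are mapped back to data units. Returns (spec, dataset)
    where the spec's edge list equals the argmax network.
    """
    from .simulate import SimulationConfig, simulate as run_sim

    if result.failures:
        raise FitError(
            f"cannot assemble system; targets failed: {sorted(result.failures)}"
        )
    norm = result.normalized
    rules: dict[str, NodeRule] = {}
    for post in result.posteriors:
        edge = post.top_edge()
        th = post.score_for(edge).theta_star
        rules[post.target] = NodeRule(
            inputs=[(edge.regulator, edge.sign)],
            hill_params=[(th.n, th.K)],
            alpha=th.alpha,
            beta=th.beta,
            gamma=th.gamma,
        )
    genes = list(norm.gene_names)
    spec = NetworkSpec(
        genes,
        rules,
        initial_state={g: float(norm.gene(g)[0]) for g in genes},
    )
    t = norm.times
    config = SimulationConfig(
        t_start=float(t[0]), t_end=float(t[-1]), n_samples=t.size, times=t
    )
    sim = run_sim(spec, config)
    values = np.empty_like(sim.values)
    for i, g in enumerate(genes):
        sc = result.scalers[g]
        values[i] = sim.gene(g) * sc.span + sc.offset
    return spec, ExpressionDataset(genes, t.copy(), values)
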