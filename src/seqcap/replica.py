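"""Replica-symmetric theory of the sign-constrained (bistable) perceptron.

For uncorrelated inputs the Gardner volume of nonnegative weight vectors
satisfying the sequence constraints can be averaged over pattern realizations
with the replica method.  Because inputs are independent across patterns, the
quenched average depends on the targets only through the stationary pair
probabilities of the output Markov chain, which weight four constraint
classes (previous target, current target):

    (0,1)  switch up:   h > theta_up  + kappa     (weight p01)
    (1,1)  stay up:     h > theta_down + kappa    (weight p11)
    (1,0)  switch down: h < theta_down - kappa    (weight p10)
    (0,0)  stay down:   h < theta_up  - kappa     (weight p00)

Working in units of the input-current fluctuation scale
``sqrt(N f_in (1-f_in) <w^2>)``, each class contributes a scalar offset

    a_k = kappa + eps_k * (gamma + eta_k * delta_s / 2)

where ``eps_k = +1`` for active targets, ``eta_k = +1`` when the previous
target is 0, ``gamma`` is the (saddle-determined) gap between the midpoint
threshold and the mean drive, and ``delta_s`` the scaled bistable range.

The replica-symmetric saddle point couples three order parameters — the mean
weight ``B``, the self-overlap ``Q`` (gauged to 1) and the replica overlap
``q`` — with their conjugates.  :func:`solve_saddle` solves the six coupled
equations at fixed load ``alpha``; the maximal capacity is the load where the
solution-space volume vanishes (``q -> 1``).  In that limit the equations
close over ``gamma``, the truncation point ``s0`` of the weight distribution,
and ``alpha`` (see :func:`capacity_replica`); the weight distribution becomes
a delta mass ``Phi(s0)`` at zero plus a Gaussian branch of scale ``sigma_w``
truncated at zero:

    P(w) = Phi(s0) delta(w) + (w > 0)  N(-sigma_w s0, sigma_w^2).

At ``kappa = 0`` the saddle places ``s0 = 0``: half the synapses are silent
and the positive branch is a zero-mean truncated Gaussian, independently of
the output correlation — reproducing the classical sign-constrained results
(capacity 1 at ``f_out = 1/2``).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, special

from .markov import MarkovSpec, pair_probabilities

__all__ = [
    "ScaledParams",
    "ReplicaSolution",
    "TruncatedGaussianBranch",
    "solve_saddle",
    "capacity_replica",
    "optimal_bistable_range",
    "weight_distribution_theory",
    "delta_sim_to_scaled",
    "delta_scaled_to_sim",
    "kappa_scaled_to_margin",
]

_SQRT2 = math.sqrt(2.0)
_SQRT_2_PI = math.sqrt(2.0 / math.pi)

# 301-node Gauss-Hermite rule for integrals against the standard Gaussian
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(301)
_GH_Z = _GH_X * _SQRT2
_GH_P = _GH_W / math.sqrt(math.pi)


def _phi(x):
    return np.exp(-0.5 * np.square(x)) / math.sqrt(2.0 * math.pi)


def _H(x):
    """Gaussian tail probability P(Z > x)."""
    return special.ndtr(-np.asarray(x, dtype=float))


def _Phi(x):
    return special.ndtr(np.asarray(x, dtype=float))


def _mills_tail(x):
    """phi(x) / H(x), computed stably for any x (~x for large x, ~0 for very negative)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    safe = x > -30.0
    out[safe] = _SQRT_2_PI / special.erfcx(x[safe] / _SQRT2)
    out[~safe] = 0.0
    return out


def _mills_head(a):
    """phi(a) / Phi(a) = phi(-a) / H(-a)."""
    return _mills_tail(-np.asarray(a, dtype=float))


def _E1(s):
    """Integral of (t - s) over the Gaussian tail t > s."""
    s = np.asarray(s, dtype=float)
    return _phi(s) - s * _H(s)


def _E2(s):
    """Integral of (t - s)^2 over the Gaussian tail t > s."""
    s = np.asarray(s, dtype=float)
    return (1.0 + s * s) * _H(s) - s * _phi(s)


def _ratio_E2_H(s):
    """E2(s) / H(s), stable for large s."""
    s = float(s)
    return 1.0 + s * s - s * float(_mills_tail(s))


@dataclasses.dataclass(frozen=True)
class ScaledParams:
    """N-independent parameters of the scaled learning problem.

    ``delta_s`` and ``kappa`` are the bistable range and robustness margin in
    units of the input-current fluctuation scale ``sqrt(N f_in(1-f_in)<w^2>)``.
    ``f_in`` does not enter the scaled theory (it is absorbed by the units)
    but is carried for the bridge back to simulation parameters.  The scaled
    threshold position ``gamma`` is not a free parameter: the mean weight
    adapts, so ``gamma`` is fixed by the saddle point and reported on the
    solution.
    """

    c_out: float
    f_out: float = 0.5
    delta_s: float = 0.0
    kappa: float = 0.0
    f_in: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_out < 1.0:
            raise ValueError(f"c_out must lie in [0, 1), got {self.c_out}")
        for name in ("f_out", "f_in"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.delta_s < 0.0:
            raise ValueError(f"delta_s must be nonnegative, got {self.delta_s}")
        if self.kappa < 0.0:
            raise ValueError(f"kappa must be nonnegative, got {self.kappa}")


def _class_weights(params: ScaledParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair probabilities, constraint signs and hysteresis signs per class.

    Order: (0,0), (0,1), (1,0), (1,1).
    """
    pp = pair_probabilities(MarkovSpec(f=params.f_out, c=params.c_out))
    probs = np.array([pp.p00, pp.p01, pp.p10, pp.p11])
    eps = np.array([-1.0, 1.0, -1.0, 1.0])  # -1: output must stay below threshold
    eta = np.array([1.0, 1.0, -1.0, -1.0])  # +1: previous target 0 -> theta_up applies
    return probs, eps, eta


def _class_offsets(params: ScaledParams, gamma: float) -> np.ndarray:
    probs, eps, eta = _class_weights(params)
    return params.kappa + eps * (gamma + eta * params.delta_s / 2.0)


@dataclasses.dataclass(frozen=True)
class TruncatedGaussianBranch:
    """Positive branch of the theoretical weight distribution.

    The branch is a Gaussian of mean ``loc`` and scale ``scale`` truncated to
    ``w > 0`` carrying probability mass ``mass``; weights are expressed in
    units of the root-mean-square weight (the ``Q = 1`` gauge).
    """

    loc: float
    scale: float
    mass: float

    def pdf(self, w):
        w = np.asarray(w, dtype=float)
        return np.where(w > 0.0, _phi((w - self.loc) / self.scale) / self.scale, 0.0)

    def cdf_positive(self, w):
        """CDF of the branch conditional on w > 0."""
        w = np.asarray(w, dtype=float)
        lo = _Phi(-self.loc / self.scale)
        return np.clip((_Phi((w - self.loc) / self.scale) - lo) / self.mass, 0.0, 1.0)

    @property
    def mean_positive(self) -> float:
        s0 = -self.loc / self.scale
        return self.scale * float(_E1(s0)) / self.mass

    @property
    def std_positive(self) -> float:
        s0 = -self.loc / self.scale
        e1, e2 = float(_E1(s0)), float(_E2(s0))
        return self.scale * math.sqrt(e2 / self.mass - (e1 / self.mass) ** 2)


@dataclasses.dataclass
class ReplicaSolution:
    """Replica-symmetric saddle point (optionally in the capacity limit)."""

    alpha: float
    at_capacity: bool
    gamma: float
    q: float
    B: float
    Q: float
    B_hat: float
    Q_hat: float
    r_hat: float
    s0: float
    silent_fraction: float
    weight_scale: float
    residual: float
    params: ScaledParams


def _solve_gamma(params: ScaledParams, q: float | None = None) -> float:
    """Threshold-balance equation: potentiating and depressing pressures cancel.

    In the capacity limit (``q=None``) this reads
    ``sum_k p_k eps_k [a_k Phi(a_k) + phi(a_k)] = 0``; at finite ``q`` the
    integrand is the stabilised Mills ratio.  The left side is strictly
    increasing in gamma, so a bracketed root always exists.
    """
    probs, eps, _ = _class_weights(params)

    if q is None:
        def balance(g: float) -> float:
            a = _class_offsets(params, g)
            return float(np.sum(probs * eps * (a * _Phi(a) + _phi(a))))
    else:
        fac = 1.0 / math.sqrt(1.0 - q)

        def balance(g: float) -> float:
            a = _class_offsets(params, g)
            X = (a[:, None] + math.sqrt(q) * _GH_Z[None, :]) * fac
            return float(np.sum(probs[:, None] * eps[:, None] * _mills_tail(X) * _GH_P[None, :]))

    lo, hi = -60.0, 60.0
    return float(optimize.brentq(balance, lo, hi, xtol=1e-13))


def _capacity_system(params: ScaledParams) -> tuple[float, float, float]:
    """Solve the q->1 (vanishing-volume) limit: returns (gamma, s0, alpha_c)."""
    probs, _, _ = _class_weights(params)
    gamma = _solve_gamma(params)
    a = _class_offsets(params, gamma)
    num = float(np.sum(probs * _Phi(a)))          # fraction of marginal constraints
    den = float(np.sum(probs * _E2(-a)))          # constraint "pressure"
    target = num / den

    def g(s: float) -> float:
        return _ratio_E2_H(s) - target

    lo, hi = -40.0, 40.0
    s0 = float(optimize.brentq(g, lo, hi, xtol=1e-13))
    alpha_c = float(_H(s0)) / num
    return gamma, s0, alpha_c


def capacity_replica(params: ScaledParams) -> float:
    """Replica-symmetric maximal capacity ``alpha_c`` (associations per synapse).

    Solves the ``q -> 1`` limit of the saddle-point equations, i.e. the load
    at which the typical volume of admissible weight vectors vanishes, via
    two monotone scalar root problems (threshold balance, then truncation
    point) and an explicit expression for ``alpha_c``.
    """
    return _capacity_system(params)[2]


def capacity_solution(params: ScaledParams) -> ReplicaSolution:
    """Full capacity-limit solution including the weight distribution."""
    gamma, s0, alpha_c = _capacity_system(params)
    e2 = float(_E2(s0))
    sigma_w = 1.0 / math.sqrt(e2)        # Q = 1 gauge
    B = sigma_w * float(_E1(s0))
    return ReplicaSolution(
        alpha=alpha_c,
        at_capacity=True,
        gamma=gamma,
        q=1.0,
        B=B,
        Q=1.0,
        B_hat=math.inf,
        Q_hat=-math.inf,
        r_hat=math.inf,
        s0=s0,
        silent_fraction=float(_Phi(s0)),
        weight_scale=sigma_w,
        residual=0.0,
        params=params,
    )


def _pattern_integrals(params: ScaledParams, gamma: float, q: float) -> tuple[float, float]:
    """Class-weighted integrals of (phi/H)^2 and X*phi/H at overlap q."""
    probs, _, _ = _class_weights(params)
    a = _class_offsets(params, gamma)
    X = (a[:, None] + math.sqrt(q) * _GH_Z[None, :]) / math.sqrt(1.0 - q)
    r = _mills_tail(X)
    F2 = float(np.sum(probs[:, None] * r * r * _GH_P[None, :]))
    F3 = float(np.sum(probs[:, None] * X * r * _GH_P[None, :]))
    return F2, F3


def _site_moments(B_hat: float, r_hat: float, lam: float) -> tuple[float, float, float]:
    """Gaussian-field averages of the single-synapse truncated measure.

    The measure is ``exp(-lam w^2/2 + (sqrt(r_hat) t - B_hat) w)`` on w >= 0
    with t standard normal; returns (<<w>>, <<w^2>>, <<w>^2>).
    """
    u = math.sqrt(r_hat) * _GH_Z - B_hat
    sigma = 1.0 / math.sqrt(lam)
    m = u / lam
    aa = m / sigma
    R = _mills_head(aa)
    w1 = m + sigma * R
    w2 = m * w1 + sigma * sigma
    return (
        float(np.sum(_GH_P * w1)),
        float(np.sum(_GH_P * w2)),
        float(np.sum(_GH_P * w1 * w1)),
    )


def _solve_B_hat(r_hat: float, lam: float) -> float:
    """Find B_hat so that the self-overlap <<w^2>> equals 1 (Q = 1 gauge)."""

    def g(b: float) -> float:
        return _site_moments(b, r_hat, lam)[1] - 1.0

    lo, hi = -1.0, 1.0
    scale = math.sqrt(r_hat + lam)
    lo, hi = -4.0 * scale, 4.0 * scale
    while g(lo) < 0.0:
        lo *= 2.0
    while g(hi) > 0.0:
        hi *= 2.0
    return float(optimize.brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16))


def solve_saddle(params: ScaledParams, alpha: float, q_bracket: tuple[float, float] = (1e-6, 1.0 - 1e-7)) -> ReplicaSolution:
    """Solve the six coupled replica-symmetric equations at load ``alpha``.

    Works in the gauge ``Q = <w^2> = 1``.  The six unknowns are the threshold
    gap ``gamma``, the overlap ``q``, the mean weight ``B`` and the three
    conjugate parameters; the equations are the threshold balance, the three
    moment self-consistencies and the two conjugate definitions.  They are
    reduced to a single monotone scalar problem in ``q`` (with ``gamma`` and
    the conjugates solved exactly inside) and the fixed point is polished to
    residual norm below 1e-10.

    Raises
    ------
    RuntimeError
        If no overlap ``q < 1`` solves the equations, i.e. ``alpha`` is at or
        above the capacity ``alpha_c`` where the admissible volume vanishes.
    """
    if alpha <= 0.0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    alpha_c = capacity_replica(params)
    if alpha >= alpha_c:
        raise RuntimeError(
            f"no replica-symmetric solution with q < 1 at alpha={alpha}: the admissible "
            f"volume vanishes at alpha_c={alpha_c:.6g} (q -> 1, conjugates diverge)"
        )

    state: dict[str, float] = {}

    def overlap_residual(q: float) -> float:
        gamma = _solve_gamma(params, q)
        F2, F3 = _pattern_integrals(params, gamma, q)
        r_hat = alpha / (1.0 - q) * F2
        lam = alpha / (1.0 - q) * (F2 - F3)  # lam = 2*Q_hat + r_hat > 0
        B_hat = _solve_B_hat(r_hat, lam)
        w1, w2, w1sq = _site_moments(B_hat, r_hat, lam)
        state.update(gamma=gamma, r_hat=r_hat, lam=lam, B_hat=B_hat, B=w1, w2=w2, w1sq=w1sq)
        return q - w1sq

    qlo, qhi = q_bracket
    # quadrature degrades in the extreme q -> 1 regime; back the upper bracket
    # away from 1 until the residual is positive (the root exists: alpha < alpha_c)
    while overlap_residual(qhi) < 0.0:
        qhi = 1.0 - 10.0 * (1.0 - qhi)
        if qhi <= qlo:
            raise RuntimeError(
                f"overlap root could not be bracketed at alpha={alpha}; "
                "the load is too close to capacity for the finite-q solver"
            )
    if overlap_residual(qlo) > 0.0:
        # weight disorder so weak that the overlap root sits below the bracket
        qlo = 1e-12
    q = float(optimize.brentq(overlap_residual, qlo, qhi, xtol=1e-15, rtol=8.9e-16))
    final = overlap_residual(q)

    Q_hat = (state["lam"] - state["r_hat"]) / 2.0
    residual = abs(final) + abs(state["w2"] - 1.0)
    s0 = state["B_hat"] / math.sqrt(state["r_hat"])
    return ReplicaSolution(
        alpha=alpha,
        at_capacity=False,
        gamma=state["gamma"],
        q=q,
        B=state["B"],
        Q=state["w2"],
        B_hat=state["B_hat"],
        Q_hat=Q_hat,
        r_hat=state["r_hat"],
        s0=s0,
        silent_fraction=float(_Phi(s0)),
        weight_scale=1.0 / math.sqrt(state["lam"] * (1.0 - q)) if q < 1 else math.nan,
        residual=residual,
        params=params,
    )


def optimal_bistable_range(
    c_out: float,
    f_out: float = 0.5,
    kappa: float = 0.0,
    f_in: float = 0.5,
    delta_max: float = 20.0,
) -> tuple[float, float]:
    """Scaled bistable range maximizing the replica capacity, and its value.

    Returns ``(delta_star, alpha_at_star)``.  The boundary ``delta = 0`` is
    compared against the interior optimum, so ``delta_star`` is exactly zero
    whenever bistability does not help (e.g. ``c_out = 0``).
    """

    def neg_alpha(d: float) -> float:
        p = ScaledParams(c_out=c_out, f_out=f_out, delta_s=d, kappa=kappa, f_in=f_in)
        return -capacity_replica(p)

    res = optimize.minimize_scalar(neg_alpha, bounds=(0.0, delta_max), method="bounded",
                                   options={"xatol": 1e-10})
    alpha0 = -neg_alpha(0.0)
    if not res.success or -res.fun <= alpha0 * (1.0 + 1e-12):
        return 0.0, alpha0
    return float(res.x), float(-res.fun)


def weight_distribution_theory(solution: ReplicaSolution) -> tuple[float, TruncatedGaussianBranch]:
    """Silent-synapse mass and truncated-Gaussian branch at maximal capacity.

    The distribution is ``Phi(s0) delta(w) + (w>0) N(-sigma_w s0, sigma_w^2)``
    in RMS-weight units; at ``kappa = 0`` the saddle sets ``s0 = 0`` so half
    the synapses are silent and the branch is a zero-mean half-Gaussian.
    """
    if not solution.at_capacity:
        raise ValueError("weight distribution is defined at maximal capacity; "
                         "use capacity_solution / optimal_bistable_range first")
    s0, sigma = solution.s0, solution.weight_scale
    branch = TruncatedGaussianBranch(loc=-sigma * s0, scale=sigma, mass=float(_H(s0)))
    return solution.silent_fraction, branch


def delta_sim_to_scaled(
    delta: float,
    theta: float,
    N: int,
    f_in: float = 0.5,
    f_out: float = 0.5,
    c_out: float = 0.0,
    kappa: float = 0.0,
    iterations: int = 8,
) -> float:
    """Map a simulation bistable range ``Delta`` (current units) to ``delta_s``.

    At capacity the mean weight is pinned by the threshold, which fixes the
    RMS weight through the distribution shape; eliminating it gives

        delta_s = (Delta sqrt(N) / theta) sqrt(f_in/(1-f_in)) E1(s0)/sqrt(E2(s0))

    with ``s0`` the truncation point of the capacity solution.  ``s0`` itself
    depends weakly on ``delta_s``, so the map is iterated to a fixed point.
    """
    if delta == 0.0:
        return 0.0
    base = (delta * math.sqrt(N) / theta) * math.sqrt(f_in / (1.0 - f_in))
    s0 = 0.0
    d = base * float(_E1(s0)) / math.sqrt(float(_E2(s0)))
    for _ in range(iterations):
        p = ScaledParams(c_out=c_out, f_out=f_out, delta_s=d, kappa=kappa, f_in=f_in)
        _, s0, _ = _capacity_system(p)
        d_new = base * float(_E1(s0)) / math.sqrt(float(_E2(s0)))
        if abs(d_new - d) < 1e-12:
            d = d_new
            break
        d = d_new
    return d


def kappa_scaled_to_margin(
    kappa: float,
    theta: float,
    N: int,
    f_in: float = 0.5,
    f_out: float = 0.5,
    c_out: float = 0.0,
    delta_s: float = 0.0,
    iterations: int = 8,
) -> float:
    """Absolute robustness margin (current units) for a scaled ``kappa``.

    Like the threshold and the bistable range, the robustness margin is a
    fixed current offset; at capacity the RMS weight is pinned by the
    threshold, giving

        margin = kappa * theta / (sqrt(N f_in/(1-f_in)) * E1(s0)/sqrt(E2(s0)))

    with ``s0`` from the capacity solution (iterated to self-consistency,
    since ``s0`` depends on ``kappa``).
    """
    if kappa == 0.0:
        return 0.0
    base = theta / (math.sqrt(N) * math.sqrt(f_in / (1.0 - f_in)))
    s0 = 0.0
    for _ in range(iterations):
        p = ScaledParams(c_out=c_out, f_out=f_out, delta_s=delta_s, kappa=kappa, f_in=f_in)
        _, s0_new, _ = _capacity_system(p)
        if abs(s0_new - s0) < 1e-12:
            s0 = s0_new
            break
        s0 = s0_new
    return kappa * base * math.sqrt(float(_E2(s0))) / float(_E1(s0))


def delta_scaled_to_sim(
    delta_s: float,
    theta: float,
    N: int,
    f_in: float = 0.5,
    f_out: float = 0.5,
    c_out: float = 0.0,
    kappa: float = 0.0,
) -> float:
    """Inverse of :func:`delta_sim_to_scaled` for a given scaled range."""
    if delta_s == 0.0:
        return 0.0
    p = ScaledParams(c_out=c_out, f_out=f_out, delta_s=delta_s, kappa=kappa, f_in=f_in)
    _, s0, _ = _capacity_system(p)
    factor = math.sqrt(f_in / (1.0 - f_in)) * float(_E1(s0)) / math.sqrt(float(_E2(s0)))
    return delta_s * theta / (math.sqrt(N) * factor)
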