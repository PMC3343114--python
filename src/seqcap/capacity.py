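"""Simulation-based estimation of the maximal storage capacity alpha = P/N.

A sequence length ``P`` is *learnable* when the perceptron rule converges to
an error-free pass within its epoch budget.  Each trial brackets the largest
learnable ``P`` by adaptive expansion and bisection; the capacity estimate is
the mean of ``P_max / N`` over independently seeded trials, with the standard
deviation over trials as the error bar (matching the 10-trial protocol of the
reference figures).  The divergence of capacity with the common input/output
correlation ``c`` is summarized by fitting ``alpha(c) = A + B (1-c)^(-beta)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dynamics import NeuronConfig
from .learning import LearnerConfig, TrainResult, train
from .markov import MarkovSpec, generate_associations

__all__ = [
    "CapacityEstimate",
    "DivergenceFit",
    "EdgeState",
    "estimate_capacity",
    "capacity_edge_states",
    "capacity_surface",
    "fit_divergence",
]


@dataclasses.dataclass
class CapacityEstimate:
    """Capacity estimate over trials plus protocol metadata."""

    alpha: float
    spread: float
    n_trials: int
    N: int
    alphas: list[float]
    resolution: int
    max_epochs: int
    budget_limited_probes: int
    bracket_exhausted: bool
    edge_weights: list[np.ndarray] = dataclasses.field(default_factory=list)
    edge_patterns: list[int] = dataclasses.field(default_factory=list)


def _run_seed(master: int, *key: int) -> int:
    """Deterministic 32-bit child seed for one training/generation run."""
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0] % (2**31))


def estimate_capacity(
    input_spec: MarkovSpec,
    output_spec: MarkovSpec,
    neuron: NeuronConfig,
    learner: LearnerConfig,
    N: int | None = None,
    n_trials: int = 10,
    alpha_hint: float = 1.0,
    alpha_max: float = 8.0,
    resolution: int | None = None,
    keep_weights: bool = False,
    first_pattern_rule: str = "midpoint",
) -> CapacityEstimate:
    """Estimate the maximal learnable sequence length per synapse.

    Per trial: expand a bracket [largest learnable P, smallest unlearnable P]
    starting from ``alpha_hint * N``, then bisect to ``resolution`` patterns
    (default ``max(1, N // 100)``).  Trials, sequences and presentations are
    all seeded deterministically from ``learner.seed``.  With
    ``keep_weights=True`` the weight vector of the last error-free pass at
    the capacity edge is retained for each trial.
    """
    if N is None:
        N = neuron.N
    if N != neuron.N:
        raise ValueError(f"N={N} does not match neuron.N={neuron.N}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    res = resolution if resolution is not None else max(1, N // 100)
    p_cap = int(round(alpha_max * N))

    alphas: list[float] = []
    edge_weights: list[np.ndarray] = []
    edge_patterns: list[int] = []
    budget_limited = 0
    exhausted = False

    for trial in range(n_trials):
        results: dict[int, TrainResult] = {}

        def learnable(P: int) -> bool:
            nonlocal budget_limited
            seq = generate_associations(
                input_spec, output_spec, N, P, seed=_run_seed(learner.seed, 3, trial, P)
            )
            lc = dataclasses.replace(learner, seed=_run_seed(learner.seed, 4, trial, P))
            result = train(seq, neuron, lc, first_pattern_rule=first_pattern_rule)
            results[P] = result
            if not result.converged:
                budget_limited += 1
            return result.converged

        p = max(2, int(round(alpha_hint * N)))
        if learnable(p):
            lo = p
            hi = None
            while hi is None:
                p = min(int(p * 1.4) + 1, p_cap)
                if learnable(p):
                    lo = p
                    if p >= p_cap:
                        exhausted = True
                        hi = p + 1  # report the cap; flagged above
                else:
                    hi = p
        else:
            hi = p
            lo = None
            while lo is None:
                p = max(int(p / 1.4), 1)
                if learnable(p):
                    lo = p
                elif p <= 1:
                    lo = 0
                else:
                    hi = p

        while hi - lo > res and lo > 0:
            mid = (lo + hi) // 2
            if learnable(mid):
                lo = mid
            else:
                hi = mid

        alphas.append(lo / N)
        if keep_weights and lo > 0:
            edge_weights.append(results[lo].weights)
            edge_patterns.append(lo)

    arr = np.asarray(alphas)
    return CapacityEstimate(
        alpha=float(arr.mean()),
        spread=float(arr.std(ddof=1)) if n_trials > 1 else 0.0,
        n_trials=n_trials,
        N=N,
        alphas=alphas,
        resolution=res,
        max_epochs=learner.max_epochs,
        budget_limited_probes=budget_limited,
        bracket_exhausted=exhausted,
        edge_weights=edge_weights,
        edge_patterns=edge_patterns,
    )


@dataclasses.dataclass
class EdgeState:
    """Weights of a first error-free pass at an instance's exact capacity edge."""

    alpha: float
    P: int
    weights: np.ndarray
    converged_at_edge: bool
    eta: float


def capacity_edge_states(
    input_spec: MarkovSpec,
    output_spec: MarkovSpec,
    neuron: NeuronConfig,
    learner: LearnerConfig,
    n_seeds: int = 10,
    alpha_hint: float = 1.0,
    alpha_max: float = 4.0,
    max_step_downs: int = 6,
) -> list[EdgeState]:
    """Train at each instance's exact feasibility edge and return the weights.

    The theoretical weight distribution describes the capacity limit, where
    the set of admissible weight vectors shrinks to a point.  A training run
    at a load below an instance's critical load stops at an interior point of
    a still-large solution set and underestimates the silent fraction, so
    here the critical sequence length of each sampled instance is located
    *exactly* (resolution one pattern) with the linear-programming
    feasibility oracle, and the perceptron is then trained at that edge; the
    weights of the first error-free pass are returned.  If the learner's
    epoch budget is exhausted at the edge, the load is stepped down one
    pattern at a time until a run converges, staying as close to the edge
    as the budget allows.

    Requires ``kappa = 0`` (oracle scope).
    """
    from .oracle import feasible

    N = neuron.N
    states: list[EdgeState] = []
    eta = learner.eta if learner.eta is not None else 0.01 * neuron.theta / (N * input_spec.f)

    for s in range(n_seeds):
        p_cap = int(round(alpha_max * N))
        seq_full = generate_associations(
            input_spec, output_spec, N, p_cap, seed=_run_seed(learner.seed, 6, s)
        )

        def ok(P: int) -> bool:
            return feasible(seq_full.prefix(P), neuron)[0]

        p = max(2, int(round(alpha_hint * N)))
        if ok(p):
            lo = p
            hi = None
            while hi is None:
                p = min(int(p * 1.3) + 1, p_cap)
                if ok(p):
                    lo = p
                    if p >= p_cap:
                        hi = p + 1
                else:
                    hi = p
        else:
            hi = p
            lo = None
            while lo is None:
                p = max(int(p / 1.3), 1)
                if ok(p):
                    lo = p
                elif p <= 1:
                    lo = 1
                else:
                    hi = p
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if ok(mid):
                lo = mid
            else:
                hi = mid

        edge = lo
        P = edge
        lc = dataclasses.replace(learner, eta=eta, seed=_run_seed(learner.seed, 7, s))
        for attempt in range(max_step_downs + 1):
            result = train(seq_full.prefix(P), neuron, lc)
            if result.converged:
                states.append(
                    EdgeState(alpha=P / N, P=P, weights=result.weights,
                              converged_at_edge=(P == edge), eta=eta)
                )
                break
            P = max(1, P - 1)
    return states


_SURFACE_KEYS = ("c_in", "c_out", "f_in", "f_out", "kappa", "delta")


def capacity_surface(
    grid: Iterable[Mapping[str, float]],
    N: int,
    theta: float = 1.0,
    n_trials: int = 10,
    seed: int = 0,
    rule: str = "standard",
    max_epochs: int = 500,
    alpha_hint: float = 1.0,
    cache_path: str | Path | None = None,
    sign_constrained: bool = True,
) -> pd.DataFrame:
    """Capacity estimates over a parameter grid, one row per grid point.

    Grid points are mappings with any of the keys ``c_in, c_out, f_in, f_out,
    kappa, delta`` (missing keys default to the uncorrelated unbiased case);
    ``kappa`` and ``delta`` are in the replica theory's scaled units and are
    converted to current units with the scaled-unit bridges.
    When ``cache_path`` is given, completed points are appended to the CSV as
    they finish and are skipped on re-run, making sweeps resumable.  A failed
    point is recorded with ``alpha_mean = NaN`` and its error message; the
    rest of the surface still completes.
    """
    cache = Path(cache_path) if cache_path is not None else None
    done: set[tuple] = set()
    rows: list[dict] = []
    if cache is not None and cache.exists():
        prev = pd.read_csv(cache)
        rows = prev.to_dict("records")
        done = {tuple(round(float(r[k]), 12) for k in _SURFACE_KEYS) for r in rows}

    for point in grid:
        params = {"c_in": 0.0, "c_out": 0.0, "f_in": 0.5, "f_out": 0.5, "kappa": 0.0, "delta": 0.0}
        unknown = set(point) - set(params)
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        params.update(point)
        key = tuple(round(float(params[k]), 12) for k in _SURFACE_KEYS)
        if key in done:
            continue
        row = dict(params, N=N, n_trials=n_trials, seed=seed, rule=rule)
        try:
            from .replica import delta_scaled_to_sim, kappa_scaled_to_margin

            bridge_kw = dict(
                theta=theta, N=N, f_in=params["f_in"], f_out=params["f_out"],
                c_out=params["c_out"],
            )
            neuron = NeuronConfig(
                N=N, theta=theta,
                delta=delta_scaled_to_sim(params["delta"], kappa=params["kappa"], **bridge_kw),
                kappa=kappa_scaled_to_margin(params["kappa"], delta_s=params["delta"], **bridge_kw),
            )
            learner = LearnerConfig(
                rule=rule, max_epochs=max_epochs, seed=_run_seed(seed, 5, *map(hash, (key,))),
                sign_constrained=sign_constrained,
            )
            est = estimate_capacity(
                MarkovSpec(f=params["f_in"], c=params["c_in"]),
                MarkovSpec(f=params["f_out"], c=params["c_out"]),
                neuron,
                learner,
                n_trials=n_trials,
                alpha_hint=alpha_hint,
            )
            row.update(
                alpha_mean=est.alpha,
                alpha_sd=est.spread,
                budget_limited_probes=est.budget_limited_probes,
                error="",
            )
        except Exception as exc:  # pragma: no cover - defensive surface completion
            row.update(alpha_mean=np.nan, alpha_sd=np.nan, budget_limited_probes=-1, error=str(exc))
        rows.append(row)
        done.add(key)
        if cache is not None:
            pd.DataFrame(rows).to_csv(cache, index=False)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class DivergenceFit:
    """Fit of the capacity-vs-correlation law ``alpha = A + B (1-c)^(-beta)``."""

    offset: float
    amplitude: float
    exponent: float
    residuals: np.ndarray
    rms_residual: float
    diverges: bool
    success: bool
    message: str = ""

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.offset + self.amplitude * np.power(1.0 - c, -self.exponent)


def fit_divergence(c: Sequence[float], alpha: Sequence[float]) -> DivergenceFit:
    """Least-squares fit of ``alpha(c) = A + B (1-c)^(-beta)``.

    The curve diverges as ``c -> 1`` when both ``B`` and ``beta`` are
    positive; a flat curve is reported with ``diverges=False`` rather than an
    arbitrary parameter combination.
    """
    c = np.asarray(c, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 points to fit the divergence law")
    if np.any(c >= 1.0):
        raise ValueError("fit requires c < 1")
    if float(alpha.std()) < 1e-12:
        return DivergenceFit(
            offset=float(alpha.mean()), amplitude=0.0, exponent=0.0,
            residuals=alpha - alpha.mean(), rms_residual=0.0,
            diverges=False, success=True, message="constant curve: no divergence",
        )

    def law(cc, A, B, beta):
        return A + B * np.power(1.0 - cc, -beta)

    try:
        popt, _ = curve_fit(
            law, c, alpha, p0=(0.0, max(alpha[0], 1e-3), 0.5),
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, 20.0]), maxfev=20000,
        )
    except RuntimeError as exc:
        return DivergenceFit(
            offset=np.nan, amplitude=np.nan, exponent=np.nan,
            residuals=np.full_like(alpha, np.nan), rms_residual=np.nan,
            diverges=False, success=False, message=f"fit failed: {exc}",
        )
    A, B, beta = map(float, popt)
    resid = alpha - law(c, *popt)
    return DivergenceFit(
        offset=A, amplitude=B, exponent=beta, residuals=resid,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        diverges=(B > 1e-8 and beta > 1e-8), success=True,
    )
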