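"""Error-driven perceptron learning with a hard weight floor at zero.

The weight update on an error is the standard perceptron rule

    w_i <- max(0, w_i + eta (y_target - y) x_i)

so potentiation occurs when the teacher fires without the unit (LTP) and
depression when the unit fires without the teacher (LTD); weights can never
become negative.  Three rule variants are provided:

``standard``
    Plain threshold unit, every pattern compared against ``theta``.
``bistable_switching``
    Bistable unit whose state is reset to the target after every pattern (the
    error signal switches the state as well as the weights), so the effective
    threshold of pattern ``mu`` is determined by the *target* at ``mu - 1``.
``bistable_nss``
    "No state switching" control: the unit's own previous output sets the
    threshold and errors are never corrected; the sequence is swept in order.

Training stops at the first epoch whose exact constraint check finds no
violation, or at ``max_epochs``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._kernels import sweep_chunk
from .dynamics import NeuronConfig, effective_thresholds
from .markov import AssociationSequence

__all__ = ["LearnerConfig", "TrainResult", "apply_update", "train", "safe_learning_rate", "updates_bound"]

RULES = ("standard", "bistable_switching", "bistable_nss")


@dataclasses.dataclass(frozen=True)
class LearnerConfig:
    """Learning-rule configuration.

    ``eta=None`` selects the conservative default ``0.1 * theta / (N f_in)``,
    an order-1/N rate compatible with the convergence-proof scaling.
    ``presentation`` is ignored by ``bistable_nss``, which must sweep the
    sequence in order.  ``sign_constrained=False`` removes the weight floor
    (classical perceptron reference without the excitatory constraint).
    """

    eta: float | None = None
    rule: str = "standard"
    max_epochs: int = 500
    seed: int = 0
    presentation: str = "random"
    sign_constrained: bool = True

    def __post_init__(self) -> None:
        if self.eta is not None and self.eta <= 0.0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.presentation not in ("sequential", "random"):
            raise ValueError(f"presentation must be 'sequential' or 'random', got {self.presentation!r}")


@dataclasses.dataclass
class TrainResult:
    """Outcome of a training run.

    ``updates`` counts error-driven weight changes (the step counter of the
    convergence proof), not pattern presentations.  ``errors_per_epoch`` holds
    the number of violated constraints at each end-of-epoch exact check.
    """

    weights: np.ndarray
    converged: bool
    updates: int
    epochs: int
    final_errors: int
    errors_per_epoch: list[int] = dataclasses.field(default_factory=list)


def apply_update(
    w: np.ndarray, x: np.ndarray, y: int, y_t: int, eta: float, sign_constrained: bool = True
) -> np.ndarray:
    """One perceptron step ``w_i <- max(0, w_i + eta (y_t - y) x_i)``."""
    w = np.asarray(w, dtype=float).copy()
    err = int(y_t) - int(y)
    if err != 0:
        w += eta * err * np.asarray(x, dtype=float)
        if sign_constrained:
            np.maximum(w, 0.0, out=w)
    return w


def _default_eta(neuron: NeuronConfig, f_in: float) -> float:
    """Default rate 0.01 theta / (N f_in): one update then moves the drive by
    about 1% of the threshold, well below the margin scale near capacity."""
    return 0.01 * neuron.theta / (neuron.N * f_in)


def train(
    seq: AssociationSequence,
    neuron: NeuronConfig,
    learner: LearnerConfig,
    first_pattern_rule: str = "midpoint",
    w_init: np.ndarray | None = None,
) -> TrainResult:
    """Train a unit on an association sequence from zero initial weights.

    One epoch is ``P`` presentations (drawn uniformly with replacement under
    random presentation, or one ordered sweep); after each epoch all ``P``
    constraints are checked exactly and training stops at the first clean
    pass.  Non-convergence within ``max_epochs`` is a reported outcome, not
    an error.  ``w_init`` warm-starts from a previous result instead of the
    zero vector (used by incremental-loading protocols).
    """
    P, N = seq.n_patterns, seq.n_inputs
    if neuron.N != N:
        raise ValueError(f"neuron expects {neuron.N} inputs, sequence has {N}")
    Xf = np.asarray(seq.inputs, dtype=np.float64)
    targets = np.asarray(seq.targets, dtype=np.int64)
    f_in = seq.input_spec.f
    eta = learner.eta if learner.eta is not None else _default_eta(neuron, f_in)
    kappa = neuron.kappa
    clip = learner.sign_constrained

    if learner.rule == "bistable_nss":
        return _train_nss(Xf, targets, neuron, eta, learner.max_epochs, clip, w_init)

    if learner.rule == "standard":
        theta_eff = np.full(P, neuron.theta)
        constrained = np.ones(P, dtype=bool)
    else:  # bistable_switching: teacher-forced previous state fixes thresholds
        theta_eff, constrained = effective_thresholds(targets, neuron, first_pattern_rule)

    sign = np.where(targets == 1, 1.0, -1.0).astype(np.float64)
    rng = np.random.default_rng(np.random.SeedSequence(learner.seed, spawn_key=(2,)))
    w = np.zeros(N) if w_init is None else np.array(w_init, dtype=np.float64)
    updates = 0
    errors_per_epoch: list[int] = []
    theta_eff = np.ascontiguousarray(theta_eff, dtype=np.float64)
    constrained_arr = np.ascontiguousarray(constrained, dtype=np.bool_)

    chunk = 256
    epochs_done = 0
    while epochs_done < learner.max_epochs:
        n_ep = min(chunk, learner.max_epochs - epochs_done)
        if learner.presentation == "random":
            orders = rng.integers(0, P, size=(n_ep, P), dtype=np.int64)
        else:
            orders = np.tile(np.arange(P, dtype=np.int64), (n_ep, 1))
        conv_at, upd, errs = sweep_chunk(
            Xf, sign, theta_eff, constrained_arr, w, orders, float(eta), float(kappa), clip
        )
        updates += int(upd)
        errors_per_epoch.extend(int(e) for e in errs)
        if conv_at >= 0:
            return TrainResult(w, True, updates, epochs_done + conv_at + 1, 0, errors_per_epoch)
        epochs_done += n_ep
    return TrainResult(w, False, updates, learner.max_epochs, errors_per_epoch[-1], errors_per_epoch)


def _train_nss(
    Xf: np.ndarray, targets: np.ndarray, neuron: NeuronConfig, eta: float, max_epochs: int,
    clip: bool, w_init: np.ndarray | None = None,
) -> TrainResult:
    """Sequential training where the unit's own (uncorrected) state persists.

    Pattern 1 is evaluated against the midpoint threshold; afterwards the
    unit's actual previous output selects ``theta_up`` or ``theta_down``.
    Convergence means a full ordered replay with no output error.
    """
    P, N = Xf.shape
    w = np.zeros(N) if w_init is None else np.array(w_init, dtype=np.float64)
    updates = 0
    errors_per_epoch: list[int] = []
    for epoch in range(1, max_epochs + 1):
        n_err = 0
        state = 0
        for mu in range(P):
            if mu == 0:
                thr = neuron.theta
            else:
                thr = neuron.theta_down if state else neuron.theta_up
            h = float(w @ Xf[mu])
            out = int(h > thr)
            if out != targets[mu]:
                w += (eta * (float(targets[mu]) - out)) * Xf[mu]
                if clip:
                    np.maximum(w, 0.0, out=w)
                updates += 1
                n_err += 1
            state = out  # the error signal does not switch the state
        errors_per_epoch.append(n_err)
        if n_err == 0:
            return TrainResult(w, True, updates, epoch, 0, errors_per_epoch)
    return TrainResult(w, False, updates, max_epochs, n_err, errors_per_epoch)


def safe_learning_rate(
    neuron: NeuronConfig, feasibility_margin: float, max_active_fraction: float, safety: float = 0.5
) -> float:
    """Learning rate certified to converge on feasible sequences.

    If some nonnegative ``w*`` satisfies every constraint with margin at least
    ``feasibility_margin`` (in current units) and at most ``max_active_fraction``
    of the inputs are active in any pattern, the perceptron rule converges in
    finitely many updates whenever

        eta < 2 (m - Delta) / (F N)   and   eta < 2 theta_down / (F N).

    The returned rate is ``safety`` times the binding bound; it scales as
    ``1/N`` at fixed threshold and margin.
    """
    if feasibility_margin <= 0.0 or not 0.0 < max_active_fraction <= 1.0:
        raise ValueError("feasibility_margin and max_active_fraction must be positive")
    if feasibility_margin <= neuron.delta:
        raise ValueError(
            "convergence bound requires the feasible margin to exceed the bistable range "
            f"(margin {feasibility_margin} <= delta {neuron.delta})"
        )
    fn = max_active_fraction * neuron.N
    bound = 2.0 * min(feasibility_margin - neuron.delta, neuron.theta_down) / fn
    return safety * bound


def updates_bound(
    neuron: NeuronConfig,
    w_star: np.ndarray,
    feasibility_margin: float,
    eta: float,
    max_active_fraction: float,
) -> float:
    """Upper bound on error-driven updates for a rate from the safe regime.

    With ``rho = (theta_up + eta F N / 2) / (theta_down - eta F N / 2)`` and
    ``g = theta_down + m - rho (theta_up - m)`` the update count satisfies

        t <= (1 + rho) |w*|^2 (2 theta_up + eta F N (1 + rho)) / (eta g^2).
    """
    fn = max_active_fraction * neuron.N
    denom = neuron.theta_down - eta * fn / 2.0
    if denom <= 0.0:
        raise ValueError("eta too large: theta_down - eta F N / 2 must stay positive")
    rho = (neuron.theta_up + eta * fn / 2.0) / denom
    g = neuron.theta_down + feasibility_margin - rho * (neuron.theta_up - feasibility_margin)
    if g <= 0.0:
        raise ValueError("eta outside the certified regime (g <= 0); lower eta")
    norm_sq = float(np.asarray(w_star, dtype=float) @ np.asarray(w_star, dtype=float))
    n_plus = norm_sq * (2.0 * neuron.theta_up + eta * fn * (1.0 + rho)) / (eta * g * g)
    return (1.0 + rho) * n_plus
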