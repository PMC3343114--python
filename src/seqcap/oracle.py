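"""Exact feasibility oracle for the learning constraint system.

Decides by linear programming whether any nonnegative weight vector strictly
satisfies all pattern constraints (``kappa = 0``), independently of the
learning dynamics.  The open constraint set is handled by maximizing the
minimum slack under a total-weight cap; the system is declared feasible iff
the optimum exceeds a small tolerance relative to the threshold.  Intended
for small instances (up to roughly 10^3 constraints) as ground truth for the
learner and as an alternative capacity probe.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .dynamics import NeuronConfig, effective_thresholds
from .markov import AssociationSequence

__all__ = ["feasible"]


def feasible(
    seq: AssociationSequence,
    neuron: NeuronConfig,
    sign_constrained: bool = True,
    first_pattern_rule: str = "midpoint",
    tol: float = 1e-9,
) -> tuple[bool, np.ndarray | None]:
    """Return ``(is_feasible, witness)`` for the constraint system of ``seq``.

    Maximizes the minimal slack ``s`` over weights with ``w >= 0`` (when sign
    constrained) under a generous total-weight cap; the cap only pins the
    scale, which is immaterial because feasibility is invariant under joint
    scaling of ``(w, theta, delta)``.  Feasible iff ``s* > tol * theta``;
    the witness maximizes the margin under the cap.

    A fixed robustness margin ``neuron.kappa`` keeps the system linear (it
    simply shifts every constraint) and is supported; feasibility then means
    a weight vector clearing every threshold by at least ``kappa``.
    """
    P, N = seq.n_patterns, seq.n_inputs
    if neuron.N != N:
        raise ValueError(f"neuron expects {neuron.N} inputs, sequence has {N}")

    X = np.asarray(seq.inputs, dtype=float)
    theta_eff, constrained = effective_thresholds(seq.targets, neuron, first_pattern_rule)
    sign = np.where(np.asarray(seq.targets) == 1, 1.0, -1.0)

    # constraint rows: -sign*(X w - theta_eff) + kappa + s <= 0
    rows = np.flatnonzero(constrained)
    A_ub = np.empty((rows.size, N + 1))
    A_ub[:, :N] = -sign[rows, None] * X[rows]
    A_ub[:, N] = 1.0
    b_ub = -sign[rows] * theta_eff[rows] - neuron.kappa

    # Total-weight cap: solutions need sum w ~ theta/f_in, so 50x that leaves
    # ample room; scale invariance makes the exact value immaterial.
    cap = 50.0 * neuron.theta / seq.input_spec.f
    if sign_constrained:
        # total-weight cap sum w <= cap
        A_ub = np.vstack([A_ub, np.append(np.ones(N), 0.0)])
        b_ub = np.append(b_ub, cap)
        bounds = [(0.0, None)] * N + [(None, None)]
    else:
        bounds = [(-cap, cap)] * N + [(None, None)]

    c = np.zeros(N + 1)
    c[N] = -1.0  # maximize s
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        # an unbounded objective can only mean arbitrarily large slack
        if res.status == 3:
            return True, None
        raise RuntimeError(f"LP solver failed: {res.message}")
    s_opt = -res.fun
    if s_opt > tol * neuron.theta:
        return True, res.x[:N].copy()
    return False, None
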