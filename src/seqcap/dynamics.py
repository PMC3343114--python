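"""Forward dynamics of standard and bistable threshold units.

A standard unit fires when its synaptic drive strictly exceeds the threshold
``theta``.  A bistable unit has two thresholds ``theta_up = theta + delta/2``
and ``theta_down = theta - delta/2``: from the inactive state the drive must
exceed ``theta_up`` to switch on, while an active unit stays on until the
drive falls to ``theta_down`` or below.  Drives inside the hysteresis band
leave the state unchanged.  With ``delta = 0`` the bistable unit reduces
identically to the standard one.

The robustness margin ``kappa`` is a *fixed* current offset by which the
drive must clear the threshold for a classification to count, like the
threshold itself (at large N it scales as ``sqrt(N)`` while the threshold
scales as ``N``).  The replica module expresses the same margin in units of
the input-current fluctuation scale ``sqrt(N f_in (1-f_in) <w^2>)`` and
provides the bridge between the two (:func:`seqcap.replica.kappa_scaled_to_margin`).
A margin proportional to each weight vector's own norm would be a different
model: an exact identity of the saddle-point equations shows it leaves the
silent-synapse fraction at 1/2 for every kappa, whereas a fixed margin
drives it above 1/2 — the behaviour the robustness analysis describes.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .markov import AssociationSequence

__all__ = [
    "NeuronConfig",
    "drive",
    "output_standard",
    "output_bistable",
    "margin_scale",
    "effective_thresholds",
    "constraint_margins",
    "margins_table",
]


@dataclasses.dataclass(frozen=True)
class NeuronConfig:
    """Threshold unit parameters.

    Parameters
    ----------
    N
        Number of input synapses.
    theta
        Firing threshold, strictly positive.
    delta
        Bistable range ``theta_up - theta_down >= 0``; ``theta_down`` must
        remain positive.
    kappa
        Robustness margin as a fixed current offset (see module docstring);
        convert from scaled units with :func:`seqcap.replica.kappa_scaled_to_margin`.
    """

    N: int
    theta: float
    delta: float = 0.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.theta <= 0.0:
            raise ValueError(f"theta must be strictly positive, got {self.theta}")
        if self.delta < 0.0:
            raise ValueError(f"delta must be nonnegative, got {self.delta}")
        if self.kappa < 0.0:
            raise ValueError(f"kappa must be nonnegative, got {self.kappa}")
        if self.theta - self.delta / 2.0 <= 0.0:
            raise ValueError("theta_down = theta - delta/2 must remain positive")

    @property
    def theta_up(self) -> float:
        return self.theta + self.delta / 2.0

    @property
    def theta_down(self) -> float:
        return self.theta - self.delta / 2.0


def drive(w: np.ndarray, x: np.ndarray) -> float:
    """Synaptic drive ``sum_i w_i x_i`` of input pattern ``x``."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x)
    if w.shape != x.shape:
        raise ValueError(f"dimension mismatch: weights {w.shape} vs input {x.shape}")
    return float(w @ x)


def output_standard(h: float, config: NeuronConfig) -> int:
    """Heaviside output: 1 iff the drive strictly exceeds ``theta``."""
    return int(h > config.theta)


def output_bistable(h: float, previous_output: int, config: NeuronConfig) -> int:
    """Hysteretic output given the unit's previous state.

    From state 0 the unit fires iff ``h > theta_up``; from state 1 it keeps
    firing iff ``h > theta_down``.  Firing always requires the drive to be
    strictly above the applicable threshold, so ``delta = 0`` reduces exactly
    to :func:`output_standard`.
    """
    if previous_output:
        return int(h > config.theta_down)
    return int(h > config.theta_up)


def margin_scale(w: np.ndarray, f_in: float) -> float:
    """Current-fluctuation scale ``sqrt(f_in (1 - f_in)) * ||w||_2`` of ``w``.

    The standard deviation of the drive over random patterns with coding
    level ``f_in``; useful to express a trained network's margins in the
    replica theory's scaled units.
    """
    w = np.asarray(w, dtype=float)
    return float(np.sqrt(f_in * (1.0 - f_in)) * np.linalg.norm(w))


def effective_thresholds(
    targets: np.ndarray, config: NeuronConfig, first_pattern_rule: str = "midpoint"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern effective threshold and a mask of constrained patterns.

    For pattern ``mu >= 2`` the effective threshold is ``theta_up`` when the
    previous target is 0 and ``theta_down`` when it is 1 (an active unit only
    has to stay above the lower threshold).  The first pattern has no
    predecessor: under the default ``"midpoint"`` rule it is constrained
    against ``theta`` itself; under ``"unconstrained"`` it is skipped.
    """
    targets = np.asarray(targets)
    P = targets.shape[0]
    theta_eff = np.empty(P, dtype=float)
    constrained = np.ones(P, dtype=bool)
    theta_eff[1:] = np.where(targets[:-1] == 0, config.theta_up, config.theta_down)
    if first_pattern_rule == "midpoint":
        theta_eff[0] = config.theta
    elif first_pattern_rule == "unconstrained":
        theta_eff[0] = config.theta
        constrained[0] = False
    else:
        raise ValueError(f"unknown first_pattern_rule {first_pattern_rule!r}")
    return theta_eff, constrained


def constraint_margins(
    w: np.ndarray,
    seq: "AssociationSequence",
    config: NeuronConfig,
    first_pattern_rule: str = "midpoint",
) -> np.ndarray:
    """Signed slack of every learning constraint under weights ``w``.

    For target 1 the slack is ``h - theta_eff - kappa`` and for target 0 it
    is ``theta_eff - h - kappa``.  The sequence is learned iff all slacks of
    constrained patterns are positive (``kappa = 0``) or nonnegative
    (``kappa > 0``).  Unconstrained first patterns get slack ``+inf``.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (seq.n_inputs,):
        raise ValueError(f"weights have shape {w.shape}, expected ({seq.n_inputs},)")
    h = seq.inputs @ w
    theta_eff, constrained = effective_thresholds(seq.targets, config, first_pattern_rule)
    sign = np.where(seq.targets == 1, 1.0, -1.0)
    slack = sign * (h - theta_eff) - config.kappa
    slack[~constrained] = np.inf
    return slack


def margins_table(
    w: np.ndarray,
    seq: "AssociationSequence",
    config: NeuronConfig,
    first_pattern_rule: str = "midpoint",
):
    """Margins as a DataFrame (pattern index, target, previous target, slack)."""
    import pandas as pd

    slack = constraint_margins(w, seq, config, first_pattern_rule)
    prev = np.empty(seq.n_patterns, dtype=float)
    prev[0] = np.nan
    prev[1:] = seq.targets[:-1]
    return pd.DataFrame(
        {
            "pattern": np.arange(seq.n_patterns),
            "target": seq.targets.astype(int),
            "previous_target": prev,
            "slack": slack,
        }
    )
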