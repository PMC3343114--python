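"""Correlated binary association sequences generated by two-state Markov chains.

Each input cell's activity across the sequence is an independent realization
of a stationary two-state Markov chain with coding level ``f`` (stationary
probability of being active) and lag-1 Pearson correlation ``c`` between
successive states.  The target output sequence is one further independent
realization with its own ``(f, c)``.  The chain is parametrized by

    P(active | previously active)   = f + c (1 - f)
    P(active | previously inactive) = f (1 - c)

which is the unique two-state chain with stationary mean ``f`` and lag-1
correlation ``c``.  The first state of every stream is drawn from the
stationary distribution, so no burn-in is needed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "MarkovSpec",
    "PairProbabilities",
    "AssociationSequence",
    "EmpiricalStats",
    "transition_probabilities",
    "pair_probabilities",
    "generate_associations",
    "empirical_stats",
    "save_sequence",
    "load_sequence",
]


@dataclasses.dataclass(frozen=True)
class MarkovSpec:
    """Coding level and lag-1 correlation of one binary Markov stream.

    Parameters
    ----------
    f
        Stationary probability that a unit is active, ``0 < f < 1``.
    c
        Lag-1 Pearson correlation between successive states, ``0 <= c <= 1``.
    """

    f: float
    c: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"coding level f must lie in (0, 1), got {self.f}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"lag-1 correlation c must lie in [0, 1], got {self.c}")


class PairProbabilities(NamedTuple):
    """Stationary joint probabilities of (previous state, current state)."""

    p00: float
    p01: float
    p10: float
    p11: float


@dataclasses.dataclass(frozen=True)
class AssociationSequence:
    """A P x N binary input matrix with its length-P binary target sequence."""

    inputs: np.ndarray
    targets: np.ndarray
    input_spec: MarkovSpec
    output_spec: MarkovSpec
    seed: int

    @property
    def n_patterns(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[1]

    def prefix(self, P: int) -> "AssociationSequence":
        """First ``P`` patterns.  Because every cell is a single Markov stream,
        this equals the sequence that would have been generated with length P."""
        if not 1 <= P <= self.n_patterns:
            raise ValueError(f"P must lie in [1, {self.n_patterns}], got {P}")
        return AssociationSequence(
            inputs=self.inputs[:P], targets=self.targets[:P],
            input_spec=self.input_spec, output_spec=self.output_spec, seed=self.seed,
        )


class EmpiricalStats(NamedTuple):
    """Sample mean and lag-1 correlation of a binary stream.

    ``correlation_defined`` is False (and ``lag1_corr`` NaN) for constant
    streams, where the Pearson correlation is undefined.
    """

    mean: float
    lag1_corr: float
    correlation_defined: bool


def transition_probabilities(spec: MarkovSpec) -> tuple[float, float]:
    """Return ``(P(active | previously active), P(active | previously inactive))``.

    The returned pair ``(f + c(1-f), f(1-c))`` defines the unique two-state
    chain whose stationary activity probability is ``f`` and whose lag-1
    Pearson correlation is ``c``.
    """
    f, c = spec.f, spec.c
    return f + c * (1.0 - f), f * (1.0 - c)


def pair_probabilities(spec: MarkovSpec) -> PairProbabilities:
    """Stationary joint distribution of a successive pair of states.

    Marginals satisfy ``p11 + p10 = p11 + p01 = f``; the off-diagonal terms
    are equal because a stationary two-state chain is reversible.
    """
    f, c = spec.f, spec.c
    p11 = f * (f + c * (1.0 - f))
    p10 = f * (1.0 - f) * (1.0 - c)
    p01 = p10
    p00 = (1.0 - f) * ((1.0 - f) + c * f)
    return PairProbabilities(p00=p00, p01=p01, p10=p10, p11=p11)


def _stream(spec: MarkovSpec, length: int, rng: np.random.Generator) -> np.ndarray:
    """One stationary realization of the chain as an int8 0/1 array."""
    p_stay_active, p_become_active = transition_probabilities(spec)
    u = rng.random(length)
    s = np.empty(length, dtype=np.int8)
    s[0] = u[0] < spec.f
    for t in range(1, length):
        thresh = p_stay_active if s[t - 1] else p_become_active
        s[t] = u[t] < thresh
    return s


def _seed_for(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def generate_associations(
    input_spec: MarkovSpec,
    output_spec: MarkovSpec,
    N: int,
    P: int,
    seed: int,
) -> AssociationSequence:
    """Generate a P-pattern association sequence over N input cells.

    Every input column is an independent realization of the input chain; the
    target sequence is an independent realization of the output chain.  Child
    random streams are derived from ``seed`` by column index, so enlarging
    ``N`` or ``P`` leaves the activity of the existing cells unchanged.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if P < 1:
        raise ValueError(f"P must be >= 1, got {P}")
    targets = _stream(output_spec, P, _seed_for(seed, 0))
    inputs = np.empty((P, N), dtype=np.int8)
    for i in range(N):
        inputs[:, i] = _stream(input_spec, P, _seed_for(seed, 1, i))
    return AssociationSequence(
        inputs=inputs, targets=targets, input_spec=input_spec, output_spec=output_spec, seed=seed
    )


def empirical_stats(stream: np.ndarray) -> EmpiricalStats:
    """Sample mean and lag-1 Pearson correlation of a binary stream."""
    s = np.asarray(stream, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("stream must be one-dimensional with length >= 2")
    mean = float(s.mean())
    a, b = s[:-1], s[1:]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return EmpiricalStats(mean=mean, lag1_corr=float("nan"), correlation_defined=False)
    cov = float(((a - a.mean()) * (b - b.mean())).mean())
    return EmpiricalStats(mean=mean, lag1_corr=cov / float(np.sqrt(va * vb)), correlation_defined=True)


def save_sequence(seq: AssociationSequence, path: str | Path) -> None:
    """Write a sequence as plain text plus a JSON metadata sidecar.

    One pattern per row, space-separated 0/1, final column the target.  A
    ``.gz`` suffix produces a compressed archive; the sidecar ``<path>.json``
    records the Markov specs and the seed.
    """
    path = Path(path)
    matrix = np.column_stack([seq.inputs, seq.targets])
    np.savetxt(path, matrix, fmt="%d")
    meta = {
        "n_inputs": seq.n_inputs,
        "n_patterns": seq.n_patterns,
        "input_spec": dataclasses.asdict(seq.input_spec),
        "output_spec": dataclasses.asdict(seq.output_spec),
        "seed": seq.seed,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_sequence(path: str | Path) -> AssociationSequence:
    """Read a sequence written by :func:`save_sequence`."""
    path = Path(path)
    matrix = np.loadtxt(path, dtype=np.int8, ndmin=2)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return AssociationSequence(
        inputs=matrix[:, :-1],
        targets=matrix[:, -1],
        input_spec=MarkovSpec(**meta["input_spec"]),
        output_spec=MarkovSpec(**meta["output_spec"]),
        seed=meta["seed"],
    )
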