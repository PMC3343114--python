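"""Empirical synaptic-weight distribution summaries.

At maximal capacity the theory predicts a finite fraction of exactly silent
synapses plus a truncated-Gaussian positive branch.  Trained weight vectors
are summarized with a *relative* silent threshold (a fixed fraction of the
mean nonzero weight) because the absolute weight scale depends on the
learning rate and on N.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["SilentFraction", "silent_fraction", "truncated_gaussian_summary", "weight_histogram"]

DEFAULT_RELATIVE_TOL = 1e-3


class SilentFraction(NamedTuple):
    fraction: float
    threshold: float
    degenerate: bool  # True when every weight is zero


def silent_fraction(
    w: np.ndarray, relative_tol: float = DEFAULT_RELATIVE_TOL, quantum: float = 0.0
) -> SilentFraction:
    """Fraction of weights below ``relative_tol`` times the mean nonzero weight.

    ``quantum`` is the resolution of the process that produced the weights
    (for a trained perceptron, the learning rate ``eta``): weights cannot
    settle closer to zero than a few update quanta, so the silent threshold
    is floored at ``5 * quantum``.  An all-zero vector is degenerate: the
    fraction is 1 and flagged.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0.0):
        raise ValueError("weights must be nonnegative")
    nonzero = w[w > 0.0]
    if nonzero.size == 0:
        return SilentFraction(fraction=1.0, threshold=0.0, degenerate=True)
    thr = max(relative_tol * float(nonzero.mean()), 5.0 * quantum)
    return SilentFraction(
        fraction=float(np.count_nonzero(w < thr)) / w.size, threshold=thr, degenerate=False
    )


class TruncatedGaussianSummary(NamedTuple):
    mean_nonzero: float
    std_nonzero: float
    std_over_mean: float


def truncated_gaussian_summary(
    w: np.ndarray, relative_tol: float = DEFAULT_RELATIVE_TOL, quantum: float = 0.0
) -> TruncatedGaussianSummary:
    """Moments of the positive part of a weight vector.

    ``std_over_mean`` is scale invariant; for a zero-mean Gaussian truncated
    at zero it equals ``sqrt(pi/2 - 1) ~= 0.7555``, the theoretical value at
    maximal capacity without robustness constraint.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0.0):
        raise ValueError("weights must be nonnegative")
    sf = silent_fraction(w, relative_tol, quantum)
    pos = w[w >= sf.threshold] if not sf.degenerate else np.empty(0)
    pos = pos[pos > 0.0]
    if pos.size < 2:
        raise ValueError("need at least 2 nonzero weights for a positive-branch summary")
    mean = float(pos.mean())
    std = float(pos.std(ddof=1))
    return TruncatedGaussianSummary(mean_nonzero=mean, std_nonzero=std, std_over_mean=std / mean)


def weight_histogram(w: np.ndarray, bins: int = 40):
    """Histogram of weights in mean-weight units as a DataFrame (edges, counts)."""
    import pandas as pd

    w = np.asarray(w, dtype=float)
    scale = w.mean() if w.mean() > 0 else 1.0
    counts, edges = np.histogram(w / scale, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
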