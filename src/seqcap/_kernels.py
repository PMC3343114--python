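"""Inner training loops, JIT-compiled with numba when available.

The kernel advances training by a chunk of epochs: each epoch presents the
patterns listed in one row of ``orders`` (drawn outside, so randomness stays
under the caller's seed control), applies the error-driven updates in place,
then checks every constraint exactly and stops at the first clean pass.  The
pure-Python fallback implements the identical algorithm and is exercised
against the compiled path in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sweep_chunk", "HAVE_NUMBA"]


def _sweep_chunk_py(Xf, sign, theta_eff, constrained, w, orders, eta, margin, clip):
    P = Xf.shape[0]
    n_epochs = orders.shape[0]
    updates = 0
    errors = np.empty(n_epochs, dtype=np.int64)
    converged_at = -1
    for e in range(n_epochs):
        for mu in orders[e]:
            if not constrained[mu]:
                continue
            slack = sign[mu] * (float(w @ Xf[mu]) - theta_eff[mu])
            bad = slack < margin if margin > 0.0 else slack <= 0.0
            if bad:
                w += (eta * sign[mu]) * Xf[mu]
                if clip:
                    np.maximum(w, 0.0, out=w)
                updates += 1
        slacks = sign * (Xf @ w - theta_eff)
        if margin > 0.0:
            bad_mask = (slacks < margin) & constrained
        else:
            bad_mask = (slacks <= 0.0) & constrained
        n_bad = int(np.count_nonzero(bad_mask))
        errors[e] = n_bad
        if n_bad == 0:
            converged_at = e
            break
    n_done = converged_at + 1 if converged_at >= 0 else n_epochs
    return converged_at, updates, errors[:n_done]


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _sweep_chunk_nb(Xf, sign, theta_eff, constrained, w, orders, eta, margin, clip):
        P, N = Xf.shape
        n_epochs = orders.shape[0]
        updates = 0
        errors = np.empty(n_epochs, dtype=np.int64)
        converged_at = -1
        for e in range(n_epochs):
            for j in range(P):
                mu = orders[e, j]
                if not constrained[mu]:
                    continue
                h = 0.0
                for i in range(N):
                    h += w[i] * Xf[mu, i]
                slack = sign[mu] * (h - theta_eff[mu])
                if margin > 0.0:
                    bad = slack < margin
                else:
                    bad = slack <= 0.0
                if bad:
                    step = eta * sign[mu]
                    for i in range(N):
                        w[i] += step * Xf[mu, i]
                        if clip and w[i] < 0.0:
                            w[i] = 0.0
                    updates += 1
            n_bad = 0
            for mu in range(P):
                if not constrained[mu]:
                    continue
                h = 0.0
                for i in range(N):
                    h += w[i] * Xf[mu, i]
                slack = sign[mu] * (h - theta_eff[mu])
                if margin > 0.0:
                    if slack < margin:
                        n_bad += 1
                elif slack <= 0.0:
                    n_bad += 1
            errors[e] = n_bad
            if n_bad == 0:
                converged_at = e
                break
        n_done = converged_at + 1 if converged_at >= 0 else n_epochs
        return converged_at, updates, errors[:n_done]

    sweep_chunk = _sweep_chunk_nb
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    sweep_chunk = _sweep_chunk_py
    HAVE_NUMBA = False

sweep_chunk_py = _sweep_chunk_py
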