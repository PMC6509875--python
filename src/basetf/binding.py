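"""Probability model linking motif counts to binding strength.

The tau above-threshold motif occurrences in a promoter are treated as
independent Bernoulli binding opportunities, each bound with probability
p0, so the factor binds the region (at least one site) with probability
1 - (1 - p0)^tau. For small p0 this is approximately tau * p0, and because
the BASE cumulative function normalises by the weighted total, the common
factor p0 cancels: the counts tau can be used directly as the binding
vector, with no per-factor p0 to estimate.
"""

from __future__ import annotations

import numpy as np

from .core import BindingCountMatrix

__all__ = [
    "binding_probability",
    "linear_approximation_error",
    "counts_to_binding",
]


def _check_p0(p0: float) -> float:
    p0 = float(p0)
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    return p0


def binding_probability(tau, p0: float):
    """P(at least one of tau sites bound) = 1 - (1 - p0)^tau.

    ``tau`` may be a scalar or an integer array. Evaluated as
    ``-expm1(tau * log1p(-p0))`` for accuracy at small p0.
    """
    p0 = _check_p0(p0)
    tau = np.asarray(tau)
    if np.any(tau < 0) or not np.all(np.equal(np.mod(tau, 1), 0)):
        raise ValueError("tau must be a nonnegative integer")
    out = -np.expm1(tau * np.log1p(-p0))
    return float(out) if out.ndim == 0 else out


def linear_approximation_error(tau, p0: float):
    """Signed error tau*p0 - [1 - (1-p0)^tau] of the linear approximation.

    Nonnegative by the union bound, and at most tau*(tau-1)*p0^2/2
    (second-order binomial term); exactly zero at tau in {0, 1}.
    """
    p0 = _check_p0(p0)
    tau = np.asarray(tau)
    err = tau * p0 - binding_probability(tau, p0)
    return float(err) if np.ndim(err) == 0 else err


def counts_to_binding(counts: BindingCountMatrix, p0: float | None = None) -> np.ndarray:
    """Per-motif binding vectors b from the count matrix.

    With ``p0`` omitted (the default pipeline), b = tau: the scale factor p0
    cancels in the BASE cumulative function, so the counts themselves serve
    as binding strengths. Supplying ``p0`` returns the exact probabilities
    1 - (1-p0)^tau, useful for sensitivity analysis when p0 is not small.
    """
    if p0 is None:
        return counts.counts.astype(float)
    return binding_probability(counts.counts, p0)
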