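"""Lyapunov spectra of the macroscopic map.

The full 8-exponent spectrum is computed by the standard QR method: the
analytic Jacobian is evaluated along the post-transient orbit, products
of Jacobians are re-orthonormalised at a fixed interval, and the
exponents are the time averages of the logs of the R-factor diagonal.

The zero-exponent count is the attractor's number of neutral
directions and is what distinguishes an invariant closed curve
(one zero exponent: the tangential direction) from a two-torus
(two zero exponents) among the model's quasi-periodic attractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import iterate_mean_field
from .fixed_points import jacobian
from .params import NetworkParams
from .states import as_omega, check_macro_bounds, default_initial_state

__all__ = ["LyapunovSpectrum", "lyapunov_spectrum", "count_zero_exponents"]

#: |exponent| below this (nats/step) counts as zero at the default n_iter.
ZERO_TOL = 1e-3

_CHUNK = 8192


class DivergentOrbitError(RuntimeError):
    """The orbit left the admissible region; the spectrum is undefined."""


@dataclass
class LyapunovSpectrum:
    """Full spectrum (nats per time step, descending)."""

    exponents: np.ndarray
    n_iter: int
    transient: int
    reortho_interval: int
    drift: float          # max change of the running means over the last 10%
    zero_tol: float = ZERO_TOL

    @property
    def zero_count(self) -> int:
        return count_zero_exponents(self, self.zero_tol)[0]

    @property
    def ambiguous(self) -> bool:
        return count_zero_exponents(self, self.zero_tol)[1]


def lyapunov_spectrum(params: NetworkParams, initial=None, *,
                      n_iter: int = 100_000, transient: int = 10_000,
                      reortho_interval: int = 1,
                      zero_tol: float = ZERO_TOL) -> LyapunovSpectrum:
    """Lyapunov spectrum along the attractor reached from ``initial``.

    Deterministic for a fixed initial state.  The orbit is generated in
    chunks, Jacobians are evaluated in batch, and an 8x8 QR
    re-orthonormalisation is applied every ``reortho_interval`` steps.
    """
    if reortho_interval < 1:
        raise ValueError("reortho_interval must be >= 1")
    omega = as_omega(initial) if initial is not None \
        else default_initial_state(params)
    omega = iterate_mean_field(omega, params, transient)
    if not check_macro_bounds(omega, strict=False):
        raise DivergentOrbitError("orbit left the admissible region "
                                  "during the transient")
    Q = np.eye(8)
    logs = np.zeros(8)
    mark = int(0.9 * n_iter)
    at_mark = None
    done = 0
    while done < n_iter:
        n = min(_CHUNK, n_iter - done)
        orbit = np.empty((n, 8))
        orbit[0] = omega
        if n > 1:
            orbit[1:] = iterate_mean_field(omega, params, n - 1, keep=True)
        omega = iterate_mean_field(orbit[-1], params, 1)
        if not np.all(np.isfinite(orbit)):
            raise DivergentOrbitError("orbit diverged")
        K = jacobian(orbit, params)          # (n, 8, 8)
        with np.errstate(divide="ignore"):   # exactly-singular directions
            for t in range(n):
                Q = K[t] @ Q
                if (done + t + 1) % reortho_interval == 0:
                    Q, R = np.linalg.qr(Q)
                    logs += np.log(np.abs(np.diagonal(R)))
                if done + t + 1 == mark:
                    at_mark = logs / mark if mark else logs.copy()
        done += n
    # flush a partial product left by a non-divisor interval
    if n_iter % reortho_interval:
        Q, R = np.linalg.qr(Q)
        with np.errstate(divide="ignore"):
            logs += np.log(np.abs(np.diagonal(R)))
    exponents = np.sort(logs / n_iter)[::-1]
    if at_mark is not None:
        prev = np.sort(at_mark)[::-1]
        ok = np.isfinite(prev) & np.isfinite(exponents)
        drift = float(np.max(np.abs(prev[ok] - exponents[ok]))) \
            if ok.any() else 0.0
    else:
        drift = np.inf
    return LyapunovSpectrum(exponents, n_iter, transient, reortho_interval,
                            drift, zero_tol)


def count_zero_exponents(spectrum, tolerance: float = ZERO_TOL):
    """Number of exponents within ``tolerance`` of zero.

    Returns ``(count, ambiguous)``; the flag is set when the gap
    structure is unclear, i.e. some exponent falls between the cut and
    twice the cut, so a small tolerance change would alter the count.
    """
    exps = spectrum.exponents if isinstance(spectrum, LyapunovSpectrum) \
        else np.asarray(spectrum, dtype=float)
    mags = np.abs(exps)
    count = int(np.count_nonzero(mags < tolerance))
    ambiguous = bool(np.any((mags >= tolerance) & (mags < 2.0 * tolerance)))
    return count, ambiguous
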