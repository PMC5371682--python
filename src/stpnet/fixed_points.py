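"""Fixed points of the macroscopic map and their linear stability.

The 8-D fixed-point problem reduces to two scalar equations in the mean
activities (mbarE, mbarI): eliminating the synaptic variables at
stationarity gives the composite synaptic drive

    D(m) = tau_a m (1 + tau_F m)
           / (1 + (tau_F + tau_R) U_se m + U_se tau_F tau_R m^2)

so that mbar_xi = g[J_rec D_xi(mbar_xi) + J_cross D_eta(mbar_eta) + I_xi].
The reduced system is solved by damped Newton from a grid of starts, the
synaptic components are recovered from the stationarity relations, and
stability follows from the eigenvalues of the analytic 8x8 Jacobian.

The Jacobian rows/columns are ordered by subnetwork blocks,
(m, A, X, U) for E then for I; :data:`BLOCKED_PERM` maps Omega order to
this blocked order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import activation, activation_deriv, step_mean_field
from .params import NetworkParams
from .states import IDX, as_omega

__all__ = [
    "BLOCKED_PERM", "BLOCKED_LABELS", "FixedPointResult", "synaptic_drive",
    "closure", "jacobian", "jacobian_block", "solve_fixed_points",
    "classify_stability", "sort_eigenvalues",
]

#: Omega order -> blocked (m,A,X,U | E then I) order.
BLOCKED_PERM = np.array([0, 2, 4, 6, 1, 3, 5, 7])
BLOCKED_LABELS = ("m0E", "A0E", "X0E", "U0E", "m0I", "A0I", "X0I", "U0I")


def synaptic_drive(m, tau_a, tau_R, tau_F, U_se):
    """Stationary synaptic current fed back per unit coupling gain.

    The closed form obtained by eliminating the stationary X and U from
    A = tau_a m X U / U_se.
    """
    m = np.asarray(m, dtype=float)
    num = tau_a * m * (1.0 + tau_F * m)
    den = 1.0 + (tau_F + tau_R) * U_se * m + U_se * tau_F * tau_R * m * m
    out = num / den
    return out if out.ndim else float(out)


def synaptic_drive_deriv(m, tau_a, tau_R, tau_F, U_se):
    """d/dm of :func:`synaptic_drive` (quotient rule)."""
    m = np.asarray(m, dtype=float)
    b = (tau_F + tau_R) * U_se
    c = U_se * tau_F * tau_R
    num = tau_a * (m + tau_F * m * m)
    dnum = tau_a * (1.0 + 2.0 * tau_F * m)
    den = 1.0 + b * m + c * m * m
    dden = b + 2.0 * c * m
    out = (dnum * den - num * dden) / (den * den)
    return out if out.ndim else float(out)


def closure(m, tau_a, tau_R, tau_F, U_se):
    """Stationary (A, X, U) for a clamped mean activity m."""
    U = U_se * (1.0 + tau_F * m) / (1.0 + tau_F * U_se * m)
    X = 1.0 / (1.0 + tau_R * U * m)
    A = tau_a * U * m * X / U_se
    return A, X, U


@dataclass
class FixedPointResult:
    """A converged macroscopic fixed point with its stability data."""

    omega: np.ndarray                 # 8-vector, Omega order
    residual: float                   # sup-norm of the reduced-system residual
    eigenvalues: np.ndarray           # 8 complex, descending modulus
    leading_modulus: float
    label: str                        # stable / NS-unstable / other-unstable
    converged: bool = True
    guess: tuple = field(default=None)

    @property
    def m(self) -> tuple:
        return float(self.omega[IDX["m0E"]]), float(self.omega[IDX["m0I"]])

    def to_dict(self) -> dict:
        return {
            "omega": self.omega.tolist(),
            "residual": self.residual,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "leading_modulus": self.leading_modulus,
            "label": self.label,
            "converged": self.converged,
            "guess": list(self.guess) if self.guess is not None else None,
        }


def _reduced_residual(m, params: NetworkParams):
    """F(m) = m - f(m) for the reduced 2-D system, plus its Jacobian."""
    mE, mI = m
    DE = synaptic_drive(mE, params.tau_a_E, params.tau_R_E,
                        params.tau_F_E, params.U_se_E)
    DI = synaptic_drive(mI, params.tau_a_I, params.tau_R_I,
                        params.tau_F_I, params.U_se_I)
    dDE = synaptic_drive_deriv(mE, params.tau_a_E, params.tau_R_E,
                               params.tau_F_E, params.U_se_E)
    dDI = synaptic_drive_deriv(mI, params.tau_a_I, params.tau_R_I,
                               params.tau_F_I, params.U_se_I)
    hE = params.J_EE * DE + params.J_EI * DI + params.I_E
    hI = params.J_II * DI + params.J_IE * DE + params.I_I
    gE, gI = activation(hE, params.T_E), activation(hI, params.T_I)
    dgE, dgI = activation_deriv(hE, params.T_E), activation_deriv(hI, params.T_I)
    F = np.array([mE - gE, mI - gI])
    J = np.array([
        [1.0 - dgE * params.J_EE * dDE, -dgE * params.J_EI * dDI],
        [-dgI * params.J_IE * dDE, 1.0 - dgI * params.J_II * dDI],
    ])
    return F, J


def _newton(m0, params, *, tol=1e-12, max_iter=100):
    """Damped Newton with step halving on the reduced 2-D system."""
    m = np.clip(np.asarray(m0, dtype=float), 1e-12, 1.0 - 1e-12)
    F, J = _reduced_residual(m, params)
    norm = np.max(np.abs(F))
    for _ in range(max_iter):
        if norm <= tol:
            return m, norm, True
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            return m, norm, False
        lam = 1.0
        for _ in range(40):
            m_try = np.clip(m - lam * step, 0.0, 1.0)
            F_try, J_try = _reduced_residual(m_try, params)
            norm_try = np.max(np.abs(F_try))
            if norm_try < norm:
                m, F, J, norm = m_try, F_try, J_try, norm_try
                break
            lam *= 0.5
        else:
            return m, norm, norm <= tol
    return m, norm, norm <= tol


def assemble_fixed_point(m, params: NetworkParams) -> np.ndarray:
    """Build the full 8-vector (Omega order) from (mbarE, mbarI)."""
    mE, mI = m
    AE, XE, UE = closure(mE, params.tau_a_E, params.tau_R_E,
                         params.tau_F_E, params.U_se_E)
    AI, XI, UI = closure(mI, params.tau_a_I, params.tau_R_I,
                         params.tau_F_I, params.U_se_I)
    return np.array([mE, mI, AE, AI, XE, XI, UE, UI])


def jacobian(omega, params: NetworkParams) -> np.ndarray:
    """Analytic Jacobian of the macroscopic map at a state.

    Accepts a single 8-vector or a batch (..., 8); returns (..., 8, 8)
    in blocked (m, A, X, U | E then I) order.  The same formulas serve
    fixed-point stability and along-orbit Lyapunov products.  Entries
    not generated by the map's dependencies are structurally zero; in
    particular every (A, X, U) row couples only within its own
    subnetwork and the m rows depend only on the A components.
    """
    omega = as_omega(omega)
    batch = omega.shape[:-1]
    mE, mI = omega[..., 0], omega[..., 1]
    AE, AI = omega[..., 2], omega[..., 3]
    XE, XI = omega[..., 4], omega[..., 5]
    UE, UI = omega[..., 6], omega[..., 7]
    hE = params.J_EE * AE + params.J_EI * AI + params.I_E
    hI = params.J_II * AI + params.J_IE * AE + params.I_I
    gpE = activation_deriv(hE, params.T_E)
    gpI = activation_deriv(hI, params.T_I)

    K = np.zeros(batch + (8, 8))
    for base, (m, X, U, gp, J_rec, J_cross, tau_a, tau_R, tau_F, use) in {
        0: (mE, XE, UE, gpE, params.J_EE, params.J_EI,
            params.tau_a_E, params.tau_R_E, params.tau_F_E, params.U_se_E),
        4: (mI, XI, UI, gpI, params.J_II, params.J_IE,
            params.tau_a_I, params.tau_R_I, params.tau_F_I, params.U_se_I),
    }.items():
        other = 4 - base
        K[..., base + 0, base + 1] = gp * J_rec        # dm'/dA own
        K[..., base + 0, other + 1] = gp * J_cross     # dm'/dA other
        K[..., base + 1, base + 0] = U * X / use       # dA'/dm
        K[..., base + 1, base + 1] = 1.0 - 1.0 / tau_a
        K[..., base + 1, base + 2] = m * U / use       # dA'/dX
        K[..., base + 1, base + 3] = m * X / use       # dA'/dU
        K[..., base + 2, base + 0] = -U * X            # dX'/dm
        K[..., base + 2, base + 2] = (1.0 - 1.0 / tau_R) - m * U
        K[..., base + 2, base + 3] = -m * X            # dX'/dU
        K[..., base + 3, base + 0] = use * (1.0 - U)   # dU'/dm
        K[..., base + 3, base + 3] = (1.0 - 1.0 / tau_F) - use * m
    return K


def jacobian_block(K: np.ndarray, xi: str) -> np.ndarray:
    """Extract one subnetwork's 4x4 block (exact for zero cross-coupling)."""
    sl = slice(0, 4) if xi == "E" else slice(4, 8)
    return K[..., sl, sl]


def sort_eigenvalues(eigvals: np.ndarray) -> np.ndarray:
    """Descending modulus; ties broken by descending real part."""
    order = np.lexsort((-eigvals.real, -np.abs(eigvals)))
    return eigvals[order]


def classify_stability(eigenvalues, *, tol: float = 1e-8):
    """Stability label from map eigenvalues.

    stable: all moduli < 1 (within ``tol``); NS-unstable: the leading
    modulus >= 1 belongs to a complex pair (nonzero imaginary part);
    other-unstable: a real leading eigenvalue crosses instead.
    Returns (label, leading_modulus).
    """
    ev = sort_eigenvalues(np.asarray(eigenvalues, dtype=complex))
    lead = ev[0]
    modulus = float(np.abs(lead))
    if modulus < 1.0 - tol:
        return "stable", modulus
    if abs(lead.imag) > tol:
        return "NS-unstable", modulus
    return "other-unstable", modulus


def leading_modulus(params: NetworkParams, m, *, subnetwork: str | None = None):
    """Leading eigenvalue (modulus, value) at the fixed point built from m."""
    omega = assemble_fixed_point(m, params)
    K = jacobian(omega, params)
    if subnetwork is not None:
        K = jacobian_block(K, subnetwork)
    ev = sort_eigenvalues(np.linalg.eigvals(K))
    return float(np.abs(ev[0])), ev[0]


def solve_fixed_points(params: NetworkParams, guesses=None, *,
                       tol: float = 1e-12, grid: int = 11,
                       dedup: float = 1e-6,
                       stability_tol: float = 1e-8) -> list[FixedPointResult]:
    """All macroscopic fixed points reachable from a grid of Newton starts.

    ``guesses`` is an optional iterable of (mE, mI) starting pairs; by
    default an 11x11 grid over (0,1)^2 is used.  Distinct converged
    roots (pairwise distance >= ``dedup`` in the reduced variables) are
    reported sorted by mbarE, each with the Jacobian spectrum of the
    full 8-D map and a stability label.
    """
    if guesses is None:
        pts = (np.arange(grid) + 0.5) / grid
        guesses = [(a, b) for a in pts for b in pts]
    roots, results = [], []
    for g in guesses:
        m, res, ok = _newton(g, params, tol=tol)
        if not ok:
            continue
        if any(np.hypot(m[0] - r[0], m[1] - r[1]) < dedup for r in roots):
            continue
        roots.append(tuple(m))
        omega = assemble_fixed_point(m, params)
        ev = sort_eigenvalues(np.linalg.eigvals(jacobian(omega, params)))
        label, lead = classify_stability(ev, tol=stability_tol)
        results.append(FixedPointResult(
            omega=omega, residual=float(res), eigenvalues=ev,
            leading_modulus=lead, label=label, converged=True,
            guess=tuple(np.asarray(g, dtype=float))))
    results.sort(key=lambda r: r.omega[IDX["m0E"]])
    return results


def fixed_point_step_residual(result: FixedPointResult,
                              params: NetworkParams) -> float:
    """Sup-norm of one map step applied at the fixed point (diagnostic)."""
    omega = result.omega
    return float(np.max(np.abs(step_mean_field(omega, params) - omega)))
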