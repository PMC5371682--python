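"""Bifurcation localisation, sweep diagrams and hysteresis analysis.

A fixed point of the macroscopic map loses stability through a
Neimark-Sacker (NS) bifurcation when a complex eigenvalue pair of its
Jacobian crosses the unit circle; :func:`locate_ns` pins the crossing
down by bisection on the leading modulus.  One- and two-parameter
sweeps classify each grid point into the model's attractor taxonomy:

* single subnetworks: SS (stable fixed point), OSE (oscillation of the
  excitatory network, recurrent gain J0 > 0) or OSI (inhibitory,
  J0 < 0);
* the coupled network: SS, OS1C / OS2C (one zero Lyapunov exponent;
  OS2C additionally shows a slow spectral component) or OS2T (two zero
  exponents: a two-torus).

Sweeps are continuation runs: each grid point warm-starts from the
previous attractor, which is what exposes hysteresis between the OS1C
and OS2T branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixed_points import (
    FixedPointResult, assemble_fixed_point, classify_stability, jacobian,
    jacobian_block, solve_fixed_points, sort_eigenvalues, synaptic_drive,
    synaptic_drive_deriv,
)
from .lyapunov import lyapunov_spectrum, count_zero_exponents
from .model import activation, activation_deriv, iterate_mean_field, \
    step_mean_field
from .oscillation import DEFAULT_WINDOW, dominant_period
from .params import NetworkParams
from .states import IDX, default_initial_state

__all__ = [
    "BifurcationPoint", "SweepResult", "locate_ns", "bifurcation_diagram_1d",
    "phase_diagram_2d", "hysteresis_sweep",
]

#: Periods longer than this (time steps) count as "slow" when telling
#: OS2C (slow + fast component) from OS1C (fast only).
SLOW_PERIOD = 20.0


class BracketError(ValueError):
    """The bisection bracket does not enclose a stability change."""


class NotNSError(RuntimeError):
    """The crossing eigenvalue is real, so the bifurcation is not NS."""


@dataclass
class BifurcationPoint:
    param: str
    value: float
    bracket_width: float
    type: str                      # NS (fixed point) or torus types
    label_before: str
    label_after: str


@dataclass
class SweepResult:
    """Per-grid-point classification of a parameter sweep."""

    sweep_param: str
    grid: np.ndarray
    frame: pd.DataFrame
    direction: str = "static"      # forward / backward / static
    meta: dict = field(default_factory=dict)


def _infer_subnetwork(params: NetworkParams, sweep_param: str):
    """For a decoupled system, the subnetwork whose 4x4 block to watch."""
    if params.coupled:
        return None
    if sweep_param.endswith("_E") or sweep_param in ("J_EE",):
        return "E"
    if sweep_param.endswith("_I") or sweep_param in ("J_II",):
        return "I"
    return None


def _leading_eigenvalue(params: NetworkParams, root: FixedPointResult,
                        subnetwork):
    if subnetwork is None:
        return root.eigenvalues[0]
    K = jacobian_block(jacobian(root.omega, params), subnetwork)
    return sort_eigenvalues(np.linalg.eigvals(K))[0]


def _tracked_root(params: NetworkParams, prev_m=None):
    """Solve fixed points, continuing from the previous root if given."""
    guesses = None
    if prev_m is not None:
        roots = solve_fixed_points(params, guesses=[prev_m])
        if roots:
            return roots[0]
    roots = solve_fixed_points(params, guesses=guesses)
    if not roots:
        return None
    if prev_m is not None:
        dist = [np.hypot(r.m[0] - prev_m[0], r.m[1] - prev_m[1])
                for r in roots]
        return roots[int(np.argmin(dist))]
    return roots[0]


def locate_ns(params: NetworkParams, sweep_param: str, bracket, *,
              tol: float = 1e-6, subnetwork: str | None = "auto",
              max_iter: int = 200) -> BifurcationPoint:
    """Bisect a Neimark-Sacker crossing of the fixed point.

    The bracketed function is (leading eigenvalue modulus - 1) of the
    fixed point tracked by continuation across the bracket; for a
    decoupled system the relevant subnetwork's 4x4 block is used so the
    inert subnetwork's eigenvalues cannot shadow the crossing.  The
    leading eigenvalue at the crossing must be a complex pair.
    """
    if subnetwork == "auto":
        subnetwork = _infer_subnetwork(params, sweep_param)
    state = {"m": None}

    def excess(value):
        p = params.replace(**{sweep_param: float(value)})
        root = _tracked_root(p, state["m"])
        if root is None:
            raise BracketError(f"no fixed point found at {sweep_param}={value}")
        state["m"] = root.m
        lead = _leading_eigenvalue(p, root, subnetwork)
        return float(np.abs(lead)) - 1.0, lead

    lo, hi = map(float, bracket)
    f_lo, _ = excess(lo)
    f_hi, ev_hi = excess(hi)
    if f_lo == 0.0 or f_hi == 0.0:
        pass
    elif np.sign(f_lo) == np.sign(f_hi):
        raise BracketError(
            f"leading modulus - 1 does not change sign on [{lo}, {hi}] "
            f"({f_lo:+.3g} vs {f_hi:+.3g})")
    ev_cross = ev_hi
    for _ in range(max_iter):
        if abs(hi - lo) <= tol:
            break
        mid = 0.5 * (lo + hi)
        f_mid, ev_mid = excess(mid)
        ev_cross = ev_mid
        if f_mid == 0.0:
            lo = hi = mid
            break
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    if abs(np.imag(ev_cross)) <= 1e-8:
        raise NotNSError(
            f"leading eigenvalue is real at the crossing "
            f"({sweep_param} ~ {0.5 * (lo + hi):.6g}); not a NS bifurcation")
    before = "stable" if f_lo < 0 else "unstable"
    after = "unstable" if before == "stable" else "stable"
    return BifurcationPoint(sweep_param, 0.5 * (lo + hi), abs(hi - lo),
                            "NS", before, after)


# ---------------------------------------------------------------------------
# 1-D diagrams
# ---------------------------------------------------------------------------

def _oscillation_label(params: NetworkParams, subnetwork: str | None) -> str:
    if subnetwork == "E":
        return "OSE"
    if subnetwork == "I":
        return "OSI"
    return "OSC"


def bifurcation_diagram_1d(params: NetworkParams, sweep_param: str,
                           grid, *, monitor: str | None = None,
                           n_steps: int = DEFAULT_WINDOW,
                           transient: int = 10_000,
                           subnetwork: str | None = "auto",
                           amplitude_tol: float = 1e-8) -> SweepResult:
    """Fixed-point branch, attractor extrema and period along a 1-D sweep.

    At every grid value the continued fixed point is classified; where
    it is unstable the map is simulated (warm-started from the previous
    grid point's final state) and the post-transient extrema of the
    monitored variable plus the spectral period are recorded.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not (np.all(np.diff(grid) > 0)
                              or np.all(np.diff(grid) < 0)):
        raise ValueError("grid must be strictly monotone")
    if subnetwork == "auto":
        subnetwork = _infer_subnetwork(params, sweep_param)
    if monitor is None:
        monitor = "m0I" if subnetwork == "I" else "m0E"
    mcol = IDX[monitor]
    rows = []
    prev_m = None
    omega = None
    for value in grid:
        p = params.replace(**{sweep_param: float(value)})
        root = _tracked_root(p, prev_m)
        row = {sweep_param: float(value)}
        if root is None:
            row.update(label="indeterminate", state="indeterminate")
            rows.append(row)
            continue
        prev_m = root.m
        if subnetwork is None:
            label = root.label
            lead = root.leading_modulus
        else:
            ev = _leading_eigenvalue(p, root, subnetwork)
            label, lead = classify_stability(
                np.linalg.eigvals(jacobian_block(jacobian(root.omega, p),
                                                 subnetwork)))
        row.update(fixed_point=root.omega[mcol], fp_label=label,
                   leading_modulus=lead)
        if label == "stable":
            row.update(state="SS", minimum=root.omega[mcol],
                       maximum=root.omega[mcol], period=np.nan)
            omega = None if omega is None else omega
        else:
            if omega is None:
                omega = root.omega.copy()
                omega[2:4] += 1e-3   # nudge A off the fixed point
            omega = iterate_mean_field(omega, p, transient)
            traj = iterate_mean_field(omega, p, n_steps, keep=True)
            omega = traj[-1]
            series = traj[:, mcol]
            amp = float(series.max() - series.min())
            est = dominant_period(series, window=min(n_steps, len(series)))
            if amp <= amplitude_tol or est.no_peak:
                state = "SS" if amp <= amplitude_tol else "indeterminate"
                row.update(state=state, minimum=series.min(),
                           maximum=series.max(), period=np.nan)
            else:
                row.update(state=_oscillation_label(p, subnetwork),
                           minimum=series.min(), maximum=series.max(),
                           period=est.period)
        rows.append(row)
    return SweepResult(sweep_param, grid, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# 2-D phase diagrams
# ---------------------------------------------------------------------------

def _single_fixed_points_vec(J0, I, sub: dict, *, n_starts: int = 11,
                             tol: float = 1e-12, max_iter: int = 80):
    """Vectorised scalar Newton for m = g[J0 D(m) + I] over a cell grid.

    Returns per-cell root lists encoded as (roots, counts): ``roots``
    is (ncells, n_starts) with converged values and nan elsewhere.
    """
    J0 = np.asarray(J0, dtype=float)[:, None]
    I = np.asarray(I, dtype=float)[:, None]
    starts = (np.arange(n_starts) + 0.5) / n_starts
    m = np.broadcast_to(starts, (len(J0), n_starts)).copy()
    for _ in range(max_iter):
        D = synaptic_drive(m, sub["tau_a"], sub["tau_R"], sub["tau_F"],
                           sub["U_se"])
        dD = synaptic_drive_deriv(m, sub["tau_a"], sub["tau_R"],
                                  sub["tau_F"], sub["U_se"])
        h = J0 * D + I
        g = activation(h, sub["T"])
        dg = activation_deriv(h, sub["T"])
        F = m - g
        dF = 1.0 - dg * J0 * dD
        step = np.where(np.abs(dF) > 1e-14, F / np.where(dF == 0, 1, dF), F)
        m = np.clip(m - step, 0.0, 1.0)
    D = synaptic_drive(m, sub["tau_a"], sub["tau_R"], sub["tau_F"],
                       sub["U_se"])
    F = m - activation(J0 * D + I, sub["T"])
    conv = np.abs(F) < 1e-9
    roots = np.where(conv, m, np.nan)
    # deduplicate within each cell
    roots.sort(axis=1)
    dup = np.zeros_like(roots, dtype=bool)
    dup[:, 1:] = np.abs(np.diff(roots, axis=1)) < 1e-6
    roots[dup] = np.nan
    return roots


def _single_block_stability(roots, J0, I, sub: dict):
    """Leading 4x4-block eigenvalue modulus for each (cell, root)."""
    ncells, nroots = roots.shape
    flat_m = roots.ravel()
    ok = np.isfinite(flat_m)
    lead = np.full(flat_m.shape, np.nan)
    complex_lead = np.zeros(flat_m.shape, dtype=bool)
    if ok.any():
        m = flat_m[ok]
        J = np.repeat(np.asarray(J0, dtype=float), nroots)[ok]
        Iv = np.repeat(np.asarray(I, dtype=float), nroots)[ok]
        U = sub["U_se"] * (1.0 + sub["tau_F"] * m) \
            / (1.0 + sub["tau_F"] * sub["U_se"] * m)
        X = 1.0 / (1.0 + sub["tau_R"] * U * m)
        A = sub["tau_a"] * U * m * X / sub["U_se"]
        h = J * A + Iv
        gp = activation_deriv(h, sub["T"])
        K = np.zeros((len(m), 4, 4))
        K[:, 0, 1] = gp * J
        K[:, 1, 0] = U * X / sub["U_se"]
        K[:, 1, 1] = 1.0 - 1.0 / sub["tau_a"]
        K[:, 1, 2] = m * U / sub["U_se"]
        K[:, 1, 3] = m * X / sub["U_se"]
        K[:, 2, 0] = -U * X
        K[:, 2, 2] = (1.0 - 1.0 / sub["tau_R"]) - m * U
        K[:, 2, 3] = -m * X
        K[:, 3, 0] = sub["U_se"] * (1.0 - U)
        K[:, 3, 3] = (1.0 - 1.0 / sub["tau_F"]) - sub["U_se"] * m
        ev = np.linalg.eigvals(K)
        mods = np.abs(ev)
        idx = np.argmax(mods, axis=1)
        lead_ev = ev[np.arange(len(m)), idx]
        lead[ok] = np.abs(lead_ev)
        complex_lead[ok] = np.abs(lead_ev.imag) > 1e-8
    return lead.reshape(roots.shape), complex_lead.reshape(roots.shape)


def _simulate_cells(params_vec: NetworkParams, omega0, transient, n_steps,
                    mcol):
    """Advance a batch of cells and return the monitored series (n, ncells)."""
    omega = omega0
    for _ in range(transient):
        omega = step_mean_field(omega, params_vec)
    out = np.empty((n_steps, omega.shape[0]))
    for t in range(n_steps):
        omega = step_mean_field(omega, params_vec)
        out[t] = omega[:, mcol]
    return out


def phase_diagram_2d(params: NetworkParams, param_x: str, param_y: str,
                     grid_x, grid_y, *, subnetwork: str | None = "auto",
                     n_steps: int = DEFAULT_WINDOW, transient: int = 10_000,
                     lyap_iter: int = 50_000,
                     amplitude_tol: float = 1e-8) -> SweepResult:
    """Classify every cell of a two-parameter grid.

    For a decoupled subnetwork the classification is fixed-point
    stability (SS) versus oscillation (OSE/OSI by the sign of the
    recurrent gain), with the spectral period recorded; the whole grid
    is advanced as one vectorised batch.  For the coupled network each
    cell is classified by its zero-Lyapunov-exponent count and the
    presence of a slow spectral component, which is necessarily
    per-cell and much slower.  Indeterminate cells are flagged, not
    guessed.
    """
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    GX, GY = np.meshgrid(grid_x, grid_y, indexing="ij")
    fx, fy = GX.ravel(), GY.ravel()
    if subnetwork == "auto":
        subnetwork = _infer_subnetwork(params, param_x) \
            or _infer_subnetwork(params, param_y)
    if subnetwork is not None and not params.coupled:
        frame = _phase2d_single(params, param_x, param_y, fx, fy, subnetwork,
                                n_steps, transient, amplitude_tol)
    else:
        frame = _phase2d_coupled(params, param_x, param_y, fx, fy,
                                 n_steps, transient, lyap_iter)
    return SweepResult(f"{param_x},{param_y}", np.stack([fx, fy]), frame,
                       meta={"grid_x": grid_x, "grid_y": grid_y,
                             "subnetwork": subnetwork})


def _phase2d_single(params, param_x, param_y, fx, fy, xi, n_steps, transient,
                    amplitude_tol):
    pvec = params.replace(**{param_x: fx, param_y: fy})
    sub = pvec.sub(xi)
    J0, I = np.asarray(sub["J_rec"], dtype=float), np.asarray(sub["I"],
                                                              dtype=float)
    J0 = np.broadcast_to(J0, fx.shape).astype(float)
    I = np.broadcast_to(I, fx.shape).astype(float)
    roots = _single_fixed_points_vec(J0, I, sub)
    lead, _ = _single_block_stability(roots, J0, I, sub)
    has_root = np.any(np.isfinite(roots), axis=1)
    any_stable = np.any(lead < 1.0 - 1e-8, axis=1)
    unstable = has_root & ~any_stable
    n_roots = np.sum(np.isfinite(roots), axis=1)

    period = np.full(fx.shape, np.nan)
    amplitude = np.full(fx.shape, np.nan)
    label = np.where(has_root, "SS", "indeterminate").astype(object)
    if unstable.any():
        sel = np.flatnonzero(unstable)
        p_sel = params.replace(**{param_x: fx[sel], param_y: fy[sel]})
        mcol = IDX[f"m0{xi}"]
        omega0 = np.empty((len(sel), 8))
        omega0[:, IDX["m0E"]] = activation(np.broadcast_to(
            np.asarray(p_sel.I_E, dtype=float), (len(sel),)), params.T_E)
        omega0[:, IDX["m0I"]] = activation(np.broadcast_to(
            np.asarray(p_sel.I_I, dtype=float), (len(sel),)), params.T_I)
        omega0[:, IDX["A0E"]] = 1e-3
        omega0[:, IDX["A0I"]] = 1e-3
        omega0[:, IDX["X0E"]] = omega0[:, IDX["X0I"]] = 1.0
        omega0[:, IDX["U0E"]] = params.U_se_E
        omega0[:, IDX["U0I"]] = params.U_se_I
        series = _simulate_cells(p_sel, omega0, transient, n_steps, mcol)
        osc = "OSE" if xi == "E" else "OSI"
        for j, cell in enumerate(sel):
            s = series[:, j]
            amplitude[cell] = s.max() - s.min()
            est = dominant_period(s, window=n_steps)
            if amplitude[cell] <= amplitude_tol:
                label[cell] = "SS"
            elif est.no_peak:
                label[cell] = "indeterminate"
            else:
                label[cell] = osc
                period[cell] = est.period
    return pd.DataFrame({
        param_x: fx, param_y: fy, "label": label,
        "n_fixed_points": n_roots,
        "leading_modulus": np.nanmax(np.where(np.isfinite(lead), lead,
                                              -np.inf), axis=1),
        "amplitude": amplitude, "period": period,
    })


def _classify_coupled_cell(p: NetworkParams, omega, *, transient, n_steps,
                           lyap_iter):
    """(label, zero_count, slow_period, fast_period, amp_slow, final_state).

    The slow (excitatory) component is decisive where the
    zero-exponent count is: a fast-only oscillation is OS1C whatever
    the marginal exponents say (near the torus birth the contracting
    pair sits inside any finite zero tolerance), while states with a
    genuine slow component are split OS2T / OS2C by the count.
    """
    omega = iterate_mean_field(omega, p, transient)
    traj = iterate_mean_field(omega, p, n_steps, keep=True)
    final = traj[-1]
    mE = traj[:, IDX["m0E"]]
    mI = traj[:, IDX["m0I"]]
    amp_slow = float(mE.max() - mE.min())
    amp = max(amp_slow, mI.max() - mI.min())
    if amp <= 1e-8:
        return "SS", 0, np.nan, np.nan, amp_slow, final
    spec = lyapunov_spectrum(p, final, n_iter=lyap_iter, transient=0)
    zeros, ambiguous = count_zero_exponents(spec.exponents, spec.zero_tol)
    est_slow = dominant_period(mE, window=n_steps)
    est_fast = dominant_period(mI, window=n_steps, prefer="largest")
    slow_period = est_slow.period if not est_slow.no_peak else np.nan
    fast_period = est_fast.period if not est_fast.no_peak else np.nan
    has_slow = np.isfinite(slow_period) and slow_period > SLOW_PERIOD
    if not has_slow:
        label = "OS1C"
    elif zeros == 2 and not ambiguous:
        label = "OS2T"
    elif zeros == 1 and not ambiguous:
        label = "OS2C"
    else:
        label = "indeterminate"
    return label, zeros, slow_period, fast_period, amp_slow, final


def _phase2d_coupled(params, param_x, param_y, fx, fy, n_steps, transient,
                     lyap_iter):
    rows = []
    for x, y in zip(fx, fy):
        p = params.replace(**{param_x: float(x), param_y: float(y)})
        label, zeros, slow_p, fast_p, amp_slow, _ = _classify_coupled_cell(
            p, default_initial_state(p), transient=transient,
            n_steps=n_steps, lyap_iter=lyap_iter)
        rows.append({param_x: float(x), param_y: float(y), "label": label,
                     "zero_exponents": zeros, "slow_period": slow_p,
                     "fast_period": fast_p, "slow_amplitude": amp_slow})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

def hysteresis_sweep(params: NetworkParams, sweep_param: str, grid, *,
                     transient: int = 5_000, n_steps: int = DEFAULT_WINDOW,
                     lyap_iter: int = 50_000):
    """Forward and backward continuation sweeps of the coupled network.

    Both directions warm-start each grid point from the previous
    attractor, so a multistable window shows up as a disagreement
    between the two sweeps.  The declared hysteresis interval is based
    on the slow-component amplitude (max - min of the excitatory mean
    activity over the analysis window), which jumps discontinuously
    between the coexisting branches and stays insensitive to the
    zero-exponent counting ambiguity right at a bifurcation; the label
    sequences are reported alongside.  Returns ``(forward, backward,
    interval)`` where ``interval`` is the (min, max) of the disagreeing
    grid values, or ``None`` when the sweeps agree everywhere.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")

    def run(values, direction):
        rows = []
        omega = None
        for v in values:
            p = params.replace(**{sweep_param: float(v)})
            if omega is None:
                omega = default_initial_state(p)
                omega = iterate_mean_field(omega, p, 20_000)
            label, zeros, slow_p, fast_p, amp_slow, omega = \
                _classify_coupled_cell(p, omega, transient=transient,
                                       n_steps=n_steps, lyap_iter=lyap_iter)
            rows.append({sweep_param: float(v), "label": label,
                         "zero_exponents": zeros, "slow_period": slow_p,
                         "fast_period": fast_p, "slow_amplitude": amp_slow})
        frame = pd.DataFrame(rows).sort_values(sweep_param) \
            .reset_index(drop=True)
        return SweepResult(sweep_param, grid, frame, direction=direction)

    forward = run(grid, "forward")
    backward = run(grid[::-1], "backward")
    amp_f = forward.frame["slow_amplitude"].to_numpy()
    amp_b = backward.frame["slow_amplitude"].to_numpy()
    disagree = np.abs(amp_f - amp_b) > 0.05 + 0.2 * np.maximum(amp_f, amp_b)
    interval = None
    if disagree.any():
        vals = grid[disagree]
        interval = (float(vals.min()), float(vals.max()))
    return forward, backward, interval
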