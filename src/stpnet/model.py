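"""The three dynamical systems.

Three levels of description of the same network:

* **stochastic** -- binary neurons fire as Bernoulli draws with
  probability ``g[h] = (1 + tanh(beta h)) / 2`` of the synaptic input h;
  each synapse carries a current a, a releasable-resource fraction x
  (depression) and a calcium variable u (facilitation).
* **microscopic mean field** -- the same per-neuron system after a
  noise average, assuming s decorrelates from x and u in the
  large-N limit (weights of order 1/N).
* **macroscopic mean field** -- the population average under uniform
  all-to-all weights J/N: a deterministic 8-dimensional map for
  Omega = (m0E, m0I, A0E, A0I, X0E, X0I, U0E, U0I).

All updates are strictly synchronous: every right-hand side is
evaluated at time t.
"""

from __future__ import annotations

import math

import numpy as np

from .params import NetworkParams, ParameterError
from .states import (
    IDX, EnsembleState, MicroState, StateError, Trajectory, as_omega,
    default_initial_state,
)

__all__ = [
    "activation", "activation_deriv", "step_mean_field", "step_stochastic",
    "step_microscopic", "population_average", "simulate", "iterate_mean_field",
]


def activation(h, T):
    """Firing probability ``g[h] = (1 + tanh(h / T)) / 2``.

    Strictly increasing in the input h, with g(-h) = 1 - g(h); T > 0 is
    the noise temperature (T -> 0 gives a hard threshold).
    """
    h = np.asarray(h, dtype=float)
    T = np.asarray(T, dtype=float)
    if not np.all(T > 0):
        raise ParameterError("noise temperature T must be > 0")
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(T))):
        raise ParameterError("activation input must be finite")
    out = 0.5 * (1.0 + np.tanh(h / T))
    return out if out.ndim else float(out)

def activation_deriv(h, T):
    """dg/dh = (beta / 2) (1 - tanh^2(beta h)), beta = 1/T."""
    h = np.asarray(h, dtype=float)
    th = np.tanh(h / T)
    out = 0.5 / T * (1.0 - th * th)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# macroscopic map
# ---------------------------------------------------------------------------

def step_mean_field(omega, params: NetworkParams):
    """One iteration of the macroscopic 8-D map.

    ``omega`` may be a MacroState, an 8-vector, or an array (..., 8) of
    states; parameter fields may be broadcastable arrays, so a whole
    parameter grid can be advanced in one call.
    """
    omega = as_omega(omega)
    mE, mI = omega[..., 0], omega[..., 1]
    AE, AI = omega[..., 2], omega[..., 3]
    XE, XI = omega[..., 4], omega[..., 5]
    UE, UI = omega[..., 6], omega[..., 7]

    hE = params.J_EE * AE + params.J_EI * AI + params.I_E
    hI = params.J_II * AI + params.J_IE * AE + params.I_I

    out = np.empty(np.broadcast_shapes(omega.shape[:-1],
                                       np.shape(hE), np.shape(hI)) + (8,))
    out[..., 0] = activation(hE, params.T_E)
    out[..., 1] = activation(hI, params.T_I)
    out[..., 2] = AE - AE / params.tau_a_E + mE * XE * UE / params.U_se_E
    out[..., 3] = AI - AI / params.tau_a_I + mI * XI * UI / params.U_se_I
    out[..., 4] = XE + (1.0 - XE) / params.tau_R_E - mE * XE * UE
    out[..., 5] = XI + (1.0 - XI) / params.tau_R_I - mI * XI * UI
    out[..., 6] = UE + (params.U_se_E - UE) / params.tau_F_E \
        + params.U_se_E * (1.0 - UE) * mE
    out[..., 7] = UI + (params.U_se_I - UI) / params.tau_F_I \
        + params.U_se_I * (1.0 - UI) * mI
    return out


def iterate_mean_field(omega0, params: NetworkParams, n_steps: int,
                       *, keep: bool = False):
    """Iterate the macroscopic map ``n_steps`` times from ``omega0``.

    Scalar parameter sets use a tight scalar loop (math ops on floats),
    which is what makes multi-million-step orbits for slice collection
    practical; array-shaped states or parameters fall back to the
    vectorised step.  Returns the final state, or the full ``(n, 8)``
    array of visited states (excluding omega0) when ``keep``.
    """
    omega0 = as_omega(omega0)
    scalar = omega0.shape == (8,) and all(
        np.ndim(getattr(params, f)) == 0
        for f in ("J_EE", "J_II", "J_EI", "J_IE", "I_E", "I_I"))
    if not scalar:
        out = np.empty((n_steps,) + omega0.shape) if keep else None
        omega = omega0
        for t in range(n_steps):
            omega = step_mean_field(omega, params)
            if keep:
                out[t] = omega
        return out if keep else omega

    p = params
    bE, bI = 1.0 / p.T_E, 1.0 / p.T_I
    ita_E, ita_I = 1.0 / p.tau_a_E, 1.0 / p.tau_a_I
    itR_E, itR_I = 1.0 / p.tau_R_E, 1.0 / p.tau_R_I
    itF_E, itF_I = 1.0 / p.tau_F_E, 1.0 / p.tau_F_I
    JEE, JII, JEI, JIE = p.J_EE, p.J_II, p.J_EI, p.J_IE
    IE, II = p.I_E, p.I_I
    useE, useI = p.U_se_E, p.U_se_I

    mE, mI, AE, AI, XE, XI, UE, UI = (float(v) for v in omega0)
    out = np.empty((n_steps, 8)) if keep else None
    tanh = math.tanh
    for t in range(n_steps):
        hE = JEE * AE + JEI * AI + IE
        hI = JII * AI + JIE * AE + II
        mE1 = 0.5 * (1.0 + tanh(bE * hE))
        mI1 = 0.5 * (1.0 + tanh(bI * hI))
        AE1 = AE - AE * ita_E + mE * XE * UE / useE
        AI1 = AI - AI * ita_I + mI * XI * UI / useI
        XE1 = XE + (1.0 - XE) * itR_E - mE * XE * UE
        XI1 = XI + (1.0 - XI) * itR_I - mI * XI * UI
        UE1 = UE + (useE - UE) * itF_E + useE * (1.0 - UE) * mE
        UI1 = UI + (useI - UI) * itF_I + useI * (1.0 - UI) * mI
        mE, mI, AE, AI, XE, XI, UE, UI = mE1, mI1, AE1, AI1, XE1, XI1, UE1, UI1
        if keep:
            out[t] = (mE, mI, AE, AI, XE, XI, UE, UI)
    if keep:
        return out
    return np.array([mE, mI, AE, AI, XE, XI, UE, UI])


# ---------------------------------------------------------------------------
# stochastic network
# ---------------------------------------------------------------------------

def _synaptic_field(state: EnsembleState, params: NetworkParams, xi: str):
    """Total input h_i for subnetwork xi (recurrent sum excludes j = i)."""
    eta = "I" if xi == "E" else "E"
    a_own = getattr(state, f"a_{xi}")
    a_other = getattr(state, f"a_{eta}")
    N_own = getattr(params, f"N_{xi}")
    N_other = getattr(params, f"N_{eta}")
    J_rec = getattr(params, f"J_{xi}{xi}") / N_own
    J_cross = (params.J_EI if xi == "E" else params.J_IE) / N_other
    I_ext = getattr(params, f"I_{xi}")
    # uniform weights J/N; the self term a_i is removed from the recurrent sum
    return J_rec * (a_own.sum() - a_own) + J_cross * a_other.sum() + I_ext


def _update_synapses(s, a, x, u, tau_a, tau_R, tau_F, U_se):
    release = s * x * u
    a1 = a - a / tau_a + release / U_se
    x1 = x + (1.0 - x) / tau_R - release
    u1 = u + (U_se - u) / tau_F + U_se * (1.0 - u) * s
    return a1, x1, u1


def step_stochastic(state: EnsembleState, params: NetworkParams,
                    rng: np.random.Generator) -> EnsembleState:
    """One synchronous update of the stochastic network.

    Spikes at t+1 are independent Bernoulli draws with probability
    g[h_i(t)]; the synapse variables are driven by the *previous* spikes
    s_i(t).  One uniform variate is drawn per neuron per step.
    """
    for xi in ("E", "I"):
        if int(getattr(params, f"N_{xi}")) < 1:
            raise ParameterError(f"N_{xi} must be >= 1 for the stochastic model")
    new = {}
    for xi in ("E", "I"):
        h = _synaptic_field(state, params, xi)
        p_fire = activation(h, getattr(params, f"T_{xi}"))
        s_new = (rng.random(len(h)) < p_fire).astype(float)
        a1, x1, u1 = _update_synapses(
            getattr(state, f"s_{xi}"), getattr(state, f"a_{xi}"),
            getattr(state, f"x_{xi}"), getattr(state, f"u_{xi}"),
            getattr(params, f"tau_a_{xi}"), getattr(params, f"tau_R_{xi}"),
            getattr(params, f"tau_F_{xi}"), getattr(params, f"U_se_{xi}"))
        new[xi] = (s_new, a1, x1, u1)
    return EnsembleState(*new["E"], *new["I"])


def population_average(state: EnsembleState) -> np.ndarray:
    """Population means of (s, a, x, u), ordered like Omega."""
    return np.array([
        state.s_E.mean(), state.s_I.mean(),
        state.a_E.mean(), state.a_I.mean(),
        state.x_E.mean(), state.x_I.mean(),
        state.u_E.mean(), state.u_I.mean(),
    ])


# ---------------------------------------------------------------------------
# microscopic mean field
# ---------------------------------------------------------------------------

def uniform_weights(params: NetworkParams) -> dict:
    """All-to-all weight tables J/N with zeroed diagonals for recurrence."""
    NE, NI = int(params.N_E), int(params.N_I)
    W = {
        "EE": np.full((NE, NE), params.J_EE / NE),
        "II": np.full((NI, NI), params.J_II / NI),
        "EI": np.full((NE, NI), params.J_EI / NI),
        "IE": np.full((NI, NE), params.J_IE / NE),
    }
    np.fill_diagonal(W["EE"], 0.0)
    np.fill_diagonal(W["II"], 0.0)
    return W


def step_microscopic(state: MicroState, params: NetworkParams,
                     weights: dict) -> MicroState:
    """One update of the per-neuron noise-averaged system.

    ``weights`` maps 'EE', 'II', 'EI', 'IE' to per-pair coupling tables;
    recurrent tables must already have zero diagonals (the recurrent sum
    excludes the self term).
    """
    NE, NI = len(state.m_E), len(state.m_I)
    for key, shape in (("EE", (NE, NE)), ("II", (NI, NI)),
                       ("EI", (NE, NI)), ("IE", (NI, NE))):
        if np.shape(weights[key]) != shape:
            raise ParameterError(
                f"weight table {key} must have shape {shape}, "
                f"got {np.shape(weights[key])}")
    hE = weights["EE"] @ state.A_E + weights["EI"] @ state.A_I + params.I_E
    hI = weights["II"] @ state.A_I + weights["IE"] @ state.A_E + params.I_I
    mE1 = activation(hE, params.T_E)
    mI1 = activation(hI, params.T_I)
    AE1, XE1, UE1 = _update_synapses(
        state.m_E, state.A_E, state.X_E, state.U_E,
        params.tau_a_E, params.tau_R_E, params.tau_F_E, params.U_se_E)
    AI1, XI1, UI1 = _update_synapses(
        state.m_I, state.A_I, state.X_I, state.U_I,
        params.tau_a_I, params.tau_R_I, params.tau_F_I, params.U_se_I)
    return MicroState(np.atleast_1d(mE1), AE1, XE1, UE1,
                      np.atleast_1d(mI1), AI1, XI1, UI1)


# ---------------------------------------------------------------------------
# unified simulation front end
# ---------------------------------------------------------------------------

def simulate(kind: str, params: NetworkParams, *, n_steps: int,
             transient: int = 0, initial=None, seed=None,
             weights: dict | None = None) -> Trajectory:
    """Run one of the three models and return the post-transient trajectory.

    ``kind`` is 'macroscopic', 'microscopic' or 'stochastic'.  The
    stored samples are macroscopic 8-vectors (population averages for
    the stochastic/microscopic models).  Stochastic runs are
    bit-reproducible for a fixed seed.
    """
    if not (n_steps > transient >= 0):
        raise ValueError("need n_steps > transient >= 0")
    n_keep = n_steps - transient

    if kind == "macroscopic":
        omega = as_omega(initial) if initial is not None \
            else default_initial_state(params)
        omega = iterate_mean_field(omega, params, transient) if transient \
            else omega.copy()
        data = np.empty((n_keep, 8))
        data[0] = omega
        if n_keep > 1:
            data[1:] = iterate_mean_field(omega, params, n_keep - 1, keep=True)
        return Trajectory(data, t0=transient, kind=kind, params=params)

    if kind == "stochastic":
        rng = np.random.default_rng(seed)
        state = initial if initial is not None else EnsembleState.quiescent(params)
        data = np.empty((n_keep, 8))
        for t in range(n_steps):
            if t >= transient:
                data[t - transient] = population_average(state)
            state = step_stochastic(state, params, rng)
        return Trajectory(data, t0=transient, kind=kind, seed=seed,
                          params=params)

    if kind == "microscopic":
        if weights is None:
            weights = uniform_weights(params)
        if initial is None:
            omega = default_initial_state(params)
            NE, NI = int(params.N_E), int(params.N_I)
            initial = MicroState(
                np.full(NE, omega[0]), np.full(NE, omega[2]),
                np.full(NE, omega[4]), np.full(NE, omega[6]),
                np.full(NI, omega[1]), np.full(NI, omega[3]),
                np.full(NI, omega[5]), np.full(NI, omega[7]))
        state = initial
        data = np.empty((n_keep, 8))
        for t in range(n_steps):
            if t >= transient:
                data[t - transient] = np.array([
                    state.m_E.mean(), state.m_I.mean(),
                    state.A_E.mean(), state.A_I.mean(),
                    state.X_E.mean(), state.X_I.mean(),
                    state.U_E.mean(), state.U_I.mean()])
            state = step_microscopic(state, params, weights)
        return Trajectory(data, t0=transient, kind=kind, params=params)

    raise ValueError(f"unknown model kind {kind!r}")
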