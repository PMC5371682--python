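"""State containers for the three model levels.

The macroscopic state is the 8-vector

    Omega = (m0E, m0I, A0E, A0I, X0E, X0I, U0E, U0I)

holding, per subnetwork, the mean activity m, the mean synaptic current
A, the mean releasable-resource fraction X and the mean calcium variable
U.  Throughout the package trajectories are plain ``(n, 8)`` float
arrays in this component order; :data:`OMEGA_LABELS` gives the column
names used in CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OMEGA_LABELS", "IDX", "MacroState", "EnsembleState", "MicroState",
    "Trajectory", "default_initial_state", "check_macro_bounds",
]

OMEGA_LABELS = ("m0E", "m0I", "A0E", "A0I", "X0E", "X0I", "U0E", "U0I")

#: Component name -> index into the macroscopic state vector.
IDX = {name: i for i, name in enumerate(OMEGA_LABELS)}


class StateError(ValueError):
    """Raised when a state violates a model invariant."""


@dataclass
class MacroState:
    """Named view of the macroscopic 8-vector."""

    m0E: float
    m0I: float
    A0E: float
    A0I: float
    X0E: float
    X0I: float
    U0E: float
    U0I: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in OMEGA_LABELS], dtype=float)

    @classmethod
    def from_array(cls, omega) -> "MacroState":
        omega = np.asarray(omega, dtype=float)
        if omega.shape != (8,):
            raise StateError(f"expected an 8-vector, got shape {omega.shape}")
        return cls(*omega.tolist())


def as_omega(state) -> np.ndarray:
    """Coerce a MacroState or array-like to a float array (..., 8)."""
    if isinstance(state, MacroState):
        return state.to_array()
    omega = np.asarray(state, dtype=float)
    if omega.shape[-1] != 8:
        raise StateError(f"last axis must have length 8, got {omega.shape}")
    return omega


def check_macro_bounds(omega, *, strict: bool = True) -> bool:
    """Verify the admissible-region invariants of a macroscopic state.

    m, X and U lie in [0, 1] and A >= 0.  With ``strict`` a violation
    raises :class:`StateError` (the map is never silently clamped:
    leaving the region indicates an inadmissible parameter set, e.g. a
    time constant below 1).
    """
    omega = as_omega(omega)
    m = omega[..., 0:2]
    A = omega[..., 2:4]
    XU = omega[..., 4:8]
    ok = (np.all(m >= 0) and np.all(m <= 1) and np.all(A >= 0)
          and np.all(XU >= 0) and np.all(XU <= 1)
          and np.all(np.isfinite(omega)))
    if strict and not ok:
        raise StateError(
            "state left the admissible region (m,X,U in [0,1], A >= 0); "
            "check parameter invariants (tau >= 1, U_se in (0,1])")
    return bool(ok)


@dataclass
class EnsembleState:
    """Per-neuron state of the stochastic network.

    Arrays are length ``N_E`` / ``N_I``: binary spikes ``s``, synaptic
    currents ``a >= 0``, resources ``x in [0,1]`` and calcium
    ``u in [0,1]``.
    """

    s_E: np.ndarray
    a_E: np.ndarray
    x_E: np.ndarray
    u_E: np.ndarray
    s_I: np.ndarray
    a_I: np.ndarray
    x_I: np.ndarray
    u_I: np.ndarray

    def __post_init__(self):
        for xi in ("E", "I"):
            n = len(getattr(self, f"s_{xi}"))
            for var in ("s", "a", "x", "u"):
                arr = np.asarray(getattr(self, f"{var}_{xi}"), dtype=float)
                if arr.shape != (n,):
                    raise StateError(
                        f"{var}_{xi} must be a length-{n} vector")
                setattr(self, f"{var}_{xi}", arr)

    @classmethod
    def quiescent(cls, params) -> "EnsembleState":
        """All-silent ensemble at the synaptic rest point (a=0, x=1, u=U_se)."""
        def sub(xi):
            n = int(getattr(params, f"N_{xi}"))
            use = getattr(params, f"U_se_{xi}")
            return (np.zeros(n), np.zeros(n), np.ones(n), np.full(n, use))
        sE, aE, xE, uE = sub("E")
        sI, aI, xI, uI = sub("I")
        return cls(sE, aE, xE, uE, sI, aI, xI, uI)


@dataclass
class MicroState:
    """Per-neuron noise-averaged state (m_i, A_i, X_i, U_i per subnetwork)."""

    m_E: np.ndarray
    A_E: np.ndarray
    X_E: np.ndarray
    U_E: np.ndarray
    m_I: np.ndarray
    A_I: np.ndarray
    X_I: np.ndarray
    U_I: np.ndarray

    def __post_init__(self):
        for name in ("m_E", "A_E", "X_E", "U_E", "m_I", "A_I", "X_I", "U_I"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass
class Trajectory:
    """Post-transient time course of the 8 macroscopic components.

    ``data`` has shape (n, 8) in :data:`OMEGA_LABELS` order; ``t0`` is
    the map-iteration index of the first stored sample.
    """

    data: np.ndarray
    t0: int = 0
    kind: str = "macroscopic"
    seed: Optional[int] = None
    params: Optional[object] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != 8:
            raise StateError("trajectory data must have 8 columns")
        if len(self.data) < 1:
            raise StateError("trajectory must contain at least one sample")

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[:, IDX[name]]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.data))

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.data, columns=list(OMEGA_LABELS))
        frame.insert(0, "t", self.t)
        return frame


def default_initial_state(params, *, perturbation: float = 1e-3) -> np.ndarray:
    """Default macroscopic initial condition.

    The synaptic rest point with the activities at their open-loop
    values: m = g[I] (the A=0 input), A = 0 plus a small perturbation to
    move off any exactly-invariant subspace, X = 1, U = U_se.
    """
    from .model import activation

    omega = np.empty(8)
    omega[IDX["m0E"]] = activation(params.I_E, params.T_E)
    omega[IDX["m0I"]] = activation(params.I_I, params.T_I)
    omega[IDX["A0E"]] = perturbation
    omega[IDX["A0I"]] = perturbation
    omega[IDX["X0E"]] = 1.0
    omega[IDX["X0I"]] = 1.0
    omega[IDX["U0E"]] = params.U_se_E
    omega[IDX["U0I"]] = params.U_se_I
    return omega
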