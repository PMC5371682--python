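"""Network parameters for the two-population model.

The network consists of an excitatory (E) and an inhibitory (I)
subnetwork of stochastic binary neurons coupled through dynamic synapses
(short-term depression via the releasable-resource variable x, and
facilitation via the presynaptic-calcium variable u).  All times are
measured in map iterations ("time steps"); every other quantity is
dimensionless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["NetworkParams", "SUBNETWORKS", "PARAM_FIELDS"]

SUBNETWORKS = ("E", "I")

#: Names of the per-run tunable fields (all accepted by ``replace``).
PARAM_FIELDS = (
    "T_E", "T_I",
    "J_EE", "J_II", "J_EI", "J_IE",
    "I_E", "I_I",
    "tau_a_E", "tau_a_I",
    "tau_R_E", "tau_R_I",
    "tau_F_E", "tau_F_I",
    "U_se_E", "U_se_I",
    "N_E", "N_I",
)


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


def _all(x) -> bool:
    return bool(np.all(x))


@dataclass(frozen=True)
class NetworkParams:
    """All constants of the two-subnetwork model.

    Fields may be scalars or (for vectorised parameter sweeps) numpy
    arrays with a common broadcastable shape.

    Parameters
    ----------
    T_E, T_I : float
        Noise temperature of each subnetwork; the inverse gain
        ``beta = 1/T`` of the sigmoidal activation.
    J_EE, J_II : float
        Recurrent coupling gains (the per-pair weight is ``J/N``).
    J_EI, J_IE : float
        Cross-coupling gains: ``J_EI`` scales input from I onto E,
        ``J_IE`` scales input from E onto I.
    I_E, I_I : float
        Constant external inputs.
    tau_a_E, tau_a_I : float
        Decay time constants of the synaptic current (>= 1).
    tau_R_E, tau_R_I : float
        Recovery time constants of the releasable resource (>= 1).
    tau_F_E, tau_F_I : float
        Facilitation (calcium) time constants (>= 1).
    U_se_E, U_se_I : float
        Baseline release fractions, in (0, 1].
    N_E, N_I : int
        Neuron counts (used by the stochastic and microscopic models).
    """

    T_E: float = 0.8
    T_I: float = 0.8
    J_EE: float = 0.0
    J_II: float = 0.0
    J_EI: float = 0.0
    J_IE: float = 0.0
    I_E: float = 0.0
    I_I: float = 0.0
    tau_a_E: float = 2.5
    tau_a_I: float = 2.5
    tau_R_E: float = 70.0
    tau_R_I: float = 70.0
    tau_F_E: float = 70.0 / 11.7
    tau_F_I: float = 70.0 / 11.7
    U_se_E: float = 0.1
    U_se_I: float = 0.1
    N_E: int = 10_000
    N_I: int = 10_000

    def __post_init__(self):
        for xi in SUBNETWORKS:
            if not _all(np.asarray(getattr(self, f"T_{xi}")) > 0):
                raise ParameterError(f"T_{xi} must be > 0")
            for tau in ("tau_a", "tau_R", "tau_F"):
                if not _all(np.asarray(getattr(self, f"{tau}_{xi}")) >= 1):
                    raise ParameterError(
                        f"{tau}_{xi} must be >= 1 (the update map leaves "
                        "the admissible region otherwise)")
            u = np.asarray(getattr(self, f"U_se_{xi}"))
            if not (_all(u > 0) and _all(u <= 1)):
                raise ParameterError(f"U_se_{xi} must lie in (0, 1]")
            if not _all(np.asarray(getattr(self, f"N_{xi}")) >= 1):
                raise ParameterError(f"N_{xi} must be >= 1")
        for name in PARAM_FIELDS:
            if not _all(np.isfinite(np.asarray(getattr(self, name), dtype=float))):
                raise ParameterError(f"{name} must be finite")

    # -- convenience -----------------------------------------------------

    @property
    def beta_E(self) -> float:
        return 1.0 / self.T_E

    @property
    def beta_I(self) -> float:
        return 1.0 / self.T_I

    @property
    def coupled(self) -> bool:
        """True when the E and I subnetworks interact."""
        return bool(np.any(np.asarray(self.J_EI) != 0)
                    or np.any(np.asarray(self.J_IE) != 0))

    def replace(self, **kwargs) -> "NetworkParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def sub(self, xi: str) -> dict:
        """Per-subnetwork constants as a plain dict (keys without suffix)."""
        if xi not in SUBNETWORKS:
            raise ValueError(f"subnetwork must be 'E' or 'I', got {xi!r}")
        return {
            "T": getattr(self, f"T_{xi}"),
            "J_rec": getattr(self, f"J_{xi}{xi}"),
            "J_cross": self.J_EI if xi == "E" else self.J_IE,
            "I": getattr(self, f"I_{xi}"),
            "tau_a": getattr(self, f"tau_a_{xi}"),
            "tau_R": getattr(self, f"tau_R_{xi}"),
            "tau_F": getattr(self, f"tau_F_{xi}"),
            "U_se": getattr(self, f"U_se_{xi}"),
            "N": getattr(self, f"N_{xi}"),
        }

    @classmethod
    def single(cls, xi: str, J0: float, I: float, tau_a: float, *,
               tau_ratio: float = 11.7, T: float = 0.8, U_se: float = 0.1,
               tau_R: float = 70.0, N: int = 10_000) -> "NetworkParams":
        """A single decoupled subnetwork (the other one is inert).

        ``tau_ratio`` is the depression/facilitation ratio tau_R/tau_F;
        tau_F is derived as ``tau_R / tau_ratio``.
        """
        tau_F = tau_R / tau_ratio
        kw = dict(
            T_E=T, T_I=T, U_se_E=U_se, U_se_I=U_se,
            tau_R_E=tau_R, tau_R_I=tau_R, tau_F_E=tau_F, tau_F_I=tau_F,
            J_EI=0.0, J_IE=0.0, N_E=N, N_I=N,
        )
        if xi == "E":
            kw.update(J_EE=J0, I_E=I, tau_a_E=tau_a,
                      J_II=0.0, I_I=0.0, tau_a_I=tau_a)
        elif xi == "I":
            kw.update(J_II=J0, I_I=I, tau_a_I=tau_a,
                      J_EE=0.0, I_E=0.0, tau_a_E=tau_a)
        else:
            raise ValueError(f"subnetwork must be 'E' or 'I', got {xi!r}")
        return cls(**kw)

    @classmethod
    def coupled_pair(cls, *, E: tuple, I: tuple, J_EI: float, J_IE: float,
                     tau_ratio: float = 11.7, T: float = 0.8,
                     U_se: float = 0.1, tau_R: float = 70.0,
                     N: int = 10_000) -> "NetworkParams":
        """Bidirectionally coupled subnetworks.

        ``E`` and ``I`` are (J0, I, tau_a) triples for the respective
        subnetwork, matching how parameter sets are usually quoted.
        """
        tau_F = tau_R / tau_ratio
        J0E, IE, taE = E
        J0I, II, taI = I
        return cls(
            T_E=T, T_I=T, U_se_E=U_se, U_se_I=U_se,
            tau_R_E=tau_R, tau_R_I=tau_R, tau_F_E=tau_F, tau_F_I=tau_F,
            J_EE=J0E, I_E=IE, tau_a_E=taE,
            J_II=J0I, I_I=II, tau_a_I=taI,
            J_EI=J_EI, J_IE=J_IE, N_E=N, N_I=N,
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_FIELDS}
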