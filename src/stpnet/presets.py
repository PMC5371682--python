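"""Named parameter presets for the studied regimes.

Each preset bundles a full parameter set with run defaults for one of
the reference regimes: the oscillatory excitatory (OSE) and inhibitory
(OSI) single networks, and the coupled-network states OS1C (single fast
frequency on a closed curve), OS2T (slow + fast on a two-torus,
continuous phase-amplitude coupling) and OS2C (slow + fast on a closed
curve, intermittent coupling).  All use noise temperature T = 0.8,
baseline release fraction U_se = 0.1, recovery constant tau_R = 70 and
depression-type synapses with tau_R/tau_F = 11.7; stochastic variants
use 10^4 neurons per subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import NetworkParams

__all__ = ["Preset", "load_presets", "get_preset"]


@dataclass(frozen=True)
class Preset:
    name: str
    params: NetworkParams
    description: str
    kind: str = "macroscopic"
    steps: int = 14_096
    transient: int = 10_000
    sweep: dict = field(default_factory=dict)


def load_presets() -> dict[str, Preset]:
    """Catalogue of named run configurations."""
    presets = {}

    def add(p: Preset):
        presets[p.name] = p

    add(Preset(
        "fig3B",
        NetworkParams.single("E", 2.0, -1.0, 2.5),
        "excitatory single network, J0 sweep through the OSE window "
        "(I, tau_a) = (-1, 2.5)",
        sweep={"param": "J_EE", "start": 0.0, "stop": 4.5, "num": 46}))
    add(Preset(
        "fig3C",
        NetworkParams.single("I", -5.0, 1.0, 2.5),
        "inhibitory single network, J0 sweep across the OSI onset "
        "(I, tau_a) = (1, 2.5)",
        sweep={"param": "J_II", "start": -6.0, "stop": 0.0, "num": 61}))
    add(Preset(
        "fig6E",
        NetworkParams.single("E", 2.0, -1.0, 2.5),
        "typical OSE state: slow oscillation of the excitatory network, "
        "(J0, I, tau_a) = (2, -1, 2.5)"))
    add(Preset(
        "fig6I",
        NetworkParams.single("I", -10.0, 1.0, 12.5),
        "typical OSI state: fast oscillation of the inhibitory network, "
        "(J0, I, tau_a) = (-10, 1, 12.5)"))
    coupled = dict(E=(2.0, -1.0, 2.5), I=(-10.0, 16.0, 12.5))
    add(Preset(
        "fig9",
        NetworkParams.coupled_pair(**coupled, J_EI=-0.15, J_IE=2.0),
        "OS1C state of the coupled network: fast oscillation only, "
        "closed-curve attractor, couplings (J_EI, J_IE) = (-0.15, 2)"))
    add(Preset(
        "fig10",
        NetworkParams.coupled_pair(**coupled, J_EI=-0.05, J_IE=2.0),
        "OS2T state: slow + fast oscillation on a two-torus (continuous "
        "CFC), couplings (J_EI, J_IE) = (-0.05, 2)"))
    add(Preset(
        "fig11",
        NetworkParams.coupled_pair(**coupled, J_EI=-0.05, J_IE=5.0),
        "OS2C state: slow + fast oscillation on a closed curve "
        "(intermittent CFC), couplings (J_EI, J_IE) = (-0.05, 5)"))
    return presets


def get_preset(name: str) -> Preset:
    presets = load_presets()
    if name not in presets:
        known = ", ".join(sorted(presets))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}")
    return presets[name]
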