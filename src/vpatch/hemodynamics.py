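"""Reduced-order lumen hemodynamics.

A deliberately simple stand-in for full 3-D CFD: the cross-section-
averaged Reynolds-number profile along the centerline and a comparative
pressure-drop estimate (distributed Poiseuille loss plus a Young/Tsai-
type turbulent constriction loss).  Intended for ranking reconstruction
scenarios, not for absolute pressure predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import CenterlineProfile
from .units import lpm


@dataclass
class FlowSpec:
    """Steady mean pulmonary flow and blood properties.

    Defaults: 4 L/min mean pulmonary flow; blood density 1060 kg/m^3 and
    viscosity 3.5 mPa*s (standard literature values for blood, which also
    reproduce the reported pre-operative peak Reynolds number).
    """

    flow_rate: float = lpm(4.0)    # m^3/s
    density: float = 1060.0        # kg/m^3
    viscosity: float = 3.5e-3      # Pa*s

    def __post_init__(self) -> None:
        for name in ("density", "viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be non-negative")


def reynolds_profile(profile: CenterlineProfile, flow: FlowSpec
                     ) -> np.ndarray:
    """Re(s) = rho * Q * D_eq / (mu * A) with D_eq = sqrt(4A/pi).

    Returns (S, 2) rows of (arclength, Re); the maximum sits at the
    minimum-area section.
    """
    A = profile.areas
    if np.any(A <= 0):
        raise ValueError("profile contains non-positive areas")
    d_eq = np.sqrt(4.0 * A / np.pi)
    re = flow.density * flow.flow_rate * d_eq / (flow.viscosity * A)
    return np.column_stack([profile.arclength, re])


def max_reynolds(profile: CenterlineProfile, flow: FlowSpec) -> float:
    return float(reynolds_profile(profile, flow)[:, 1].max())


def pressure_drop_estimate(profile: CenterlineProfile, flow: FlowSpec,
                           kt: float = 1.52) -> float:
    """Comparative pressure drop through the lumen, Pa.

    Distributed fully-developed (Poiseuille) loss integrated along the
    centerline plus a turbulent constriction loss
    ``kt/2 * rho * (A_ref/A_throat - 1)^2 * v_ref^2`` concentrated at the
    narrowest section, with the maximum cross-section as reference.
    Useful for ordering scenarios; not an absolute CFD value.
    """
    if flow.flow_rate == 0:
        return 0.0
    A = profile.areas
    s = profile.arclength
    d_eq = np.sqrt(4.0 * A / np.pi)
    v = flow.flow_rate / A
    dp_visc = float(np.trapezoid(32.0 * flow.viscosity * v / d_eq ** 2, s))
    a_ref = A.max()
    v_ref = flow.flow_rate / a_ref
    ratio = a_ref / A.min() - 1.0
    dp_turb = 0.5 * kt * flow.density * ratio ** 2 * v_ref ** 2
    return dp_visc + dp_turb
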