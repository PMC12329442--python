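"""Reference-like parameter presets used as simulator defaults and prior centers.

The presets are package fixtures: plausible five-process parameter sets that
produce human-shaped height and weight trajectories (adult stature around
165 cm for girls / 178 cm for boys, a pubertal velocity peak near age 12 /
14 since birth).  They are calibrated against textbook growth-reference
shapes, not against any fitted dataset, and exist so that simulations and
weakly informative priors have a sensible center.
"""

from __future__ import annotations

import numpy as np

from .growth_core import ComponentParams, CompositeParams
from .transforms import to_transformed

__all__ = ["reference_composite", "reference_theta"]


def _component(A: float, lam: float, q: float, i: float) -> ComponentParams:
    """Build a component from its asymptote A, decay rate lam = Kq/(1+2q),
    allometric exponent q and initiation age i."""
    K = lam * (1.0 + 2.0 * q) / q
    H = 0.5 * K * A**q
    return ComponentParams(H=H, K=K, q=q, i=i)


# (asymptote cm, decay rate 1/yr, q, initiation age since conception)
_PRESETS = {
    "F": [
        (70.0, 1.85, 0.55, 0.0),   # in utero
        (40.0, 0.55, 0.50, 0.5),   # infancy
        (27.0, 0.40, 0.50, 2.0),   # early childhood
        (10.0, 0.35, 0.45, 6.0),   # mid childhood
        (18.0, 0.70, 0.45, 11.8),  # puberty
    ],
    "M": [
        (71.0, 1.85, 0.55, 0.0),
        (42.0, 0.55, 0.50, 0.5),
        (29.0, 0.40, 0.50, 2.0),
        (12.0, 0.30, 0.45, 6.5),
        (22.0, 0.60, 0.45, 13.2),
    ],
}


def reference_composite(sex: str = "F") -> CompositeParams:
    """The reference-like five-process parameter set for the given sex."""
    try:
        rows = _PRESETS[sex]
    except KeyError:
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}") from None
    return CompositeParams(components=tuple(_component(*r) for r in rows))


def reference_theta(sex: str = "F") -> np.ndarray:
    """Transformed 19-vector of the reference preset (simulator mean /
    default prior center)."""
    return to_transformed(reference_composite(sex))
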