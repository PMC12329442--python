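"""Closed-form and ODE representations of composite von Bertalanffy growth.

The body is stylized as a cylinder of height ``h`` and radius ``r`` whose
substrate-absorbing (intestinal) surface is ``2*pi*r*h``.  Mass grows by the
Pütter / von Bertalanffy balance ``dm/dt = H*s - K*m`` — anabolism ``H``
(synthesized mass per unit absorbing surface per year) times surface, minus
catabolism ``K`` (destructed mass per unit mass per year) times mass.  With
the ontogenetic allometry ``r = h**q`` (0 < q < 1) this yields the height ODE

    dh/dt = h**(1-q) * ( 2H / (D*(1+2q)) - K * h**q / (1+2q) )

whose solution, for total age ``t`` (years since conception) at or after the
process initiation age ``i``, is

    h(t) = [ (2H/(D*K)) * (1 - exp(K*q/(1+2q) * (i - t))) ] ** (1/q)

with mass following exactly as ``m = D*pi*h**(1+2q)``.  Overall stature is
the Iverson-gated sum of five such component processes (in utero, infancy,
early childhood, mid-childhood, puberty), the first initiating at conception
(``i = 0``).  All ages in this package are *total* ages since conception;
birth sits at 0.75 yr on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ComponentParams",
    "CompositeParams",
    "PROCESS_LABELS",
    "component_height",
    "component_mass",
    "composite_height",
    "composite_mass",
    "height_velocity",
    "asymptotic_height",
    "radius_from_height",
    "ode_growth_rates",
]

#: Descriptive labels for the five component processes, by position.  The
#: labels name the ontogenetic phase in which each process typically
#: dominates; they are not constraints on the fitted parameters.
PROCESS_LABELS = ("in_utero", "infancy", "early_childhood", "mid_childhood", "puberty")


class GrowthDomainError(ValueError):
    """Raised when an evaluation leaves the model's numeric domain."""


@dataclass(frozen=True)
class ComponentParams:
    """Parameters of one component growth process.

    Parameters
    ----------
    H : float
        Anabolic rate, g·cm⁻²·yr⁻¹ (mass synthesized per unit absorbing
        surface per year).  Strictly positive.
    K : float
        Catabolic rate, yr⁻¹ (mass destructed per unit mass per year).
        Strictly positive.
    q : float
        Allometric exponent linking radius to height, ``r = h**q``;
        must lie in the open interval (0, 1).
    i : float
        Initiation age in total years since conception; nonnegative.
    """

    H: float
    K: float
    q: float
    i: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.H) and self.H > 0):
            raise ValueError(f"H must be finite and > 0, got {self.H!r}")
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValueError(f"K must be finite and > 0, got {self.K!r}")
        if not (np.isfinite(self.q) and 0.0 < self.q < 1.0):
            raise ValueError(f"q must lie in (0, 1), got {self.q!r}")
        if not (np.isfinite(self.i) and self.i >= 0):
            raise ValueError(f"i must be finite and >= 0, got {self.i!r}")


@dataclass(frozen=True)
class CompositeParams:
    """An individual's full trajectory: five ordered component processes.

    ``components[0]`` initiates at conception (``i == 0``) and components are
    ordered by nondecreasing initiation age.  ``D`` is tissue density in
    g·cm⁻³ (1 by default, matching the closed forms).
    """

    components: tuple[ComponentParams, ...]
    D: float = 1.0

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) != 5:
            raise ValueError(f"expected exactly 5 components, got {len(comps)}")
        if comps[0].i != 0.0:
            raise ValueError("components[0] must initiate at conception (i == 0)")
        ii = [c.i for c in comps]
        if any(b < a for a, b in zip(ii, ii[1:])):
            raise ValueError(f"initiation ages must be nondecreasing, got {ii}")
        if not (np.isfinite(self.D) and self.D > 0):
            raise ValueError(f"density D must be > 0, got {self.D!r}")

    @property
    def n_parameters(self) -> int:
        """Component-level parameter count (4 per process)."""
        return 4 * len(self.components)

    def with_component(self, index: int, p: ComponentParams) -> "CompositeParams":
        comps = list(self.components)
        comps[index] = p
        return replace(self, components=tuple(comps))


def _bracket(p: ComponentParams, t: np.ndarray, D: float) -> np.ndarray:
    """(2H/(DK))·(1 − e^{Kq/(1+2q)·(i−t)}) clamped at 0, gated to 0 for t<i."""
    rate = p.K * p.q / (1.0 + 2.0 * p.q)
    with np.errstate(over="raise"):
        try:
            expo = np.exp(rate * (p.i - np.asarray(t, dtype=float)))
        except FloatingPointError as err:  # pragma: no cover - defensive
            raise GrowthDomainError(
                f"overflow evaluating growth exponent for params {p}"
            ) from err
    # clamp absorbs float underflow at t ≈ i; gate enforces Iverson [t >= i]
    b = (2.0 * p.H / (D * p.K)) * np.clip(1.0 - expo, 0.0, None)
    return np.where(np.asarray(t, dtype=float) >= p.i, b, 0.0)


def component_height(p: ComponentParams, t, D: float = 1.0):
    """Height contribution (cm) of one component process at total age ``t``.

    Zero for ``t < i``; rises monotonically to the asymptote
    ``(2H/(DK))**(1/q)`` afterwards.  ``t`` may be a scalar or array.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("total age t must be >= 0")
    h = _bracket(p, t, D) ** (1.0 / p.q)
    if not np.all(np.isfinite(h)):
        raise GrowthDomainError(f"non-finite height for params {p}")
    return h if h.ndim else float(h)


def component_mass(p: ComponentParams, t, D: float = 1.0):
    """Mass contribution (g) of one component: ``D·π·h**(1+2q)``."""
    t = np.asarray(t, dtype=float)
    m = D * np.pi * _bracket(p, t, D) ** (1.0 / p.q + 2.0)
    if not np.all(np.isfinite(m)):
        raise GrowthDomainError(f"non-finite mass for params {p}")
    return m if m.ndim else float(m)


def composite_height(cp: CompositeParams, t):
    """Total height (cm): Iverson-gated sum of the five component heights."""
    t = np.asarray(t, dtype=float)
    h = sum(component_height(c, t, cp.D) for c in cp.components)
    return h if np.ndim(h) else float(h)


def composite_mass(cp: CompositeParams, t):
    """Total mass (g): sum of the five component masses."""
    t = np.asarray(t, dtype=float)
    m = sum(component_mass(c, t, cp.D) for c in cp.components)
    return m if np.ndim(m) else float(m)


def height_velocity(cp: CompositeParams, t):
    """Total height growth velocity dh/dt (cm·yr⁻¹) at total age ``t``.

    Each active component contributes its ODE right-hand side evaluated at
    its own current height; at ``t == i`` the contribution is the limit
    value 0 (valid since ``1 - q > 0``).
    """
    t = np.asarray(t, dtype=float)
    v = np.zeros_like(t, dtype=float)
    for c in cp.components:
        h = np.asarray(component_height(c, t, cp.D), dtype=float)
        denom = 1.0 + 2.0 * c.q
        with np.errstate(invalid="ignore"):
            term = h ** (1.0 - c.q) * (
                2.0 * c.H / (cp.D * denom) - (c.K / denom) * h**c.q
            )
        v += np.where(h > 0.0, term, 0.0)
    return v if v.ndim else float(v)


def asymptotic_height(p: ComponentParams, D: float = 1.0) -> float:
    """Asymptote (cm) of one component process: ``(2H/(DK))**(1/q)``."""
    return float((2.0 * p.H / (D * p.K)) ** (1.0 / p.q))


def radius_from_height(h, q: float):
    """Cylinder radius (cm) from height via the allometric law ``r = h**q``."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("height must be >= 0")
    r = h**q
    return r if r.ndim else float(r)


def ode_growth_rates(p: ComponentParams, h, D: float = 1.0):
    """Right-hand sides (dh/dt, dm/dt) of the growth ODEs at height ``h``.

    The mass rate is evaluated from the mass-form ODE

        dm/dt = (2H/D)·(Dπ)^{q/(2q+1)} · m^{(q+1)/(2q+1)} − K·m

    with ``m = D·π·h**(1+2q)``, consistent with the height form by the
    chain rule.  Used by the integration oracle in the test suite.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("height must be >= 0")
    denom = 1.0 + 2.0 * p.q
    with np.errstate(invalid="ignore"):
        dhdt = np.where(
            h > 0.0,
            h ** (1.0 - p.q) * (2.0 * p.H / (D * denom) - (p.K / denom) * h**p.q),
            0.0,
        )
    m = D * np.pi * h ** (1.0 + 2.0 * p.q)
    ex = p.q / (2.0 * p.q + 1.0)
    dmdt = np.where(
        m > 0.0,
        (2.0 * p.H / D) * (D * np.pi) ** ex * m ** ((p.q + 1.0) / (2.0 * p.q + 1.0))
        - p.K * m,
        0.0,
    )
    if dhdt.ndim:
        return dhdt, dmdt
    return float(dhdt), float(dmdt)
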