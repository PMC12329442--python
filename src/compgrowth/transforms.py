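"""Transformed-scale parameterization shared by the simulator and estimator.

Each individual's 20 natural parameters (H, K, q, i for five processes, with
i1 pinned to 0 at conception) map to a 19-vector on an unconstrained scale:

* ``ln H_1..5``               (anabolic rates, positive)
* ``ln K_1..5``               (catabolic rates, positive)
* ``logit q_1..5``            (allometric exponents, in (0, 1))
* ``ln d_2..5``               (initiation-age increments: i_x = i_{x-1} + d_x)

The cumulative-increment form of the initiation ages enforces the ordering
i1=0 < i2 < i3 < i4 < i5 by construction, which both matches the biology and
prevents label switching between processes during estimation.

Parameters are grouped into four *families* (H, K, q, i); multilevel offsets
covary across the five processes within a family but not across families.
"""

from __future__ import annotations

import numpy as np

from .growth_core import ComponentParams, CompositeParams

__all__ = [
    "FAMILIES",
    "FAMILY_SLICES",
    "N_TRANSFORMED",
    "PARAM_NAMES",
    "to_transformed",
    "from_transformed",
    "slot_index",
]

FAMILIES = ("H", "K", "q", "i")

#: Columns of the 19-vector occupied by each family.
FAMILY_SLICES = {
    "H": slice(0, 5),
    "K": slice(5, 10),
    "q": slice(10, 15),
    "i": slice(15, 19),
}

N_TRANSFORMED = 19

PARAM_NAMES = tuple(
    [f"log_H{x}" for x in range(1, 6)]
    + [f"log_K{x}" for x in range(1, 6)]
    + [f"logit_q{x}" for x in range(1, 6)]
    + [f"log_di{x}" for x in range(2, 6)]
)


def slot_index(family: str, process: int) -> int:
    """Column of the transformed vector for ``family`` (H/K/q/i) and 1-based
    ``process``.  For the i family the slot is the increment introducing
    ``i_process`` (process 2..5)."""
    if family not in FAMILIES:
        raise KeyError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if family == "i":
        if not 2 <= process <= 5:
            raise IndexError("i increments exist for processes 2..5 only")
        return FAMILY_SLICES["i"].start + (process - 2)
    if not 1 <= process <= 5:
        raise IndexError("process must be 1..5")
    return FAMILY_SLICES[family].start + (process - 1)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def to_transformed(cp: CompositeParams) -> np.ndarray:
    """Map natural composite parameters to the 19-vector transformed scale."""
    H = np.array([c.H for c in cp.components])
    K = np.array([c.K for c in cp.components])
    q = np.array([c.q for c in cp.components])
    i = np.array([c.i for c in cp.components])
    d = np.diff(i)
    if np.any(d <= 0):
        raise ValueError(
            "initiation ages must be strictly increasing to transform "
            f"(got {i.tolist()})"
        )
    return np.concatenate([np.log(H), np.log(K), _logit(q), np.log(d)])


def from_transformed(theta: np.ndarray, D: float = 1.0) -> CompositeParams:
    """Back-transform a 19-vector to natural-scale composite parameters."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (N_TRANSFORMED,):
        raise ValueError(f"expected shape ({N_TRANSFORMED},), got {theta.shape}")
    H = np.exp(theta[FAMILY_SLICES["H"]])
    K = np.exp(theta[FAMILY_SLICES["K"]])
    q = _expit(theta[FAMILY_SLICES["q"]])
    i = np.concatenate([[0.0], np.cumsum(np.exp(theta[FAMILY_SLICES["i"]]))])
    comps = tuple(
        ComponentParams(H=float(H[x]), K=float(K[x]), q=float(q[x]), i=float(i[x]))
        for x in range(5)
    )
    return CompositeParams(components=comps, D=D)


def natural_array(theta: np.ndarray) -> np.ndarray:
    """Vectorized back-transform: (..., 19) -> (..., 4, 5) natural values.

    Last-but-one axis indexes the family (H, K, q, i); the last the process.
    Used on whole posterior draw arrays where building ``CompositeParams``
    objects per draw would be wasteful.
    """
    theta = np.asarray(theta, dtype=float)
    H = np.exp(theta[..., FAMILY_SLICES["H"]])
    K = np.exp(theta[..., FAMILY_SLICES["K"]])
    q = _expit(theta[..., FAMILY_SLICES["q"]])
    d = np.exp(theta[..., FAMILY_SLICES["i"]])
    i = np.concatenate(
        [np.zeros(theta.shape[:-1] + (1,)), np.cumsum(d, axis=-1)], axis=-1
    )
    return np.stack([H, K, q, i], axis=-2)
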