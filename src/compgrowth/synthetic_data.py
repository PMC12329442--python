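"""Simulation of growth-parameter populations and measurement datasets.

The generator mirrors the statistical structure the estimator assumes: each
person's 19 transformed parameters are a baseline mean plus a group-level
offset plus an individual offset, with individual offsets drawn from
family-wise multivariate normals (one 5x5 covariance each for H, K, q and a
4x4 for the initiation-age increments — offsets covary across processes
within a family, not across families).  Observations are lognormal around
the model trajectory with the egg-cell offsets of the measurement model:

    ln h_obs ~ Normal( ln(0.012 + h(t)),      sigma_eta )
    ln m_obs ~ Normal( ln(1.02e-6 + m(t)),    sigma_mu  )

Two measurement designs are emulated:

* ``dense`` — an identical deterministic grid per person: birth (total age
  0.75), quarterly through age two, then annually to total age 18.75
  (roughly 25 measurements, ~33 after carry-forward to 26);
* ``sparse`` — 1-3 measurements per person at integer ages since birth
  drawn uniformly from 1..24, with counts from the mixture
  P(1,2,3) = (0.70, 0.29, 0.01), reproducing a 70% singleton share and a
  mean of 1.31 measurements per person.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_prep import (
    EGG_HEIGHT_CM,
    EGG_WEIGHT_G,
    GESTATION_YR,
    MeasurementRecord,
    PreparedDataset,
    prepare_dataset,
    records_to_frame,
)
from .growth_core import CompositeParams, composite_height, composite_mass
from .presets import reference_theta
from .transforms import FAMILIES, FAMILY_SLICES, N_TRANSFORMED, from_transformed

__all__ = [
    "PopulationConfig",
    "ScheduleDesign",
    "PopulationDraw",
    "SPARSE_COUNT_PROBS",
    "default_covariances",
    "draw_population",
    "make_schedule",
    "simulate_measurements",
    "simulate_study",
    "prepare_study",
]

#: Mixture over measurements-per-person in the sparse design.
SPARSE_COUNT_PROBS = (0.70, 0.29, 0.01)

#: Default individual-offset SDs on the transformed scale, per family.
_DEFAULT_OFFSET_SD = {"H": 0.04, "K": 0.04, "q": 0.04, "i": 0.05}


def default_covariances(scale: Optional[dict] = None) -> dict[str, np.ndarray]:
    """Diagonal per-family covariance matrices for individual offsets."""
    sds = dict(_DEFAULT_OFFSET_SD)
    if scale:
        sds.update(scale)
    out = {}
    for fam in FAMILIES:
        p = FAMILY_SLICES[fam].stop - FAMILY_SLICES[fam].start
        out[fam] = np.eye(p) * sds[fam] ** 2
    return out


def _check_psd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T):
        raise ValueError(f"covariance {name} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError(f"covariance {name} is not positive semi-definite")


@dataclass
class PopulationConfig:
    """True population structure for simulation.

    ``mu`` is the 19-vector of transformed-scale baseline means (log H, log
    K, logit q, log initiation increments); ``group_offsets`` maps group
    label -> 19-vector added to the baseline; ``covs`` maps family -> PSD
    covariance of individual offsets; ``group_sizes`` maps group -> number
    of persons; ``sigma_h`` / ``sigma_w`` are log-scale measurement SDs.
    """

    mu: np.ndarray = None
    group_offsets: dict = None
    covs: dict = None
    group_sizes: dict = None
    sigma_h: float = 0.03
    sigma_w: float = 0.08
    sex: str = "F"
    seed: int = 0
    D: float = 1.0

    def __post_init__(self) -> None:
        if self.mu is None:
            self.mu = reference_theta(self.sex)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (N_TRANSFORMED,):
            raise ValueError(f"mu must have shape ({N_TRANSFORMED},)")
        if self.group_sizes is None:
            self.group_sizes = {"reference": 30}
        if self.group_offsets is None:
            self.group_offsets = {g: np.zeros(N_TRANSFORMED) for g in self.group_sizes}
        self.group_offsets = {
            g: np.asarray(v, dtype=float) for g, v in self.group_offsets.items()
        }
        for g in self.group_sizes:
            self.group_offsets.setdefault(g, np.zeros(N_TRANSFORMED))
        if self.covs is None:
            self.covs = default_covariances()
        for fam in FAMILIES:
            sl = FAMILY_SLICES[fam]
            mat = np.asarray(self.covs[fam], dtype=float)
            if mat.shape != (sl.stop - sl.start,) * 2:
                raise ValueError(f"covariance for family {fam} has wrong shape")
            _check_psd(mat, fam)
            self.covs[fam] = mat
        if not (self.sigma_h > 0 and self.sigma_w > 0):
            raise ValueError("measurement SDs must be positive")
        # mean-implied initiation ages are ordered by construction (positive
        # increments); make sure the increments are finite
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite")


@dataclass
class ScheduleDesign:
    """Measurement-age design: ``dense`` (fixed grid) or ``sparse``."""

    kind: str = "dense"
    dense_ages: Optional[np.ndarray] = None
    sparse_age_range: tuple[int, int] = (1, 24)
    count_probs: Sequence[float] = SPARSE_COUNT_PROBS

    def __post_init__(self) -> None:
        if self.kind not in ("dense", "sparse"):
            raise ValueError("kind must be 'dense' or 'sparse'")
        if self.dense_ages is None:
            quarterly = np.arange(1.0, 2.75 + 1e-9, 0.25)
            annual = np.arange(3.75, 18.75 + 1e-9, 1.0)
            self.dense_ages = np.concatenate([[GESTATION_YR], quarterly, annual])
        self.dense_ages = np.asarray(self.dense_ages, dtype=float)
        if np.any(np.diff(self.dense_ages) <= 0):
            raise ValueError("dense ages must be strictly increasing")
        probs = np.asarray(self.count_probs, dtype=float)
        if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-12 or np.any(probs < 0):
            raise ValueError("count_probs must be 3 nonnegative values summing to 1")


@dataclass
class PopulationDraw:
    """True parameters drawn for a simulated population."""

    persons: list  # CompositeParams per person
    thetas: np.ndarray  # (n_persons, 19) transformed
    person_groups: list  # group label per person
    config: PopulationConfig


def draw_population(
    cfg: PopulationConfig, rng: Optional[np.random.Generator] = None
) -> PopulationDraw:
    """Draw per-person composite parameters from the multilevel structure.

    For person j in group g, transformed parameters are
    ``mu + group_offsets[g] + u_j`` with ``u_j`` stacked from independent
    family-wise multivariate normals, then back-transformed to the natural
    scale (i1 is 0 by construction of the increment parameterization).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    # eigen square root tolerates PSD-singular (e.g. all-zero) covariances
    chols = {}
    for fam in FAMILIES:
        w, v = np.linalg.eigh(cfg.covs[fam])
        chols[fam] = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    persons: list[CompositeParams] = []
    thetas: list[np.ndarray] = []
    groups: list[str] = []
    for g, n in cfg.group_sizes.items():
        base = cfg.mu + cfg.group_offsets[g]
        for _ in range(n):
            theta = base.copy()
            for fam in FAMILIES:
                sl = FAMILY_SLICES[fam]
                z = rng.standard_normal(sl.stop - sl.start)
                theta[sl] += chols[fam] @ z
            thetas.append(theta)
            persons.append(from_transformed(theta, D=cfg.D))
            groups.append(g)
    return PopulationDraw(
        persons=persons,
        thetas=np.array(thetas),
        person_groups=groups,
        config=cfg,
    )


def make_schedule(
    design: ScheduleDesign,
    n_persons: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[np.ndarray]:
    """Per-person sorted total-age measurement lists for a design."""
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    if design.kind == "dense":
        return [design.dense_ages.copy() for _ in range(n_persons)]
    rng = np.random.default_rng(seed) if rng is None else rng
    counts = rng.choice([1, 2, 3], size=n_persons, p=np.asarray(design.count_probs))
    lo, hi = design.sparse_age_range
    ages_sb = np.arange(lo, hi + 1)
    out = []
    for c in counts:
        picked = rng.choice(ages_sb, size=c, replace=False)
        out.append(np.sort(picked) + GESTATION_YR)
    return out


def simulate_measurements(
    persons: Sequence[CompositeParams],
    schedules: Sequence[np.ndarray],
    sigma_h: float,
    sigma_w: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    person_groups: Optional[Sequence[str]] = None,
    sex: str = "F",
    person_ids: Optional[Sequence[str]] = None,
) -> list[MeasurementRecord]:
    """Draw lognormal height and weight observations on the given schedules.

    Both modalities are observed at every scheduled age.  Observations carry
    the egg-cell offsets inside the log-mean, exactly as the estimator's
    likelihood assumes.
    """
    if not (sigma_h > 0 and sigma_w > 0):
        raise ValueError("measurement SDs must be positive")
    if len(persons) != len(schedules):
        raise ValueError("need one schedule per person")
    rng = np.random.default_rng(seed) if rng is None else rng
    groups = person_groups if person_groups is not None else ["reference"] * len(persons)
    ids = (
        list(person_ids)
        if person_ids is not None
        else [f"p{k:05d}" for k in range(len(persons))]
    )
    records: list[MeasurementRecord] = []
    for pid, grp, cp, ages in zip(ids, groups, persons, schedules):
        h = np.atleast_1d(composite_height(cp, ages))
        m = np.atleast_1d(composite_mass(cp, ages))
        ln_h = rng.normal(np.log(EGG_HEIGHT_CM + h), sigma_h)
        ln_m = rng.normal(np.log(EGG_WEIGHT_G + m), sigma_w)
        for t, lh, lm in zip(ages, ln_h, ln_m):
            records.append(
                MeasurementRecord(
                    person_id=pid,
                    group=grp,
                    sex=sex,
                    t=float(t),
                    height_cm=float(np.exp(lh)),
                    weight_g=float(np.exp(lm)),
                    provenance="observed",
                )
            )
    return records


def simulate_study(
    cfg: PopulationConfig,
    designs: Optional[dict] = None,
    seed: Optional[int] = None,
) -> tuple[list[MeasurementRecord], PopulationDraw]:
    """Draw a population and a full measurement dataset in one call.

    ``designs`` maps group label -> :class:`ScheduleDesign` (default: dense
    for every group).  The single ``seed`` (default ``cfg.seed``) drives the
    population draw, the schedules and the measurement noise.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pop = draw_population(cfg, rng=rng)
    designs = designs or {}
    schedules: list[np.ndarray] = []
    for k, g in enumerate(pop.person_groups):
        design = designs.get(g, ScheduleDesign(kind="dense"))
        schedules.extend(make_schedule(design, 1, rng=rng))
    records = simulate_measurements(
        pop.persons,
        schedules,
        cfg.sigma_h,
        cfg.sigma_w,
        rng=rng,
        person_groups=pop.person_groups,
        sex=cfg.sex,
        person_ids=[f"{g}_{k:04d}" for k, g in enumerate(pop.person_groups)],
    )
    return records, pop


def prepare_study(
    records: Sequence[MeasurementRecord],
    designs: Optional[dict] = None,
    carry_forward_to: float = 26.0,
) -> PreparedDataset:
    """Prepare a mixed-design dataset with per-group augmentation.

    Conception anchors are added for everyone; the last-value carry-forward
    (to ``carry_forward_to`` years since birth) is applied *only* to groups
    whose design is dense — duplicating a sparse person's single childhood
    measurement into adulthood would poison the likelihood.
    """
    frame = records_to_frame(records)
    designs = designs or {}
    dense_groups = {
        g for g in frame["group"].unique()
        if designs.get(g, ScheduleDesign(kind="dense")).kind == "dense"
    }
    parts = []
    for g, sub in frame.groupby("group", sort=False):
        prepared = prepare_dataset(
            sub,
            add_conception=True,
            carry_forward_to=carry_forward_to if g in dense_groups else None,
        )
        parts.append(prepared.frame)
    import pandas as pd

    combined = pd.concat(parts, ignore_index=True)
    return prepare_dataset(combined, add_conception=False, carry_forward_to=None)
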