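"""Organ volumes, effective orbital volume and IREOV.

The outcome statistic implemented here is the *increase rate of effective
orbital volume* (IREOV).  With V_orb the orbital volume, V_org the summed
volume of the contained organs (by default the four rectus muscles, the
superior rectus measured together with the levator palpebrae as one
complex), and pre/post denoting the surgical timepoints:

    IREOV = [(V_orb_post - V_org_post) - (V_orb_pre - V_org_pre)] / V_orb_pre

The parenthesized terms are the *effective orbital volume* — the orbital
space not occupied by the organs.  IREOV is dimensionless; dividing by the
preoperative orbital volume normalizes for the intrinsic size of the
orbit.  Negative values are admissible and indicate a net loss of effective
space (e.g., muscle expansion outpacing the bony decompression).

Orbital-volume convention
-------------------------
A labelmap assigns one label per voxel, so the orbital cavity label cannot
spatially overlap the organ labels.  The orbital volume is therefore
computed as the union of the cavity label and all soft-tissue organ labels
present in the schema (globe, recti, optic nerve).  With this convention
the organs are part of the orbital volume, the sum of organ volumes never
exceeds it, and adding a rigid organ to the accounting set cancels exactly
in the IREOV numerator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import schema as sc
from .labelmap import LabelMap

DEFAULT_ORGAN_SET: tuple[str, ...] = sc.RECTUS_ROLES


class VolumetryError(ValueError):
    pass


class DataQualityWarning(UserWarning):
    """Measurement is computable but violates an expected anatomical relation."""


@dataclass(frozen=True)
class OrbitMeasurement:
    """Per-orbit, per-timepoint volumes in mm^3."""

    orbit_id: str
    timepoint: str  # "pre" | "post"
    orbital_volume: float
    organ_volumes: dict[str, float]
    organ_set: tuple[str, ...] = DEFAULT_ORGAN_SET

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise VolumetryError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")
        vols = [self.orbital_volume, *self.organ_volumes.values()]
        if not all(np.isfinite(v) and v >= 0 for v in vols):
            raise VolumetryError("volumes must be finite and non-negative")
        missing = [r for r in self.organ_set if r not in self.organ_volumes]
        if missing:
            raise VolumetryError(f"organ_set roles missing from organ_volumes: {missing}")

    @property
    def total_organ_volume(self) -> float:
        return float(sum(self.organ_volumes[r] for r in self.organ_set))


@dataclass(frozen=True)
class IreovResult:
    """IREOV for one orbit, with the per-muscle volume changes feeding it."""

    orbit_id: str
    orbital_volume_pre: float
    organ_volume_pre: float
    orbital_volume_post: float
    organ_volume_post: float
    ireov: float
    muscle_delta: dict[str, float] = field(default_factory=dict)
    organ_set: tuple[str, ...] = DEFAULT_ORGAN_SET


def organ_volume(labelmap: LabelMap, role: str) -> float:
    """Volume (mm^3) of one anatomical role: voxel count x voxel volume."""
    mask = labelmap.organ_mask(role)
    return float(np.count_nonzero(mask.data)) * labelmap.voxel_volume


def orbital_volume(labelmap: LabelMap) -> float:
    """Orbital volume (mm^3): cavity plus contained soft-tissue organs."""
    roles = [sc.ORBITAL_CAVITY] + [r for r in sc.SOFT_TISSUE_ROLES
                                   if r in labelmap.schema.roles]
    return float(np.count_nonzero(labelmap.union_mask(roles).data)) * labelmap.voxel_volume


def measure_orbit(labelmap: LabelMap, organ_set=DEFAULT_ORGAN_SET, *,
                  orbit_id: str = "orbit", timepoint: str = "pre") -> OrbitMeasurement:
    """Measure the orbital volume and each organ volume of one labelmap.

    ``organ_set`` controls which organs enter the IREOV accounting
    (default: the four rectus roles); all organs are measured regardless.
    Emits :class:`DataQualityWarning` if an organ is spatially disconnected
    from the orbital region.
    """
    for role in (sc.ORBITAL_CAVITY, *organ_set):
        labelmap.schema.label(role)  # raises if absent

    organ_roles = [r for r in sc.SOFT_TISSUE_ROLES if r in labelmap.schema.roles]
    vols = {r: organ_volume(labelmap, r) for r in set(organ_roles) | set(organ_set)}
    v_orb = orbital_volume(labelmap)
    _check_containment(labelmap, organ_set)
    return OrbitMeasurement(orbit_id, timepoint, v_orb, vols, tuple(organ_set))


def _check_containment(labelmap: LabelMap, organ_set) -> None:
    """Warn if any accounted organ is disconnected from the orbital region."""
    roles = [sc.ORBITAL_CAVITY] + [r for r in sc.SOFT_TISSUE_ROLES
                                   if r in labelmap.schema.roles]
    union = labelmap.union_mask(roles).data
    if not union.any():
        return
    comp, n = ndimage.label(union)
    if n == 1:
        return
    cavity = labelmap.organ_mask(sc.ORBITAL_CAVITY).data
    cavity_comps = set(np.unique(comp[cavity])) - {0}
    for role in organ_set:
        m = labelmap.organ_mask(role).data
        outside = np.count_nonzero(m & ~np.isin(comp, list(cavity_comps)))
        if outside:
            warnings.warn(
                f"{role}: {outside} voxels disconnected from the orbital cavity",
                DataQualityWarning, stacklevel=3,
            )


def effective_orbital_volume(m: OrbitMeasurement) -> float:
    """V_orb minus the summed organ volumes of the measurement's organ set."""
    eff = m.orbital_volume - m.total_organ_volume
    if eff < 0:
        warnings.warn(
            f"{m.orbit_id} ({m.timepoint}): organ volumes exceed orbital volume",
            DataQualityWarning, stacklevel=2,
        )
    return eff


def ireov(pre: OrbitMeasurement, post: OrbitMeasurement) -> IreovResult:
    """Increase rate of effective orbital volume between two measurements."""
    if pre.orbit_id != post.orbit_id:
        raise VolumetryError(f"orbit mismatch: {pre.orbit_id!r} vs {post.orbit_id!r}")
    if pre.organ_set != post.organ_set:
        raise VolumetryError("pre and post measurements use different organ sets")
    if (pre.timepoint, post.timepoint) != ("pre", "post"):
        raise VolumetryError("arguments must be (pre, post) measurements")
    if pre.orbital_volume <= 0:
        raise VolumetryError("preoperative orbital volume must be > 0")

    eff_pre = pre.orbital_volume - pre.total_organ_volume
    eff_post = post.orbital_volume - post.total_organ_volume
    value = (eff_post - eff_pre) / pre.orbital_volume
    delta = {r: post.organ_volumes[r] - pre.organ_volumes[r]
             for r in pre.organ_set}
    return IreovResult(
        orbit_id=pre.orbit_id,
        orbital_volume_pre=pre.orbital_volume,
        organ_volume_pre=pre.total_organ_volume,
        orbital_volume_post=post.orbital_volume,
        organ_volume_post=post.total_organ_volume,
        ireov=value,
        muscle_delta=delta,
        organ_set=pre.organ_set,
    )


def muscle_change_table(results: list[IreovResult]) -> pd.DataFrame:
    """Per-muscle volume-change summary and its association with IREOV.

    For each muscle role in the (shared) organ set: mean and sample SD of
    the volume change across orbits, plus the Spearman rank correlation of
    that change with IREOV.  Correlations of constant change vectors are
    undefined and reported as NaN.
    """
    if len(results) < 3:
        raise VolumetryError("need at least 3 results for a change table")
    organ_set = results[0].organ_set
    if any(r.organ_set != organ_set for r in results):
        raise VolumetryError("results use different organ sets")

    vals = np.array([r.ireov for r in results])
    rows = []
    for role in organ_set:
        dv = np.array([r.muscle_delta[role] for r in results])
        if np.ptp(dv) == 0 or np.ptp(vals) == 0:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(dv, vals)
        rows.append({
            "muscle": role,
            "mean_delta_mm3": float(dv.mean()),
            "sd_delta_mm3": float(dv.std(ddof=1)),
            "spearman_rho_vs_ireov": float(rho),
            "p_value": float(p),
        })
    return pd.DataFrame(rows).set_index("muscle")
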