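"""Muscle-hypertrophy vs fat-hyperplasia phenotype calls.

Clinically, orbitopathy patients are grouped by whether enlarged extraocular
muscles or expanded orbital fat dominates the crowding.  No numeric
criterion for that grouping is standardized, so the rule here is an
explicit, user-supplied configuration: the statistic is the preoperative
total rectus volume divided by the orbital volume, and the threshold has
deliberately **no default** — supplying one is a clinical judgement this
package refuses to make.  Calls at exactly the threshold go to
muscle hypertrophy (MH) by the default tie policy.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import schema as sc
from .volumetry import OrbitMeasurement


class PhenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeRule:
    """Thresholded muscle/orbit volume-ratio rule for MH vs FH calls."""

    threshold: float
    statistic: str = "rectus_orbit_ratio"
    tie_policy: str = "MH"  # call at exactly the threshold

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise PhenotypeError("threshold must be > 0")
        if self.statistic != "rectus_orbit_ratio":
            raise PhenotypeError(f"unknown statistic {self.statistic!r}")
        if self.tie_policy not in ("MH", "FH"):
            raise PhenotypeError("tie_policy must be 'MH' or 'FH'")


@dataclass(frozen=True)
class PhenotypeCall:
    orbit_id: str
    statistic: float
    call: str  # "MH" | "FH"
    rule: PhenotypeRule


def classify_phenotype(m: OrbitMeasurement, rule: PhenotypeRule) -> PhenotypeCall:
    """Classify a preoperative orbit as MH or FH under an explicit rule."""
    if m.orbital_volume <= 0:
        raise PhenotypeError("orbital volume must be > 0")
    missing = [r for r in sc.RECTUS_ROLES if r not in m.organ_volumes]
    if missing:
        raise PhenotypeError(f"rectus volumes missing: {missing}")
    stat = sum(m.organ_volumes[r] for r in sc.RECTUS_ROLES) / m.orbital_volume
    if stat > rule.threshold:
        call = "MH"
    elif stat < rule.threshold:
        call = "FH"
    else:
        call = rule.tie_policy
    return PhenotypeCall(orbit_id=m.orbit_id, statistic=float(stat), call=call, rule=rule)
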