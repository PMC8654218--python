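"""Thermodynamic-cycle algebra on leg estimates.

A cycle links two legs simulated in different receptor states (inactive
R, active R*) into an experimentally meaningful double difference ΔΔG.
Sign conventions are fixed once, package-wide:

========================  =========================================  ==========================
quantity                  definition                                 positive value means
========================  =========================================  ==========================
conformational
selectivity               ΔΔG_cs = ΔG_b,R* − ΔG_b,R                  the first-named ligand of
                                                                     the transformation (the
                                                                     agonist, by convention the
                                                                     FEP start species) prefers
                                                                     the active state
basal-activity shift      ΔΔG_R*→R = ΔG_m,R* − ΔG_m,R                the mutation destabilizes
                                                                     the active state
                                                                     (constitutively inactive
                                                                     mutation, lower basal
                                                                     activity)
efficacy shift            ΔΔG_EC50 = ΔG_m,R*+L − ΔG_m,R              efficacy/potency LOSS upon
                                                                     mutation; negative values
                                                                     predict a potency gain
========================  =========================================  ==========================

Uncertainties propagate by independent-error quadrature: legs come from
independent sets of simulations.  Composition refuses legs whose
annotations (state, environment, transformation label) do not match the
cycle template rather than silently reordering them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from fepcycles.energetics import LegEstimate
from fepcycles.errors import CompositionError, FepInputError


@dataclass(frozen=True)
class CycleResult:
    """A composed ΔΔG with its component legs and propagated SEM.

    ``decomposition`` (efficacy shifts only, when the shared apo-active
    leg is supplied) maps term names to ``(value, sem)`` pairs whose
    values sum to ``ddg`` exactly.
    """

    kind: str                       # selectivity | basal_shift | efficacy_shift
    ddg: float
    sem: float | None
    components: dict = field(default_factory=dict)
    decomposition: dict | None = None

    def qualitative_call(self, significance: float = 2.0) -> str:
        """Human-readable interpretation under the package sign table."""
        if self.sem is not None and abs(self.ddg) <= significance * self.sem:
            return "not significant"
        pos = self.ddg > 0
        return {
            "selectivity": ("agonist prefers active state" if pos
                            else "agonist prefers inactive state"),
            "basal_shift": ("active state destabilized (CIM-like)" if pos
                            else "active state stabilized"),
            "efficacy_shift": ("efficacy/potency loss" if pos
                               else "efficacy/potency gain"),
        }[self.kind]


def _quad_sem(*legs: LegEstimate) -> float | None:
    sems = [leg.sem_dg for leg in legs]
    if any(s is None for s in sems):
        return None
    return math.sqrt(sum(s * s for s in sems))


def conformational_selectivity(leg_active: LegEstimate,
                               leg_inactive: LegEstimate) -> CycleResult:
    """ΔΔG_cs = ΔG_b,R* − ΔG_b,R for one ligand transformation.

    Both legs must be the same ligand-bound transformation, simulated
    in the active (R*) and inactive (R) receptor respectively.  A
    positive result means the FEP start species (the agonist, by
    convention) selects for the active conformation.
    """
    if leg_active.state_label != "Rstar" or leg_inactive.state_label != "R":
        raise CompositionError(
            "selectivity needs an R* leg and an R leg, got "
            f"{leg_active.state_label!r} / {leg_inactive.state_label!r}")
    if leg_active.transformation != leg_inactive.transformation:
        raise CompositionError(
            f"transformation labels differ: {leg_active.transformation!r} "
            f"vs {leg_inactive.transformation!r}")
    if leg_active.environment != "bound" or leg_inactive.environment != "bound":
        raise CompositionError("selectivity legs must both be ligand-bound")
    return CycleResult(
        kind="selectivity",
        ddg=leg_active.mean_dg - leg_inactive.mean_dg,
        sem=_quad_sem(leg_active, leg_inactive),
        components={"active": leg_active, "inactive": leg_inactive})


def basal_activity_shift(mut_leg_active_apo: LegEstimate,
                         mut_leg_inactive_apo: LegEstimate) -> CycleResult:
    """ΔΔG_R*→R = ΔG_m,R* − ΔG_m,R for one mutation (apo receptor).

    Both legs are the same side-chain perturbation (e.g. wt→Ala
    annihilation) in the empty receptor.  A positive result means the
    mutation selectively destabilizes the active state — constitutively
    inactive mutation (CIM) behaviour, reduced basal activity.
    """
    if (mut_leg_active_apo.state_label != "Rstar"
            or mut_leg_inactive_apo.state_label != "R"):
        raise CompositionError(
            "basal shift needs an R* leg and an R leg, got "
            f"{mut_leg_active_apo.state_label!r} / "
            f"{mut_leg_inactive_apo.state_label!r}")
    if mut_leg_active_apo.transformation != mut_leg_inactive_apo.transformation:
        raise CompositionError(
            "mutation labels differ: "
            f"{mut_leg_active_apo.transformation!r} vs "
            f"{mut_leg_inactive_apo.transformation!r}")
    if (mut_leg_active_apo.environment != "apo"
            or mut_leg_inactive_apo.environment != "apo"):
        raise CompositionError("basal-shift legs must both be apo")
    return CycleResult(
        kind="basal_shift",
        ddg=mut_leg_active_apo.mean_dg - mut_leg_inactive_apo.mean_dg,
        sem=_quad_sem(mut_leg_active_apo, mut_leg_inactive_apo),
        components={"active_apo": mut_leg_active_apo,
                    "inactive_apo": mut_leg_inactive_apo})


def efficacy_shift(mut_leg_bound_active: LegEstimate,
                   mut_leg_apo_inactive: LegEstimate,
                   mut_leg_apo_active: LegEstimate | None = None
                   ) -> CycleResult:
    """Combined-cycle efficacy shift ΔΔG_EC50 = ΔG_m,R*+L − ΔG_m,R.

    The two mandatory legs are the mutation perturbation in the
    ligand-bound active receptor (R*+L) and in the apo inactive
    receptor (R).  When the shared apo-active leg ΔG_m,R* is supplied,
    the result is decomposed into a basal-activity term
    (ΔG_m,R* − ΔG_m,R) and a ligand-affinity term
    (ΔG_m,R*+L − ΔG_m,R*); the two terms sum to ``ddg`` exactly because
    the shared leg cancels.  Negative ``ddg`` predicts a potency gain
    for the ligand upon mutation.
    """
    legs = [mut_leg_bound_active, mut_leg_apo_inactive]
    if mut_leg_apo_active is not None:
        legs.append(mut_leg_apo_active)
    labels = {leg.transformation for leg in legs}
    if len(labels) != 1:
        raise CompositionError(f"inconsistent mutation labels: {sorted(labels)}")
    if (mut_leg_bound_active.state_label != "Rstar"
            or mut_leg_bound_active.environment != "bound"):
        raise CompositionError("first leg must be bound/R* (ΔG_m,R*+L)")
    if (mut_leg_apo_inactive.state_label != "R"
            or mut_leg_apo_inactive.environment != "apo"):
        raise CompositionError("second leg must be apo/R (ΔG_m,R)")
    components = {"bound_active": mut_leg_bound_active,
                  "apo_inactive": mut_leg_apo_inactive}
    ddg = mut_leg_bound_active.mean_dg - mut_leg_apo_inactive.mean_dg
    decomposition = None
    if mut_leg_apo_active is not None:
        if (mut_leg_apo_active.state_label != "Rstar"
                or mut_leg_apo_active.environment != "apo"):
            raise CompositionError("shared leg must be apo/R* (ΔG_m,R*)")
        components["apo_active"] = mut_leg_apo_active
        basal = (mut_leg_apo_active.mean_dg
                 - mut_leg_apo_inactive.mean_dg)
        affinity = (mut_leg_bound_active.mean_dg
                    - mut_leg_apo_active.mean_dg)
        # the shared leg cancels analytically; defining ddg as the term
        # sum keeps basal + affinity == ddg bit-for-bit (the direct
        # difference can disagree by one ulp)
        ddg = basal + affinity
        decomposition = {
            "basal": (basal,
                      _quad_sem(mut_leg_apo_active, mut_leg_apo_inactive)),
            "ligand_affinity": (affinity,
                                _quad_sem(mut_leg_bound_active,
                                          mut_leg_apo_active)),
        }
    return CycleResult(
        kind="efficacy_shift",
        ddg=ddg,
        sem=_quad_sem(mut_leg_bound_active, mut_leg_apo_inactive),
        components=components,
        decomposition=decomposition)


def cycle_closure(legs: list[tuple[LegEstimate, int]]) -> float:
    """Signed sum of leg free energies around a (nominally closed) cycle.

    For a true thermodynamic cycle the state function ΔG sums to zero;
    the returned residual measures how well sampled legs close it.
    Requires at least three legs.
    """
    if len(legs) < 3:
        raise FepInputError("a cycle needs at least three legs")
    for _, sign in legs:
        if sign not in (1, -1):
            raise FepInputError("signs must be +1 or -1")
    # fsum: exact telescoping cancellation for closed cycles
    return math.fsum(sign * leg.mean_dg for leg, sign in legs)
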