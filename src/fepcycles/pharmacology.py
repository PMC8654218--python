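"""Experimental pharmacology on the free-energy scale.

Converts fitted pharmacology readouts (E_max as % of a reference full
agonist, EC50) into the quantities the thermodynamic cycles predict,
and scores qualitative concordance between calculated ΔΔG values and
experimental efficacy differences.

Orientation convention for EC50 shifts: ΔΔG = RT·ln(EC50_mut/EC50_wt),
so a potency gain upon mutation (smaller mutant EC50) gives a negative
value — the same orientation as the cycle module's efficacy shift,
where negative means predicted potency gain.

The EC50 conversion defaults to T = 298.15 K (RT = 0.59248 kcal/mol),
the standard laboratory condition of the assays being converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from fepcycles.cycles import CycleResult
from fepcycles.energetics import R_KCAL
from fepcycles.errors import FepInputError

#: Default assay temperature for EC50 conversions (K).
ASSAY_TEMPERATURE = 298.15

PROFILES = ("full_agonist", "partial_agonist", "neutral_antagonist")


@dataclass(frozen=True)
class PharmRecord:
    """One ligand/receptor-variant pharmacology measurement.

    ``emax_percent`` is relative to the reference full agonist of the
    assay (e.g. NECA or CGS21680 set to 100%).
    """

    ligand: str
    receptor_variant: str = "wt"
    emax_percent: float = 0.0
    emax_sem: float = 0.0
    ec50: float | None = None           # nM
    profile: str | None = None

    def __post_init__(self):
        if self.emax_sem < 0:
            raise FepInputError("emax_sem must be >= 0")
        if self.ec50 is not None and self.ec50 <= 0:
            raise FepInputError("ec50 must be positive when present")
        if self.profile is not None and self.profile not in PROFILES:
            raise FepInputError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class ComparisonPair:
    """A calculated cycle result matched with an experimental Δ-efficacy.

    ``delta_efficacy`` is E_max(agonist) − E_max(antagonist) of the
    matched chemotype pair, in %, with its SEM.
    """

    calc: CycleResult
    delta_efficacy: float
    delta_sem: float
    label: str = ""


def ec50_shift_to_ddg(ec50_wt: float, ec50_mut: float,
                      temperature: float = ASSAY_TEMPERATURE) -> float:
    """Mutation-induced EC50 shift on the free-energy scale.

    Returns RT·ln(EC50_mut/EC50_wt) in kcal/mol: negative for a
    potency gain (smaller mutant EC50).  Scale-invariant in the common
    concentration unit and exactly antisymmetric under swapping the
    two arguments.
    """
    if ec50_wt <= 0 or ec50_mut <= 0:
        raise FepInputError("EC50 values must be positive")
    # difference-of-logs form makes antisymmetry under argument swap exact
    return R_KCAL * temperature * (math.log(ec50_mut) - math.log(ec50_wt))


def delta_efficacy(ago: PharmRecord, antago: PharmRecord
                   ) -> tuple[float, float]:
    """Δ-efficacy = E_max,ago − E_max,antago (%, SEM by quadrature).

    Both records must refer to the same receptor variant.
    """
    if ago.receptor_variant != antago.receptor_variant:
        raise FepInputError(
            f"receptor variants differ: {ago.receptor_variant!r} vs "
            f"{antago.receptor_variant!r}")
    value = ago.emax_percent - antago.emax_percent
    sem = math.sqrt(ago.emax_sem ** 2 + antago.emax_sem ** 2)
    return value, sem


def classify_profile(record: PharmRecord, z_threshold: float = 2.0,
                     full_agonist_cutoff: float = 80.0) -> str:
    """Classify a ligand from its relative E_max.

    ``neutral_antagonist`` when E_max is indistinguishable from 0
    (|E_max| ≤ z·SEM), ``full_agonist`` when E_max ≥ the cutoff
    (default 80%), ``partial_agonist`` otherwise.  Both thresholds are
    configuration; only the neutral-antagonist criterion is a fixed
    pharmacological definition.
    """
    if abs(record.emax_percent) <= z_threshold * record.emax_sem:
        return "neutral_antagonist"
    if record.emax_percent >= full_agonist_cutoff:
        return "full_agonist"
    return "partial_agonist"


def concordance(pairs: list[ComparisonPair], significance: float = 2.0
                ) -> tuple[float, list[dict]]:
    """Qualitative agreement between calculated ΔΔG and Δ-efficacy.

    A pair is concordant when the calculated ΔΔG and the experimental
    Δ-efficacy agree in sign and the calculation is significant
    (|ΔΔG| > significance·SEM), or when both are indistinguishable
    from zero by the same rule.  Returns the concordant fraction and a
    per-pair call table.
    """
    if not pairs:
        raise FepInputError("concordance needs at least one pair")
    calls = []
    n_concordant = 0
    for p in pairs:
        calc_sem = p.calc.sem if p.calc.sem is not None else 0.0
        calc_null = abs(p.calc.ddg) <= significance * calc_sem
        exp_null = abs(p.delta_efficacy) <= significance * p.delta_sem
        if calc_null and exp_null:
            ok = True
            reason = "both null"
        elif calc_null != exp_null:
            ok = False
            reason = "one null, one significant"
        else:
            ok = math.copysign(1, p.calc.ddg) == math.copysign(
                1, p.delta_efficacy)
            reason = "sign match" if ok else "sign mismatch"
        n_concordant += ok
        calls.append({"label": p.label, "ddg": p.calc.ddg, "sem": p.calc.sem,
                      "delta_efficacy": p.delta_efficacy,
                      "delta_sem": p.delta_sem,
                      "concordant": bool(ok), "reason": reason})
    return n_concordant / len(pairs), calls
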