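"""Ionisation state and pH-dependent distribution coefficients.

Weak acids and bases interconvert between neutral and charged species
according to the Henderson-Hasselbalch relation; only the neutral (unionised)
species is assumed to cross membranes and to partition into lipid. The
fraction unionised at a given pH is

    acids:  f_un = 1 / (1 + 10^(pH − pKa))
    bases:  f_un = 1 / (1 + 10^(pKa − pH))

and the distribution coefficient of the equilibrium mixture follows as
LogD(pH) = LogP + log10(f_un).

An optional ionisation correction of the plasma fraction unbound is provided
for use as input to milk protein-binding predictors: increased ionisation
reduces binding to plasma proteins, so the bound:free ratio K = (1 − fu)/fu is
shifted on the log10 scale in proportion to the change in ionised fraction
between plasma and milk pH, with a per-charge-class coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .records import DrugRecord

__all__ = [
    "dominant_pka",
    "fraction_unionised",
    "logd_at_ph",
    "IonisationBindingAdjustment",
    "adjust_fup_for_ionisation",
]


def dominant_pka(drug: DrugRecord, ph_ref: float = 7.4) -> float:
    """Single pKa governing ionisation near ``ph_ref``.

    Multiprotic drugs are collapsed onto the dissociation nearest
    physiological pH; microstate speciation is out of scope.
    """
    if not drug.pka_values:
        raise ValidationError(
            f"{drug.name}: no pKa available for ionisable class {drug.charge_class!r}"
        )
    return min(drug.pka_values, key=lambda p: abs(p - ph_ref))


def _hh_branch(drug: DrugRecord) -> str:
    if drug.charge_class in ("acid", "base"):
        return drug.charge_class
    # zwitterions: user-declared branch, defaulting to the acidic group
    return drug.hh_class or "acid"


def fraction_unionised(drug: DrugRecord, ph: float) -> float:
    """Fraction of drug in its neutral species at ``ph``.

    Neutral drugs return exactly 1. Zwitterions use the declared
    Henderson-Hasselbalch branch with the pKa nearest physiological pH.
    """
    if drug.charge_class == "neutral":
        return 1.0
    pka = dominant_pka(drug)
    if _hh_branch(drug) == "acid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def logd_at_ph(drug: DrugRecord, ph: float) -> float:
    """LogD of the species mixture at ``ph``: LogP + log10(f_unionised)."""
    if drug.logp is None:
        raise ValidationError(f"{drug.name}: LogP is required to compute LogD")
    return drug.logp + float(np.log10(fraction_unionised(drug, ph)))


@dataclass(frozen=True)
class IonisationBindingAdjustment:
    """Configuration of the ionisation correction to fu_p.

    ``class_coefficients`` maps charge class to the log10 shift of the
    bound:free ratio per unit increase in ionised fraction. Negative values
    encode "more ionised ⇒ less protein-bound". The defaults are deliberately
    modest (an order of magnitude of binding lost on full ionisation) and are
    configuration surface, not fitted constants; see the methods note.
    """

    enabled: bool = True
    class_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "acid": -1.0,
            "base": -1.0,
            "zwitterion": -0.5,
            "neutral": 0.0,
        }
    )


def adjust_fup_for_ionisation(
    fu_p: float,
    drug: DrugRecord,
    ph: float,
    config: IonisationBindingAdjustment | None = None,
    ph_plasma: float = 7.4,
) -> float:
    """Adjust fu_p for the change in ionisation between plasma and ``ph``.

    Identity when ``config`` is None or disabled. The adjusted value is the
    fraction unbound implied by shifting log10((1 − fu)/fu) by
    ``coef · (f_ion(ph) − f_ion(ph_plasma))``. Output stays in (0, 1] and is
    monotone non-decreasing in ``fu_p`` at fixed class.
    """
    if not 0.0 < fu_p <= 1.0:
        raise ValidationError(f"{drug.name}: fu_p must be in (0, 1], got {fu_p}")
    if config is None or not config.enabled:
        return fu_p
    try:
        coef = config.class_coefficients[drug.charge_class]
    except KeyError:
        warnings.warn(
            f"{drug.name}: no ionisation-binding coefficient for class "
            f"{drug.charge_class!r}; fu_p left unadjusted",
            stacklevel=2,
        )
        return fu_p
    if coef == 0.0 or drug.charge_class == "neutral":
        return fu_p
    d_ion = (1.0 - fraction_unionised(drug, ph)) - (
        1.0 - fraction_unionised(drug, ph_plasma)
    )
    if fu_p == 1.0:
        return 1.0  # no bound fraction to release
    log_k = np.log10((1.0 - fu_p) / fu_p) + coef * d_ion
    return float(1.0 / (1.0 + 10.0**log_k))
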