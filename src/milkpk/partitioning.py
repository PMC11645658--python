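"""Milk protein binding, milk-fat partitioning, and the skim:whole ratio.

Whole milk is treated as a two-compartment matrix: an aqueous (skim) phase in
which the drug is partly protein-bound, and a lipid (cream) phase occupying a
volume fraction equal to the creamatocrit. Only the unbound drug in skim milk
is available to partition into the lipid, with apparent partition coefficient
Papp_milk, so mass balance over a unit volume of whole milk gives

    C_whole = (1 − Crt)·C_skim + Crt·(fu_m · Papp_milk · C_skim)
    S/W     = C_skim / C_whole = 1 / (1 + Crt·(fu_m·Papp_milk − 1))

Three published regressions predict the milk fraction unbound fu_m from the
plasma fraction unbound (Atkinson/Begg saturating isotherm, the Ito linear
form, and the Yang form which adds a polar-surface-area term), and six
alternative formulae predict Papp_milk from LogP or LogD at milk pH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, UnknownModelError, ValidationError
from .physchem import logd_at_ph
from .records import DrugRecord

__all__ = [
    "PAPP_MODELS",
    "FUM_MODELS",
    "PappModel",
    "FumModel",
    "fum_atkinson_begg",
    "fum_ito",
    "fum_yang",
    "papp_milk",
    "skim_to_whole",
]

PAPP_MODELS = (
    "phase_distribution",
    "logpow",
    "abi",
    "mcdb",
    "bartels_logp",
    "bartels_logd",
)
FUM_MODELS = ("atkinson_begg", "ito", "yang")

# Default coefficients of each Papp_milk formula, keyed by model name. These
# are published fits reused verbatim, exposed so alternative parenthesisation
# readings of the source equations can be explored without code changes.
_PAPP_DEFAULTS: dict[str, dict[str, float]] = {
    "phase_distribution": {"intercept": -0.88, "slope": 1.29},
    "logpow": {},
    "abi": {"slope": 0.4017, "intercept": 0.1548},
    "mcdb": {"a": 7.489, "b": 5.327, "c": 0.1153},
    "bartels_logp": {"floor": -4.653, "span": 7.972, "x0": 0.1175, "k": 0.2849},
    "bartels_logd": {"floor": -4.653, "span": 7.972, "x0": 0.1175, "k": 0.2849},
}


@dataclass(frozen=True)
class PappModel:
    """A named milk-fat partitioning formula with (overridable) coefficients."""

    name: str
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in PAPP_MODELS:
            raise UnknownModelError(
                f"unknown Papp model {self.name!r}; valid names: {', '.join(PAPP_MODELS)}"
            )

    def coef(self) -> dict[str, float]:
        merged = dict(_PAPP_DEFAULTS[self.name])
        merged.update(self.coefficients)
        return merged


@dataclass(frozen=True)
class FumModel:
    """A named milk protein-binding predictor.

    ``ionisation_adjusted`` flags that the fu_p fed to the predictor should
    first be corrected for the ionisation difference between plasma and milk.
    """

    name: str
    ionisation_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.name not in FUM_MODELS:
            raise UnknownModelError(
                f"unknown fu_m model {self.name!r}; valid names: {', '.join(FUM_MODELS)}"
            )


def _check_fup(fu_p: float) -> None:
    if fu_p <= 0:
        raise DomainError(f"fu_p must be positive, got {fu_p}")


def _clamp_fraction(value: float, what: str) -> float:
    """Clamp a predicted fraction unbound into (0, 1]; fractions cannot exceed 1."""
    if value > 1.0:
        warnings.warn(f"{what} = {value:.4f} > 1 clamped to 1", stacklevel=3)
        return 1.0
    if value <= 0.0:
        warnings.warn(f"{what} = {value:.4f} <= 0 clamped to eps", stacklevel=3)
        return np.finfo(float).tiny
    return value


def fum_atkinson_begg(fu_p: float) -> float:
    """Milk fraction unbound from the saturating-isotherm regression.

    fu_m = fu_p^0.448 / ((6.94e-4)^0.448 + fu_p^0.448); strictly increasing in
    fu_p and bounded in (0, 1).
    """
    _check_fup(fu_p)
    t = fu_p**0.448
    return t / ((6.94e-4) ** 0.448 + t)


def fum_ito(fu_p: float) -> float:
    """Linear milk-binding regression fu_m = 0.4956·fu_p + 0.5335, clamped to <= 1."""
    _check_fup(fu_p)
    return _clamp_fraction(0.4956 * fu_p + 0.5335, "fum_ito")


def fum_yang(fu_p: float, psa: float) -> float:
    """Milk binding with a polar-surface-area term.

    fu_m = 1.033·fu_p/(0.988 + fu_p) + 0.1017·ln(PSA), clamped to (0, 1].
    """
    _check_fup(fu_p)
    if psa is None or psa <= 1:
        raise ValidationError(f"Yang fu_m model requires PSA > 1 Å², got {psa}")
    return _clamp_fraction(1.033 * fu_p / (0.988 + fu_p) + 0.1017 * np.log(psa), "fum_yang")


def papp_milk(model: PappModel, drug: DrugRecord, ph_milk: float) -> float:
    """Apparent milk-fat:skim partition coefficient under ``model``.

    LogD-based formulae evaluate LogD at milk pH. The ``logpow`` variant
    returns LogP itself (a literal re-implementation of a published model that
    conflates the coefficient with its logarithm); it can therefore be
    negative, which is preserved and warned about rather than clipped.
    """
    if drug.logp is None:
        raise ValidationError(f"{drug.name}: LogP is required for Papp_milk")
    c = model.coef()
    name = model.name
    if name == "phase_distribution":
        logd = logd_at_ph(drug, ph_milk)
        return 10.0 ** (c["intercept"] + c["slope"] * logd)
    if name == "logpow":
        if drug.logp < 0:
            warnings.warn(
                f"{drug.name}: logpow model yields negative Papp ({drug.logp}); "
                "propagating literally",
                stacklevel=2,
            )
        return drug.logp
    if name == "abi":
        logd = logd_at_ph(drug, ph_milk)
        return 10.0 ** (c["slope"] * logd + c["intercept"])
    if name == "mcdb":
        return 10.0 ** (c["a"] - c["b"] * np.exp(-c["c"] * drug.logp))
    if name in ("bartels_logp", "bartels_logd"):
        x = drug.logp if name == "bartels_logp" else logd_at_ph(drug, ph_milk)
        log_papp = c["floor"] + c["span"] / (1.0 + 10.0 ** (c["x0"] - c["k"] * x))
        return 10.0**log_papp
    raise UnknownModelError(name)  # pragma: no cover - guarded in PappModel


def skim_to_whole(crt: float, fu_m: float, papp: float) -> float:
    """Skim-to-whole milk concentration ratio, S/W = 1/(1 + Crt·(fu_m·Papp − 1)).

    Equals 1 when there is no lipid phase (Crt = 0) or when the lipid is
    equipotent with the aqueous phase (fu_m·Papp = 1); below 1 when the lipid
    concentrates drug. A non-positive denominator (possible only for negative
    Papp from the logpow model) is a domain error, surfaced not clipped.
    """
    denom = 1.0 + crt * (fu_m * papp - 1.0)
    if denom <= 0:
        raise DomainError(
            f"skim-to-whole denominator {denom:.4g} <= 0 "
            f"(crt={crt}, fu_m={fu_m:.4g}, papp={papp:.4g}); negative Papp "
            "from the logpow model is the usual cause"
        )
    return 1.0 / denom
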