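"""Steady-state milk-to-plasma ratio engines and the model registry.

Two engines are provided.

**Phase engine.** The unbound, unionised drug equilibrates between plasma
water and milk water, so the skim-phase concentration ratio is
(fu_p·f_un,p)/(fu_m·f_un,m); dividing by the skim-to-whole ratio converts it
to a whole-milk M/P:

    M/P = fu_p·f_un,p / (fu_m·f_un,m) · (1 + Crt·(fu_m·Papp − 1))

The named model variants differ only in how Papp_milk and fu_m are predicted.

**Log-transformed engine.** Empirical log-linear regressions fitted
separately to acidic and basic drugs:

    acids:  ln M/P = −0.405 + 9.36·ln(f_un,p/f_un,m) − 0.69·ln fu_p − 1.54·ln K
    bases:  ln M/P = 0.02477 + 2.28·ln(f_un,p/f_un,m) + 0.886·ln fu_p + 0.505·ln K

with the whole-milk capacity term K = (1 − Crt)·fu_m + Crt·Papp_milk, fu_m
from the Atkinson/Begg isotherm and Papp from the phase-distribution LogD
regression. There is no formula for neutral drugs; they raise
:class:`~milkpk.errors.UnsupportedDrugClassError`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, UnknownModelError, UnsupportedDrugClassError, ValidationError
from .partitioning import (
    FumModel,
    PappModel,
    fum_atkinson_begg,
    fum_ito,
    fum_yang,
    papp_milk,
    skim_to_whole,
)
from .physchem import IonisationBindingAdjustment, adjust_fup_for_ionisation, fraction_unionised
from .records import DrugRecord, MilkComposition

__all__ = [
    "ModelSpec",
    "predict_mp",
    "predict_mp_phase",
    "predict_mp_log_transformed",
    "registry",
    "get_model",
]

# Log-transformed engine coefficients: (intercept, ionisation, ln fu_p, ln K)
_LOGT_COEFS = {
    "acid": (-0.405, 9.36, -0.69, -1.54),
    "base": (0.02477, 2.28, 0.886, 0.505),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named, fully-determined M/P model variant.

    ``engine`` selects the phase or log-transformed formulation; the phase
    engine further needs a :class:`PappModel` and :class:`FumModel`.
    ``use_observed_fum`` substitutes a measured milk fraction unbound for the
    predicted one when the drug record carries it (an explicit per-run switch,
    never a silent default). ``k_literal`` switches the log-transformed K term
    to the literal reading 1 − Crt·fu_m + Crt·Papp.
    """

    name: str
    engine: str = "phase"
    papp_model: PappModel | None = None
    fum_model: FumModel = FumModel("atkinson_begg")
    use_observed_fum: bool = False
    ionisation_config: IonisationBindingAdjustment | None = None
    k_literal: bool = False

    def __post_init__(self) -> None:
        if self.engine not in ("phase", "log_transformed"):
            raise UnknownModelError(f"unknown engine {self.engine!r}")
        if self.engine == "phase" and self.papp_model is None:
            raise ValidationError(f"{self.name}: phase engine requires a Papp model")


def _predict_fum(drug: DrugRecord, milk: MilkComposition, spec: ModelSpec) -> float:
    if spec.use_observed_fum and drug.observed_fum is not None:
        return drug.observed_fum
    fu_p = drug.fu_p
    if fu_p is None:
        raise ValidationError(f"{drug.name}: fu_p is required")
    if spec.fum_model.ionisation_adjusted:
        cfg = spec.ionisation_config or IonisationBindingAdjustment()
        fu_p = adjust_fup_for_ionisation(
            fu_p, drug, milk.ph_milk, cfg, ph_plasma=milk.ph_plasma
        )
    if spec.fum_model.name == "atkinson_begg":
        return fum_atkinson_begg(fu_p)
    if spec.fum_model.name == "ito":
        return fum_ito(fu_p)
    return fum_yang(fu_p, drug.psa)


def predict_mp_phase(
    drug: DrugRecord, milk: MilkComposition, spec: ModelSpec
) -> float:
    """Whole-milk M/P ratio from the phase-distribution equilibrium."""
    if spec.engine != "phase":
        raise ValidationError(f"{spec.name}: engine is {spec.engine!r}, not 'phase'")
    if drug.fu_p is None or drug.logp is None:
        raise ValidationError(f"{drug.name}: fu_p and LogP are required")
    f_un_p = fraction_unionised(drug, milk.ph_plasma)
    f_un_m = fraction_unionised(drug, milk.ph_milk)
    fu_m = _predict_fum(drug, milk, spec)
    papp = papp_milk(spec.papp_model, drug, milk.ph_milk)
    try:
        sw = skim_to_whole(milk.crt, fu_m, papp)
    except DomainError as exc:
        raise DomainError(f"model {spec.name!r}: {exc}") from exc
    skim_ratio = (drug.fu_p * f_un_p) / (fu_m * f_un_m)
    return skim_ratio / sw


def predict_mp_log_transformed(
    drug: DrugRecord, milk: MilkComposition, spec: ModelSpec | None = None
) -> float:
    """Whole-milk M/P from the class-specific log-linear regressions."""
    spec = spec or get_model("log_transformed")
    branch = drug.charge_class
    if branch not in _LOGT_COEFS:
        raise UnsupportedDrugClassError(
            f"{drug.name}: the log-transformed model has no formula for "
            f"{drug.charge_class!r} drugs"
        )
    if drug.fu_p is None or drug.logp is None:
        raise ValidationError(f"{drug.name}: fu_p and LogP are required")
    f_un_p = fraction_unionised(drug, milk.ph_plasma)
    f_un_m = fraction_unionised(drug, milk.ph_milk)
    fu_m = _predict_fum(drug, milk, spec)
    papp = papp_milk(PappModel("phase_distribution"), drug, milk.ph_milk)
    if spec.k_literal:
        k = 1.0 - milk.crt * fu_m + milk.crt * papp
    else:
        k = (1.0 - milk.crt) * fu_m + milk.crt * papp
    c0, c_ion, c_fup, c_k = _LOGT_COEFS[branch]
    ln_mp = (
        c0
        + c_ion * np.log(f_un_p / f_un_m)
        + c_fup * np.log(drug.fu_p)
        + c_k * np.log(k)
    )
    return float(np.exp(ln_mp))


def predict_mp(drug: DrugRecord, milk: MilkComposition, spec: ModelSpec) -> float:
    """Dispatch to the engine named in ``spec``."""
    if spec.engine == "phase":
        return predict_mp_phase(drug, milk, spec)
    return predict_mp_log_transformed(drug, milk, spec)


def registry() -> dict[str, ModelSpec]:
    """Built-in model variants, keyed by stable CLI-safe names.

    The seven core variants cover the two engines and six Papp formulae; the
    suffixed variants swap the milk-binding predictor (``_ito``, ``_yang``)
    or feed it an ionisation-corrected fu_p (``_ion``), and ``_obsfum``
    substitutes measured milk binding where available.
    """
    ab = FumModel("atkinson_begg")
    specs = [
        ModelSpec("phase_distribution", papp_model=PappModel("phase_distribution"), fum_model=ab),
        ModelSpec("logpow", papp_model=PappModel("logpow"), fum_model=ab),
        ModelSpec("log_transformed", engine="log_transformed", fum_model=ab),
        ModelSpec("abi", papp_model=PappModel("abi"), fum_model=ab),
        ModelSpec("mcdb", papp_model=PappModel("mcdb"), fum_model=ab),
        ModelSpec("bartels_logp", papp_model=PappModel("bartels_logp"), fum_model=ab),
        ModelSpec("bartels_logd", papp_model=PappModel("bartels_logd"), fum_model=ab),
    ]
    out = {s.name: s for s in specs}
    bld = out["bartels_logd"]
    out["bartels_logd_ito"] = replace(bld, name="bartels_logd_ito", fum_model=FumModel("ito"))
    out["bartels_logd_yang"] = replace(bld, name="bartels_logd_yang", fum_model=FumModel("yang"))
    for base_name in ("bartels_logd", "bartels_logd_ito", "bartels_logd_yang"):
        src = out[base_name]
        out[base_name + "_ion"] = replace(
            src,
            name=base_name + "_ion",
            fum_model=replace(src.fum_model, ionisation_adjusted=True),
        )
    out["bartels_logd_obsfum"] = replace(bld, name="bartels_logd_obsfum", use_observed_fum=True)
    return out


#: Names of the seven core evaluated variants (no fu_m modifiers).
CORE_MODELS = (
    "phase_distribution",
    "logpow",
    "log_transformed",
    "abi",
    "mcdb",
    "bartels_logp",
    "bartels_logd",
)


def get_model(name: str) -> ModelSpec:
    """Look up a registry model by name, with a helpful error."""
    reg = registry()
    try:
        return reg[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {name!r}; available: {', '.join(sorted(reg))}"
        ) from None
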