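"""Core domain records: drugs and milk composition states.

A :class:`DrugRecord` carries the physicochemical constants the partitioning
models consume (charge class, pKa values, LogP, plasma fraction unbound, and
optional descriptors), together with the observed AUC milk-to-plasma ratio and
transporter-substrate annotations used for evaluation and filtering.

A :class:`MilkComposition` is one physiological state of breastmilk: its pH and
creamatocrit (the volume fraction occupied by the fat layer, a proxy for milk
lipid content). Plasma pH is carried alongside because the pH-partition
equations need both sides of the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "CHARGE_CLASSES",
    "DrugRecord",
    "MilkComposition",
    "StudyObservation",
]

from .errors import ValidationError

CHARGE_CLASSES = ("acid", "base", "neutral", "zwitterion")

#: Plasma pH used throughout unless overridden; physiological standard.
DEFAULT_PLASMA_PH = 7.4


@dataclass
class DrugRecord:
    """One drug's constants and annotations.

    Parameters
    ----------
    name : str
        Identifier (lower-case names are conventional).
    charge_class : {'acid', 'base', 'neutral', 'zwitterion'}
        Dominant ionisation behaviour; the models branch on it, so it is an
        explicit field rather than being inferred from the pKa list.
    pka_values : list of float
        Dissociation constants (pH units). May be empty only for neutrals.
        Multiprotic drugs are handled through the single pKa nearest
        physiological pH (see :func:`milkpk.physchem.dominant_pka`).
    logp : float
        Octanol:water partition coefficient of the neutral species (log10).
    fu_p : float
        Fraction unbound in plasma, in (0, 1].
    psa : float, optional
        Polar surface area (Å²); required by the Yang milk-binding model.
    mw, hbd, hba : optional
        Molecular weight (g/mol) and hydrogen-bond donor/acceptor counts;
        used only for property-correlation diagnostics.
    observed_mp : float, optional
        Observed AUC milk-to-plasma ratio (> 0), typically a sample-size
        weighted mean across studies.
    observed_fum : float, optional
        Measured fraction unbound in skimmed milk, in (0, 1].
    transporters : list of str
        Transporters for which the drug is a known substrate.
    hh_class : {'acid', 'base'}, optional
        Henderson-Hasselbalch branch for zwitterions (default 'acid').
    pub_year : int, optional
        Earliest publication year of the observed M/P data.
    """

    name: str
    charge_class: str
    pka_values: list[float] = field(default_factory=list)
    logp: float | None = None
    fu_p: float | None = None
    psa: float | None = None
    mw: float | None = None
    hbd: int | None = None
    hba: int | None = None
    observed_mp: float | None = None
    observed_fum: float | None = None
    transporters: list[str] = field(default_factory=list)
    hh_class: str | None = None
    pub_year: int | None = None

    def __post_init__(self) -> None:
        if self.charge_class not in CHARGE_CLASSES:
            raise ValidationError(
                f"{self.name}: unknown charge class {self.charge_class!r}; "
                f"expected one of {CHARGE_CLASSES}"
            )
        if self.charge_class != "neutral" and not self.pka_values:
            raise ValidationError(
                f"{self.name}: charge class {self.charge_class!r} requires at "
                "least one pKa value"
            )
        if self.fu_p is not None and not 0.0 < self.fu_p <= 1.0:
            raise ValidationError(f"{self.name}: fu_p must be in (0, 1], got {self.fu_p}")
        if self.observed_mp is not None and self.observed_mp <= 0:
            raise ValidationError(
                f"{self.name}: observed M/P must be positive, got {self.observed_mp}"
            )
        if self.observed_fum is not None and not 0.0 < self.observed_fum <= 1.0:
            raise ValidationError(
                f"{self.name}: observed fu_m must be in (0, 1], got {self.observed_fum}"
            )
        if self.hh_class is not None and self.hh_class not in ("acid", "base"):
            raise ValidationError(
                f"{self.name}: hh_class must be 'acid' or 'base', got {self.hh_class!r}"
            )

    def is_substrate_of(self, transporter: str) -> bool:
        return transporter.upper() in (t.upper() for t in self.transporters)


@dataclass(frozen=True)
class MilkComposition:
    """One (pH, creamatocrit) state of breastmilk.

    ``crt`` is a fraction (0.03–0.12 covers the usual 3%–12% physiological
    window). Milk pH outside [6, 8] is allowed but triggers a warning since it
    is outside anything reported physiologically.
    """

    ph_milk: float
    crt: float
    ph_plasma: float = DEFAULT_PLASMA_PH

    def __post_init__(self) -> None:
        if not 0.0 <= self.crt < 1.0:
            raise ValidationError(f"creamatocrit must be in [0, 1), got {self.crt}")
        if not 6.0 <= self.ph_milk <= 8.0:
            warnings.warn(
                f"milk pH {self.ph_milk} is outside the physiological window [6, 8]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StudyObservation:
    """A single study's observed AUC M/P ratio for one drug."""

    drug: str
    mp_auc: float
    n_subjects: int = 1
    year: int | None = None
    milk_ph: float | None = None
    crt: float | None = None
    observed_fum: float | None = None

    def __post_init__(self) -> None:
        if self.mp_auc <= 0:
            raise ValidationError(f"{self.drug}: observed M/P must be positive")
        if self.n_subjects < 1:
            raise ValidationError(f"{self.drug}: n_subjects must be >= 1")
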