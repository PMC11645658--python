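"""Drug-table I/O, study aggregation, transporter filtering, synthetic data.

Column dictionary for drug tables (comma-separated, UTF-8, header row):

======================  ======================================================
column                  meaning
======================  ======================================================
name                    drug identifier (mandatory)
charge_class            acid | base | neutral | zwitterion (mandatory)
pka_values              semicolon-separated pKa list; empty for neutrals
logp                    octanol:water LogP of the neutral species
fu_p                    plasma fraction unbound, (0, 1]
psa                     polar surface area, Å² (optional)
mw                      molecular weight, g/mol (optional)
hbd / hba               H-bond donor / acceptor counts (optional)
observed_mp             observed AUC M/P ratio (optional)
observed_fum            measured milk fraction unbound (optional)
transporters            semicolon-separated substrate annotations (optional)
hh_class                HH branch for zwitterions: acid | base (optional)
pub_year                earliest observation year (optional)
======================  ======================================================

Percent-valued columns use the ``_pct`` suffix (e.g. ``crt_pct`` in
composition tables) and are converted to fractions on read.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UnsupportedDrugClassError, ValidationError
from .heterogeneity import PH_MEAN
from .models import ModelSpec, predict_mp
from .records import DrugRecord, MilkComposition, StudyObservation

__all__ = [
    "TRANSPORTER_ROSTER",
    "read_drug_table",
    "write_drug_table",
    "drugs_to_frame",
    "example_drugs",
    "weighted_observed_mp",
    "filter_transporter_substrates",
    "generate_synthetic_drugs",
]

#: Transporters expressed in human mammary epithelium for which substrates
#: were identified; substrates of these are excluded from passive-diffusion
#: model evaluation by default.
TRANSPORTER_ROSTER = (
    "BCRP",
    "MDR1",
    "MRP2",
    "OCTN1",
    "OCTN2",
    "OCT1",
    "OCT3",
    "OATP1A2",
    "OATP2B1",
)

_LIST_SEP = ";"
_OPTIONAL_FLOAT = ("logp", "fu_p", "psa", "mw", "observed_mp", "observed_fum")
_OPTIONAL_INT = ("hbd", "hba", "pub_year")


def _parse_list(cell) -> list:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return []
    return [part.strip() for part in str(cell).split(_LIST_SEP) if part.strip()]


def _row_to_record(row: pd.Series) -> DrugRecord:
    kwargs = {
        "name": str(row["name"]).strip(),
        "charge_class": str(row["charge_class"]).strip().lower(),
        "pka_values": [float(p) for p in _parse_list(row.get("pka_values"))],
        "transporters": _parse_list(row.get("transporters")),
    }
    for col in _OPTIONAL_FLOAT:
        val = row.get(col)
        if val is not None and not pd.isna(val):
            kwargs[col] = float(val)
    for col in _OPTIONAL_INT:
        val = row.get(col)
        if val is not None and not pd.isna(val):
            kwargs[col] = int(val)
    hh = row.get("hh_class")
    if hh is not None and not pd.isna(hh) and str(hh).strip():
        kwargs["hh_class"] = str(hh).strip().lower()
    return DrugRecord(**kwargs)


def read_drug_table(path, sep: str = ",") -> list[DrugRecord]:
    """Read and validate a drug table; all row errors are reported together."""
    df = pd.read_csv(path, sep=sep)
    missing = {"name", "charge_class"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s): {sorted(missing)}")
    records: list[DrugRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return records


def drugs_to_frame(drugs: list[DrugRecord]) -> pd.DataFrame:
    rows = []
    for d in drugs:
        rows.append(
            {
                "name": d.name,
                "charge_class": d.charge_class,
                "pka_values": _LIST_SEP.join(f"{p:g}" for p in d.pka_values),
                "logp": d.logp,
                "fu_p": d.fu_p,
                "psa": d.psa,
                "mw": d.mw,
                "hbd": d.hbd,
                "hba": d.hba,
                "observed_mp": d.observed_mp,
                "observed_fum": d.observed_fum,
                "transporters": _LIST_SEP.join(d.transporters),
                "hh_class": d.hh_class,
                "pub_year": d.pub_year,
            }
        )
    return pd.DataFrame(rows)


def write_drug_table(drugs: list[DrugRecord], path, sep: str = ",") -> None:
    """Inverse of :func:`read_drug_table` (round-trip safe)."""
    drugs_to_frame(drugs).to_csv(path, sep=sep, index=False)


def example_drugs() -> list[DrugRecord]:
    """Bundled worked-example drug set.

    Physicochemical constants and observed M/P ratios were transcribed from
    public databases and the clinical lactation literature; they are
    approximate literature values for demonstration and testing, not a
    benchmark dataset.
    """
    with resources.as_file(
        resources.files("milkpk.data").joinpath("example_drugs.csv")
    ) as p:
        return read_drug_table(p)


def weighted_observed_mp(observations: list[StudyObservation]) -> float:
    """Sample-size-weighted mean observed M/P across studies of one drug."""
    if not observations:
        raise ValidationError("no study observations supplied")
    weights = np.array([o.n_subjects for o in observations], dtype=float)
    values = np.array([o.mp_auc for o in observations], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValidationError("zero total weight")
    return float((values * weights).sum() / total)


def filter_transporter_substrates(
    drugs: list[DrugRecord],
    transporters: list[str] | tuple[str, ...] = TRANSPORTER_ROSTER,
    mode: str = "exclude_any",
) -> list[DrugRecord]:
    """Filter a drug list by transporter-substrate status.

    Modes: ``exclude_any`` drops substrates of any listed transporter (the
    passive-diffusion evaluation set); ``only_substrates_of`` keeps substrates
    of the (single) listed transporter; ``substrates_of_only`` keeps drugs
    whose *entire* annotation is within the listed transporters — e.g. drugs
    mediated only by MDR1.
    """
    wanted = {t.upper() for t in transporters}
    if mode == "exclude_any":
        return [d for d in drugs if not wanted & {t.upper() for t in d.transporters}]
    if mode == "only_substrates_of":
        return [d for d in drugs if wanted & {t.upper() for t in d.transporters}]
    if mode == "substrates_of_only":
        return [
            d
            for d in drugs
            if d.transporters and {t.upper() for t in d.transporters} <= wanted
        ]
    raise ValidationError(
        f"unknown filter mode {mode!r}; expected exclude_any, only_substrates_of "
        "or substrates_of_only"
    )


def generate_synthetic_drugs(
    n: int,
    seed: int,
    model_for_truth: ModelSpec,
    noise_sd_log: float = float(np.log(1.5)),
    reference_ph: float = PH_MEAN,
    reference_crt: float = 0.075,
) -> list[DrugRecord]:
    """Seed-deterministic synthetic drug table with model-generated truth.

    Charge class, pKa (class-appropriate windows), LogP uniform on [-2, 5],
    fu_p log-uniform on [0.005, 1] and PSA uniform on [20, 150] are drawn per
    drug; the observed M/P is the truth model's prediction at the reference
    composition (pH 7.12, Crt 7.5% — the centres of the physiological windows)
    multiplied by lognormal noise with the given log-SD. Classes the truth
    model cannot predict are simply never drawn for that model.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    classes = ("acid", "base", "neutral")
    class_p = (0.35, 0.45, 0.20)
    if model_for_truth.engine == "log_transformed":
        classes, class_p = ("acid", "base"), (0.45, 0.55)
    milk = MilkComposition(ph_milk=reference_ph, crt=reference_crt)
    pka_windows = {"acid": (3.0, 9.0), "base": (5.0, 11.0)}
    drugs: list[DrugRecord] = []
    for i in range(n):
        charge = rng.choice(classes, p=class_p)
        pkas = []
        if charge in pka_windows:
            lo, hi = pka_windows[charge]
            pkas = [float(rng.uniform(lo, hi))]
        drug = DrugRecord(
            name=f"synth{i:04d}",
            charge_class=str(charge),
            pka_values=pkas,
            logp=float(rng.uniform(-2.0, 5.0)),
            fu_p=float(np.exp(rng.uniform(np.log(0.005), 0.0))),
            psa=float(rng.uniform(20.0, 150.0)),
            mw=float(rng.uniform(150.0, 500.0)),
            hbd=int(rng.integers(0, 6)),
            hba=int(rng.integers(0, 10)),
        )
        try:
            truth = predict_mp(drug, milk, model_for_truth)
        except UnsupportedDrugClassError:  # pragma: no cover - classes filtered above
            continue
        noise = float(np.exp(rng.normal(0.0, noise_sd_log))) if noise_sd_log > 0 else 1.0
        drug.observed_mp = truth * noise
        drugs.append(drug)
    return drugs
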