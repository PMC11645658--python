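"""Score predicted M/P ranges against observed data.

Per drug, the accuracy measure is the predicted-to-observed (P/O) ratio.
Because each drug has a *range* of predictions across the composition grid, a
drug counts as "within k-fold" if any predicted value across the physiological
range lies within [observed/k, observed·k] (closed intervals: touching the
bound counts). Dataset-level summaries are the percentage within 2- and
5-fold, the average fold error AFE = mean of max(P/O, O/P) on the central
prediction (± SD; geometric-mean alternative available), and the squared
linear correlation R² between central predicted and observed M/P.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UnsupportedDrugClassError, ValidationError
from .heterogeneity import CompositionGrid, PredictionRange, predict_range
from .models import ModelSpec
from .records import DrugRecord

__all__ = [
    "po_ratio",
    "within_fold",
    "EvaluationReport",
    "evaluate_dataset",
    "stratify_by_transporter",
    "correlate_po_with_property",
]


def po_ratio(predicted: float, observed: float) -> float:
    """Predicted-to-observed M/P ratio."""
    if predicted <= 0 or observed <= 0:
        raise DomainError(
            f"P/O requires positive inputs, got predicted={predicted}, observed={observed}"
        )
    return predicted / observed


def within_fold(
    prange: PredictionRange, observed: float, fold: float
) -> tuple[bool, str]:
    """Any-in-range fold rule.

    Returns ``(flag, direction)`` where direction is 'over' if even the lowest
    prediction exceeds observed·fold, 'under' if even the highest falls short
    of observed/fold, and 'within' otherwise.
    """
    if observed <= 0:
        raise DomainError(f"observed M/P must be positive, got {observed}")
    if fold < 1:
        raise ValidationError(f"fold must be >= 1, got {fold}")
    if prange.mp_min > observed * fold:
        return False, "over"
    if prange.mp_max < observed / fold:
        return False, "under"
    return True, "within"


@dataclass
class EvaluationReport:
    """Per-drug P/O statistics plus dataset-level metrics for one model."""

    model: str
    per_drug: pd.DataFrame
    dataset: dict
    excluded: list[str] = field(default_factory=list)

    def summary(self) -> str:
        d = self.dataset
        lines = [
            f"model: {self.model}",
            f"drugs evaluated: {d['n_drugs']} (excluded: {len(self.excluded)})",
            f"within 2-fold: {d['pct_within_2fold']:.1f}%",
            f"within 5-fold: {d['pct_within_5fold']:.1f}%",
            f"AFE: {d['afe_mean']:.2f} +/- {d['afe_sd']:.2f}",
            f"R^2 (central vs observed): {d['r_squared']:.2f}",
        ]
        return "\n".join(lines)


def _fold_error(po: float) -> float:
    return max(po, 1.0 / po)


def evaluate_dataset(
    drugs: list[DrugRecord],
    spec: ModelSpec,
    grid: CompositionGrid,
    afe: str = "arithmetic",
    r2_on_log: bool = False,
) -> EvaluationReport:
    """Evaluate one model over a drug set and composition grid.

    Drugs the model cannot predict (neutral/zwitterionic drugs under the
    log-transformed engine) are excluded from the denominator; their names are
    reported on the returned :class:`EvaluationReport`.
    """
    if not drugs:
        raise ValidationError("empty drug dataset")
    if afe not in ("arithmetic", "geometric"):
        raise ValidationError(f"afe must be 'arithmetic' or 'geometric', got {afe!r}")
    rows = []
    excluded: list[str] = []
    for drug in drugs:
        if drug.observed_mp is None:
            raise ValidationError(f"{drug.name}: observed M/P is required for evaluation")
        try:
            pr = predict_range(drug, spec, grid)
        except UnsupportedDrugClassError:
            excluded.append(drug.name)
            continue
        w2, dir2 = within_fold(pr, drug.observed_mp, 2)
        w5, dir5 = within_fold(pr, drug.observed_mp, 5)
        po_c = po_ratio(pr.mp_central, drug.observed_mp)
        rows.append(
            {
                "drug": drug.name,
                "model": spec.name,
                "observed_mp": drug.observed_mp,
                "mp_min": pr.mp_min,
                "mp_central": pr.mp_central,
                "mp_max": pr.mp_max,
                "po_min": pr.mp_min / drug.observed_mp,
                "po_central": po_c,
                "po_max": pr.mp_max / drug.observed_mp,
                "fold_error": _fold_error(po_c),
                "within_2fold": w2,
                "within_5fold": w5,
                "direction": dir2,
            }
        )
    if not rows:
        raise ValidationError(
            f"model {spec.name!r} could not predict any drug in the dataset"
        )
    per_drug = pd.DataFrame(rows)
    if excluded:
        warnings.warn(
            f"model {spec.name!r}: {len(excluded)} drug(s) excluded "
            f"(unsupported charge class): {', '.join(excluded)}",
            stacklevel=2,
        )
    fe = per_drug["fold_error"].to_numpy()
    if afe == "arithmetic":
        afe_mean, afe_sd = float(fe.mean()), float(fe.std(ddof=1)) if len(fe) > 1 else 0.0
    else:
        log_fe = np.log(fe)
        afe_mean = float(np.exp(log_fe.mean()))
        afe_sd = float(np.exp(log_fe.std(ddof=1))) if len(fe) > 1 else 1.0
    pred = per_drug["mp_central"].to_numpy()
    obs = per_drug["observed_mp"].to_numpy()
    if r2_on_log:
        pred, obs = np.log(pred), np.log(obs)
    if len(pred) > 2 and np.ptp(pred) > 0 and np.ptp(obs) > 0:
        r_squared = float(stats.pearsonr(pred, obs)[0] ** 2)
    else:
        r_squared = math.nan
    dataset = {
        "n_drugs": int(len(per_drug)),
        "n_excluded": len(excluded),
        "pct_within_2fold": 100.0 * float(per_drug["within_2fold"].mean()),
        "pct_within_5fold": 100.0 * float(per_drug["within_5fold"].mean()),
        "afe_mean": afe_mean,
        "afe_sd": afe_sd,
        "r_squared": r_squared,
    }
    return EvaluationReport(model=spec.name, per_drug=per_drug, dataset=dataset,
                            excluded=excluded)


def stratify_by_transporter(
    report: EvaluationReport,
    drugs: list[DrugRecord],
    transporter: str,
    min_n: int = 5,
) -> dict:
    """Descriptive P/O summaries for substrates vs non-substrates.

    No inferential statistics are computed here; groups smaller than ``min_n``
    are flagged so downstream comparison knows they are under-powered.
    """
    by_name = {d.name: d for d in drugs}
    po = report.per_drug.set_index("drug")["po_central"]
    sub_mask = po.index.map(
        lambda n: n in by_name and by_name[n].is_substrate_of(transporter)
    )

    def _summ(values: pd.Series) -> dict:
        n = int(len(values))
        out = {"n": n, "below_min_n": n < min_n}
        if n:
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            out.update(median_po=float(med), iqr_po=(float(q1), float(q3)))
        else:
            out.update(median_po=math.nan, iqr_po=(math.nan, math.nan))
        return out

    return {
        "transporter": transporter,
        "min_n": min_n,
        "substrates": _summ(po[sub_mask]),
        "non_substrates": _summ(po[~sub_mask]),
    }


_PROPERTY_GETTERS = {
    "fu_p": lambda d, report_logd: d.fu_p,
    "mw": lambda d, report_logd: d.mw,
    "psa": lambda d, report_logd: d.psa,
    "hbd": lambda d, report_logd: d.hbd,
    "hba": lambda d, report_logd: d.hba,
}


def correlate_po_with_property(
    report: EvaluationReport,
    drugs: list[DrugRecord],
    prop: str,
    logd_ph: float = 7.12,
) -> dict:
    """OLS of central P/O ratio against a physicochemical property.

    ``prop`` is one of fu_p, logd, mw, psa, hbd, hba; ``logd`` is evaluated at
    ``logd_ph``. Drugs missing the property are dropped (count reported).
    Includes a Spearman rank correlation alongside the linear fit, which is a
    more honest summary where the relationship is non-linear (as it is for
    fu_p, where highly bound drugs tend to be underpredicted).
    """
    from .physchem import logd_at_ph

    if prop == "logd":
        getter = lambda d, ph=logd_ph: logd_at_ph(d, ph)  # noqa: E731
    elif prop in _PROPERTY_GETTERS:
        getter = lambda d: _PROPERTY_GETTERS[prop](d, None)  # noqa: E731
    else:
        raise ValidationError(
            f"unknown property {prop!r}; expected one of fu_p, logd, mw, psa, hbd, hba"
        )
    by_name = {d.name: d for d in drugs}
    xs, ys = [], []
    n_missing = 0
    for _, row in report.per_drug.iterrows():
        drug = by_name.get(row["drug"])
        value = getter(drug) if drug is not None else None
        if value is None:
            n_missing += 1
            continue
        xs.append(float(value))
        ys.append(float(row["po_central"]))
    if len(xs) < 3:
        raise ValidationError(
            f"need >= 3 drugs with {prop!r}, got {len(xs)} ({n_missing} missing)"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    out = {"property": prop, "n": len(xs), "n_missing": n_missing}
    if np.ptp(x) == 0:
        out.update(slope=math.nan, intercept=math.nan, r_squared=math.nan,
                   spearman_rho=math.nan, degenerate=True)
        return out
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    out.update(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        spearman_rho=float(rho),
        degenerate=False,
    )
    return out
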