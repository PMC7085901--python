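"""Standard curves, replicate QC and Pfaffl efficiency-corrected expression.

The amplification model throughout is Cq = c0 - log_E(input): one cycle per
E-fold of template.  A standard curve regresses Cq on log10(relative input),
so E = 10^(-1/slope); the Pfaffl ratio corrects the classic ddCq for target
and reference assays amplifying at different efficiencies:

    ratio = E_target^(dCq_target) / E_reference^(dCq_reference),

with dCq = Cq(calibrator) - Cq(sample).
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CqTable, NORMALIZER

__all__ = [
    "StandardCurve",
    "qc_replicates",
    "fit_standard_curve",
    "fit_all_curves",
    "pfaffl_ratio",
    "relative_expression",
]


@dataclass(frozen=True)
class StandardCurve:
    assay: str
    slope: float  # cycles per log10(input)
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)


def qc_replicates(
    table: pd.DataFrame,
    max_dev: float = 0.5,
    max_cv: float = 0.10,
    cv_on: str = "cq",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse technical replicates to means, discarding unreliable samples.

    A sample (one assay x biological sample) is discarded when any replicate
    failed to amplify (missing Cq), when the replicate range exceeds
    ``max_dev`` cycles (strictly greater), or when the coefficient of
    variation reaches ``max_cv``.  ``cv_on`` selects whether the CV is taken
    on Cq cycles directly (default) or on linear quantities 2^-Cq.

    Returns (kept table with one mean-Cq row per sample, discard log).
    """
    if cv_on not in ("cq", "linear"):
        raise ValueError("cv_on must be 'cq' or 'linear'")
    kept_rows = []
    discarded = []
    group_cols = [c for c in ("assay", "stage", "temperature", "sample_id") if c in table.columns]
    for key, grp in table.groupby(group_cols, sort=False):
        info = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        cq = grp["Cq"].to_numpy(dtype=float)
        if len(cq) < 2:
            discarded.append({**info, "reason": "single replicate"})
            continue
        if np.isnan(cq).any():
            discarded.append({**info, "reason": "no amplification"})
            continue
        dev = float(cq.max() - cq.min())
        if dev > max_dev:
            discarded.append({**info, "reason": f"replicate deviation {dev:.3f} > {max_dev}"})
            continue
        values = cq if cv_on == "cq" else np.power(2.0, -cq)
        cv = float(np.std(values, ddof=1) / np.mean(values))
        if cv >= max_cv:
            discarded.append({**info, "reason": f"replicate CV {cv:.4f} >= {max_cv}"})
            continue
        kept_rows.append({**info, "Cq": float(cq.mean()), "n_reps": len(cq)})
    return pd.DataFrame(kept_rows), pd.DataFrame(discarded, columns=group_cols + ["reason"])


def fit_standard_curve(standards: pd.DataFrame, assay: str | None = None) -> StandardCurve:
    """Least-squares line of Cq on log10(relative input) for one assay."""
    sub = standards if assay is None else standards[standards["assay"] == assay]
    if assay is None:
        assays = sub["assay"].unique() if "assay" in sub.columns else ["?"]
        if len(assays) != 1:
            raise ValueError("multiple assays present; pass assay=")
        assay = str(assays[0])
    sub = sub.dropna(subset=["Cq"])
    x = np.log10(sub["relative_input"].to_numpy(dtype=float))
    y = sub["Cq"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"assay {assay}: need >= 3 distinct dilution steps with Cq, got {len(np.unique(x))}"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"assay {assay}: zero variance in input")
    fit = stats.linregress(x, y)
    return StandardCurve(assay, float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def fit_all_curves(standards: pd.DataFrame) -> dict[str, StandardCurve]:
    return {
        str(a): fit_standard_curve(standards, str(a))
        for a in standards["assay"].unique()
    }


def pfaffl_ratio(
    target_efficiency: float,
    target_dcq: float,
    reference_efficiency: float,
    reference_dcq: float,
) -> float:
    """Efficiency-corrected relative expression (target vs reference assay).

    dCq values are calibrator minus sample, so a sample with *more* target
    template than the calibrator has positive dCq and ratio > 1.
    """
    for e in (target_efficiency, reference_efficiency):
        if not 1.0 < e < 2.5:
            raise ValueError(f"efficiency {e} outside (1, 2.5)")
    if not (np.isfinite(target_dcq) and np.isfinite(reference_dcq)):
        raise ValueError("dCq values must be finite")
    return float(
        target_efficiency**target_dcq / reference_efficiency**reference_dcq
    )


def relative_expression(
    cq_table: CqTable,
    reference_assay: str = NORMALIZER,
    calibrator_step: int = 3,
    max_dev: float = 0.5,
    max_cv: float = 0.10,
) -> tuple[pd.DataFrame, dict[str, StandardCurve], pd.DataFrame]:
    """Full qPCR pipeline: QC -> standard curves -> per-sample Pfaffl ratios.

    The calibrator is the per-assay mean Cq of the pooled standard at
    ``calibrator_step`` of the dilution series (a mid-curve point, stable and
    present on every plate).  Returns (relative-expression table, curves,
    discard log).  The expression table has one row per biological sample and
    target assay with the Pfaffl ratio against ``reference_assay``.
    """
    kept, dropped = qc_replicates(cq_table.samples, max_dev=max_dev, max_cv=max_cv)
    curves = fit_all_curves(cq_table.standards)
    cal = (
        cq_table.standards[cq_table.standards["dilution_step"] == calibrator_step]
        .groupby("assay")["Cq"]
        .mean()
    )
    if reference_assay not in curves:
        raise ValueError(f"reference assay {reference_assay!r} has no standard curve")
    ref = kept[kept["assay"] == reference_assay].set_index("sample_id")
    rows = []
    for assay in curves:
        if assay == reference_assay:
            continue
        for _, row in kept[kept["assay"] == assay].iterrows():
            sid = row["sample_id"]
            if sid not in ref.index:
                continue  # reference failed QC for this sample
            ratio = pfaffl_ratio(
                curves[assay].efficiency,
                float(cal[assay] - row["Cq"]),
                curves[reference_assay].efficiency,
                float(cal[reference_assay] - ref.loc[sid, "Cq"]),
            )
            rows.append(
                {
                    "sample_id": sid,
                    "assay": assay,
                    "stage": row.get("stage"),
                    "temperature": row.get("temperature"),
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows), curves, dropped
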