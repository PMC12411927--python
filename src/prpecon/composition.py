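"""Platelet-rich plasma composition metrics.

Per-injection quantities derived from paired complete-blood-count (CBC)
panels of whole blood and the PRP injectate:

* platelet dose  D = C x V / 1000      (x10^3/uL times mL gives x10^9 platelets)
* extraction     E = D_prp / D_wb      (fraction of drawn platelets recovered)
* concentration factor  F = C_prp / C_wb

Extraction is a dose ratio, not a concentration ratio: a method can have a
modest concentration factor yet recover nearly all platelets by keeping a
large plasma volume. Observed extraction can exceed 1 through cell-counter
measurement noise; such values are flagged, never clamped, and retained in
cohort averages.

Cohort-level summaries report both the mean of per-injection extraction
(matching per-subject trajectories) and the ratio of mean doses (the
headline "cohort extraction"); these differ on skewed data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CBCPanel",
    "CompositionMetrics",
    "ReferenceTechnique",
    "CohortCompositionSummary",
    "UndefinedExtractionError",
    "platelet_dose",
    "compute_metrics",
    "exclude_invalid",
    "pair_panels",
    "summarize_cohort",
    "read_panels_csv",
    "default_reference_techniques",
]

WHOLE_BLOOD = "whole_blood"
PRP = "prp"

# qc flags
EXTRACTION_GT_ONE = "EXTRACTION_GT_ONE"
WBC_DIFFERENTIAL_INCONSISTENT = "WBC_DIFFERENTIAL_INCONSISTENT"


class UndefinedExtractionError(ValueError):
    """Raised when the whole-blood platelet mass is zero, so E = D_prp / D_wb is undefined."""


@dataclass(frozen=True)
class CBCPanel:
    """One cellular analysis (whole blood or PRP) for one injection.

    Concentrations: platelets/WBC/differential in x10^3 per uL, RBC in
    x10^6 per uL, haemoglobin in g/dL; volume in mL.
    """

    injection_id: str
    source: str  # "whole_blood" | "prp"
    volume_ml: float
    platelet_conc: float
    wbc_conc: float = 0.0
    neutrophil_conc: float = 0.0
    lymphocyte_conc: float = 0.0
    rbc_conc: float = 0.0
    hb_conc: float = 0.0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.source not in (WHOLE_BLOOD, PRP):
            raise ValueError(f"unknown panel source {self.source!r}")
        if self.volume_ml <= 0:
            raise ValueError(f"panel volume must be positive, got {self.volume_ml}")
        for name in ("platelet_conc", "wbc_conc", "neutrophil_conc",
                     "lymphocyte_conc", "rbc_conc", "hb_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")

    @property
    def differential_consistent(self) -> bool:
        # slack only for floating error; a printed differential that exceeds
        # total WBC is reported via a qc flag, not rejected
        return self.neutrophil_conc + self.lymphocyte_conc <= self.wbc_conc * (1 + 1e-9) + 1e-12

    @property
    def platelet_dose(self) -> float:
        return platelet_dose(self.platelet_conc, self.volume_ml)


def platelet_dose(conc_1e3_ul: float, volume_ml: float) -> float:
    """Absolute platelet count in x10^9 ("billions"): conc (x10^3/uL) x volume (mL) / 1000."""
    return conc_1e3_ul * volume_ml / 1000.0


@dataclass(frozen=True)
class CompositionMetrics:
    """Derived per-injection quantities from one whole-blood/PRP panel pair."""

    injection_id: str
    platelet_dose_wb: float
    platelet_dose_prp: float
    extraction_rate: float
    concentration_factor: float
    leukocyte_class: str  # "rich" | "poor"
    qc_flags: frozenset = field(default_factory=frozenset)

    @property
    def concentration_factor_reported(self) -> float:
        """Concentration factor at the one-decimal reporting precision."""
        return round(self.concentration_factor, 1)


def compute_metrics(wb: CBCPanel, prp: CBCPanel) -> CompositionMetrics:
    """Derive dose, extraction, concentration factor and leukocyte class for one injection.

    Both panels must be valid and share an injection id. A PRP whose WBC
    concentration strictly exceeds that of whole blood is classified
    leukocyte-rich; equality counts as poor. Extraction above 1 is flagged
    (``EXTRACTION_GT_ONE``) and retained.
    """
    if wb.injection_id != prp.injection_id:
        raise ValueError(
            f"mismatched injection ids: {wb.injection_id!r} vs {prp.injection_id!r}"
        )
    if wb.source != WHOLE_BLOOD or prp.source != PRP:
        raise ValueError("compute_metrics expects (whole_blood, prp) panels in that order")
    if not (wb.valid and prp.valid):
        raise ValueError(f"invalid panel(s) for injection {wb.injection_id!r}")

    dose_wb = wb.platelet_dose
    dose_prp = prp.platelet_dose
    if dose_wb == 0:
        raise UndefinedExtractionError(
            f"whole-blood platelet mass is zero for injection {wb.injection_id!r}"
        )
    extraction = dose_prp / dose_wb
    factor = prp.platelet_conc / wb.platelet_conc if wb.platelet_conc > 0 else math.inf

    flags = set()
    if extraction > 1.0:
        flags.add(EXTRACTION_GT_ONE)
    if not (wb.differential_consistent and prp.differential_consistent):
        flags.add(WBC_DIFFERENTIAL_INCONSISTENT)

    return CompositionMetrics(
        injection_id=wb.injection_id,
        platelet_dose_wb=dose_wb,
        platelet_dose_prp=dose_prp,
        extraction_rate=extraction,
        concentration_factor=factor,
        leukocyte_class="rich" if prp.wbc_conc > wb.wbc_conc else "poor",
        qc_flags=frozenset(flags),
    )


def exclude_invalid(panels: Sequence[CBCPanel]) -> tuple[list[CBCPanel], list[dict]]:
    """Drop panels flagged invalid, logging each with a reason.

    Returns ``(kept, dropped)`` where ``dropped`` entries carry injection id,
    source and reason. The paired PRP panel of a dropped whole-blood panel is
    *kept* here: it is excluded from extraction (no valid pair) but remains in
    PRP-only summaries.
    """
    kept: list[CBCPanel] = []
    dropped: list[dict] = []
    for panel in panels:
        if panel.valid:
            kept.append(panel)
        else:
            dropped.append(
                {
                    "injection_id": panel.injection_id,
                    "source": panel.source,
                    "reason": "panel flagged invalid (e.g. inaccurate counter reading)",
                }
            )
    return kept, dropped


def pair_panels(panels: Sequence[CBCPanel]) -> list[tuple[CBCPanel, CBCPanel]]:
    """Pair valid whole-blood/PRP panels by injection id (order preserved)."""
    wb_by_id = {p.injection_id: p for p in panels if p.source == WHOLE_BLOOD and p.valid}
    pairs = []
    for p in panels:
        if p.source == PRP and p.valid and p.injection_id in wb_by_id:
            pairs.append((wb_by_id[p.injection_id], p))
    return pairs


@dataclass(frozen=True)
class ReferenceTechnique:
    """Published extraction rate for a comparator preparation technique."""

    name: str
    mean: float
    ci_low: float
    ci_high: float


def default_reference_techniques() -> list[ReferenceTechnique]:
    """Commercial neutrophil-poor kit benchmark: extraction ~0.30-0.60, mean 0.45."""
    return [ReferenceTechnique("commercial_kit", 0.45, 0.30, 0.60)]


@dataclass(frozen=True)
class CohortCompositionSummary:
    n_injections: int
    metric_means: dict
    metric_sds: dict
    mean_extraction: float
    extraction_ci: tuple[float, float]
    cohort_extraction_ratio_of_means: float
    concentration_factor_reported: float
    n_leukocyte_rich: int
    reference_comparisons: list[dict]

    def to_dict(self) -> dict:
        return {
            "n_injections": self.n_injections,
            "metric_means": self.metric_means,
            "metric_sds": self.metric_sds,
            "mean_extraction": self.mean_extraction,
            "extraction_ci_95": list(self.extraction_ci),
            "cohort_extraction_ratio_of_means": self.cohort_extraction_ratio_of_means,
            "concentration_factor_reported": self.concentration_factor_reported,
            "n_leukocyte_rich": self.n_leukocyte_rich,
            "reference_comparisons": self.reference_comparisons,
        }


def summarize_cohort(
    metrics: Sequence[CompositionMetrics],
    reference: Iterable[ReferenceTechnique] = (),
) -> CohortCompositionSummary:
    """Cohort mean/SD of per-injection metrics with a t-based 95% CI on extraction.

    The CI is mean +/- t(0.975, n-1) * SD / sqrt(n). Two extraction summaries
    are reported: the mean of per-injection extraction rates, and the ratio of
    mean doses (sum of PRP platelets over sum of whole-blood platelets); the
    latter is the headline cohort figure. Comparison against each reference
    technique is a CI-disjointness verdict.
    """
    n = len(metrics)
    if n < 2:
        raise ValueError(f"cohort CI undefined for n={n} (need >= 2 injections)")

    extraction = np.array([m.extraction_rate for m in metrics], dtype=float)
    factor = np.array([m.concentration_factor for m in metrics], dtype=float)
    dose_wb = np.array([m.platelet_dose_wb for m in metrics], dtype=float)
    dose_prp = np.array([m.platelet_dose_prp for m in metrics], dtype=float)

    mean_ext = float(extraction.mean())
    sd_ext = float(extraction.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd_ext / math.sqrt(n)
    ci = (mean_ext - half, mean_ext + half)

    means = {
        "extraction_rate": mean_ext,
        "concentration_factor": float(factor.mean()),
        "platelet_dose_wb": float(dose_wb.mean()),
        "platelet_dose_prp": float(dose_prp.mean()),
    }
    sds = {
        "extraction_rate": sd_ext,
        "concentration_factor": float(factor.std(ddof=1)),
        "platelet_dose_wb": float(dose_wb.std(ddof=1)),
        "platelet_dose_prp": float(dose_prp.std(ddof=1)),
    }

    comparisons = []
    for ref in reference:
        disjoint = ci[0] > ref.ci_high or ci[1] < ref.ci_low
        comparisons.append(
            {
                "technique": ref.name,
                "reference_mean": ref.mean,
                "reference_ci": [ref.ci_low, ref.ci_high],
                "cohort_ci": list(ci),
                "ci_disjoint": bool(disjoint),
            }
        )

    return CohortCompositionSummary(
        n_injections=n,
        metric_means=means,
        metric_sds=sds,
        mean_extraction=mean_ext,
        extraction_ci=ci,
        cohort_extraction_ratio_of_means=float(dose_prp.mean() / dose_wb.mean()),
        concentration_factor_reported=round(float(factor.mean()), 1),
        n_leukocyte_rich=sum(m.leukocyte_class == "rich" for m in metrics),
        reference_comparisons=comparisons,
    )


_PANEL_COLUMNS = {
    "injection_id": "injection_id",
    "source": "source",
    "volume_ml": "volume_ml",
    "plt_1e3_ul": "platelet_conc",
    "wbc_1e3_ul": "wbc_conc",
    "neut_1e3_ul": "neutrophil_conc",
    "lymph_1e3_ul": "lymphocyte_conc",
    "rbc_1e6_ul": "rbc_conc",
    "hb_g_dl": "hb_conc",
    "valid": "valid",
}


def read_panels_csv(path: str | Path) -> list[CBCPanel]:
    """Read CBC panels from the `cbc_panels.csv` schema."""
    df = pd.read_csv(path)
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cbc_panels.csv missing columns: {sorted(missing)}")
    panels = []
    for _, row in df.iterrows():
        kwargs = {attr: row[col] for col, attr in _PANEL_COLUMNS.items()}
        kwargs["injection_id"] = str(kwargs["injection_id"])
        kwargs["valid"] = bool(kwargs["valid"])
        panels.append(CBCPanel(**kwargs))
    return panels


def metrics_to_frame(metrics: Sequence[CompositionMetrics]) -> pd.DataFrame:
    """Tabulate per-injection metrics for `composition_metrics.csv`."""
    return pd.DataFrame(
        {
            "injection_id": [m.injection_id for m in metrics],
            "platelet_dose_wb_1e9": [m.platelet_dose_wb for m in metrics],
            "platelet_dose_prp_1e9": [m.platelet_dose_prp for m in metrics],
            "extraction_rate": [m.extraction_rate for m in metrics],
            "concentration_factor": [m.concentration_factor for m in metrics],
            "leukocyte_class": [m.leukocyte_class for m in metrics],
            "qc_flags": ["|".join(sorted(m.qc_flags)) for m in metrics],
        }
    )
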