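"""Synthetic cohort generator for the full analysis pipeline.

Emulates a single-arm knee-osteoarthritis injection cohort — patients with
optionally bilateral knees, paired whole-blood/PRP cell counts for each of
up to two injections per knee, longitudinal patient-reported outcomes at
baseline and 1/3/6/12 months, and the cost-model inputs — with the
statistical structure the downstream analysis assumes, so every stage is
testable without access to patient data.

Generative model highlights:

* Observed platelet extraction is ``true extraction x multiplicative
  log-normal measurement noise`` (cell-counter error scales with
  concentration), so observed values can exceed 1 without truncation; the
  noise factor has mean one, so the observed mean stays at the configured
  true mean.
* WOMAC scores are built from 24 Likert items (pain 5, stiffness 2,
  function 17; each 0-4) drawn Binomial(4, p) around a per-knee latent
  severity; the latent baseline distribution is a gamma calibrated by
  median/IQR matching so summaries land on the configured targets, and the
  integer item scale produces the ties the signed-rank machinery must
  handle. Follow-up severity is the baseline latent scaled by the per-visit
  effect profile, so a stronger configured improvement strictly lowers
  expected follow-up totals.
* Bilateral knees share a patient-level Gaussian-copula random effect
  (default correlation 0.6).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cea import MarkovConfig, StrategySpec, reference_case
from .costing import CostItem, LaborInput, default_supply_items
from .outcomes import VISITS, FOLLOWUP_VISITS

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "CostModelInputs",
    "generate_cohort",
    "generate_cost_inputs",
    "write_cohort",
]

VISIT_MONTHS = {"baseline": 0.0, "1m": 1.0, "3m": 3.0, "6m": 6.0, "12m": 12.0}

# WOMAC structure: per-item Likert 0-4
N_PAIN_ITEMS = 5
N_STIFF_ITEMS = 2
N_FUNC_ITEMS = 17
N_ITEMS = N_PAIN_ITEMS + N_STIFF_ITEMS + N_FUNC_ITEMS  # 24 -> total range 0-96
MAX_TOTAL = 4 * N_ITEMS

# Whole-blood / PRP CBC anchors (means, SDs) other than the configurable
# platelet parameters; units x10^3/uL for leukocytes, x10^6/uL RBC, g/dL Hb.
CBC_REFERENCE = {
    "wb_neut": (3.1, 1.0),
    "wb_lymph": (1.4, 0.3),
    "wb_other_wbc": (0.4, 0.15),
    "wb_rbc": (4.0, 0.5),
    "wb_hb": (13.0, 1.5),
    "prp_neut": (0.08, 0.1),
    "prp_lymph": (2.6, 1.4),
    "prp_other_wbc": (0.6, 0.3),
    "prp_rbc": (0.02, 0.02),
    "prp_hb": (0.1, 0.05),
}

KL_GRADES = (1, 2, 3)
KL_GRADE_PROBS = (11 / 30, 12 / 30, 7 / 30)


def _default_effect_profile() -> dict:
    # follow-up / baseline expected-total ratios implied by the calibration
    # medians 19.5 -> 7.0 / 7.0 / 5.5 / 6.5
    return {"1m": 7.0 / 19.5, "3m": 7.0 / 19.5, "6m": 5.5 / 19.5, "12m": 6.5 / 19.5}


def _default_utility_profiles() -> dict:
    lc, cortico, _cfg = reference_case()
    return {
        "lc_prp": {m: u for m, u, _ in lc.utility_by_timepoint},
        "corticosteroid": {m: u for m, u, _ in cortico.utility_by_timepoint},
    }


def _default_satisfaction() -> dict:
    return {
        # P(satisfied with the treated knee) per visit; baseline 0.15 mirrors
        # 85% pre-treatment dissatisfaction
        "knee": {"baseline": 0.15, "1m": 0.60, "3m": 0.65, "6m": 0.85, "12m": 0.75},
        # P(satisfied with the procedure), follow-ups only
        "procedure": {"1m": 0.75, "3m": 0.80, "6m": 0.90, "12m": 0.75},
    }


def _default_global_assessment() -> dict:
    return {"baseline": 60.0, "1m": 70.0, "3m": 75.0, "6m": 80.0, "12m": 70.0}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    n_patients: int = 20
    bilateral_fraction: float = 0.5
    seed: int = 0
    # blood draw & platelet model
    wb_platelet_mean: float = 183.0  # x10^3/uL
    wb_platelet_sd: float = 51.4
    wb_volume: float = 45.0  # mL
    prp_volume_mean: float = 14.9
    prp_volume_sd: float = 3.0
    true_extraction_mean: float = 0.85
    true_extraction_sd: float = 0.08
    measurement_cv: float = 0.05
    # outcome model
    womac_baseline_median: float = 19.5
    womac_baseline_iqr: float = 12.5
    effect_profile: dict = field(default_factory=_default_effect_profile)
    global_assessment_profile: dict = field(default_factory=_default_global_assessment)
    global_assessment_sd: float = 12.0
    utility_profile_by_arm: dict = field(default_factory=_default_utility_profiles)
    utility_sd: float = 0.10
    satisfaction_probs: dict = field(default_factory=_default_satisfaction)
    bilateral_correlation: float = 0.6
    arm: str = "lc_prp"
    # protocol deviations
    n_single_injection_patients: int = 1
    n_invalid_wb: int = 3

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in ("bilateral_fraction", "true_extraction_mean", "measurement_cv",
                     "bilateral_correlation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("wb_platelet_sd", "prp_volume_sd", "true_extraction_sd",
                     "utility_sd", "global_assessment_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("wb_volume", "prp_volume_mean", "wb_platelet_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for arm, profile in self.utility_profile_by_arm.items():
            for month, u in profile.items():
                if not (0.0 <= u <= 1.0):
                    raise ValueError(f"utility {u} for arm {arm!r} month {month} outside [0, 1]")
        for group in self.satisfaction_probs.values():
            for visit, p in group.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"satisfaction prob {p} at {visit!r} outside [0, 1]")
        missing = set(FOLLOWUP_VISITS) - set(self.effect_profile)
        if missing:
            raise ValueError(f"effect_profile missing visits: {sorted(missing)}")


@dataclass
class CostModelInputs:
    """Itemized injectate costs, labor, and (mean, SE) pairs for the payer model."""

    supply_items: list[CostItem]
    labor: LaborInput
    cortico_medication_usd: tuple[float, float]
    strategies: tuple[StrategySpec, StrategySpec]  # (intervention, comparator)
    markov: MarkovConfig

    def to_dict(self) -> dict:
        def strat_dict(s: StrategySpec) -> dict:
            return {
                "name": s.name,
                "injection_schedule": [list(x) for x in s.injection_schedule],
                "per_injection_payer_cost": list(s.per_injection_payer_cost),
                "medication_cost": list(s.medication_cost),
                "utility_by_timepoint": [list(x) for x in s.utility_by_timepoint],
            }

        return {
            "supply_items": [
                {"name": i.name, "unit_cost_usd": i.unit_cost_cents / 100, "quantity": i.quantity}
                for i in self.supply_items
            ],
            "labor": {
                "wage_usd_per_hour": self.labor.wage_cents_per_hour / 100,
                "minutes_per_injection": self.labor.minutes_per_injection,
            },
            "cortico_medication_usd": list(self.cortico_medication_usd),
            "strategies": [strat_dict(s) for s in self.strategies],
            "markov": {
                "horizon_months": self.markov.horizon_months,
                "cycle_months": self.markov.cycle_months,
                "discount_rate": self.markov.discount_rate,
                "wtp": self.markov.wtp,
                "n_psa": self.markov.n_psa,
                "seed": self.markov.seed,
            },
        }


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    patients: pd.DataFrame
    panels: pd.DataFrame  # cbc_panels.csv schema
    outcomes: pd.DataFrame  # outcomes.csv schema
    cost_inputs: CostModelInputs

    @property
    def n_knees(self) -> int:
        return int(self.patients["n_knees"].sum())

    @property
    def n_injections(self) -> int:
        return int(self.panels["injection_id"].nunique())


# ---------------------------------------------------------------------------
# WOMAC latent calibration
# ---------------------------------------------------------------------------

def _mixed_total_quartiles(shape: float, scale: float) -> tuple[float, float, float]:
    """Quartiles of the observed WOMAC total under the gamma-binomial mixture.

    The observed total is Binomial(96, x/96) with latent x ~ Gamma(shape,
    scale); its pmf is computed by quadrature over latent quantiles, and
    quartiles are read off the cdf with each integer's mass spread over a
    unit interval (matching how sample quantiles behave on integer data).
    """
    u = (np.arange(400) + 0.5) / 400.0
    x = stats.gamma.ppf(u, shape, scale=scale)
    p = np.clip(x / MAX_TOTAL, 0.0, 0.97)
    support = np.arange(MAX_TOTAL + 1)
    pmf = stats.binom.pmf(support[:, None], MAX_TOTAL, p[None, :]).mean(axis=1)
    cdf = np.cumsum(pmf)

    def quantile(prob: float) -> float:
        k = int(np.searchsorted(cdf, prob))
        c_prev = cdf[k - 1] if k > 0 else 0.0
        return k - 0.5 + (prob - c_prev) / max(pmf[k], 1e-300)

    return quantile(0.25), quantile(0.5), quantile(0.75)


def _calibrate_latent_gamma(median: float, iqr: float) -> tuple[float, float]:
    """Gamma (shape, scale) such that the *observed* total (after Binomial
    item noise) has the target median and IQR.

    Solved numerically against the exact gamma-binomial mixture; the
    moment-matched latent gamma (median/IQR of the latent itself) seeds the
    optimizer.
    """
    target_ratio = iqr / median

    def latent_ratio(shape: float) -> float:
        q25, q50, q75 = stats.gamma.ppf([0.25, 0.5, 0.75], shape)
        return (q75 - q25) / q50 - target_ratio

    shape0 = optimize.brentq(latent_ratio, 0.05, 500.0)
    scale0 = median / stats.gamma.ppf(0.5, shape0)

    def residuals(log_params: np.ndarray) -> np.ndarray:
        shape, scale = np.exp(log_params)
        q25, q50, q75 = _mixed_total_quartiles(shape, scale)
        return np.array([q50 - median, (q75 - q25) - iqr])

    sol = optimize.least_squares(
        residuals, np.log([shape0, scale0]), xtol=1e-10, ftol=1e-10
    )
    shape, scale = np.exp(sol.x)
    return float(shape), float(scale)


def _latent_severity(
    config: SyntheticConfig, rng: np.random.Generator, knees: pd.DataFrame
) -> np.ndarray:
    """Per-knee latent expected baseline WOMAC total (gamma via Gaussian copula)."""
    shape, scale = _calibrate_latent_gamma(
        config.womac_baseline_median, config.womac_baseline_iqr
    )
    rho = config.bilateral_correlation
    z_pat = {pid: rng.standard_normal() for pid in knees["patient_id"].unique()}
    z = np.array(
        [
            math.sqrt(rho) * z_pat[pid] + math.sqrt(1 - rho) * rng.standard_normal()
            for pid in knees["patient_id"]
        ]
    )
    u = stats.norm.cdf(z)
    return stats.gamma.ppf(u, shape, scale=scale)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _clip_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size=None
):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)

    # --- patients and knees -------------------------------------------------
    n_bilateral = int(round(config.bilateral_fraction * config.n_patients))
    bilateral_flags = np.array(
        [True] * n_bilateral + [False] * (config.n_patients - n_bilateral)
    )
    rng.shuffle(bilateral_flags)

    single_injection = np.zeros(config.n_patients, dtype=bool)
    if config.n_single_injection_patients > 0:
        idx = rng.choice(
            config.n_patients,
            size=min(config.n_single_injection_patients, config.n_patients),
            replace=False,
        )
        single_injection[idx] = True

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(config.n_patients)],
            "age": np.round(_clip_normal(rng, 48.8, 14.2, 21, 85, config.n_patients), 1),
            "sex": np.where(rng.random(config.n_patients) < 0.60, "F", "M"),
            "bmi": np.round(_clip_normal(rng, 26.5, 4.1, 17, 40, config.n_patients), 1),
            "bilateral": bilateral_flags,
            "n_knees": np.where(bilateral_flags, 2, 1),
            "single_injection": single_injection,
        }
    )

    knee_rows = []
    for _, p in patients.iterrows():
        sides = ("L", "R") if p["bilateral"] else (rng.choice(["L", "R"]),)
        for side in sides:
            knee_rows.append(
                {
                    "knee_id": f"{p['patient_id']}{side}",
                    "patient_id": p["patient_id"],
                    "side": side,
                    "kl_grade": int(rng.choice(KL_GRADES, p=KL_GRADE_PROBS)),
                    "n_injections": 1 if p["single_injection"] else 2,
                }
            )
    knees = pd.DataFrame(knee_rows)

    # --- CBC panels ----------------------------------------------------------
    panel_rows = []
    injection_ids = []
    for _, knee in knees.iterrows():
        for j in range(int(knee["n_injections"])):
            injection_ids.append((f"{knee['knee_id']}-I{j + 1}", knee["knee_id"]))

    n_inj = len(injection_ids)
    invalid_wb = np.zeros(n_inj, dtype=bool)
    if config.n_invalid_wb > 0:
        bad = rng.choice(n_inj, size=min(config.n_invalid_wb, n_inj), replace=False)
        invalid_wb[bad] = True

    sigma = math.sqrt(math.log1p(config.measurement_cv**2))
    for i, (inj_id, knee_id) in enumerate(injection_ids):
        # counter granularity: report platelets to 0.1 x10^3/uL and volume to
        # 0.1 mL *before* deriving the PRP concentration, so that with zero
        # noise the observed extraction is exactly the true extraction
        wb_plt = round(
            float(_clip_normal(rng, config.wb_platelet_mean, config.wb_platelet_sd, 20, 600)), 1
        )
        prp_vol = round(
            float(_clip_normal(rng, config.prp_volume_mean, config.prp_volume_sd, 6.0, 22.0)), 1
        )
        true_ext = float(
            _clip_normal(rng, config.true_extraction_mean, config.true_extraction_sd, 0.05, 1.0)
        )
        # PRP platelet mass = true extraction x whole-blood platelet mass,
        # re-expressed over the drawn PRP volume; mean-one log-normal counter noise
        prp_conc_true = true_ext * wb_plt * config.wb_volume / prp_vol
        noise = math.exp(rng.normal(-sigma**2 / 2.0, sigma)) if sigma > 0 else 1.0
        prp_conc = prp_conc_true * noise

        wb_neut = float(_clip_normal(rng, *CBC_REFERENCE["wb_neut"], 0.2, 10))
        wb_lymph = float(_clip_normal(rng, *CBC_REFERENCE["wb_lymph"], 0.2, 5))
        wb_other = float(_clip_normal(rng, *CBC_REFERENCE["wb_other_wbc"], 0.0, 2))
        prp_neut = float(_clip_normal(rng, *CBC_REFERENCE["prp_neut"], 0.0, 1))
        prp_lymph = float(_clip_normal(rng, *CBC_REFERENCE["prp_lymph"], 0.0, 8))
        prp_other = float(_clip_normal(rng, *CBC_REFERENCE["prp_other_wbc"], 0.0, 2))

        panel_rows.append(
            {
                "injection_id": inj_id,
                "knee_id": knee_id,
                "source": "whole_blood",
                "volume_ml": config.wb_volume,
                "plt_1e3_ul": wb_plt,
                "wbc_1e3_ul": round(wb_neut + wb_lymph + wb_other, 2),
                "neut_1e3_ul": round(wb_neut, 2),
                "lymph_1e3_ul": round(wb_lymph, 2),
                "rbc_1e6_ul": round(float(_clip_normal(rng, *CBC_REFERENCE["wb_rbc"], 2, 7)), 2),
                "hb_g_dl": round(float(_clip_normal(rng, *CBC_REFERENCE["wb_hb"], 7, 19)), 1),
                "valid": not invalid_wb[i],
            }
        )
        panel_rows.append(
            {
                "injection_id": inj_id,
                "knee_id": knee_id,
                "source": "prp",
                "volume_ml": prp_vol,
                "plt_1e3_ul": prp_conc,
                "wbc_1e3_ul": round(prp_neut + prp_lymph + prp_other, 2),
                "neut_1e3_ul": round(prp_neut, 2),
                "lymph_1e3_ul": round(prp_lymph, 2),
                "rbc_1e6_ul": round(float(_clip_normal(rng, *CBC_REFERENCE["prp_rbc"], 0, 1)), 2),
                "hb_g_dl": round(float(_clip_normal(rng, *CBC_REFERENCE["prp_hb"], 0, 2)), 2),
                "valid": True,
            }
        )
    panels = pd.DataFrame(panel_rows)

    # --- outcomes ------------------------------------------------------------
    latent_baseline = _latent_severity(config, rng, knees)
    utility_profile = config.utility_profile_by_arm[config.arm]
    utility_by_visit = {
        v: utility_profile[VISIT_MONTHS[v]] if VISIT_MONTHS[v] in utility_profile
        else utility_profile[str(VISIT_MONTHS[v])]
        for v in VISITS
    }

    outcome_rows = []
    for knee_idx, (_, knee) in enumerate(knees.iterrows()):
        for visit in VISITS:
            factor = 1.0 if visit == "baseline" else config.effect_profile[visit]
            expected_total = latent_baseline[knee_idx] * factor
            p_item = min(max(expected_total / MAX_TOTAL, 0.0), 0.97)
            pain = int(rng.binomial(4 * N_PAIN_ITEMS, p_item))
            stiff = int(rng.binomial(4 * N_STIFF_ITEMS, p_item))
            func = int(rng.binomial(4 * N_FUNC_ITEMS, p_item))
            ga = float(
                np.round(
                    _clip_normal(
                        rng,
                        config.global_assessment_profile[visit],
                        config.global_assessment_sd,
                        0,
                        100,
                    )
                )
            )
            utility = float(np.clip(rng.normal(utility_by_visit[visit], config.utility_sd), 0, 1))
            sat_knee = bool(rng.random() < config.satisfaction_probs["knee"][visit])
            sat_proc = (
                bool(rng.random() < config.satisfaction_probs["procedure"][visit])
                if visit != "baseline"
                else None
            )
            outcome_rows.append(
                {
                    "knee_id": knee["knee_id"],
                    "patient_id": knee["patient_id"],
                    "visit": visit,
                    "womac_pain": pain,
                    "womac_stiffness": stiff,
                    "womac_function": func,
                    "womac_total": pain + stiff + func,
                    "global_assessment": ga,
                    "satisfied_with_knee": sat_knee,
                    "satisfied_with_procedure": sat_proc,
                    "eq5d_utility": round(utility, 3),
                }
            )
    outcomes = pd.DataFrame(outcome_rows)

    cost_inputs = generate_cost_inputs(config)
    patients_out = patients.merge(
        knees.groupby("patient_id")["kl_grade"].agg(list).rename("kl_grades"),
        on="patient_id",
    )
    return SyntheticCohort(
        config=config,
        patients=patients_out,
        panels=panels,
        outcomes=outcomes,
        cost_inputs=cost_inputs,
    )


def generate_cost_inputs(config: SyntheticConfig | None = None) -> CostModelInputs:
    """Cost-model inputs: itemized supplies, labor, and PSA-ready (mean, SE) pairs.

    Every PSA-varied parameter carries a (mean, SE) pair; a parameter
    supplied without an SE defaults to SE = 20% of its mean (see
    ``cea.DEFAULT_SE_FRACTION``).
    """
    seed = config.seed if config is not None else 0
    lc_prp, cortico, markov = reference_case(seed=seed)
    return CostModelInputs(
        supply_items=default_supply_items(),
        labor=LaborInput.from_dollars(21.0, 20.0),
        cortico_medication_usd=(10.0, 2.0),
        strategies=(lc_prp, cortico),
        markov=markov,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write cohort files (RFC-4180 CSV, UTF-8) and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort_patients": outdir / "cohort_patients.csv",
        "cbc_panels": outdir / "cbc_panels.csv",
        "outcomes": outdir / "outcomes.csv",
        "cost_inputs": outdir / "cost_inputs.json",
    }
    patients = cohort.patients.copy()
    patients["kl_grades"] = patients["kl_grades"].apply(
        lambda g: "|".join(str(x) for x in g)
    )
    patients.to_csv(paths["cohort_patients"], index=False, lineterminator="\r\n")
    cohort.panels.to_csv(paths["cbc_panels"], index=False, lineterminator="\r\n")
    cohort.outcomes.to_csv(paths["outcomes"], index=False, lineterminator="\r\n")
    with open(paths["cost_inputs"], "w", encoding="utf-8") as fh:
        json.dump(cohort.cost_inputs.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
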