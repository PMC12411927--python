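"""End-to-end orchestration: simulate -> composition -> outcomes -> cost -> CEA.

Runs the full analysis on a synthetic (or ingested) cohort, writes each
stage's output files, a consolidated ``report.json`` mirroring the results
structure of the study (composition summary, outcome tests, per-injection
costs, base-case CEA, PSA), and a ``manifest.json`` with the seed, a config
hash and SHA-256 digests of every file written. The manifest is written even
when a stage fails partway, so partial runs remain auditable.

One global seed fans out to per-stage child seeds by stable hashing of the
stage name, so adding a stage never perturbs another stage's random stream.
All randomness flows through numpy ``default_rng`` instances created from
those child seeds; no stage touches global entropy.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import MarkovConfig, run_base_case, run_psa
from .composition import (
    compute_metrics,
    default_reference_techniques,
    exclude_invalid,
    metrics_to_frame,
    pair_panels,
    read_panels_csv,
    summarize_cohort,
    ReferenceTechnique,
)
from .costing import LaborInput, default_supply_items, dollars_to_cents, injectate_cost
from .outcomes import FOLLOWUP_VISITS, VISITS, mcid_responders, summarize_visit, test_all_visits
from .synthetic import SyntheticConfig, generate_cohort, write_cohort

__all__ = ["RunManifest", "run_all", "child_seed", "validate_config", "DEFAULT_CONFIG"]

logger = logging.getLogger("prpecon")

DEFAULT_CONFIG: dict = {
    "synthetic": {},
    "outcomes": {"mcid": 6.6, "cluster": "knee"},
    "cea": {},
}

_SYNTH_FIELDS = {f.name for f in dc_fields(SyntheticConfig)}
_CEA_FIELDS = {"n_psa", "wtp", "discount_rate", "horizon_months", "cycle_months"}


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed: sha256 of 'seed:stage', folded below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def validate_config(config: dict) -> list[str]:
    """Validate a run configuration; returns a list of 'path: problem' strings."""
    problems: list[str] = []
    if not isinstance(config, dict):
        return ["$: config must be a JSON object"]
    for key in config:
        if key not in DEFAULT_CONFIG:
            problems.append(f"$.{key}: unknown section")
    synth = config.get("synthetic", {})
    if not isinstance(synth, dict):
        problems.append("$.synthetic: must be an object")
    else:
        for key in synth:
            if key not in _SYNTH_FIELDS:
                problems.append(f"$.synthetic.{key}: unknown parameter")
    out = config.get("outcomes", {})
    if not isinstance(out, dict):
        problems.append("$.outcomes: must be an object")
    else:
        if "cluster" in out and out["cluster"] not in ("knee", "patient"):
            problems.append("$.outcomes.cluster: must be 'knee' or 'patient'")
        if "mcid" in out and not (isinstance(out["mcid"], (int, float)) and out["mcid"] > 0):
            problems.append("$.outcomes.mcid: must be a positive number")
    cea_cfg = config.get("cea", {})
    if not isinstance(cea_cfg, dict):
        problems.append("$.cea: must be an object")
    else:
        for key in cea_cfg:
            if key not in _CEA_FIELDS:
                problems.append(f"$.cea.{key}: unknown parameter")
        if "n_psa" in cea_cfg and not (isinstance(cea_cfg["n_psa"], int) and cea_cfg["n_psa"] >= 1):
            problems.append("$.cea.n_psa: must be an integer >= 1")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str
    input_digests: dict = field(default_factory=dict)
    output_files: dict = field(default_factory=dict)  # name -> {path, sha256}
    warnings: list = field(default_factory=list)
    completed_stages: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "input_digests": self.input_digests,
            "output_files": self.output_files,
            "warnings": self.warnings,
            "completed_stages": self.completed_stages,
            "failed_stage": self.failed_stage,
        }


def _merge_config(config: dict | None) -> dict:
    merged = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for key, value in (config or {}).items():
        if isinstance(value, dict):
            merged.setdefault(key, {}).update(value)
        else:
            merged[key] = value
    return merged


def run_all(
    config: dict | str | Path | None = None,
    outdir: str | Path = "results",
    seed: int = 1,
) -> RunManifest:
    """Execute the full pipeline; stage failures halt downstream stages but
    preserve upstream outputs and still write the manifest."""
    input_digests = {}
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        input_digests["config"] = _sha256(cfg_path)
        config = json.loads(cfg_path.read_text())
    problems = validate_config(config or {})
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(problems))
    cfg = _merge_config(config)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    cfg_bytes = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        seed=seed,
        config_hash=hashlib.sha256(cfg_bytes).hexdigest(),
        version=__version__,
        input_digests=input_digests,
    )
    report: dict = {"schema_version": 1, "seed": seed}

    def emit(name: str, path: Path) -> None:
        manifest.output_files[name] = {"path": str(path), "sha256": _sha256(path)}

    def write_json(name: str, path: Path, payload: dict) -> None:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
        emit(name, path)

    try:
        # --- stage 1: simulate -------------------------------------------
        stage = "simulate"
        logger.info("stage %s", stage)
        synth_kwargs = dict(cfg["synthetic"])
        synth_kwargs.setdefault("seed", child_seed(seed, "synthetic"))
        cohort = generate_cohort(SyntheticConfig(**synth_kwargs))
        paths = write_cohort(cohort, outdir)
        for name, path in paths.items():
            emit(name, path)
        manifest.completed_stages.append(stage)

        # --- stage 2: composition ----------------------------------------
        stage = "composition"
        logger.info("stage %s", stage)
        panels = read_panels_csv(paths["cbc_panels"])
        kept, dropped = exclude_invalid(panels)
        if dropped:
            manifest.warnings.append(
                f"{len(dropped)} invalid panel(s) excluded from extraction"
            )
        metrics = [compute_metrics(wb, prp) for wb, prp in pair_panels(panels)]
        summary = summarize_cohort(metrics, default_reference_techniques())
        metrics_to_frame(metrics).to_csv(outdir / "composition_metrics.csv", index=False)
        emit("composition_metrics", outdir / "composition_metrics.csv")
        comp_payload = summary.to_dict()
        comp_payload["n_panels_dropped"] = len(dropped)
        write_json("composition_summary", outdir / "composition_summary.json", comp_payload)
        report["composition"] = comp_payload
        manifest.completed_stages.append(stage)

        # --- stage 3: outcomes -------------------------------------------
        stage = "outcomes"
        logger.info("stage %s", stage)
        mcid = cfg["outcomes"]["mcid"]
        cluster = cfg["outcomes"]["cluster"]
        tests = test_all_visits(
            cohort.outcomes, cluster=cluster, seed=child_seed(seed, "outcomes")
        )
        tests.to_csv(outdir / "outcome_tests.csv", index=False)
        emit("outcome_tests", outdir / "outcome_tests.csv")
        summaries = [summarize_visit(cohort.outcomes, v) for v in VISITS]
        vs_rows = []
        for s in summaries:
            row = {"visit": s["visit"], "n": s["n"]}
            for m in ("womac_total", "womac_pain", "womac_function", "global_assessment"):
                row[f"{m}_median"] = s[m]["median"]
                row[f"{m}_iqr"] = s[m]["iqr"]
            row["satisfied_with_knee"] = s["satisfied_with_knee"]
            row["satisfied_with_procedure"] = s["satisfied_with_procedure"]
            vs_rows.append(row)
        pd.DataFrame(vs_rows).to_csv(outdir / "visit_summaries.csv", index=False)
        emit("visit_summaries", outdir / "visit_summaries.csv")
        responders = pd.DataFrame(
            [mcid_responders(cohort.outcomes, v, mcid) for v in FOLLOWUP_VISITS]
        )
        responders.to_csv(outdir / "responders.csv", index=False)
        emit("responders", outdir / "responders.csv")
        report["outcomes"] = {
            "tests": tests.to_dict(orient="records"),
            "responders": responders.to_dict(orient="records"),
            "unit_of_analysis": cluster,
            "mcid": mcid,
        }
        manifest.completed_stages.append(stage)

        # --- stage 4: micro-costing --------------------------------------
        stage = "cost"
        logger.info("stage %s", stage)
        ci = cohort.cost_inputs
        lc_cost = injectate_cost(ci.supply_items, ci.labor, 0, strategy="lc_prp")
        cortico_cost = injectate_cost(
            [], None, dollars_to_cents(ci.cortico_medication_usd[0]), strategy="corticosteroid"
        )
        cost_payload = {"lc_prp": lc_cost.to_dict(), "corticosteroid": cortico_cost.to_dict()}
        write_json("injection_costs", outdir / "injection_costs.json", cost_payload)
        report["costs"] = cost_payload
        manifest.completed_stages.append(stage)

        # --- stage 5: CEA (base case + PSA) ------------------------------
        stage = "cea"
        logger.info("stage %s", stage)
        intervention, comparator = ci.strategies
        cea_overrides = dict(cfg["cea"])
        markov = MarkovConfig(
            horizon_months=cea_overrides.get("horizon_months", ci.markov.horizon_months),
            cycle_months=cea_overrides.get("cycle_months", ci.markov.cycle_months),
            discount_rate=cea_overrides.get("discount_rate", ci.markov.discount_rate),
            wtp=cea_overrides.get("wtp", ci.markov.wtp),
            n_psa=cea_overrides.get("n_psa", ci.markov.n_psa),
            seed=child_seed(seed, "cea"),
        )
        base = run_base_case(intervention, comparator, markov)
        write_json("base_case", outdir / "base_case.json", base.base_case_dict())
        psa = run_psa(intervention, comparator, markov)
        ce_plane = pd.DataFrame(
            {
                "iteration": range(1, markov.n_psa + 1),
                "delta_cost_usd": psa.psa_delta_cost,
                "delta_qaly": psa.psa_delta_qaly,
            }
        )
        ce_plane.to_csv(outdir / "ce_plane.csv", index=False)
        emit("ce_plane", outdir / "ce_plane.csv")
        psa.ceac_table.to_csv(outdir / "ceac.csv", index=False)
        emit("ceac", outdir / "ceac.csv")
        psa_payload = {
            "n_psa": markov.n_psa,
            "prob_dominant": psa.prob_dominant,
            "prob_cost_effective_at_wtp": psa.prob_cost_effective,
            "wtp_usd_per_qaly": markov.wtp,
            "scaled_down": markov.n_psa < 10_000,
        }
        write_json("psa_summary", outdir / "psa_summary.json", psa_payload)
        report["cea_base_case"] = base.base_case_dict()
        report["psa"] = psa_payload
        manifest.completed_stages.append(stage)
    except Exception:
        manifest.failed_stage = stage
        logger.exception("stage %s failed", stage)
        raise
    finally:
        report_path = outdir / "report.json"
        report_path.write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
        )
        manifest.output_files["report"] = {
            "path": str(report_path),
            "sha256": _sha256(report_path),
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        logger.removeHandler(handler)
        handler.close()

    return manifest
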