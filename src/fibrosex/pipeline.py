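"""Full-analysis orchestration: validate → perturb → drug screen.

One :class:`RunConfig` drives all three stages across the requested sex
conditions and writes a reproducible report bundle: per-stage CSVs plus a
JSON manifest recording the configuration, package version and SHA-256
checksums of every output, so a bundle can be re-run and byte-compared.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .drug_screen import (
    DrugScreenConfig,
    OutputCategories,
    classify_drug_strategies,
    run_drug_screen,
)
from .exceptions import FibrosexError, ProtocolError
from .network_io import (
    load_drug_targets,
    load_network,
    load_validation_records,
    network_summary,
)
from .perturbation_screen import (
    PerturbationConfig,
    influence_scores,
    run_knockdown_screen,
    sensitivity_scores,
)
from .sex_conditions import CONDITION_NAMES, apply_condition, make_condition
from .synthetic_data import (
    make_synthetic_validation_set,
    make_toy_drug_table,
    mini_fibroblast,
    mini_output_categories,
)
from .validation_harness import ValidationProtocol, score_validation

__all__ = ["RunConfig", "run_full_analysis", "summarize_report"]

logger = logging.getLogger("fibrosex.pipeline")


@dataclass
class RunConfig:
    """Everything a full run needs; protocol constants default to the
    calibrated values (EC50 0.65, n 1.05, tension 0.65, knockdown Ymax 0.1,
    drug weight 0.85)."""

    out_dir: str = "fibrosex_run"
    model_path: str | None = None        # None -> bundled mini-fibroblast
    records_path: str | None = None      # None -> synthetic records
    drugs_path: str | None = None        # None -> toy drug table
    conditions: list = field(default_factory=lambda: list(CONDITION_NAMES))
    seed: int = 0
    # protocol constants
    default_n: float = 1.05
    default_ec50: float = 0.65
    tension_w: float = 0.65
    basal_input_w_validation: float = 0.1
    basal_input_w_screen: float = 0.4
    knockdown_ymax: float = 0.1
    w_drug: float = 0.85
    delta_threshold: float = 0.05
    strategy_epsilon: float = 0.05
    mcs_convention: str = "minus"
    signed_perturbation_sums: bool = False
    # synthetic-stage sizes (used only when paths are omitted)
    synthetic_n_records: int = 30
    synthetic_concordance: float = 0.8
    synthetic_n_drugs: int = 6
    stages: list = field(default_factory=lambda: ["validate", "perturb", "drugscreen"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_model(cfg: RunConfig):
    if cfg.model_path is None:
        return mini_fibroblast(), mini_output_categories()
    model = load_network(cfg.model_path, default_n=cfg.default_n,
                         default_ec50=cfg.default_ec50)
    return model, OutputCategories.restricted_to(model)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns the manifest dict.  Any stage failure marks the bundle partial
    with per-stage status rather than aborting the run.
    """
    for name in cfg.conditions:
        if name not in CONDITION_NAMES:
            raise ProtocolError(
                f"unknown condition {name!r}; valid: {', '.join(CONDITION_NAMES)}"
            )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, categories = _load_model(cfg)
    conds = {name: make_condition(name) for name in cfg.conditions}
    male_model = apply_condition(model, make_condition("male"))
    female_model = apply_condition(model, make_condition("female_pre"))

    status: dict[str, str] = {}
    outputs: list[Path] = []
    timings: dict[str, float] = {}

    def _stage(name):
        def deco(fn):
            if name not in cfg.stages:
                status[name] = "skipped"
                return
            t0 = time.perf_counter()
            try:
                fn()
                status[name] = "ok"
            except FibrosexError as err:
                logger.error("stage %s failed: %s", name, err)
                status[name] = f"failed: {err}"
            timings[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: %s (%.2fs)", name, status[name], timings[name])
        return deco

    @_stage("validate")
    def _validate():
        proto = ValidationProtocol(
            tension_w=cfg.tension_w, basal_input_w=cfg.basal_input_w_validation
        )
        if cfg.records_path is not None:
            records = load_validation_records(cfg.records_path)
        else:
            records = make_synthetic_validation_set(
                male_model, female_model, cfg.synthetic_concordance,
                cfg.synthetic_n_records, seed=cfg.seed, proto=proto,
            )
        score = score_validation(records, male_model, female_model, proto,
                                 threshold=cfg.delta_threshold)
        p = out / "validation_records.csv"
        score.per_record.to_csv(p, index=False)
        outputs.append(p)
        rows = [{"group": "overall", "n": score.n_total,
                 "n_match": score.n_match, "accuracy": score.accuracy}]
        rows += [{"group": g, **v} for g, v in sorted(score.by_group.items())]
        if score.estrogen_n:
            rows.append({"group": "estrogen_stimulus", "n": score.estrogen_n,
                         "n_match": score.estrogen_match,
                         "accuracy": score.estrogen_accuracy})
        p = out / "validation_summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs.append(p)

    @_stage("perturb")
    def _perturb():
        pcfg = PerturbationConfig(
            basal_input_w=cfg.basal_input_w_screen,
            knockdown_ymax=cfg.knockdown_ymax,
        )
        for name, cond in conds.items():
            km = run_knockdown_screen(model, cond, pcfg)
            p = out / f"knockdown_matrix_{name}.csv"
            km.D.to_csv(p)
            outputs.append(p)
            inf = influence_scores(km, signed=cfg.signed_perturbation_sums)
            sen = sensitivity_scores(km, signed=cfg.signed_perturbation_sums)
            p = out / f"influence_{name}.csv"
            inf.rename_axis("node").to_csv(p)
            outputs.append(p)
            p = out / f"sensitivity_{name}.csv"
            sen.rename_axis("node").to_csv(p)
            outputs.append(p)
            long = km.D.stack().rename("delta").rename_axis(
                ["knocked", "observed"]).reset_index()
            p = out / f"knockdown_long_{name}.csv"
            long.to_csv(p, index=False)
            outputs.append(p)

    @_stage("drugscreen")
    def _drugscreen():
        if cfg.drugs_path is not None:
            drugs = load_drug_targets(cfg.drugs_path)
        else:
            drugs = make_toy_drug_table(model, cfg.synthetic_n_drugs,
                                        seed=cfg.seed)
        dcfg = DrugScreenConfig(
            w_drug=cfg.w_drug, basal_input_w=cfg.basal_input_w_screen,
            categories=categories, mcs_convention=cfg.mcs_convention,
        )
        effects_by_cond = {}
        rows = []
        for name, cond in conds.items():
            effects = run_drug_screen(model, drugs, cond, dcfg)
            effects_by_cond[name] = effects
            for e in effects:
                rows.append({
                    "condition": name, "drug_id": e.drug_id,
                    "matrix": e.matrix_mean, "protease": e.protease_mean,
                    "inhibitor": e.inhibitor_mean, "mcs_delta": e.mcs_delta,
                    "failed": e.failed,
                })
        p = out / "drug_effects.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs.append(p)
        strategies = classify_drug_strategies(effects_by_cond,
                                              epsilon=cfg.strategy_epsilon)
        p = out / "drug_strategies.csv"
        strategies.to_csv(p)
        outputs.append(p)

    summary = network_summary(model)
    manifest = {
        "package": "fibrosex",
        "version": __version__,
        "config": asdict(cfg),
        "model": {"n_species": summary.n_species,
                  "n_reactions": summary.n_reactions,
                  "source": cfg.model_path or "builtin:mini_fibroblast"},
        "conditions": list(conds),
        "defaults_filling_unstated_parameters": {
            "validation_basal_input_w": cfg.basal_input_w_validation,
            "drug_baseline_hours": 80.0,
            "drug_phase_hours": 240.0,
            "strategy_epsilon": cfg.strategy_epsilon,
            "mcs_convention": cfg.mcs_convention,
            "perturbation_sum": "signed" if cfg.signed_perturbation_sums
                                 else "absolute",
        },
        "stages": status,
        "timings_s": timings,
        "partial": any(s.startswith("failed") for s in status.values()),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    cfg.to_yaml(out / "config.yaml")
    return manifest


def summarize_report(bundle_dir) -> str:
    """Human-readable summary of a report bundle (completed stages only)."""
    bundle = Path(bundle_dir)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        raise ProtocolError(f"{bundle}: no manifest.json (not a report bundle)")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"fibrosex report bundle: {bundle}",
        f"model: {manifest['model']['source']} "
        f"({manifest['model']['n_species']} species, "
        f"{manifest['model']['n_reactions']} reactions)",
    ]
    stages = manifest.get("stages", {})
    if manifest.get("partial"):
        lines.append("NOTE: bundle is partial; failed stages are omitted below")

    if stages.get("validate") == "ok":
        vs = pd.read_csv(bundle / "validation_summary.csv")
        lines.append("\nValidation accuracy by group:")
        for _, r in vs.iterrows():
            lines.append(f"  {r['group']:>18}: {r['accuracy']:.2%} "
                         f"({int(r['n_match'])}/{int(r['n'])})")
    if stages.get("perturb") == "ok":
        for f in sorted(bundle.glob("influence_*.csv")):
            cond = f.stem.replace("influence_", "")
            inf = pd.read_csv(f).head(10)
            sen = pd.read_csv(bundle / f"sensitivity_{cond}.csv").head(10)
            lines.append(f"\nTop influential nodes ({cond}): "
                         + ", ".join(inf["node"]))
            lines.append(f"Top sensitive nodes ({cond}): "
                         + ", ".join(sen["node"]))
    if stages.get("drugscreen") == "ok":
        st = pd.read_csv(bundle / "drug_strategies.csv")
        div = st[st["divergent"]]
        lines.append(f"\nDrug strategies: {len(st)} drugs, "
                     f"{len(div)} with sex-divergent labels")
        for _, r in div.iterrows():
            labels = ", ".join(
                f"{c}={r[c]}" for c in st.columns
                if c not in ("drug_id", "divergent") and not c.startswith("mcs_")
            )
            lines.append(f"  {r['drug_id']}: {labels}")
    elif stages.get("drugscreen") == "skipped":
        lines.append("\n(drug screen stage not run)")
    if not any(v == "ok" for v in stages.values()):
        raise ProtocolError("bundle contains no completed stages")
    return "\n".join(lines)
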