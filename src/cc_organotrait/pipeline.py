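"""End-to-end orchestration: config, child-seed fan-out, stage sequencing
and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cc_organotrait
from cc_organotrait.design import StudyDesign, default_design
from cc_organotrait.cohort_io import write_cohort
from cc_organotrait.models import (
    CVProtocol,
    RegressionProtocol,
    model_grid,
)
from cc_organotrait.qgen import heritability_table
from cc_organotrait.simulate import (
    ORGANS,
    IpgttShape,
    SimulationParams,
    TraitFamilyParams,
    default_params,
    generate_cohort,
)
from cc_organotrait.stats import diet_contrast, pearson_matrix, render_heatmap
from cc_organotrait.traits import derive_traits

__all__ = ["RunConfig", "run_pipeline", "params_from_dict", "config_from_yaml"]

log = logging.getLogger("cc_organotrait")

AUC_WINDOW_MIN = (0, 180)

CORRELATION_TRAITS = [
    "bw0_g", "bw12_g", "delta_bw_g", "auc_wk6", "auc_wk12",
    "liver_g", "spleen_g", "heart_g", "pct_liver", "pct_spleen", "pct_heart",
]

CONTRAST_TRAITS = [
    "delta_bw_g", "auc_wk6", "auc_wk12",
    "liver_g", "spleen_g", "heart_g",
    "pct_liver", "pct_spleen", "pct_heart",
]


@dataclass
class RunConfig:
    """Everything one full run needs; serialisable to/from YAML."""

    out_dir: Path
    seed: int = 0
    simulation: SimulationParams = None  # filled from seed if absent
    cv: CVProtocol = field(default_factory=CVProtocol)
    regression: RegressionProtocol = field(default_factory=RegressionProtocol)
    feature_set: str = "paper-text"
    correlate_by_line: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None:
            self.simulation = default_params(seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "simulation": dataclasses.asdict(self.simulation),
            "cv": dataclasses.asdict(self.cv),
            "regression": dataclasses.asdict(self.regression),
            "feature_set": self.feature_set,
            "correlate_by_line": self.correlate_by_line,
        }


def params_from_dict(d: dict, seed: int = 0) -> SimulationParams:
    """Build SimulationParams from a (possibly partial) nested mapping,
    falling back to the defaults for anything unspecified."""
    base = default_params(seed=seed)
    kwargs: dict = {}
    for fam in ("body_weight", "glucose", "liver", "spleen", "heart"):
        if fam in d:
            merged = {**dataclasses.asdict(getattr(base, fam)), **d[fam]}
            kwargs[fam] = TraitFamilyParams(**merged)
        else:
            kwargs[fam] = getattr(base, fam)
    if "ipgtt" in d:
        kwargs["ipgtt"] = IpgttShape(
            **{**dataclasses.asdict(base.ipgtt), **d["ipgtt"]}
        )
    else:
        kwargs["ipgtt"] = base.ipgtt
    for scalar in ("growth_per_week", "hfd_growth_per_week"):
        kwargs[scalar] = d.get(scalar, getattr(base, scalar))
    kwargs["seed"] = d.get("seed", seed)
    return SimulationParams(**kwargs)


def config_from_yaml(path: str | Path, out_dir: str | Path | None = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    cfg = RunConfig(
        out_dir=Path(out_dir or raw.get("out_dir", "cc_organotrait_run")),
        seed=seed,
        simulation=params_from_dict(raw.get("simulation", {}), seed=seed),
        cv=CVProtocol(**raw.get("classification", {})) if "classification" in raw
        else CVProtocol(seed=seed),
        regression=RegressionProtocol(**raw.get("regression", {}))
        if "regression" in raw
        else RegressionProtocol(seed=seed),
        feature_set=raw.get("feature_set", "paper-text"),
        correlate_by_line=bool(raw.get("correlate_by_line", False)),
    )
    return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    """Counter-based fan-out: stage i always gets the same child seed
    regardless of how many stages run."""
    return [
        int(np.random.SeedSequence([seed, i]).generate_state(1)[0]) for i in range(n)
    ]


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _correlations_long(matrices) -> pd.DataFrame:
    rows = []
    for m in matrices:
        label = ",".join(f"{k}={v}" for k, v in m.stratum.items())
        for i, ti in enumerate(m.traits):
            for tj in m.traits[i:]:
                rows.append({
                    "stratum": label, "trait_a": ti, "trait_b": tj,
                    "r": m.r.loc[ti, tj], "n": int(m.n.loc[ti, tj]),
                    "undefined": bool(m.undefined.loc[ti, tj]),
                })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, design: StudyDesign | None = None) -> dict:
    """Run simulate -> traits -> heritability -> correlations/contrasts ->
    classification/regression grids; write everything under
    ``config.out_dir`` and return the manifest dict.

    A rerun with the same config produces identical numeric outputs.
    """
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="[%(name)s] %(message)s", force=False,
    )
    design = design or default_design()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "heatmaps").mkdir(exist_ok=True)
    cfg_hash = _config_hash(config)
    sim_seed, cv_seed, reg_seed = _child_seeds(config.seed, 3)

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stage_seeds": {"simulate": sim_seed, "classify": cv_seed, "regress": reg_seed},
        "versions": {
            "cc_organotrait": cc_organotrait.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "protocol": {
            "cv_folds": config.cv.k,
            "cv_stratified": config.cv.stratified,
            "regression_iterations": config.regression.iterations,
            "regression_train_fraction": config.regression.train_fraction,
            "label_percentile": 70.0,
            "auc_window_min": list(AUC_WINDOW_MIN),
            "feature_set": config.feature_set,
        },
        "stages": {},
        "outputs": {},
        "complete": False,
    }

    def _register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "config_hash": cfg_hash,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    stage = "simulate"
    try:
        log.info("stage=simulate seed=%d", sim_seed)
        sim_params = dataclasses.replace(config.simulation, seed=sim_seed)
        records = generate_cohort(design, sim_params)
        cohort_path = out / "cohort.csv"
        write_cohort(records, cohort_path)
        manifest["stages"]["simulate"] = {"n_records": len(records)}
        _register("cohort", cohort_path)

        stage = "traits"
        log.info("stage=traits")
        traits = derive_traits(records)
        traits_path = out / "traits.csv"
        traits.to_csv(traits_path, index=False)
        manifest["stages"]["traits"] = {"n_rows": len(traits)}
        _register("traits", traits_path)

        stage = "heritability"
        log.info("stage=heritability")
        h2 = heritability_table(traits)
        h2_path = out / "h2_table.csv"
        h2.to_csv(h2_path, index=False)
        manifest["stages"]["heritability"] = {"n_rows": len(h2)}
        _register("h2_table", h2_path)

        stage = "correlations"
        log.info("stage=correlations")
        matrices = []
        for sex in ("F", "M"):
            for diet in ("CHD", "HFD"):
                m = pearson_matrix(
                    traits, {"sex": sex, "diet": diet}, CORRELATION_TRAITS
                )
                matrices.append(m)
                render_heatmap(m, out / "heatmaps" / f"corr_{sex}_{diet}.png")
        if config.correlate_by_line:
            for line in design.lines:
                sub = traits[traits["line"] == line]
                if len(sub) >= 3:
                    m = pearson_matrix(traits, {"line": line}, CORRELATION_TRAITS)
                    matrices.append(m)
                    render_heatmap(m, out / "heatmaps" / f"corr_line_{line}.png")
        corr = _correlations_long(matrices)
        corr_path = out / "correlations.csv"
        corr.to_csv(corr_path, index=False)
        manifest["stages"]["correlations"] = {
            "n_matrices": len(matrices), "n_rows": len(corr),
        }
        _register("correlations", corr_path)

        stage = "contrasts"
        log.info("stage=contrasts")
        contrast_rows = []
        for trait in CONTRAST_TRAITS:
            for sex in ("F", "M"):
                contrast_rows.append(vars(diet_contrast(traits, trait, sex=sex)))
                for line in design.lines:
                    contrast_rows.append(
                        vars(diet_contrast(traits, trait, line=line, sex=sex))
                    )
        contrasts = pd.DataFrame(contrast_rows)
        contrasts_path = out / "contrasts.csv"
        contrasts.to_csv(contrasts_path, index=False)
        manifest["stages"]["contrasts"] = {"n_rows": len(contrasts)}
        _register("contrasts", contrasts_path)

        stage = "models"
        log.info("stage=models")
        cv_protocol = dataclasses.replace(config.cv, seed=cv_seed)
        reg_protocol = dataclasses.replace(config.regression, seed=reg_seed)
        grid_counts = {}
        for organ in ORGANS:
            for task, protocol_kw in (
                ("classify", {"cv_protocol": cv_protocol}),
                ("regress", {"reg_protocol": reg_protocol}),
            ):
                grid = model_grid(
                    traits, organ, task,
                    feature_set=config.feature_set, **protocol_kw,
                )
                path = out / f"{task}_{organ}.json"
                path.write_text(json.dumps(grid.to_json_dict(), indent=2))
                _register(f"{task}_{organ}", path)
                grid_counts[f"{task}_{organ}"] = {
                    "models": len(grid.scores.index), "lines": len(grid.lines),
                }
        manifest["stages"]["models"] = grid_counts
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest
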