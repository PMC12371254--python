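"""End-to-end orchestration: simulate/load → QC → index → call → stage → DE → dynamics.

`run_core` executes the workflow in memory and returns every intermediate
result; `run_pipeline` wraps it with YAML configuration, TSV/JSON outputs and
a run manifest. All outputs are byte-deterministic for a fixed config (no
timestamps are written), so reruns can be verified by checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import Cohort, STATE_LABELS, load_cohort_dir
from .preprocess import normalize_log, qc_filter, select_hvg
from .disease_index import IndexModelConfig, IndexResult, compute_disease_index
from .risk_calling import (SlidingWindowResult, call_risk_fixed,
                           call_risk_quantile, call_risk_sliding_window,
                           threshold_sensitivity)
from .staging_assoc import (donor_risk_proportions, fit_stage_classifier,
                            group_compare, pearson_assoc, stage_donors)
from .downstream import (de_test, pseudobulk_aggregate, risk_aggregation_dynamics,
                         subtype_cluster)
from .synthetic_cohort import SimConfig, SimTruth, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "index", "call", "stage", "associate", "de", "dynamics")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def sim_config_from_dict(d: dict, seed: int | None = None) -> SimConfig:
    kwargs = dict(d or {})
    if seed is not None:
        kwargs.setdefault("seed", seed)
    return SimConfig(**kwargs)


@dataclass
class CoreResult:
    """In-memory results of one workflow run."""

    cohort: Cohort
    truth: SimTruth | None = None
    index: IndexResult | None = None
    calls: pd.DataFrame | None = None
    window: SlidingWindowResult | None = None
    profiles: pd.DataFrame | None = None
    staging: object | None = None
    classifier: dict | None = None
    group_tests: pd.DataFrame | None = None
    associations: pd.DataFrame | None = None
    de: pd.DataFrame | None = None
    clusters: pd.Series | None = None
    dynamics: pd.DataFrame | None = None
    sensitivity: pd.DataFrame | None = None


def run_core(
    cohort: Cohort,
    truth: SimTruth | None = None,
    cell_type: str = "beta",
    seed: int = 0,
    qc: dict | None = None,
    normalize: dict | None = None,
    hvg: dict | None = None,
    index: dict | None = None,
    call: dict | None = None,
    stage: dict | None = None,
    associate: dict | None = None,
    de: dict | None = None,
    dynamics: dict | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> CoreResult:
    """Run the analysis stages on an in-memory cohort.

    Stage dicts mirror the YAML config blocks; omitted keys take the package
    defaults. Stages not listed in ``stages`` are skipped (later stages that
    depend on them are skipped too).
    """
    res = CoreResult(cohort=cohort, truth=truth)
    qc = qc or {}
    call_cfg = dict(call or {})
    stage_cfg = dict(stage or {})

    if "qc" in stages:
        n0 = cohort.n_cells
        cohort = qc_filter(cohort,
                           int(qc.get("min_genes_per_cell", 200)),
                           int(qc.get("min_cells_per_gene", 3)))
        logger.info("qc: %d -> %d cells, %d genes", n0, cohort.n_cells, cohort.n_genes)
        res.cohort = cohort

    if "index" not in stages:
        return res
    idx_kwargs = dict(index or {})
    n_hvg = int((hvg or {}).get("n_top", 2000))
    scale = float((normalize or {}).get("scale", 1e4))
    idx_kwargs.setdefault("seed", seed)
    cfg = IndexModelConfig(**idx_kwargs)
    res.index = compute_disease_index(cohort, cell_type, cfg, scale=scale, n_hvg=n_hvg)
    logger.info("index: scored %d %s cells", len(res.index.table), cell_type)

    if "call" not in stages:
        return res
    method = call_cfg.get("method", "sliding_window")
    if method == "fixed":
        res.calls = call_risk_fixed(res.index, float(call_cfg.get("threshold", 0.89)))
    elif method == "quantile":
        res.calls = call_risk_quantile(res.index, float(call_cfg.get("q", 0.9)))
    elif method == "sliding_window":
        grid = call_cfg.get("grid")
        res.window = call_risk_sliding_window(
            res.index, cohort, grid=None if grid is None else np.asarray(grid, float),
            min_risk_fraction=float(call_cfg.get("min_risk_fraction", 0.01)),
            cut_low=float(stage_cfg.get("cut_low", 0.10)),
            cut_high=float(stage_cfg.get("cut_high", 0.20)))
        res.calls = res.window.calls
    else:
        raise ValueError(f"unknown calling method {method!r}")
    logger.info("call: %d / %d cells flagged (method=%s, threshold=%.3f)",
                int(res.calls["is_risk"].sum()), len(res.calls), method,
                res.calls["threshold"].iloc[0])
    if call_cfg.get("sensitivity_grid") is not None:
        res.sensitivity = threshold_sensitivity(
            res.index, cohort, np.asarray(call_cfg["sensitivity_grid"], float))

    if "stage" in stages:
        res.profiles = donor_risk_proportions(res.calls, cohort)
        res.staging = stage_donors(
            res.profiles,
            cut_low=float(stage_cfg.get("cut_low", 0.10)),
            cut_high=float(stage_cfg.get("cut_high", 0.20)),
            n_boot=int(stage_cfg.get("n_boot", 2000)),
            level=float(stage_cfg.get("level", 0.95)),
            seed=int(stage_cfg.get("seed", seed)))
        try:
            res.classifier = fit_stage_classifier(res.profiles)
        except ValueError as err:
            logger.info("stage: classifier skipped (%s)", err)
        try:
            res.group_tests = group_compare(res.profiles)
        except ValueError as err:
            logger.info("stage: group comparison skipped (%s)", err)

    if "associate" in stages and res.profiles is not None:
        covs = (associate or {}).get("covariates", ["hba1c", "bmi", "c_peptide", "age"])
        rows = []
        for cov in covs:
            if cov not in cohort.donors.columns:
                logger.info("associate: covariate %s absent, skipped", cov)
                continue
            x = cohort.donors[cov].reindex(res.profiles.index).to_numpy(dtype=float)
            try:
                r, p, n = pearson_assoc(x, res.profiles["proportion"].to_numpy())
                rows.append({"covariate": cov, "r": r, "p": p, "n": n})
            except ValueError as err:
                logger.info("associate: %s skipped (%s)", cov, err)
        res.associations = pd.DataFrame(rows)

    if "de" in stages:
        try:
            pb = pseudobulk_aggregate(cohort, res.calls,
                                      min_cells=int((de or {}).get("min_cells", 10)))
            res.de = de_test(pb)
            logger.info("de: %d genes tested, %d at p_adj<0.05", len(res.de),
                        int((res.de["p_adj"] < 0.05).sum()))
        except ValueError as err:
            logger.info("de: skipped (%s)", err)

    if "dynamics" in stages:
        dyn = dict(dynamics or {})
        from .data_model import subset_by_cell_type
        sub = subset_by_cell_type(cohort, cell_type)
        norm = select_hvg(normalize_log(sub, scale=scale),
                          min(n_hvg, cohort.n_genes))
        res.clusters = subtype_cluster(
            norm,
            n_neighbors=int(dyn.get("n_neighbors", 15)),
            n_pcs=int(dyn.get("n_pcs", 30)),
            resolution=float(dyn.get("resolution", 1.0)),
            seed=int(dyn.get("seed", seed)))
        res.dynamics = risk_aggregation_dynamics(res.clusters, res.calls, cohort)
    return res


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """Execute the configured workflow, writing TSV/JSON outputs and a manifest.

    The YAML config has top-level keys ``seed``, ``cell_type``, ``out``,
    ``stages`` (subset of {simulate, qc, index, call, stage, associate, de,
    dynamics}), an input block (``simulate: {...}`` or ``input: {dir: ...}``),
    and per-stage parameter blocks. On stage failure a FAILED marker naming
    the stage is left in the output directory and the error re-raised.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    out = Path(out_dir or cfg.get("out", "scriskcell_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = tuple(cfg.get("stages", ALL_STAGES))
    cell_type = cfg.get("cell_type", "beta")

    input_checksums = {}
    current = "setup"
    try:
        if "simulate" in stages or "simulate" in cfg:
            current = "simulate"
            sim_cfg = sim_config_from_dict(cfg.get("simulate"), seed=seed)
            cohort, truth = simulate_cohort(sim_cfg)
            if "simulate" in stages:
                write_cohort(cohort, truth, out / "cohort")
        elif "input" in cfg:
            current = "load"
            cohort_dir = Path(cfg["input"]["dir"])
            cohort = load_cohort_dir(cohort_dir,
                                     state_aliases=cfg["input"].get("state_aliases"))
            truth = None
            for f in sorted(cohort_dir.glob("*.tsv")) + sorted(cohort_dir.glob("*.mtx")):
                input_checksums[f.name] = _sha256(f)
        else:
            raise ValueError("config needs either a 'simulate' block or an 'input' block")

        current = "analysis"
        res = run_core(cohort, truth, cell_type=cell_type, seed=seed,
                       qc=cfg.get("qc"), normalize=cfg.get("normalize"),
                       hvg=cfg.get("hvg"), index=cfg.get("index"),
                       call=cfg.get("call"), stage=cfg.get("stage"),
                       associate=cfg.get("associate"), de=cfg.get("de"),
                       dynamics=cfg.get("dynamics"), stages=stages)

        current = "write"
        outputs = {}
        if res.index is not None:
            p = out / "index.tsv"
            res.index.table.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["index"] = p.name
            pd.Series(res.index.donor_folds, name="fold").rename_axis("donor_id") \
                .reset_index().to_csv(out / "donor_folds.tsv", sep="\t", index=False)
            outputs["donor_folds"] = "donor_folds.tsv"
        if res.calls is not None:
            p = out / "risk.tsv"
            res.calls.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["risk"] = p.name
        if res.window is not None:
            p = out / "window_trace.tsv"
            res.window.trace.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["window_trace"] = p.name
        if res.sensitivity is not None:
            p = out / "threshold_sensitivity.tsv"
            res.sensitivity.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["threshold_sensitivity"] = p.name
        if res.profiles is not None:
            p = out / "donor_profiles.tsv"
            prof = res.profiles.copy()
            prof["state"] = prof["state"].map(STATE_LABELS)
            prof.reset_index().to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["donor_profiles"] = p.name
        if res.staging is not None:
            report = {
                "rule_cutoffs": list(res.staging.cutoffs),
                "rule_accuracy": res.staging.accuracy,
                "predicted_state": {d: STATE_LABELS[int(s)]
                                    for d, s in res.staging.predicted_state.items()},
                "pairwise": {k: {kk: vv for kk, vv in v.items() if kk != "curve"}
                             for k, v in res.staging.pairwise.items()},
            }
            if res.classifier is not None:
                report["svm"] = {k: {"auc": v["auc"], "classifier": v["classifier"]}
                                 for k, v in res.classifier.items()}
            if res.group_tests is not None:
                report["group_tests"] = res.group_tests.to_dict(orient="records")
            if res.associations is not None and len(res.associations):
                report["associations"] = res.associations.to_dict(orient="records")
            _write_json(report, out / "staging.json")
            outputs["staging"] = "staging.json"
        if res.de is not None:
            p = out / "de.tsv"
            res.de.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["de"] = p.name
        if res.clusters is not None:
            p = out / "clusters.tsv"
            res.clusters.rename_axis("cell_id").reset_index() \
                .to_csv(p, sep="\t", index=False)
            outputs["clusters"] = p.name
        if res.dynamics is not None:
            p = out / "dynamics.tsv"
            res.dynamics.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["dynamics"] = p.name

        manifest = {
            "tool": "scriskcell",
            "version": __version__,
            "seed": seed,
            "stages": list(stages),
            "cell_type": cell_type,
            "config": cfg,
            "input_checksums": input_checksums,
            "outputs": outputs,
        }
        _write_json(manifest, out / "manifest.json")
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {current}\nerror: {err}\n")
        raise PipelineError(f"stage '{current}' failed: {err}") from err
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return out
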