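"""End-to-end orchestration: simulate -> call -> filter -> impute ->
quantitative statistics -> GWAS / genomic selection -> cross-validation.

A single TOML config (or dict) drives the run; every stage writes its
artifact into the output directory and the run closes with a manifest
recording seeds, per-stage marker counts, the genomic-control lambda and
CV summaries, keyed by a hash of the config so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .calling import MISSING, CallingThresholds, call_matrix, filter_markers_by_callrate
from .crossval import kfold_accuracy
from .gsmodels import MODEL_REGISTRY
from .gwas import gwas_scan
from .impute import ImputeConfig, knn_impute
from .quantstats import fit_variance_components, heritability_broad, progeny_blups
from .simdata import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "call", "filter", "impute", "quantstats", "gwas", "cv")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_seed(master_seed: int | None, stage_index: int) -> int | None:
    if master_seed is None:
        return None
    state = np.random.SeedSequence([master_seed, stage_index]).generate_state(1)[0]
    return int(state % (2**31 - 1))


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    writer(tmp)
    tmp.rename(path)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the enabled stages in order and return the run manifest."""
    if not isinstance(config, dict):
        config = io.read_toml(config)
    out = Path(outdir or config.get("outdir", "tetrags_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    master_seed = config.get("seed")
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": master_seed,
        "stages": list(stages),
        "counts": {},
    }

    genos = rc = None
    coded = None
    phenos = None
    truth = None

    if "simulate" in stages:
        try:
            sim_kwargs = dict(config.get("simdata", {}))
            sim_kwargs.setdefault("seed", _stage_seed(master_seed, 0))
            if "maf_range" in sim_kwargs:
                sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
            sc = SimConfig(**sim_kwargs)
            genos, rc, phenos, truth = simulate_dataset(sc)
            _atomic_write(out / "read_counts.tsv", lambda p: io.write_read_counts_tsv(rc, p))
            _atomic_write(out / "phenotypes.csv", lambda p: io.write_phenotypes_csv(phenos, p))
            _atomic_write(out / "truth.csv", lambda p: io.write_truth_csv(truth, p))
            manifest["counts"]["simulated_markers"] = genos.n_markers
            manifest["counts"]["samples"] = genos.n_samples
            manifest["simdata_seed"] = sc.seed
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", exc) from exc
    else:
        rc_path = config.get("read_counts")
        if rc_path:
            rc = io.read_read_counts_tsv(rc_path)
        ph_path = config.get("phenotypes")
        if ph_path:
            phenos = io.read_phenotypes_csv(ph_path)

    if "call" in stages:
        try:
            thr = CallingThresholds(**config.get("calling", {}))
            coded = call_matrix(rc, thr)
            manifest["counts"]["called_markers"] = coded.n_markers
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("call", exc) from exc

    if "filter" in stages:
        try:
            thr = CallingThresholds(**config.get("calling", {}))
            coded = filter_markers_by_callrate(coded, thr.max_missing_rate)
            _atomic_write(out / "genotypes_filtered.tsv", lambda p: io.write_codes_tsv(coded, p))
            manifest["counts"]["retained_markers"] = coded.n_markers
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("filter", exc) from exc

    if "impute" in stages:
        try:
            coded = knn_impute(coded, ImputeConfig(**config.get("impute", {})))
            _atomic_write(out / "genotypes_imputed.tsv", lambda p: io.write_codes_tsv(coded, p))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("impute", exc) from exc

    adjusted = None
    if "quantstats" in stages:
        try:
            trait = config.get("quantstats", {}).get("trait")
            vc = fit_variance_components(phenos, trait)
            adjusted = progeny_blups(phenos, trait)
            _atomic_write(
                out / "adjusted_phenotypes.csv",
                lambda p: adjusted.rename("value").to_csv(p, index_label="progeny"),
            )
            manifest["h2_broad"] = heritability_broad(vc)
            manifest["variance_components"] = {
                "sigma2_g": vc.sigma2_g, "sigma2_ge": vc.sigma2_ge, "sigma2_e": vc.sigma2_e,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("quantstats", exc) from exc

    if "gwas" in stages:
        try:
            if coded is None:
                raise ValueError("gwas requires called genotypes")
            if (coded.codes == MISSING).any():
                raise ValueError(
                    "genotype matrix still contains MISSING codes; enable the "
                    "impute stage (or provide a complete matrix) before gwas"
                )
            y = adjusted.reindex(coded.sample_ids).to_numpy()
            records, lam = gwas_scan(coded, y)
            _atomic_write(out / "gwas.tsv", lambda p: records.to_csv(p, sep="\t", index=False))
            manifest["gc_lambda"] = lam
            manifest["counts"]["significant_markers"] = int(records["significant"].sum())
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("gwas", exc) from exc

    if "cv" in stages:
        try:
            cv_cfg = dict(config.get("cv", {}))
            model_name = cv_cfg.pop("model", "rrblup")
            n_folds = int(cv_cfg.pop("folds", 10))
            n_reps = int(cv_cfg.pop("reps", 10))
            model = MODEL_REGISTRY[model_name](**cv_cfg.pop("model_params", {}))
            y = adjusted.reindex(coded.sample_ids).to_numpy()
            res = kfold_accuracy(
                model, coded.codes.astype(float), y,
                n_folds=n_folds, n_reps=n_reps,
                seed=_stage_seed(master_seed, 6), model_tag=model_name,
            )
            _atomic_write(out / "cv_accuracies.csv", lambda p: res.to_frame().to_csv(p, index=False))
            manifest["cv"] = res.summary()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cv", exc) from exc

    _atomic_write(out / "manifest.json", lambda p: Path(p).write_text(json.dumps(manifest, indent=2)))
    return manifest
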