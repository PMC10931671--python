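"""End-to-end orchestration: load/simulate -> filter -> impute -> standardize
-> differential + PCA -> class-separation screen -> masked SFS -> RF ranking
-> consolidated report.

Every stochastic stage derives its seeds from one master seed, so an
identical config yields byte-identical output bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .class_separation import screen_class_separating
from .differential import pca_summary, run_differential, volcano_table
from .feature_importance_rf import (RfHyperparams, default_grid, rf_repeated,
                                    tune_rf_oob)
from .feature_selection_svm import runs_table, sfs_repeated
from .io_quant import (ProteinQuantTable, read_quant_table, write_quant_table,
                       write_results_table)
from .preprocess import filter_by_peptide_evidence, impute_missing, standardize
from .synthetic_data import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the full analysis; see docs/methods.md for rationale."""

    # input: either both paths, or a synthetic spec
    table_path: str | None = None
    annotation_path: str | None = None
    synthetic: SyntheticSpec | None = None
    # contrast: (numerator, denominator) for FC orientation
    contrast: tuple[str, str] = ("resilient", "susceptible")
    # preprocessing
    min_peptides: int = 2
    min_unique: int = 2
    impute: str = "mean"
    sd_divisor: str = "n"
    # differential
    t_variant: str = "student"
    fc_up: float = 1.2
    fc_down: float = 0.80
    alpha: float = 0.05
    volcano_y: str = "q"
    # ML stages
    n_folds: int = 7
    sfs_reps: int = 100
    rf_reps: int = 100
    rf_top_k: int = 50
    rf_tune: bool = True
    rf_hyperparams: RfHyperparams | None = None
    svm_C: float = 1.0
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        has_files = self.table_path is not None and self.annotation_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("config needs either table+annotation paths or a "
                             "synthetic spec, not both / neither")
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise ValueError(f"contrast must name two distinct groups: {self.contrast}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "contrast" in d:
            d["contrast"] = tuple(d["contrast"])
        if "synthetic" in d and d["synthetic"] is not None:
            syn = dict(d["synthetic"])
            if "de_log2fc_range" in syn:
                syn["de_log2fc_range"] = tuple(syn["de_log2fc_range"])
            d["synthetic"] = SyntheticSpec(**syn)
        if "rf_hyperparams" in d and d["rf_hyperparams"] is not None:
            d["rf_hyperparams"] = RfHyperparams(**d["rf_hyperparams"])
        return cls(**d)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write one TSV per stage plus report.json.

    Returns the report dict.  Deterministic: the same config (including the
    master seed) produces byte-identical files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("resilioprot")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    # out_dir identifies the run location, not the analysis; keep it out of
    # the report so identical analyses produce identical bundles anywhere
    cfg_json = _jsonable(config)
    cfg_json.pop("out_dir", None)
    report: dict = {"version": __version__, "config": cfg_json, "stages": {}}
    try:
        # -- input ----------------------------------------------------
        if config.synthetic is not None:
            table, truth = generate_dataset(config.synthetic)
            write_quant_table(table, out / "simulated_table.tsv",
                              out / "simulated_annotation.csv")
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(_jsonable({"de_effects": truth.de_effects,
                                     "classsep": truth.classsep,
                                     "pairsep_ids": truth.pairsep_ids}),
                          fh, indent=1, sort_keys=True)
            logger.info("simulated table: %d proteins x %d samples",
                        table.n_proteins, table.n_samples)
        else:
            table = read_quant_table(config.table_path, config.annotation_path)
            logger.info("loaded table: %d proteins x %d samples",
                        table.n_proteins, table.n_samples)
        report["stages"]["input"] = {"n_proteins": table.n_proteins,
                                     "n_samples": table.n_samples}

        # -- preprocess -----------------------------------------------
        filtered = filter_by_peptide_evidence(table, config.min_peptides,
                                              config.min_unique)
        imputed = impute_missing(filtered, method=config.impute)
        std = standardize(imputed, sd_divisor=config.sd_divisor)
        report["stages"]["preprocess"] = {
            "n_after_evidence_filter": filtered.n_proteins,
            "n_after_impute": imputed.n_proteins,
        }

        num, den = config.contrast
        contrast_samples = [s for s in imputed.sample_ids
                            if imputed.sample_group[s] in (num, den)]
        sub = imputed.subset_samples(contrast_samples)

        # -- differential + PCA ---------------------------------------
        de = run_differential(sub, num, den, variant=config.t_variant,
                              fc_up=config.fc_up, fc_down=config.fc_down,
                              alpha=config.alpha)
        write_results_table(de, out / "differential.tsv")
        write_results_table(volcano_table(de, y=config.volcano_y),
                            out / "volcano.tsv")
        sub_std = standardize(sub, sd_divisor=config.sd_divisor)
        pca = pca_summary(sub_std, n_components=2)
        pca_df = pca.scores.reset_index(names="sample")
        pca_df["group"] = [sub.sample_group[s] for s in pca.scores.index]
        write_results_table(pca_df, out / "pca_scores.tsv")
        report["stages"]["differential"] = {
            "n_up": int((de["call"] == "up").sum()),
            "n_down": int((de["call"] == "down").sum()),
            "pca_explained_fraction": [round(float(v), 6)
                                       for v in pca.explained_fraction],
        }

        # -- class separation -----------------------------------------
        cs_records, separating_ids = screen_class_separating(
            sub_std, sub, contrast=(num, den))
        write_results_table(cs_records, out / "class_separating.tsv")
        report["stages"]["class_separation"] = {"n_separating": len(separating_ids)}
        logger.info("class separation: %d separating features", len(separating_ids))

        # -- masked SFS -----------------------------------------------
        labels = sub.labels_for((num, den))
        X = sub_std.values[list(labels.index)].to_numpy().T
        y = (labels.to_numpy() == num).astype(int)
        sfs_agg, sfs_runs = sfs_repeated(
            X, y, sub.protein_ids, set(separating_ids),
            n_repetitions=config.sfs_reps, master_seed=config.seed,
            n_folds=config.n_folds, C=config.svm_C)
        write_results_table(sfs_agg, out / "sfs_aggregate.tsv")
        write_results_table(runs_table(sfs_runs), out / "sfs_runs.tsv")
        max_acc = max(r.final_cv_accuracy for r in sfs_runs)
        report["stages"]["sfs"] = {
            "n_repetitions": config.sfs_reps,
            "n_masked": len(separating_ids),
            "max_final_cv_accuracy": round(float(max_acc), 6),
        }
        logger.info("SFS: max final CV accuracy %.3f over %d repetitions",
                    max_acc, config.sfs_reps)

        # -- RF importance ranking ------------------------------------
        if config.rf_hyperparams is not None:
            hp = config.rf_hyperparams
        elif config.rf_tune:
            hp = tune_rf_oob(X, y, default_grid(), seed=config.seed)
        else:
            hp = RfHyperparams()
        rf_agg, _ = rf_repeated(X, y, sub.protein_ids, hp,
                                n_repetitions=config.rf_reps,
                                master_seed=config.seed,
                                top_k=min(config.rf_top_k, sub.n_proteins))
        write_results_table(rf_agg, out / "rf_aggregate.tsv")
        report["stages"]["rf"] = {
            "n_repetitions": config.rf_reps,
            "hyperparams": _jsonable(hp),
            "top_k": min(config.rf_top_k, sub.n_proteins),
        }

        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
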