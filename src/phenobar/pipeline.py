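"""End-to-end orchestration: simulate -> normalize -> BMC -> barcodes -> classify.

``run_full_study`` executes the whole two-stream analysis from a single
configuration: the behavioral stream is always run (simulated screen unless a
wells CSV is supplied), the chemical stream only when a descriptor CSV is
provided.  Each stream is classified with the four approaches (PCoA-LDA,
UMAP-LDA, ANNE, SVM), with and without the counterion class, and the run is
summarized in a reproducibility manifest (inputs, derived seeds, artifact
hashes, per-stage summaries).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import bmc as bmc_mod
from .barcode import barcode_matrix
from .compounds import (ClassLabel, experimental_counterions, experimental_drugs,
                        study_compound_table)
from .endpoints import default_endpoint_registry, normalize_screen
from .errors import PhenobarError, ValidationError
from .features import cull_model_descriptors, standardize
from .matrix import FeatureMatrix, read_feature_matrix, write_feature_matrix
from .mlmodels import battery_summary, rank_models, run_model_battery
from .ordination import gower_distance, jackknife_pipeline, select_pcoa_axes, \
    umap_param_search
from .simulate import simulate_screen
from .tables import bmc_to_csv, normalized_to_csv, wells_to_csv

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "phenobar_run"
    n_boot: int = 1000
    n_models: int = 10
    max_levels: int = 5
    test_ratio: float = 0.22
    drop_inactive: bool = True
    counterion_variants: tuple[bool, ...] = (True, False)
    descriptor_csv: str | None = None
    wells_csv: str | None = None
    pcoa_m_range: tuple[int, int] = (2, 10)
    umap_grid: tuple[dict, ...] = field(default_factory=lambda: tuple(
        {"n_neighbors": k, "min_dist": d} for k in (4, 8, 12) for d in (0.1, 0.5)))
    ga_options: dict = field(default_factory=dict)
    anne_options: dict = field(default_factory=dict)
    svm_options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _classify_stream(m: FeatureMatrix, cfg: RunConfig, seeds, tag: str,
                     outdir: Path, manifest: dict) -> None:
    """Run the four classifiers on one prepared feature matrix."""
    labels = m.class_labels
    n = m.n_rows
    reports: dict[str, object] = {}

    lo, hi = cfg.pcoa_m_range
    m_best, jk = select_pcoa_axes(m, labels, range(lo, min(hi, n - 2) + 1))
    reports["pcoa_lda"] = {"m_axes": m_best,
                           "accuracy_jackknifed": jk.accuracy_jackknifed,
                           "accuracy_unadjusted": jk.accuracy_unadjusted,
                           "confusion": jk.confusion.counts.tolist(),
                           "class_order": [str(c) for c in jk.confusion.class_order]}

    grid = [g for g in cfg.umap_grid if g["n_neighbors"] < n]
    params, _emb, sil = umap_param_search(gower_distance(m), labels, grid,
                                          seed=int(seeds[0]))
    jk_u = jackknife_pipeline(m, labels, "umap", umap_params=params,
                              seed=int(seeds[0]))
    reports["umap_lda"] = {"params": params, "silhouette": sil,
                           "accuracy_jackknifed": jk_u.accuracy_jackknifed,
                           "accuracy_unadjusted": jk_u.accuracy_unadjusted,
                           "confusion": jk_u.confusion.counts.tolist()}

    for model_type, opts, seed in (("anne", cfg.anne_options, seeds[1]),
                                   ("svm", cfg.svm_options, seeds[2])):
        battery = run_model_battery(m, model_type, cfg.n_models,
                                    master_seed=int(seed), test_ratio=cfg.test_ratio,
                                    ga_options=cfg.ga_options, model_options=opts)
        ranking = rank_models(battery, model_type)
        best = next(r for r in battery if r.model_id == ranking.best_model_id)
        reports[model_type] = {
            "summary": {k: list(v) for k, v in battery_summary(battery).items()},
            "ranking": {"scores": ranking.scores, "ranks": ranking.ranks,
                        "best": ranking.best_model_id, "note": ranking.note},
            "best_model": {
                "test_accuracy": best.metrics_test.accuracy if best.metrics_test else None,
                "all_accuracy": best.metrics_all.accuracy,
                "n_descriptors": best.n_descriptors, "n_neurons": best.n_neurons,
                "misclassified": list(best.misclassified_ids)},
        }

    path = outdir / f"report_{tag}.json"
    path.write_text(json.dumps(reports, indent=2, default=str))
    manifest["reports"][tag] = {"path": path.name, "sha256": _sha256(path)}


def run_full_study(config: RunConfig | Mapping | str | Path) -> dict:
    """Run the complete study pipeline; returns the reproducibility manifest."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, Mapping):
        config = RunConfig(**dict(config))
    cfg = config
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(16) % (2 ** 31)
    manifest: dict = {"seed": cfg.seed, "config": {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stages": {}, "reports": {}}

    try:
        compounds = study_compound_table()
        drugs = experimental_drugs(compounds)
        counterions = experimental_counterions(compounds)
        manifest["stages"]["compounds"] = {"drugs": len(drugs),
                                           "counterions": len(counterions)}

        if cfg.wells_csv:
            from .tables import wells_from_csv
            wells = wells_from_csv(cfg.wells_csv)
        else:
            wells = simulate_screen(drugs + counterions, seed=int(seeds[0]))
        wells_path = outdir / "wells.csv"
        wells_to_csv(wells, wells_path)
        manifest["stages"]["screen"] = {"wells": len(wells),
                                        "sha256": _sha256(wells_path)}

        normalized = normalize_screen(wells, default_endpoint_registry())
        norm_path = outdir / "normalized.csv"
        normalized_to_csv(normalized, norm_path)
        manifest["stages"]["normalize"] = {"rows": len(normalized),
                                           "sha256": _sha256(norm_path)}

        results = bmc_mod.bmc_table(normalized, n_boot=cfg.n_boot, seed=int(seeds[1]))
        bmc_path = outdir / "bmc.csv"
        bmc_to_csv(results, bmc_path)
        # only chemicals actually assessed (>= 2 levels) can be called inactive
        inactive = sorted(c for c, r in bmc_mod.most_sensitive(results).items()
                          if r is None)
        manifest["stages"]["bmc"] = {"results": len(results), "inactive": inactive,
                                     "sha256": _sha256(bmc_path)}

        class_of = {c.compound_id: c.class_label for c in compounds}
        barcodes = barcode_matrix(normalized, class_of, max_levels=cfg.max_levels,
                                  drop_ids=inactive if cfg.drop_inactive else ())
        bc_path = outdir / "barcodes.csv"
        write_feature_matrix(barcodes, bc_path)
        manifest["stages"]["barcode"] = {"shape": [barcodes.n_rows, barcodes.n_columns],
                                         "sha256": _sha256(bc_path)}

        streams = {"behavioral": barcodes}
        if cfg.descriptor_csv:
            streams["chemical"] = read_feature_matrix(cfg.descriptor_csv, "chemical_2d")
        else:
            log.info("no descriptor CSV configured; chemical stream skipped")
            manifest["stages"]["chemical_stream"] = "skipped (no descriptor file)"

        for stream, matrix in streams.items():
            for with_ci in cfg.counterion_variants:
                sub = matrix
                if not with_ci and matrix.class_labels is not None:
                    keep = [r for r, l in zip(matrix.row_ids, matrix.class_labels)
                            if l is not ClassLabel.CI]
                    sub = matrix.select_rows(keep)
                prepped, report = cull_model_descriptors(sub)
                prepped = standardize(prepped)
                tag = f"{stream}_{'with' if with_ci else 'without'}_counterions"
                manifest["stages"][f"prep_{tag}"] = {
                    "kept": report.kept_count, "removed": len(report.removed)}
                _classify_stream(prepped, cfg, seeds[2 + 3 * len(manifest['reports']):],
                                 tag, outdir, manifest)
    except PhenobarError as exc:
        raise PhenobarError(f"pipeline aborted: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
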