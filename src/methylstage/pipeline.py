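"""End-to-end orchestration: simulate -> build -> select -> evaluate -> annotate.

Every stage is a pure function of (inputs, config, seeds); the run directory
contains each intermediate artifact as plain TSV/BED/JSON plus a manifest
(config copy, seeds, library versions, content hashes) sufficient to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, evaluate, features, methio, selector, synthgen

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``simulate`` is set (synthetic inputs are generated) or the three
    input paths (reports_dir, meta_path, annotation paths) must point at
    existing data.
    """

    outdir: str
    simulate: synthgen.SynthConfig | None = None
    reports_dir: str | None = None
    meta_path: str | None = None
    gff3_path: str | None = None
    te_bed_path: str | None = None
    qtl_bed_path: str | None = None
    scenario: str = "3stage"
    feature_kinds: tuple[str, ...] = ("cytosine", "region")
    min_coverage: int = 4
    gap_max: int = 100
    min_cytosines: int = 4
    context: str | None = "CG"
    rf: selector.RFConfig = field(default_factory=selector.RFConfig)
    xgb: selector.XGBConfig = field(default_factory=selector.XGBConfig)
    n_splits: int = 3
    n_repeats: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in ("3stage", "2stage"):
            raise ValueError(f"scenario must be 3stage or 2stage, got {self.scenario!r}")
        if self.simulate is None:
            for name in ("reports_dir", "meta_path", "gff3_path", "te_bed_path", "qtl_bed_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %-10s done in %.1fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and return the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "library_versions": _library_versions(),
        "config": _config_dict(config),
        "stages": {},
        "warnings": [],
        "hashes": {},
    }

    # --- inputs ------------------------------------------------------------
    if config.simulate is not None:
        annotation = _stage("simulate")(synthgen.simulate_genome_annotation)(config.simulate)
        dataset = synthgen.simulate_methylomes(config.simulate, annotation)
        synthgen.write_annotation(annotation, outdir / "inputs")
        synthgen.write_dataset(dataset, outdir / "inputs")
        reports, meta = dataset.reports, dataset.meta
    else:
        meta = methio.read_sample_metadata(config.meta_path)
        reports = {}
        for sid in meta["sample_id"]:
            matches = sorted(Path(config.reports_dir).glob(f"{sid}*"))
            if not matches:
                raise FileNotFoundError(
                    f"no cytosine report for sample {sid} in {config.reports_dir}"
                )
            reports[sid] = methio.read_cytosine_report(matches[0])
        annotation = methio.read_annotation(
            config.gff3_path, config.te_bed_path, config.qtl_bed_path
        )

    # --- composition stats --------------------------------------------------
    comp = _stage("stats")(methio.composition_table)(reports)
    comp.to_csv(outdir / "composition.tsv", sep="\t", index=False)

    # --- features ----------------------------------------------------------
    retained = _stage("filter")(features.filter_cytosines)(
        reports, min_coverage=config.min_coverage, context=config.context
    )
    matrices: dict[str, features.MethylationMatrix] = {}
    if "cytosine" in config.feature_kinds:
        matrices["cytosine"] = features.build_matrix(reports, meta, retained, kind="cytosine")
    if "region" in config.feature_kinds:
        clusters = features.cluster_regions(
            retained, gap_max=config.gap_max, min_cytosines=config.min_cytosines
        )
        matrices["region"] = features.build_matrix(reports, meta, clusters, kind="region")
    for kind, mat in matrices.items():
        features.write_matrix(mat, outdir / f"matrix_{kind}")

    # --- selection ---------------------------------------------------------
    select_input = {
        kind: (
            mat
            if config.scenario == "3stage"
            else mat.subset_samples(
                [s for s, stg in mat.labels["stage"].items() if stg != "paradormancy"]
            )
        )
        for kind, mat in matrices.items()
    }
    selected_sets: dict[str, list[str]] = {}
    for kind, mat in select_input.items():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            selected, table = _stage(f"select-{kind}")(selector.select_features)(
                mat, config.rf, config.xgb
            )
        for w in caught:
            manifest["warnings"].append(f"select-{kind}: {w.message}")
        selected_sets[kind] = selected
        table.to_csv(outdir / f"importances_{kind}.tsv", sep="\t")
        pd.Series(selected, name="feature_id").to_csv(
            outdir / f"selected_{kind}.tsv", sep="\t", index=False
        )
        manifest["stages"][f"select-{kind}"] = {
            "n_features": len(mat.feature_ids),
            "n_selected": len(selected),
        }

    # --- evaluation --------------------------------------------------------
    datasets = {}
    for kind, mat in matrices.items():
        if not selected_sets[kind]:
            manifest["warnings"].append(f"evaluate: empty selection for {kind}; skipped")
            continue
        datasets[kind] = {"full": mat, "selected": mat.subset_features(selected_sets[kind])}
    scheme = evaluate.CVScheme(
        n_splits=config.n_splits, n_repeats=config.n_repeats, seed=config.seed
    )
    if datasets:
        scenario_report = _stage("evaluate")(evaluate.run_scenario)(
            datasets,
            config.scenario,
            scheme,
            {"rf": config.rf, "xgb": config.xgb},
        )
        _write_scenario_report(scenario_report, outdir)

    # --- annotation --------------------------------------------------------
    anno_out: dict = {}
    for kind, mat in matrices.items():
        sel = selected_sets[kind]
        if not sel:
            continue
        coords = mat.coords.set_index("feature_id").loc[sel].reset_index()
        annotate.write_bed(coords, outdir / f"selected_{kind}.bed")
        assignments = annotate.assign_context(coords, annotation)
        assignments.to_csv(outdir / f"context_{kind}.tsv", sep="\t", index=False)
        crosstab = annotate.te_context_crosstab(assignments)
        crosstab.to_csv(outdir / f"te_crosstab_{kind}.tsv", sep="\t")
        anno_out[kind] = {
            "primary_context_counts": assignments["primary_context"].value_counts().to_dict()
        }
    if annotation.chrom_lengths:
        all_coords = [
            matrices[kind].coords.set_index("feature_id").loc[selected_sets[kind]].reset_index()
            for kind in matrices
            if selected_sets[kind]
        ]
        if all_coords:
            dens = annotate.density_windows(
                pd.concat(all_coords, ignore_index=True), annotation.chrom_lengths
            )
            dens.to_csv(outdir / "density_windows.tsv", sep="\t", index=False)
            qtl = annotate.qtl_colocalization(
                pd.concat(all_coords, ignore_index=True), annotation.qtl
            )
            qtl.to_csv(outdir / "qtl_colocalization.tsv", sep="\t", index=False)
        anno_out["te_genome_fraction"] = annotate.te_genome_fraction(
            annotation.te, annotation.chrom_lengths
        )
    manifest["stages"]["annotate"] = anno_out

    # --- manifest ----------------------------------------------------------
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["hashes"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _write_scenario_report(report: evaluate.ScenarioReport, outdir: Path) -> None:
    payload: dict = {"scenario": report.scenario, "reports": {}, "benefit": {}}
    for (kind, variant, model), rep in report.reports.items():
        key = f"{kind}/{variant}/{model}"
        payload["reports"][key] = {
            "mean_accuracy": rep.mean_accuracy(),
            "mean_auc": rep.mean_auc(),
            "classes": list(rep.classes),
            "pooled_confusion": rep.confusion.tolist(),
            "folds": rep.folds.to_dict(orient="records"),
        }
        np.savetxt(
            outdir / f"confusion_{kind}_{variant}_{model}.tsv",
            rep.confusion,
            fmt="%d",
            delimiter="\t",
        )
    for (kind, model), test in report.benefit.items():
        payload["benefit"][f"{kind}/{model}"] = {
            "t": test.t,
            "p": test.p,
            "degenerate": test.degenerate,
        }
    (outdir / "cv_report.json").write_text(json.dumps(payload, indent=2))


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn
    import xgboost

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }
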