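"""End-to-end orchestration: cohort -> features -> screening -> models -> evaluation.

A run is fully described by a :class:`RunConfig` (validated, defaulted,
unknown keys rejected) and a seed; the config and a manifest with package
versions, stage seeds and timings are echoed into the output directory, so
a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .synthetic_cohort import (
    CohortConfig,
    SyntheticPatient,
    cohort_labels,
    generate_cohort,
    write_cohort,
)
from .radiomic_features import FeatureTable, build_feature_table
from .feature_screening import (
    auc_distributions,
    clean_features,
    plot_auc_distributions,
    screen_features,
)
from .modeling import CVConfig, make_endpoints, run_model_grid, FAMILIES
from .evaluation import evaluate_predictions, plot_roc_pr

log = logging.getLogger("srct_radiomics")

SPACES = ("2D@0.72", "2D@2.0", "3D@2.0")


class ConfigError(ValueError):
    """Invalid run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class RunConfig(BaseModel):
    """Validated configuration of a full analysis run.

    Defaults are the study settings: 50 HU bins over [-1000, 200] HU,
    interpolation targets 0.72 / 2.0 mm in 2D and 2.0 mm in 3D, a
    3x-repeated 10-fold inner loop with 300 random-search samples, and a
    2x-repeated 5-fold outer loop.
    """

    model_config = ConfigDict(extra="forbid")

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    spaces: list[Literal["2D@0.72", "2D@2.0", "3D@2.0"]] = Field(
        default_factory=lambda: list(SPACES), min_length=1
    )
    endpoints: list[Literal["diagnosis", "staging"]] = Field(
        default_factory=lambda: ["diagnosis", "staging"], min_length=1
    )
    families: list[Literal["M", "MSDSK", "LR-LR", "ET-ET"]] = Field(
        default_factory=lambda: list(FAMILIES), min_length=1
    )
    cv: CVConfig = Field(default_factory=CVConfig)
    bin_width: float = Field(default=50.0, gt=0.0)
    hu_range: tuple[float, float] = (-1000.0, 200.0)
    wavelet: str = "coif1"
    ci_method: Literal["wald", "exact"] = "wald"
    seed: int = 0
    write_volumes: bool = True
    write_plots: bool = True
    output_dir: str = "srct_run"


def validate_config(raw: dict) -> RunConfig:
    """Parse and validate a raw mapping into a :class:`RunConfig`.

    Rejects unknown keys and out-of-range values with a message naming the
    offending field.
    """
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            "->".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid run configuration ({locs})") from err


def _parse_space(space_id: str) -> tuple[str, float]:
    space, res = space_id.split("@")
    return space, float(res)


@dataclass
class RunArtifacts:
    """Handles to everything a finished run produced."""

    out_dir: Path
    patients: list[SyntheticPatient]
    tables: dict[str, FeatureTable]
    screening: pd.DataFrame
    grid: pd.DataFrame
    manifest: dict


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"].append(
                {"stage": name, "seconds": round(dt, 3),
                 "status": "failed" if exc_type else "ok"}
            )
            log.info("stage %s: %s in %.2fs", name,
                     "FAILED" if exc_type else "done", dt)
            return False

    return _Timer()


def run(config: RunConfig) -> RunArtifacts:
    """Execute the configured analysis end to end.

    Any stage failure aborts with a stage-tagged error; artifacts written by
    completed stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "versions": _library_versions(),
        "stages": [],
    }
    (out / "run_config.json").write_text(config.model_dump_json(indent=1))

    try:
        with _stage(manifest, "cohort"):
            cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
            patients = generate_cohort(cohort_cfg)
            log.info("generated %d patients", len(patients))
            if config.write_volumes:
                write_cohort(patients, cohort_cfg, out / "cohort")

        labels = cohort_labels(patients)

        tables: dict[str, FeatureTable] = {}
        with _stage(manifest, "features"):
            feat_dir = out / "features"
            feat_dir.mkdir(exist_ok=True)
            for space_id in config.spaces:
                space, res = _parse_space(space_id)
                table = build_feature_table(
                    patients, space, res,  # type: ignore[arg-type]
                    bin_width=config.bin_width, hu_range=config.hu_range,
                    wavelet=config.wavelet,
                )
                tables[space_id] = table
                tag = space_id.replace("@", "_")
                table.to_csv(feat_dir / f"features_{tag}.csv")
                (feat_dir / f"descriptors_{tag}.json").write_text(
                    json.dumps(table.descriptor_records(), indent=1)
                )
                log.info("space %s: %d features", space_id, table.values.shape[1])

        with _stage(manifest, "screening"):
            endpoints = make_endpoints(labels)
            scr_dir = out / "screening"
            scr_dir.mkdir(exist_ok=True)
            reports = []
            for space_id, table in tables.items():
                for ep_name in config.endpoints:
                    ep = endpoints[ep_name]
                    sub = FeatureTable(
                        values=table.values.loc[ep.patient_ids],
                        descriptors=table.descriptors,
                        labels=table.labels.loc[ep.patient_ids],
                        space=table.space, resolution=table.resolution,
                    )
                    rep = screen_features(sub, ep.y, ep_name, condition=space_id)
                    reports.append(rep)
                    tag = f"{space_id.replace('@', '_')}_{ep_name}"
                    rep.to_frame().to_csv(scr_dir / f"auc_{tag}.csv", index=False)
                    rep.removed.to_csv(scr_dir / f"removed_{tag}.csv", index=False)
            screening = auc_distributions(reports)
            screening.to_csv(scr_dir / "summary.csv", index=False)
            (scr_dir / "summary.json").write_text(
                screening.to_json(orient="records", indent=1)
            )
            if config.write_plots:
                plot_auc_distributions(reports, scr_dir / "auc_distributions.png")

        with _stage(manifest, "models"):
            # label-free cleaning (missing / low-cardinality features) applied
            # once per table before any model sees it
            cleaned_tables = {
                sid: clean_features(t)[0] for sid, t in tables.items()
            }
            grid, results = run_model_grid(
                cleaned_tables, {n: endpoints[n] for n in config.endpoints},
                config.families, seed=config.seed, cv=config.cv,
            )
            mod_dir = out / "models"
            mod_dir.mkdir(exist_ok=True)
            grid.to_csv(mod_dir / "grid.csv", index=False)
            for (space_id, ep_name, family), res in results.items():
                tag = f"{space_id.replace('@', '_')}_{ep_name}_{family}"
                res.predictions.to_csv(mod_dir / f"predictions_{tag}.csv", index=False)
                (mod_dir / f"result_{tag}.json").write_text(
                    json.dumps({**res.summary(), "fold_aucs": res.fold_aucs,
                                "best_params": res.best_params}, indent=1, default=str)
                )

        with _stage(manifest, "evaluation"):
            ev_dir = out / "evaluation"
            ev_dir.mkdir(exist_ok=True)
            panel_rows = []
            for (space_id, ep_name, family), res in results.items():
                tag = f"{space_id.replace('@', '_')}_{ep_name}_{family}"
                try:
                    curve, panel, pr = evaluate_predictions(
                        res.predictions, ci_method=config.ci_method
                    )
                except Exception as exc:  # degenerate scores: skip cell
                    log.warning("evaluation skipped for %s: %s", tag, exc)
                    continue
                pd.DataFrame(
                    {"fpr": curve.fpr, "tpr": curve.tpr,
                     "threshold": curve.thresholds}
                ).to_csv(ev_dir / f"roc_{tag}.csv", index=False)
                pd.DataFrame(
                    {"recall": pr.recall, "precision": pr.precision}
                ).to_csv(ev_dir / f"pr_{tag}.csv", index=False)
                panel_rows.append(
                    {"space": space_id, "endpoint": ep_name, "family": family,
                     **panel.to_record()}
                )
                if config.write_plots:
                    plot_roc_pr(curve, panel, pr, ev_dir / f"curves_{tag}.png")
            panels = pd.DataFrame(panel_rows)
            panels.to_csv(ev_dir / "metric_panels.csv", index=False)
            (ev_dir / "metric_panels.json").write_text(
                panels.to_json(orient="records", indent=1)
            )
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunArtifacts(
        out_dir=out, patients=patients, tables=tables,
        screening=screening, grid=grid, manifest=manifest,
    )


def _library_versions() -> dict[str, str]:
    import sklearn
    import scipy
    import pywt

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "pywavelets": pywt.__version__,
    }
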