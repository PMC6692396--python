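"""End-to-end orchestration: ingest -> QC -> stability -> normalization ->
scores -> evaluation -> reports.

Every run is deterministic given (config, seed): all stage-level randomness
(bootstrap resampling) is derived from the single root seed, and no
timestamps enter the outputs, so re-running an identical config reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ct_data import qc_replicates, read_ct_table, read_sample_meta
from .drs_score import drs_one_transcript, drs_two_transcript
from .normalization import delta_ct, fold_change
from .performance_eval import drs_stability_matrix, evaluate_scores
from .refgene_stability import run_all_methods
from .synthetic_data import REFERENCE_GENES

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    ct_file: str
    out_dir: str
    meta_file: str | None = None
    input_format: str = "long"
    reference_candidates: tuple[str, ...] = REFERENCE_GENES
    n_references: int = 3
    target_fam89a: str = "FAM89A"
    target_ifi44l: str = "IFI44L"
    sd_threshold: float = 0.5
    cycle_cap: float = 40.0
    on_fail: str = "mask"
    efficiency: float = 2.0
    grouped_normfinder: bool = True
    bestkeeper_sd_mode: str = "mad"
    calibrator: str = "control"
    positive_class: str = "viral"
    log_base: float = 10.0
    n_boot: int = 2000
    ci_level: float = 0.95
    seed: int = 1

    def __post_init__(self) -> None:
        self.reference_candidates = tuple(self.reference_candidates)
        if self.n_references > len(self.reference_candidates):
            raise ValueError("n_references exceeds the candidate list")
        targets = {self.target_fam89a, self.target_ifi44l}
        if targets & set(self.reference_candidates):
            raise ValueError("target genes cannot be reference candidates")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("evaluate_two_transcript", "evaluate_one_transcript"),
            rng.integers(0, 2**31 - 1, size=2),
        )
    }

    def record(name: str, path: Path) -> None:
        outputs[name] = path.name

    # -- ingest + QC ------------------------------------------------------
    stage = "qc"
    try:
        measurements, meta = read_ct_table(
            config.ct_file, format=config.input_format, cycle_cap=config.cycle_cap
        )
        if config.meta_file:
            meta = read_sample_meta(config.meta_file)
        table, qc = qc_replicates(
            measurements,
            meta=meta,
            sd_threshold=config.sd_threshold,
            on_fail=config.on_fail,
            cycle_cap=config.cycle_cap,
        )
        qc.to_csv(out / "qc_report.csv")
        record("qc_report", out / "qc_report.csv")
        table.to_csv(out / "ct_table.csv")
        record("ct_table", out / "ct_table.csv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # -- stability --------------------------------------------------------
    stage = "stability"
    try:
        candidates = [g for g in config.reference_candidates if g in table.genes]
        reports = run_all_methods(
            table,
            candidates=candidates,
            efficiency=config.efficiency,
            grouped=config.grouped_normfinder,
            sd_mode=config.bestkeeper_sd_mode,
        )
        stab = pd.concat([r.to_frame() for r in reports.values()])
        stab.to_csv(out / "stability.csv", index=False)
        record("stability", out / "stability.csv")
        chosen = reports["comprehensive"].ordered_genes()[: config.n_references]
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- delta Ct ---------------------------------------------------------
    stage = "delta_ct"
    try:
        dct_f = delta_ct(table, config.target_fam89a, chosen)
        dct_i = delta_ct(table, config.target_ifi44l, chosen)
        dct_frame = pd.DataFrame(
            {
                config.target_fam89a: dct_f.values,
                config.target_ifi44l: dct_i.values,
            }
        )
        if table.meta is not None:
            dct_frame.insert(0, "group", table.meta.reindex(dct_frame.index))
        dct_frame.to_csv(out / "delta_ct.csv", index_label="sample_id")
        record("delta_ct", out / "delta_ct.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- fold change vs calibrator ---------------------------------------
    stage = "fold_change"
    try:
        has_calibrator = (
            table.meta is not None and (table.meta == config.calibrator).any()
        )
        if has_calibrator:
            frames = []
            for dct in (dct_f, dct_i):
                fc = fold_change(dct, config.calibrator, table.meta)
                frame = fc.table.copy()
                frame.insert(0, "target", fc.target)
                frames.append(frame)
            pd.concat(frames).to_csv(out / "fold_change.csv",
                                     index_label="sample_id")
            record("fold_change", out / "fold_change.csv")
        else:
            logger.info("no calibrator group %r: skipping fold change",
                        config.calibrator)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- DRS --------------------------------------------------------------
    stage = "drs"
    try:
        drs2 = drs_two_transcript(dct_f, dct_i, log_base=config.log_base)
        drs1 = drs_one_transcript(dct_i, log_base=config.log_base)
        drs_frame = pd.DataFrame(
            {"two_transcript": drs2.scores, "one_transcript": drs1.scores}
        )
        if table.meta is not None:
            drs_frame.insert(0, "group", table.meta.reindex(drs_frame.index))
        drs_frame["refs"] = ";".join(chosen)
        drs_frame.to_csv(out / "drs.csv", index_label="sample_id")
        record("drs", out / "drs.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- evaluation -------------------------------------------------------
    stage = "evaluate"
    performance: dict[str, dict] = {}
    try:
        vb = table.meta[table.meta.isin(["viral", "bacterial"])]
        for name, drs in (("two_transcript", drs2), ("one_transcript", drs1)):
            scores = drs.scores.reindex(vb.index).dropna()
            labels = vb.reindex(scores.index)
            report, roc = evaluate_scores(
                scores,
                labels,
                positive=config.positive_class,
                n_boot=config.n_boot,
                seed=stage_seeds[f"evaluate_{name}"],
                level=config.ci_level,
            )
            performance[name] = report.to_dict()
            _write_json(out / f"performance_{name}.json", report.to_dict())
            record(f"performance_{name}", out / f"performance_{name}.json")
            roc.to_frame().to_csv(out / f"roc_{name}.csv", index=False)
            record(f"roc_{name}", out / f"roc_{name}.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- DRS stability across reference options --------------------------
    stage = "drs_stability"
    try:
        comp_order = reports["comprehensive"].ordered_genes()
        options: dict[str, list[str]] = {g: [g] for g in candidates}
        for k in range(2, min(config.n_references + 2, len(comp_order) + 1)):
            refs = comp_order[:k]
            options["-".join(refs)] = refs
        drs_by_option = {}
        auc_by_option = {}
        from .performance_eval import auc_score

        for name, refs in options.items():
            d_f = delta_ct(table, config.target_fam89a, refs)
            d_i = delta_ct(table, config.target_ifi44l, refs)
            scores = drs_two_transcript(d_f, d_i, log_base=config.log_base).scores
            drs_by_option[name] = scores
            sub = scores.reindex(vb.index).dropna()
            auc_by_option[name] = auc_score(
                sub, vb.reindex(sub.index), positive=config.positive_class
            )
        r, r2, comparison = drs_stability_matrix(drs_by_option)
        r2.to_csv(out / "drs_correlation_r2.csv")
        record("drs_correlation_r2", out / "drs_correlation_r2.csv")
        _write_json(
            out / "drs_option_tests.json",
            {
                "kruskal_statistic": comparison.statistic,
                "kruskal_p_value": comparison.p_value,
                "auc_by_option": auc_by_option,
                "posthoc": comparison.posthoc.to_dict(orient="records")
                if comparison.posthoc is not None
                else None,
            },
        )
        record("drs_option_tests", out / "drs_option_tests.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- manifest + summary ----------------------------------------------
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "chosen_references": chosen,
        "outputs": outputs,
        "performance": performance,
    }
    _write_json(out / "manifest.json", manifest)

    lines = [
        "# Pipeline run summary",
        "",
        f"- package version: {__version__}",
        f"- seed: {config.seed}",
        f"- QC failures: {qc.n_failed}",
        f"- chosen references: {', '.join(chosen)}",
        "",
        "## Performance (viral-positive ROC)",
        "",
    ]
    for name, rep in performance.items():
        lines.append(
            f"- {name}: AUC={rep['auc']:.3f} "
            f"[{rep['auc_ci'][0]:.3f}, {rep['auc_ci'][1]:.3f}], "
            f"cut={rep['cutpoint']:.3f}, "
            f"sens={rep['sensitivity']:.3f}, spec={rep['specificity']:.3f}"
        )
    (out / "summary.md").write_text("\n".join(lines) + "\n")

    return manifest
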