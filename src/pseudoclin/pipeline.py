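"""End-to-end orchestration: simulate -> detect -> pseudonymize ->
run-experiment -> compare, with a manifest recording seeds and artifacts.

The pipeline builds synthetic material, creates the data versions
(original, plus one pseudonymized version per configured detector), runs the
cross-validated utility experiment and the pairwise comparison matrix, and
writes every artifact under one output directory.  A persisted
:class:`RunConfig` re-executes to byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .corpus_io import write_corpus, write_gazetteer
from .detect import GoldDetector, degrade_detector, evaluate_detector, scores_to_frame
from .evalstats import build_plan, comparison_matrix, report_tables, run_experiment
from .schema import corpus_stats
from .surrogate import SurrogatePolicy, pseudonymize_corpus, replacement_report
from .synth import (
    NoteGeneratorConfig,
    TaskGeneratorConfig,
    generate_gazetteer,
    generate_notes,
    generate_task_corpus,
)

__all__ = ["RunConfig", "run_end_to_end"]

_STAGES = ["simulate", "detect", "pseudonymize", "run-experiment", "compare"]


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    ``detectors`` maps pseudonymized data-version names to (miss_rate,
    spurious_rate) degradation settings applied to a gold-reading base
    detector; an empty tuple means the perfect detector.
    """

    out_dir: str = "runs/demo"
    master_seed: int = 17
    n_notes: int = 200
    note_density: float = 0.0157
    n_task_docs: int = 200
    task_type: str = "doc_classification"
    n_task_classes: int = 2
    signal_location: str = "non_pii"
    signal_strength: float = 0.9
    models: list[str] = field(default_factory=lambda: ["tf-linear"])
    detectors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"pseudo": (0.1, 0.5), "pseudo+": (0.0, 0.0)}
    )
    k: int = 10
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**raw)
        cfg.detectors = {k: tuple(v) for k, v in cfg.detectors.items()}
        return cfg


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full flow and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed
    manifest: dict = {
        "version": __version__,
        "master_seed": seed,
        "stages": [],
        "artifacts": {},
    }

    # -- simulate ------------------------------------------------------
    gz = generate_gazetteer(seed, out_dir=out / "gazetteer")
    notes = generate_notes(
        NoteGeneratorConfig(
            n_docs=config.n_notes, target_density=config.note_density, seed=seed + 1
        ),
        gz,
    )
    write_corpus(notes, out / "notes.jsonl", "jsonl")
    task_docs = generate_task_corpus(
        TaskGeneratorConfig(
            task_type=config.task_type,
            n_classes=config.n_task_classes,
            signal_location=config.signal_location,
            signal_strength=config.signal_strength,
            n_docs=config.n_task_docs,
            seed=seed + 2,
        ),
        gz,
    )
    write_corpus(task_docs, out / "task_original.jsonl", "jsonl")
    stats = corpus_stats(notes)
    manifest["stages"].append("simulate")
    manifest["artifacts"]["notes"] = str(out / "notes.jsonl")
    manifest["pii_density_pct"] = round(100 * stats.pii_density, 3)

    # -- detect --------------------------------------------------------
    gold_base = GoldDetector(list(notes) + list(task_docs))
    detectors = {}
    for name, rates in config.detectors.items():
        miss, spur = (rates + (0.0, 0.0))[:2] if rates else (0.0, 0.0)
        detectors[name] = (
            gold_base
            if (miss, spur) == (0.0, 0.0)
            else degrade_detector(gold_base, miss, spur, seed + 3)
        )
    predictions = {
        name: {d.doc_id: det.detect(d.text) for d in notes}
        for name, det in detectors.items()
    }
    gold_spans = {d.doc_id: d.spans for d in notes}
    for name, preds in predictions.items():
        frame = scores_to_frame(evaluate_detector(preds, gold_spans, "strict"))
        frame.to_csv(out / f"detector_scores_{name.replace('+', 'plus')}.csv", index=False)
    manifest["stages"].append("detect")

    # -- pseudonymize --------------------------------------------------
    policy = SurrogatePolicy(master_seed=seed + 4)
    versions = {"original": list(task_docs)}
    for name, det in detectors.items():
        pseudo_docs, records = pseudonymize_corpus(task_docs, det, gz, policy)
        versions[name] = pseudo_docs
        safe = name.replace("+", "plus")
        write_corpus(pseudo_docs, out / f"task_{safe}.jsonl", "jsonl")
        report = replacement_report(records, pseudo_docs)
        report.to_csv(out / f"replacements_{safe}.csv", index=False)
    manifest["stages"].append("pseudonymize")
    manifest["artifacts"]["task_versions"] = sorted(versions)

    # -- run-experiment ------------------------------------------------
    plan = build_plan(
        models=config.models,
        data_versions=sorted(versions),
        tasks=["synthetic-task"],
        k=config.k,
        seed=seed + 5,
    )
    scores = run_experiment(
        plan,
        {"synthetic-task": versions},
        task_types={"synthetic-task": config.task_type},
    )
    manifest["stages"].append("run-experiment")
    manifest["n_configurations"] = plan.n_configurations
    manifest["n_runs"] = plan.n_runs

    # -- compare -------------------------------------------------------
    comparisons, summary = comparison_matrix(scores, alpha=config.alpha)
    score_df, comp_df = report_tables(scores, comparisons, out_dir=out)
    manifest["stages"].append("compare")
    manifest["n_comparisons"] = summary["total_tests"]
    manifest["n_significant"] = summary["n_significant"]
    manifest["artifacts"]["scores"] = str(out / "scores.csv")
    manifest["artifacts"]["comparisons"] = str(out / "comparisons.csv")

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
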