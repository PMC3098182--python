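"""End-to-end multi-run experiment orchestration.

One config drives the whole pipeline: vocabulary filtering, ``n_runs``
independent Gibbs fits (seeds ``master_seed + i``), per-run module
extraction, cross-run stability tracking, and — when a channel-score table
is supplied — reference-network evaluation of an exemplary run and of the
stable modules, plus the co-occurrence baseline comparison.  All outputs are
plain TSV/JSON under ``out_dir``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from funmod.corpus_io import AnnotationCorpus, filter_vocabulary, read_corpus
from funmod.evaluation import (
    build_reference,
    compare_methods,
    cooccurrence_baseline,
    evaluate_module,
    read_score_table,
    write_reference,
)
from funmod.gibbs_lda import LDAConfig, estimate_distributions, fit
from funmod.module_extraction import PFModule, extract_modules
from funmod.stability import track_stable_topics

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a multi-run experiment."""

    corpus_path: str
    out_dir: str
    corpus_format: str = "wide"
    min_doc_freq: int = 10
    k: int = 200
    alpha: float = 0.5
    beta: float = 0.01
    n_iterations: int = 2500
    n_runs: int = 9
    threshold_C: float = 0.01
    master_seed: int = 0
    exemplary_run: int = 0
    score_table_path: Optional[str] = None
    min_combined: float = 0.7
    inclusion_floor: float = 0.15
    baseline_threshold: float = 0.4
    prior: float = 0.063

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write_modules(modules: list[PFModule], out_tsv: Path, out_json: Path) -> None:
    rows = [
        {"run_id": m.run_id, "topic_id": m.topic_id, "term": t, "probability": p}
        for m in modules
        for t, p in sorted(m.terms.items())
    ]
    pd.DataFrame(
        rows, columns=["run_id", "topic_id", "term", "probability"]
    ).to_csv(out_tsv, sep="\t", index=False)
    with open(out_json, "w", encoding="utf-8") as fh:
        json.dump(
            [
                {
                    "run_id": m.run_id,
                    "topic_id": m.topic_id,
                    "terms": dict(sorted(m.terms.items())),
                }
                for m in modules
            ],
            fh,
            indent=1,
        )


def _evaluation_table(modules: list[PFModule], ref) -> pd.DataFrame:
    rows = []
    for m in modules:
        ev = evaluate_module(m, ref)
        rows.append(
            {
                "run_id": m.run_id,
                "topic_id": ev.topic_id,
                "l": ev.l,
                "m": ev.m,
                "n_pwf": len(ev.pwf),
                "n_trf": len(ev.trf),
                "coverage": ev.coverage,
                "n_components": ev.n_components,
                "expected_hits": ev.expected_hits,
                "p_mult_hit": ev.p_mult_hit,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig, corpus: AnnotationCorpus | None = None
) -> dict:
    """Execute the full pipeline; returns a report dict and writes outputs.

    Any stage failure aborts with a stage-named error; outputs written before
    the failure are retained under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=1)

    stage = "corpus"
    try:
        if corpus is None:
            corpus = read_corpus(config.corpus_path, format=config.corpus_format)
        filtered = filter_vocabulary(corpus, min_doc_freq=config.min_doc_freq)

        stage = "fit"
        run_modules: list[list[PFModule]] = []
        phis: list[np.ndarray] = []
        for i in range(config.n_runs):
            lda = LDAConfig(
                k=config.k,
                alpha=config.alpha,
                beta=config.beta,
                n_iterations=config.n_iterations,
                seed=config.master_seed + i,
            )
            model = fit(filtered, lda)
            dists = estimate_distributions(model)
            phis.append(dists.phi)
            modules = extract_modules(dists, C=config.threshold_C, run_id=i)
            run_dir = out / f"run_{i}"
            run_dir.mkdir(exist_ok=True)
            _write_modules(modules, run_dir / "modules.tsv", run_dir / "modules.json")
            np.savetxt(run_dir / "theta.tsv", dists.theta, delimiter="\t")
            run_modules.append(modules)
            logger.info("run %d: %d non-empty modules", i, len(modules))

        stage = "stability"
        stable_modules: list[PFModule] = []
        chains = None
        if config.n_runs >= 2:
            stable = track_stable_topics(phis)
            chains = stable.chains
            stable_dir = out / "stability"
            stable_dir.mkdir(exist_ok=True)
            with open(stable_dir / "chains.json", "w", encoding="utf-8") as fh:
                json.dump({"n_runs": stable.n_runs, "chains": chains}, fh)
            stable_topics = set(stable.stable_run0_topics)
            stable_modules = [
                m for m in run_modules[0] if m.topic_id in stable_topics
            ]
        else:
            logger.warning("n_runs=1: stability stage skipped")

        stage = "evaluation"
        evaluation: dict = {}
        if config.score_table_path:
            table = read_score_table(config.score_table_path)
            ref = build_reference(
                table,
                filtered.vocabulary,
                min_combined=config.min_combined,
                inclusion_floor=config.inclusion_floor,
                prior=config.prior,
            )
            eval_dir = out / "evaluation"
            eval_dir.mkdir(exist_ok=True)
            write_reference(ref, eval_dir / "reference.tsv")
            exemplary = run_modules[config.exemplary_run]
            report = _evaluation_table(exemplary, ref)
            report.to_csv(eval_dir / "report.tsv", sep="\t", index=False)
            stable_report = _evaluation_table(stable_modules, ref)
            stable_report.to_csv(
                eval_dir / "report_stable.tsv", sep="\t", index=False
            )
            baseline = cooccurrence_baseline(
                table, filtered.vocabulary, threshold=config.baseline_threshold
            )
            comp = compare_methods(exemplary, baseline, ref)
            evaluation = {
                "n_reference_pairs": ref.n_pairs,
                "mean_coverage": float(report["coverage"].mean())
                if len(report)
                else 0.0,
                "mean_verified_fraction": float(
                    (report["n_pwf"] / report["m"]).mean()
                )
                if len(report)
                else 0.0,
                "recall_modules": comp["recall_modules"],
                "recall_baseline": comp["recall_baseline"],
                "n_verified_module_pairs": comp["n_verified_module_pairs"],
                "n_verified_baseline_pairs": comp["n_verified_baseline_pairs"],
            }

        stage = "summary"
        per_run_sizes = [
            [m.l for m in mods] for mods in run_modules
        ]
        per_run_terms = [
            set().union(*(m.term_set for m in mods)) if mods else set()
            for mods in run_modules
        ]
        common_terms = (
            set.intersection(*per_run_terms) if per_run_terms else set()
        )
        mean_sizes = [float(np.mean(s)) if s else 0.0 for s in per_run_sizes]
        summary = {
            "n_documents": filtered.n_documents,
            "n_vocab": len(filtered.vocabulary),
            "n_runs": config.n_runs,
            "n_modules_per_run": [len(m) for m in run_modules],
            "mean_module_size": float(np.mean(mean_sizes)),
            "sd_mean_module_size": float(np.std(mean_sizes)),
            "distinct_terms_per_run": [len(t) for t in per_run_terms],
            "n_terms_common_all_runs": len(common_terms),
            "n_stable_chains": len(chains) if chains is not None else None,
            "n_stable_modules": len(stable_modules),
        }
        pd.DataFrame(
            [(k, json.dumps(v)) for k, v in {**summary, **evaluation}.items()],
            columns=["statistic", "value"],
        ).to_csv(out / "summary.tsv", sep="\t", index=False)

        return {
            "summary": summary,
            "evaluation": evaluation,
            "modules": run_modules,
            "stable_modules": stable_modules,
            "chains": chains,
            "phis": phis,
            "corpus": filtered,
        }
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc
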