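"""End-to-end orchestration: votes -> tiers -> enrichment -> sites -> correlations.

A run either ingests a dataset directory (manifest-described, the same
schema the generator writes) or generates one from a seed. Stages write
their outputs to disk as they complete — evidence TSV, enrichment JSON,
site TSV/JSON, correlation TSVs and a report JSON with per-stage record
counts, parameters and a config hash — so the final report can always be
re-derived from the on-disk artifacts. Runs are deterministic for fixed
inputs and seed; on failure, partial outputs are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .diffexp import down_votes
from .energy import load_parameters, score_sites
from .evidence import TierThresholds, enrichment_test, evidence_table
from .io import read_dataset_dir, write_correlations_tsv, write_enrichment_json, write_evidence_tsv, write_sites_json, write_sites_tsv
from .quant import ct_table_to_levels, panel_screen
from .sites import MatureMiRNA, scan_seed_sites
from .synthetic import GeneratorConfig, generate_dataset, write_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; mirrors the CLI flags."""

    outdir: str | Path
    input_dir: str | Path | None = None  # ingest this dataset directory ...
    generator: GeneratorConfig | None = None  # ... or generate one
    seed: int | None = None
    calibrator: str = "MTOR"
    thresholds: TierThresholds = field(default_factory=TierThresholds)
    energy_params: str | Path | None = None
    mirna_name: str = "miR-100"
    mirna_sequence: str | None = None  # default: the generator's miRNA

    def __post_init__(self) -> None:
        if self.input_dir is None and self.seed is None:
            raise ValueError("either input_dir or a generator seed is required")
        if not 2 <= self.thresholds.top_min_votes <= 5:
            raise ValueError("top-candidate vote threshold must lie within the experiment count")


@dataclass
class RunReport:
    outdir: str
    seed: int | None
    config_hash: str
    counts: dict[str, int]
    evidence_tsv: str
    enrichment_json: str
    sites_tsv: str
    sites_json: str
    correlation_tsvs: dict[str, str]
    report_json: str
    metrics: dict[str, float]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, outdir: Path, written: list[Path]) -> RunReport:
    truth = None
    if config.input_dir is not None:
        experiments, predictions, transcripts, panels, manifest = read_dataset_dir(
            config.input_dir
        )
        truth = manifest.get("truth")
        mirna_seq = config.mirna_sequence or manifest.get("mirna", {}).get("sequence")
    else:
        dataset = generate_dataset(config.generator or GeneratorConfig(), seed=config.seed)
        data_dir = outdir / "dataset"
        write_dataset(dataset, data_dir)
        experiments, predictions, transcripts, panels, manifest = read_dataset_dir(data_dir)
        truth = manifest["truth"]
        mirna_seq = config.mirna_sequence or dataset.mirna.sequence
    if mirna_seq is None:
        raise ValueError("no miRNA sequence available (supply mirna_sequence)")
    mirna = MatureMiRNA(name=config.mirna_name, sequence=mirna_seq)

    t = config.thresholds
    votes = down_votes(
        experiments,
        candidate_min_votes=t.candidate_min_votes,
        top_min_votes=t.top_min_votes,
    )
    evidence = evidence_table(votes, predictions, t)
    evidence_tsv = outdir / "evidence.tsv"
    write_evidence_tsv(evidence, evidence_tsv)
    written.append(evidence_tsv)

    enrichment = enrichment_test(votes.candidate_set, votes.top_set, predictions.predicted_set)
    enrichment_json = outdir / "enrichment.json"
    write_enrichment_json(enrichment, enrichment_json)
    written.append(enrichment_json)

    params = load_parameters(config.energy_params)
    sites = []
    for tx in transcripts:
        tx_sites = scan_seed_sites(tx, mirna)
        score_sites(tx_sites, tx, mirna, params)
        sites.extend(tx_sites)
    sites.sort(key=lambda s: (s.transcript_id, s.seed_match_start))
    sites_tsv = outdir / "sites.tsv"
    sites_json = outdir / "sites.json"
    write_sites_tsv(sites, sites_tsv)
    write_sites_json(sites, sites_json)
    written += [sites_tsv, sites_json]

    correlation_tsvs: dict[str, str] = {}
    n_correlations = 0
    for name, panel in panels.items():
        ct = panel["ct"]
        mir_levels = ct_table_to_levels(
            ct[ct["assay"].isin([panel["mirna_assay"], panel["mirna_reference"]])],
            panel["mirna_reference"],
        )
        gene_levels = ct_table_to_levels(
            ct[~ct["assay"].isin([panel["mirna_assay"], panel["mirna_reference"]])],
            panel["gene_reference"],
        )
        levels = gene_levels.copy()
        levels.loc[panel["mirna_assay"]] = mir_levels.loc[panel["mirna_assay"]]
        results = panel_screen(levels, panel["mirna_assay"], list(panel["genes"]))
        path = outdir / f"correlations_{name}.tsv"
        write_correlations_tsv(results, path)
        written.append(path)
        correlation_tsvs[name] = str(path)
        n_correlations += len(results)

    metrics: dict[str, float] = {
        "enrichment_p": enrichment.p,
        "enrichment_odds_ratio": enrichment.odds_ratio,
    }
    if truth:
        true_set = set(truth["true_targets"])
        high = set(evidence.loc[evidence["tier"] == "high_confidence", "gene"])
        tp = len(high & true_set)
        metrics["high_confidence_n"] = float(len(high))
        metrics["high_confidence_precision"] = tp / len(high) if high else float("nan")
        metrics["high_confidence_recall"] = tp / len(true_set) if true_set else float("nan")

    counts = {
        "experiments": len(experiments),
        "genes_voted": len(votes.genes),
        "candidate_set": len(votes.candidate_set),
        "top_set": len(votes.top_set),
        "predicted_set": len(predictions.predicted_set),
        "transcripts": len(transcripts),
        "sites": len(sites),
        "correlations": n_correlations,
    }
    report = RunReport(
        outdir=str(outdir),
        seed=config.seed,
        config_hash=_config_hash(config),
        counts=counts,
        evidence_tsv=str(evidence_tsv),
        enrichment_json=str(enrichment_json),
        sites_tsv=str(sites_tsv),
        sites_json=str(sites_json),
        correlation_tsvs=correlation_tsvs,
        report_json=str(outdir / "report.json"),
        metrics=metrics,
    )
    payload = dataclasses.asdict(report)
    payload["version"] = __version__
    payload["thresholds"] = dataclasses.asdict(config.thresholds)
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(outdir / "report.json")
    return report
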