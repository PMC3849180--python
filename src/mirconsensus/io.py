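"""Readers and writers for the pipeline's plain-text formats.

The same schemas serve synthetic and user-supplied real data:
fold-change tables and down-lists as TSV, the prediction matrix as a
gene x tool 0/1 TSV, transcripts as FASTA plus a 1-based-inclusive
region TSV, Ct panels as long-format TSV, and sites as BED-like TSV
(with the 1-based -> 0-based half-open conversion documented in the
header) and JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .diffexp import ExperimentMode, ExpressionExperiment
from .evidence import EnrichmentResult, PredictionMatrix
from .quant import CorrelationResult
from .sites import Region, TargetSite, TranscriptRecord

__all__ = [
    "read_fold_change_experiment",
    "read_down_list_experiment",
    "read_prediction_matrix",
    "read_transcripts",
    "read_ct_table",
    "read_dataset_dir",
    "write_sites_tsv",
    "write_sites_json",
    "write_evidence_tsv",
    "write_enrichment_json",
    "write_correlations_tsv",
]


def read_fold_change_experiment(
    path: str | Path,
    *,
    id: str,
    calibrator: str,
    species: str = "human",
    log2: bool = False,
) -> ExpressionExperiment:
    """Read a gene/fold_change TSV.

    Fold changes are linear ratios; pass ``log2=True`` only when the file
    explicitly holds log2 ratios — conversion is never silent.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "fold_change"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene, fold_change")
    values = df["fold_change"].astype(float)
    if log2:
        values = 2.0**values
    fc = dict(zip(df["gene"].astype(str), values))
    if len(fc) != len(df):
        raise ValueError(f"{path}: duplicate gene symbols")
    return ExpressionExperiment(
        id=id, mode=ExperimentMode.FOLD_CHANGE, species=species, fc=fc, calibrator=calibrator
    )


def read_down_list_experiment(
    path: str | Path, *, id: str, species: str = "human"
) -> ExpressionExperiment:
    """Read a one-symbol-per-line down-regulated gene list."""
    symbols = {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
    return ExpressionExperiment(
        id=id, mode=ExperimentMode.BINARY_LIST, species=species, down_list=symbols
    )


def read_prediction_matrix(path: str | Path) -> PredictionMatrix:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError(f"{path}: expected a 'gene' column")
    df = df.set_index("gene")
    return PredictionMatrix(df.astype(int).astype(bool))


def read_transcripts(fasta: str | Path, regions_tsv: str | Path | None = None) -> list[TranscriptRecord]:
    """FASTA + optional region TSV (transcript_id, region, start, end; 1-based inclusive)."""
    regions: dict[str, list[Region]] = {}
    if regions_tsv is not None:
        rdf = pd.read_csv(regions_tsv, sep="\t")
        for row in rdf.itertuples(index=False):
            regions.setdefault(str(row.transcript_id), []).append(
                Region(str(row.region), int(row.start), int(row.end))
            )
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        out.append(
            TranscriptRecord(
                id=rec.id, sequence=str(rec.seq), regions=tuple(regions.get(rec.id, ()))
            )
        )
    if not out:
        raise ValueError(f"{fasta}: no sequences")
    return out


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "assay", "ct"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample, assay, ct")
    return df


def read_dataset_dir(indir: str | Path) -> tuple[list[ExpressionExperiment], PredictionMatrix, list[TranscriptRecord], dict, dict]:
    """Load a manifest-described dataset directory (as written by the generator).

    Returns (experiments, prediction matrix, transcripts, panels, manifest)
    where panels maps name -> dict with the Ct DataFrame and assay roles.
    """
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    experiments = []
    for meta in manifest["experiments"]:
        if meta["mode"] == "fold_change":
            experiments.append(
                read_fold_change_experiment(
                    indir / meta["file"],
                    id=meta["id"],
                    calibrator=meta["calibrator"],
                    species=meta["species"],
                )
            )
        else:
            experiments.append(
                read_down_list_experiment(
                    indir / meta["file"], id=meta["id"], species=meta["species"]
                )
            )
    predictions = read_prediction_matrix(indir / "prediction_matrix.tsv")
    transcripts = read_transcripts(indir / "transcripts.fa", indir / "regions.tsv")
    panels = {}
    for name, meta in manifest.get("panels", {}).items():
        panels[name] = {**meta, "ct": read_ct_table(indir / meta["file"])}
    return experiments, predictions, transcripts, panels, manifest


_SITES_HEADER = (
    "# BED-like site table: start is 0-based, end exclusive "
    "(converted from internal 1-based inclusive coordinates: start0 = start1 - 1)."
)


def write_sites_tsv(sites: list[TargetSite], path: str | Path) -> None:
    lines = [
        _SITES_HEADER,
        "transcript_id\tstart\tend\tregion\tsite_class\tmfe",
    ]
    for s in sites:
        mfe = "" if s.mfe is None else f"{s.mfe:.2f}"
        lines.append(
            f"{s.transcript_id}\t{s.seed_match_start - 1}\t{s.seed_match_end}\t"
            f"{s.region_label}\t{s.site_class}\t{mfe}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_json(sites: list[TargetSite], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([dataclasses.asdict(s) for s in sites], indent=2, sort_keys=True) + "\n"
    )


def write_evidence_tsv(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence.to_csv(path, sep="\t", index=False)


def write_enrichment_json(result: EnrichmentResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(result), indent=2, sort_keys=True) + "\n")


def write_correlations_tsv(results: list[CorrelationResult], path: str | Path) -> None:
    lines = ["gene\tn\tr\tp\tdirection"]
    for res in results:
        lines.append(f"{res.gene}\t{res.n}\t{res.r:.6f}\t{res.p:.6g}\t{res.direction}")
    Path(path).write_text("\n".join(lines) + "\n")
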