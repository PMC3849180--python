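"""Synthetic datasets with planted ground truth for the whole pipeline.

Emulates the five-experiment / twelve-tool study design end to end:

* three fold-change experiments (immortalized-keratinocyte-like,
  head-and-neck-carcinoma-like, prostate-carcinoma-like) carrying the
  calibrator gene (MTOR) at its published fold differences (0.88, 0.67,
  0.67), with every other gene's linear fold change drawn around 1.0
  (decoys) or around ``effect_fc`` (planted true targets) with
  multiplicative log2-scale noise;
* two literature-style binary down-lists, one flagged as mouse and
  emitted with title-case symbols to force the cross-species
  harmonization path;
* a gene x 12-tool boolean prediction matrix with per-tool sensitivity
  (true targets) and false-positive rate (decoys);
* annotated transcripts (5'UTR / CDS / 3'UTR) with seed-complementary
  sites planted at known coordinates — the first transcript mirrors the
  two-site architecture of a real target mRNA, one site in the CDS at
  position 409 and one in the 3'UTR at 2155; accidental background
  matches are scrubbed so the planting log is the complete truth;
* Ct panels: a 10-cell-line panel with stochastically planted negative
  miRNA-target correlation, and a 7-sample tissue panel (4 embryonic
  stages + 3 adult tissues) where the planted correlation is constructed
  exactly (the sample r equals the target r).

All randomness flows from one top-level integer seed through a
``numpy.random.SeedSequence`` spawn per component (stream order:
assignments, expression, predictions, transcripts, cell panel, tissue
panel), so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import ExperimentMode, ExpressionExperiment
from .evidence import DEFAULT_TOOLS, PredictionMatrix
from .sites import MatureMiRNA, Region, TranscriptRecord, reverse_complement_rna

__all__ = [
    "GeneratorConfig",
    "TruthSet",
    "PanelTable",
    "SyntheticDataset",
    "generate_dataset",
    "plant_seed_site",
    "write_dataset",
    "MIR100",
]

#: hsa-miR-100-5p mature sequence; seed (positions 2-8) = ACCCGUA, whose
#: DNA seed-complementary site reads TACGGGT.
MIR100 = MatureMiRNA(name="miR-100", sequence="AACCCGUAGAUCCGAACUUGUG")

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthSet:
    """Planted ground truth behind one synthetic dataset."""

    true_targets: frozenset[str]
    decoy_genes: frozenset[str]
    effect_fc: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.true_targets & self.decoy_genes:
            raise ValueError("true targets and decoys must be disjoint")
        if not 0.0 < self.effect_fc < 1.0:
            raise ValueError("effect_fc must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator parameters; defaults mirror the emulated study design."""

    n_genes: int = 300
    n_true: int = 20
    #: linear fold change of a true target in an experiment it is planted in
    effect_fc: float = 0.5
    #: sd of log2-scale multiplicative noise on fold changes
    noise_sd: float = 0.1
    #: experiments (out of 5) each true target is planted down in
    n_down_experiments: int = 3
    #: length of each literature-style binary down-list
    list_length: int = 80
    calibrator: str = "MTOR"
    #: calibrator fold differences in the three fold-change experiments
    calibrator_fc: tuple[float, float, float] = (0.88, 0.67, 0.67)
    tool_sensitivity: tuple[float, ...] = (
        0.90, 0.85, 0.70, 0.80, 0.90, 0.75, 0.60, 0.55, 0.70, 0.50, 0.85, 0.90,
    )
    tool_fpr: tuple[float, ...] = (
        0.03, 0.04, 0.05, 0.03, 0.06, 0.05, 0.01, 0.01, 0.04, 0.02, 0.03, 0.03,
    )
    n_transcripts: int = 10
    transcript_length: int = 2400
    #: extra sites planted at random coordinates beyond the two-site
    #: architecture on the first transcript
    n_random_sites: int = 8
    cell_panel_lines: int = 10
    cell_panel_genes: int = 6
    #: target Pearson r (log2-level scale) planted in the cell-line panel
    cell_panel_r: float = -0.4
    #: exact sample r planted in the 7-sample tissue panel
    tissue_panel_r: float = -0.79
    #: additive Gaussian noise (Ct cycles) on cell-panel gene assays
    ct_noise_sd: float = 0.25

    def validate(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be at least 50")
        if not 0 < self.n_true < self.n_genes:
            raise ValueError("n_true must be in (0, n_genes)")
        if not 0.0 < self.effect_fc < 1.0:
            raise ValueError("effect_fc must lie in (0, 1)")
        if self.effect_fc >= min(self.calibrator_fc):
            raise ValueError("effect_fc must undercut every calibrator fold change")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 1 <= self.n_down_experiments <= 5:
            raise ValueError("n_down_experiments must be within the 5 experiments")
        if len(self.tool_sensitivity) != len(DEFAULT_TOOLS) or len(self.tool_fpr) != len(
            DEFAULT_TOOLS
        ):
            raise ValueError(f"need one sensitivity and FPR per tool ({len(DEFAULT_TOOLS)})")
        if not -1.0 < self.tissue_panel_r < 1.0 or not -1.0 < self.cell_panel_r < 1.0:
            raise ValueError("planted correlations must lie in (-1, 1)")
        if self.transcript_length < 2300:
            raise ValueError("transcripts must be long enough for the 3'UTR site at 2155")


@dataclass(frozen=True)
class PanelTable:
    """One Ct panel: long-format table plus assay bookkeeping."""

    name: str
    ct: pd.DataFrame  # columns: sample, assay, ct
    mirna_assay: str
    mirna_reference: str  # U6-like small-RNA reference
    gene_reference: str  # actin-like mRNA reference
    genes: tuple[str, ...]


@dataclass
class SyntheticDataset:
    experiments: list[ExpressionExperiment]
    prediction_matrix: PredictionMatrix
    transcripts: list[TranscriptRecord]
    mirna: MatureMiRNA
    panels: dict[str, PanelTable]
    truth: TruthSet
    #: gene -> tuple of experiment ids it was planted down in
    planted_down: dict[str, tuple[str, ...]]
    #: (transcript_id, seed_match_start, region_label) per planted site
    planting_log: list[tuple[str, int, str]]
    config: GeneratorConfig


def plant_seed_site(
    transcript: TranscriptRecord,
    mirna: MatureMiRNA,
    position: int,
    region: str | None = None,
) -> TranscriptRecord:
    """Write the seed-complementary 7-mer into a transcript at ``position``.

    Positions are 1-based; the reverse complement of the miRNA seed
    (positions 2-8) replaces transcript bases position..position+6, in
    the transcript's own alphabet. If ``region`` is given the position
    must fall in that annotated region.
    """
    if position < 1 or position + 6 > len(transcript.sequence):
        raise ValueError(
            f"site at {position} does not fit in transcript {transcript.id} "
            f"(length {len(transcript.sequence)})"
        )
    actual = transcript.region_at(position)
    if region is not None and actual != region:
        raise ValueError(
            f"position {position} lies in {actual}, not requested region {region}"
        )
    needle = reverse_complement_rna(mirna.seed)
    if "U" not in transcript.sequence.upper():
        needle = needle.replace("U", "T")
    seq = transcript.sequence[: position - 1] + needle + transcript.sequence[position + 6 :]
    return TranscriptRecord(id=transcript.id, sequence=seq, regions=transcript.regions)


def _scrub_accidental_matches(seq: str, needle: str, rng: np.random.Generator) -> str:
    """Mutate one base of every background occurrence of the seed site."""
    for _ in range(100):
        pos = seq.find(needle)
        if pos == -1:
            return seq
        mid = pos + 3
        alternatives = [b for b in "ACGT" if b != seq[mid]]
        seq = seq[:mid] + str(rng.choice(alternatives)) + seq[mid + 1 :]
    raise RuntimeError("failed to scrub accidental seed matches")


def _random_transcript(
    tx_id: str, length: int, rng: np.random.Generator, needle: str
) -> TranscriptRecord:
    seq = "".join(rng.choice(_DNA, size=length))
    seq = _scrub_accidental_matches(seq, needle, rng)
    regions = (
        Region("5UTR", 1, 200),
        Region("CDS", 201, length - 700),
        Region("3UTR", length - 699, length),
    )
    return TranscriptRecord(id=tx_id, sequence=seq, regions=regions)


def _exact_r_vector(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """A vector whose sample Pearson correlation with x is exactly r."""
    n = len(x)
    xc = x - x.mean()
    for _ in range(100):
        e = rng.normal(size=n)
        ec = e - e.mean()
        ec = ec - (ec @ xc) / (xc @ xc) * xc
        norm = np.linalg.norm(ec)
        if norm > 1e-9:
            break
    else:  # pragma: no cover - essentially impossible
        raise RuntimeError("degenerate residual draw")
    xs = xc / np.linalg.norm(xc)
    es = ec / norm
    y = r * xs + np.sqrt(1.0 - r * r) * es
    return 2.0 * y  # scale to a plausible log2 dynamic range (r unchanged)


_EXPERIMENT_IDS = ("HACAT", "LN1386", "C42", "SCC29", "4T1")


def generate_dataset(config: GeneratorConfig | None = None, *, seed: int | None = None) -> SyntheticDataset:
    """Generate the full five-experiment dataset with planted truth.

    ``seed`` is mandatory (reproducibility contract): a fixed seed gives
    a bit-identical dataset, including every file written by
    :func:`write_dataset`.
    """
    config = config or GeneratorConfig()
    config.validate()
    if seed is None:
        raise ValueError("a seed is required; refusing to generate irreproducible data")
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_assign = np.random.default_rng(streams[0])
    rng_expr = np.random.default_rng(streams[1])
    rng_pred = np.random.default_rng(streams[2])
    rng_tx = np.random.default_rng(streams[3])
    rng_cell = np.random.default_rng(streams[4])
    rng_tissue = np.random.default_rng(streams[5])

    calibrator = config.calibrator.upper()
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes)] + [calibrator]
    ordinary = genes[:-1]
    true_targets = sorted(rng_assign.choice(ordinary, size=config.n_true, replace=False))
    truth = TruthSet(
        true_targets=frozenset([*true_targets, calibrator]),
        decoy_genes=frozenset(g for g in ordinary if g not in set(true_targets)),
        effect_fc=config.effect_fc,
        noise_sd=config.noise_sd,
        seed=seed,
    )

    # which experiments each true target is planted down in; the
    # calibrator is down in the three fold-change experiments by the
    # inclusive threshold rule itself
    planted_down: dict[str, tuple[str, ...]] = {
        calibrator: _EXPERIMENT_IDS[:3],
    }
    for g in true_targets:
        chosen = rng_assign.choice(5, size=config.n_down_experiments, replace=False)
        planted_down[g] = tuple(_EXPERIMENT_IDS[i] for i in sorted(chosen))

    experiments: list[ExpressionExperiment] = []
    for i, exp_id in enumerate(_EXPERIMENT_IDS[:3]):
        fc: dict[str, float] = {}
        for g in ordinary:
            base = config.effect_fc if exp_id in planted_down.get(g, ()) else 1.0
            noise = 2.0 ** rng_expr.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 1.0
            fc[g] = base * noise
        fc[calibrator] = config.calibrator_fc[i]
        experiments.append(
            ExpressionExperiment(
                id=exp_id,
                mode=ExperimentMode.FOLD_CHANGE,
                species="human",
                fc=fc,
                calibrator=calibrator,
            )
        )
    for exp_id, species in ((_EXPERIMENT_IDS[3], "human"), (_EXPERIMENT_IDS[4], "mouse")):
        members = {g for g, exps in planted_down.items() if exp_id in exps}
        # fill only with decoys so list membership of true targets stays
        # exactly as planted
        pool = [g for g in ordinary if g not in planted_down]
        n_fill = max(0, config.list_length - len(members))
        fill = rng_expr.choice(pool, size=min(n_fill, len(pool)), replace=False)
        members |= set(fill.tolist())
        if species == "mouse":
            # mouse nomenclature: title-case symbols, forcing harmonization
            members = {g.capitalize() for g in members}
        experiments.append(
            ExpressionExperiment(
                id=exp_id, mode=ExperimentMode.BINARY_LIST, species=species, down_list=members
            )
        )

    is_true = np.array([g in truth.true_targets for g in genes])
    cols = {}
    for t, tool in enumerate(DEFAULT_TOOLS):
        prob = np.where(is_true, config.tool_sensitivity[t], config.tool_fpr[t])
        cols[tool] = rng_pred.random(len(genes)) < prob
    prediction_matrix = PredictionMatrix(pd.DataFrame(cols, index=genes))

    needle_dna = reverse_complement_rna(MIR100.seed).replace("U", "T")
    transcripts = [
        _random_transcript(f"TX{i:02d}", config.transcript_length, rng_tx, needle_dna)
        for i in range(1, config.n_transcripts + 1)
    ]
    planting_log: list[tuple[str, int, str]] = []
    # two-site architecture on the first transcript: CDS site at 409 and
    # 3'UTR site at 2155, mirroring a dual-site target mRNA
    transcripts[0] = plant_seed_site(transcripts[0], MIR100, 409, region="CDS")
    planting_log.append((transcripts[0].id, 409, "CDS"))
    transcripts[0] = plant_seed_site(transcripts[0], MIR100, 2155, region="3UTR")
    planting_log.append((transcripts[0].id, 2155, "3UTR"))
    occupied: dict[str, list[tuple[int, int]]] = {transcripts[0].id: [(409, 415), (2155, 2161)]}
    planted = 0
    while planted < config.n_random_sites:
        ti = int(rng_tx.integers(0, len(transcripts)))
        pos = int(rng_tx.integers(1, config.transcript_length - 6 + 1))
        spans = occupied.setdefault(transcripts[ti].id, [])
        if any(s - 6 <= pos <= e + 6 for s, e in spans):
            continue
        transcripts[ti] = plant_seed_site(transcripts[ti], MIR100, pos)
        spans.append((pos, pos + 6))
        planting_log.append((transcripts[ti].id, pos, transcripts[ti].region_at(pos)))
        planted += 1
    planting_log.sort()

    panels = {
        "cell": _cell_panel(config, true_targets, calibrator, rng_cell),
        "tissue": _tissue_panel(config, true_targets, rng_tissue),
    }

    return SyntheticDataset(
        experiments=experiments,
        prediction_matrix=prediction_matrix,
        transcripts=transcripts,
        mirna=MIR100,
        panels=panels,
        truth=truth,
        planted_down=planted_down,
        planting_log=planting_log,
        config=config,
    )


def _cell_panel(
    config: GeneratorConfig,
    true_targets: list[str],
    calibrator: str,
    rng: np.random.Generator,
) -> PanelTable:
    """10-cell-line panel: planted negative correlation, Ct-scale noise."""
    samples = [f"CL{i:02d}" for i in range(1, config.cell_panel_lines + 1)]
    genes = tuple([calibrator, *true_targets[: config.cell_panel_genes - 1]])
    n = len(samples)
    x = rng.normal(0.0, 1.5, size=n)  # miRNA log2 level
    xs = (x - x.mean()) / x.std()
    rows: list[tuple[str, str, float]] = []
    u6 = 18.0 + rng.normal(0.0, 0.05, size=n)  # references near-constant
    actb = 17.0 + rng.normal(0.0, 0.05, size=n)
    for s, sample in enumerate(samples):
        rows.append((sample, "U6", u6[s]))
        rows.append((sample, "ACTB", actb[s]))
        rows.append((sample, "miR-100", u6[s] - x[s]))
    r = config.cell_panel_r
    for gene in genes:
        e = rng.normal(size=n)
        y = 1.5 * (r * xs + np.sqrt(1.0 - r * r) * e)
        noise = rng.normal(0.0, config.ct_noise_sd, size=n) if config.ct_noise_sd > 0 else 0.0
        ct = actb - y + noise
        for s, sample in enumerate(samples):
            rows.append((sample, gene, ct[s]))
    df = pd.DataFrame(rows, columns=["sample", "assay", "ct"])
    return PanelTable(
        name="cell",
        ct=df,
        mirna_assay="miR-100",
        mirna_reference="U6",
        gene_reference="ACTB",
        genes=genes,
    )


_TISSUE_SAMPLES = ("E07", "E11", "E15", "E17", "BRAIN", "EYE", "SGLAND")


def _tissue_panel(
    config: GeneratorConfig,
    true_targets: list[str],
    rng: np.random.Generator,
) -> PanelTable:
    """7-sample developmental/tissue panel with an exactly planted r."""
    samples = list(_TISSUE_SAMPLES)
    gene = true_targets[0]
    n = len(samples)
    x = rng.normal(0.0, 1.5, size=n)
    y = _exact_r_vector(x, config.tissue_panel_r, rng)
    rows: list[tuple[str, str, float]] = []
    for s, sample in enumerate(samples):
        rows.append((sample, "U6", 18.0))
        rows.append((sample, "ACTB", 17.0))
        rows.append((sample, "miR-100", 18.0 - x[s]))
        rows.append((sample, gene, 17.0 - y[s]))
    df = pd.DataFrame(rows, columns=["sample", "assay", "ct"])
    return PanelTable(
        name="tissue",
        ct=df,
        mirna_assay="miR-100",
        mirna_reference="U6",
        gene_reference="ACTB",
        genes=(gene,),
    )


# ---------------------------------------------------------------------------
# on-disk representation


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write every pipeline input as plain text; returns the manifest path.

    Layout: per-experiment ``<id>.fc.tsv`` (gene, fold_change) or
    ``<id>.down.tsv`` (one symbol per line), ``prediction_matrix.tsv``,
    ``transcripts.fa`` + ``regions.tsv`` (1-based inclusive),
    ``panel_<name>.tsv`` (sample, assay, ct) and ``manifest.json``
    recording seed, parameters and the truth set. Output is byte-stable
    for a fixed seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": dataset.truth.seed,
        "mirna": {"name": dataset.mirna.name, "sequence": dataset.mirna.sequence},
        "config": dataclasses.asdict(dataset.config),
        "experiments": [],
        "truth": {
            "true_targets": sorted(dataset.truth.true_targets),
            "decoy_genes": sorted(dataset.truth.decoy_genes),
            "effect_fc": dataset.truth.effect_fc,
            "noise_sd": dataset.truth.noise_sd,
        },
        "planted_down": {g: list(v) for g, v in sorted(dataset.planted_down.items())},
        "planting_log": [list(t) for t in dataset.planting_log],
    }
    for exp in dataset.experiments:
        if exp.mode is ExperimentMode.FOLD_CHANGE:
            fname = f"{exp.id}.fc.tsv"
            lines = ["gene\tfold_change"]
            lines += [f"{g}\t{exp.fc[g]:.6f}" for g in sorted(exp.fc)]
            (out / fname).write_text("\n".join(lines) + "\n")
            manifest["experiments"].append(
                {
                    "id": exp.id,
                    "mode": "fold_change",
                    "species": exp.species,
                    "file": fname,
                    "calibrator": exp.calibrator,
                }
            )
        else:
            fname = f"{exp.id}.down.tsv"
            symbols = exp.raw_down_list or exp.down_list
            (out / fname).write_text("\n".join(sorted(symbols)) + "\n")
            manifest["experiments"].append(
                {"id": exp.id, "mode": "binary_list", "species": exp.species, "file": fname}
            )

    pm = dataset.prediction_matrix.matrix.astype(int)
    pm_out = pm.copy()
    pm_out.insert(0, "gene", pm.index)
    pm_out.to_csv(out / "prediction_matrix.tsv", sep="\t", index=False)

    fasta = []
    region_lines = ["transcript_id\tregion\tstart\tend"]
    for tx in dataset.transcripts:
        fasta.append(f">{tx.id}\n{_wrap_fasta(tx.sequence)}")
        for r in tx.regions:
            region_lines.append(f"{tx.id}\t{r.label}\t{r.start}\t{r.end}")
    (out / "transcripts.fa").write_text("\n".join(fasta) + "\n")
    (out / "regions.tsv").write_text("\n".join(region_lines) + "\n")

    for name, panel in dataset.panels.items():
        lines = ["sample\tassay\tct"]
        lines += [
            f"{row.sample}\t{row.assay}\t{row.ct:.4f}" for row in panel.ct.itertuples(index=False)
        ]
        (out / f"panel_{name}.tsv").write_text("\n".join(lines) + "\n")
        manifest.setdefault("panels", {})[name] = {
            "file": f"panel_{name}.tsv",
            "mirna_assay": panel.mirna_assay,
            "mirna_reference": panel.mirna_reference,
            "gene_reference": panel.gene_reference,
            "genes": list(panel.genes),
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
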