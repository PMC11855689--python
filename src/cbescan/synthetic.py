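"""Self-contained synthetic study generator.

Generates a random genome, transcript models with planted valid ORFs,
editor-like ("cbe") and control variant-call sets, and a RefEx-style
tissue-specificity table, together with a ground-truth manifest that fully
determines the expected output of every downstream module.

What is emulated, statistically:

* cbe samples carry C>T (and antisense G>A) calls whose per-site rate is
  multiplied by configurable 5'-W and 3'-W context boosts, reproducing the
  weak-base neighborhood preference of rAPOBEC1 deaminase domains;
  control samples carry context-uniform background substitutions only;
* variant quality annotations are drawn so that a configured fraction of
  calls violates each hard-filter criterion;
* VAFs are Beta-distributed with per-sample-kind parameters;
* a designated subset of transcripts is generated with A-context
  stop-forming codon pairs at an elevated per-codon rate ("high-risk"
  transcripts) and assigned to one designated tissue, planting an
  elevated-ESD signal recoverable by the tissue-risk stage.

No read-level realism (coverage, splicing noise, expression) is attempted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import STOP_CODONS, STOP_FORMING_CODONS, revcomp
from .errors import ConfigurationError, PlacementError
from .prs_scan import CodingSequence, TranscriptModel, brute_force_prs
from .variant_profile import FilterThresholds

__all__ = [
    "SimulationConfig",
    "GroundTruthManifest",
    "SyntheticStudy",
    "simulate_genome",
    "simulate_transcripts",
    "simulate_variant_calls",
    "simulate_tissue_table",
    "simulate_study",
    "write_study",
]

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
A_ENDING_SENSE = tuple(c for c in SENSE_CODONS if c.endswith("A"))
CRITERIA_NAMES = (
    "QualByDepth", "QUAL", "StrandOddsRatio", "FisherStrand",
    "RMSMappingQuality", "MappingQualityRankSum", "ReadPosRankSum",
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; every draw goes through one seed."""

    seed: int = 0
    # genome
    n_contigs: int = 2
    contig_length: int = 100_000
    gc_content: float = 0.5
    # transcripts
    n_transcripts: int = 60
    exons_range: tuple[int, int] = (1, 3)
    codons_range: tuple[int, int] = (120, 200)
    minus_strand_fraction: float = 0.5
    intron_length_range: tuple[int, int] = (40, 120)
    intergenic_gap_range: tuple[int, int] = (150, 500)
    # planted high-risk transcripts (shorter, A-context stop-codon rich)
    n_high_risk: int = 4
    high_risk_codons_range: tuple[int, int] = (60, 80)
    high_risk_prs_rate: float = 0.25
    # substitution model
    background_rate: float = 5e-3
    cbe_rate: float = 0.01
    w5_boost: float = 6.0
    w3_boost: float = 2.0
    vaf_beta_cbe: tuple[float, float] = (8.0, 3.0)
    vaf_beta_control: tuple[float, float] = (2.0, 2.0)
    depth_range: tuple[int, int] = (20, 80)
    # per-criterion probability that a call is drawn to violate that filter
    filter_fail_fraction: float = 0.02
    # tissues
    tissues: tuple[str, ...] = ("brain", "colon", "liver", "lung", "muscle", "ovary")
    elevated_tissue: str = "colon"
    specific_fraction: float = 0.6
    low_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("gc_content", "minus_strand_fraction", "high_risk_prs_rate",
                     "background_rate", "cbe_rate", "filter_fail_fraction",
                     "specific_fraction", "low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.contig_length <= 0 or self.n_contigs <= 0:
            raise ConfigurationError("contig dimensions must be positive")
        if self.elevated_tissue not in self.tissues:
            raise ConfigurationError(
                f"elevated_tissue {self.elevated_tissue!r} not in tissues"
            )


@dataclass
class GroundTruthManifest:
    """Planted truth for every downstream assertion.

    ``variants``: per sample, one dict per call with the oriented context
    class (ACW/WCW/other), planted filter violations, and drawn VAF.
    ``transcripts``: per id, true PRS offsets (oracle-derived), planted
    A-context PRS offsets, amino-acid length, and the high-risk flag.
    ``tissues``: the designated elevated tissue and planted high-risk ids.
    """

    variants: dict[str, list[dict]] = field(default_factory=dict)
    transcripts: dict[str, dict] = field(default_factory=dict)
    tissues: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"variants": self.variants, "transcripts": self.transcripts,
             "tissues": self.tissues}, indent=1))


@dataclass
class SyntheticStudy:
    """Everything one simulated study produces, in memory."""

    config: SimulationConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    calls: dict[str, list[dict]]          # sample name -> VCF-ready rows
    tissue_table: pd.DataFrame
    manifest: GroundTruthManifest


def _contig_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_contigs)]


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Random genome as per-contig numpy character arrays (i.i.d. bases)."""
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    genome = {}
    for name in _contig_names(config):
        genome[name] = rng.choice(np.array(list("ACGT")), size=config.contig_length, p=p)
    return genome


def _make_orf(
    rng: np.random.Generator,
    n_codons: int,
    high_risk: bool,
    prs_rate: float,
) -> tuple[str, list[int]]:
    """A valid ORF (ATG ... stop, no internal stop) as a codon string.

    For high-risk transcripts, pairs (A-ending codon, CAA|CAG) are planted
    at per-position rate ``prs_rate``; returns the CDS offsets of planted
    stop-forming Cs (each ACW- and WCW-effective by construction).
    """
    codons: list[str] = ["ATG"]
    planted: list[int] = []
    while len(codons) < n_codons - 1:
        room = n_codons - 1 - len(codons)
        if high_risk and room >= 2 and rng.random() < prs_rate:
            codons.append(A_ENDING_SENSE[rng.integers(len(A_ENDING_SENSE))])
            planted.append(3 * len(codons))
            codons.append("CAA" if rng.random() < 0.5 else "CAG")
        else:
            codons.append(SENSE_CODONS[rng.integers(len(SENSE_CODONS))])
    codons.append(sorted(STOP_CODONS)[rng.integers(3)])
    return "".join(codons), planted


def simulate_transcripts(
    genome: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], dict[str, dict]]:
    """Plant valid ORFs into the genome and return transcript models.

    ORFs are written over the random background (so CDS assembly is valid
    by construction); exon structure and strand are random per transcript.
    Returns the models plus per-transcript truth entries (oracle PRS
    offsets, planted offsets, aa length, high-risk flag).
    """
    names = _contig_names(config)
    cursors = {name: 100 for name in names}
    models: list[TranscriptModel] = []
    truth: dict[str, dict] = {}
    for t_i in range(config.n_transcripts):
        high_risk = t_i < config.n_high_risk
        lo, hi = (config.high_risk_codons_range if high_risk
                  else config.codons_range)
        n_codons = int(rng.integers(lo, hi + 1))
        cds, planted = _make_orf(rng, n_codons, high_risk, config.high_risk_prs_rate)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        n_exons = int(rng.integers(config.exons_range[0], config.exons_range[1] + 1))
        n_exons = min(n_exons, len(cds) // 30 or 1)
        # split the CDS into n_exons non-empty pieces
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_exons - 1,
                                      replace=False))
            bounds = [0, *cuts.tolist(), len(cds)]
        else:
            bounds = [0, len(cds)]
        exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        introns = [int(rng.integers(*config.intron_length_range))
                   for _ in range(n_exons - 1)]
        span = len(cds) + sum(introns)
        # place on the least-occupied contig
        chrom = min(names, key=lambda n: cursors[n])
        start = cursors[chrom] + int(rng.integers(*config.intergenic_gap_range))
        if start + span > config.contig_length - 100:
            raise PlacementError(
                f"cannot place transcript {t_i} on {chrom}: "
                f"need {span} bases at {start}"
            )
        cursors[chrom] = start + span
        pieces = [cds[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
        intervals: list[tuple[int, int]] = []
        contig = genome[chrom]
        if strand == "+":
            cur = start
            for j, piece in enumerate(pieces):
                contig[cur:cur + len(piece)] = list(piece)
                intervals.append((cur, cur + len(piece)))
                cur += len(piece) + (introns[j] if j < len(introns) else 0)
        else:
            cur_end = start + span
            for j, piece in enumerate(pieces):
                block_start = cur_end - len(piece)
                contig[block_start:cur_end] = list(revcomp(piece))
                intervals.append((block_start, cur_end))
                cur_end = block_start - (introns[j] if j < len(introns) else 0)
        tid = f"TX{t_i + 1:04d}"
        models.append(TranscriptModel(
            transcript_id=tid, chrom=chrom, strand=strand,
            cds_intervals=intervals, gene_id=f"G{t_i + 1:04d}",
        ))
        oracle = brute_force_prs(CodingSequence(
            transcript_id=tid, sequence=cds, ends_with_stop=True,
        ))
        truth[tid] = {
            "prs_offsets": oracle,
            "planted_offsets": planted,
            "aa_length": n_codons - 1,
            "strand": strand,
            "high_risk": high_risk,
        }
    return models, truth


def _draw_info(rng: np.random.Generator, fail_fraction: float,
               thresholds: FilterThresholds) -> tuple[dict[str, float], list[str]]:
    """Quality annotations: nominal passing draws, with each criterion
    independently planted to fail with probability ``fail_fraction``.
    Draws stay clear of the thresholds so VCF float round-trips cannot flip
    a verdict."""
    t = thresholds
    nominal = {
        "QualByDepth": rng.uniform(t.qd_min + 3, 25.0),
        "QUAL": rng.uniform(t.qual_min + 70, 1000.0),
        "StrandOddsRatio": rng.uniform(0.2, t.sor_max - 0.5),
        "FisherStrand": rng.uniform(0.0, t.fs_max - 30),
        "RMSMappingQuality": rng.uniform(t.mq_min + 10, 60.0),
        "MappingQualityRankSum": rng.uniform(-2.0, 2.0),
        "ReadPosRankSum": rng.uniform(-2.0, 2.0),
    }
    failing = {
        "QualByDepth": rng.uniform(0.0, t.qd_min - 0.3),
        "QUAL": rng.uniform(1.0, t.qual_min - 3),
        "StrandOddsRatio": rng.uniform(t.sor_max + 0.5, 6.0),
        "FisherStrand": rng.uniform(t.fs_max + 5, 120.0),
        "RMSMappingQuality": rng.uniform(10.0, t.mq_min - 3),
        "MappingQualityRankSum": rng.uniform(-20.0, t.mq_rank_sum_min - 0.5),
        "ReadPosRankSum": rng.uniform(-15.0, t.read_pos_rank_sum_min - 0.5),
    }
    planted: list[str] = []
    info: dict[str, float] = {}
    for name in CRITERIA_NAMES:
        if rng.random() < fail_fraction:
            planted.append(name)
            info[name] = round(float(failing[name]), 3)
        else:
            info[name] = round(float(nominal[name]), 3)
    return info, planted


def _context_class(five: str, three: str) -> str:
    if five == "A" and three in "AT":
        return "ACW"
    if five in "AT" and three in "AT":
        return "WCW"
    return "other"


def simulate_variant_calls(
    genome: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_kind: str = "cbe",
    sample_name: str | None = None,
) -> tuple[list[dict], list[dict]]:
    """One sample's substitution calls plus their ground-truth entries.

    cbe samples get extra C>T calls at C sites (and G>A at G sites, the
    antisense reading) with per-site probability cbe_rate multiplied by the
    5'-W and 3'-W boosts in the oriented frame; both kinds get
    context-uniform background substitutions at background_rate.
    """
    if sample_kind not in ("cbe", "control"):
        raise ConfigurationError(f"sample_kind must be cbe|control, got {sample_kind!r}")
    sample_name = sample_name or sample_kind
    thresholds = FilterThresholds()
    a, b = (config.vaf_beta_cbe if sample_kind == "cbe"
            else config.vaf_beta_control)
    rows: list[dict] = []
    truth: list[dict] = []
    other = {base: [o for o in "ACGT" if o != base] for base in "ACGT"}
    for chrom in _contig_names(config):
        arr = genome[chrom]
        n = arr.size
        is_w = (arr == "A") | (arr == "T")
        w_prev = np.concatenate([[False], is_w[:-1]])
        w_next = np.concatenate([is_w[1:], [False]])
        p_cbe = np.zeros(n)
        if sample_kind == "cbe":
            is_c = arr == "C"
            is_g = arr == "G"
            # oriented 5'/3' neighbors: genomic prev/next for C sites,
            # swapped for G sites (W-ness is complement-invariant)
            boost_c = np.where(w_prev, config.w5_boost, 1.0) * \
                np.where(w_next, config.w3_boost, 1.0)
            boost_g = np.where(w_next, config.w5_boost, 1.0) * \
                np.where(w_prev, config.w3_boost, 1.0)
            p_cbe = config.cbe_rate * (is_c * boost_c + is_g * boost_g)
        edited = rng.random(n) < p_cbe
        background = rng.random(n) < config.background_rate
        background &= ~edited
        sites = np.flatnonzero(edited | background)
        for i in sites:
            ref = str(arr[i])
            if edited[i]:
                alt = "T" if ref == "C" else "A"
                if ref == "C":
                    five, three = str(arr[i - 1]) if i else "N", \
                        str(arr[i + 1]) if i + 1 < n else "N"
                else:
                    five = revcomp(str(arr[i + 1])) if i + 1 < n else "N"
                    three = revcomp(str(arr[i - 1])) if i else "N"
                origin = "edit"
            else:
                alt = other[ref][rng.integers(3)]
                if ref in "CG":
                    if ref == "C":
                        five = str(arr[i - 1]) if i else "N"
                        three = str(arr[i + 1]) if i + 1 < n else "N"
                    else:
                        five = revcomp(str(arr[i + 1])) if i + 1 < n else "N"
                        three = revcomp(str(arr[i - 1])) if i else "N"
                else:
                    five = three = "N"
                origin = "background"
            vaf = float(rng.beta(a, b))
            depth = int(rng.integers(*config.depth_range))
            alt_depth = min(depth, max(1, int(rng.binomial(depth, vaf))))
            info, planted_failures = _draw_info(
                rng, config.filter_fail_fraction, thresholds
            )
            rows.append({
                "chrom": chrom,
                "pos": int(i + 1),
                "ref": ref,
                "alt": alt,
                "qual": info.pop("QUAL"),
                "info": {
                    "QD": info["QualByDepth"],
                    "SOR": info["StrandOddsRatio"],
                    "FS": info["FisherStrand"],
                    "MQ": info["RMSMappingQuality"],
                    "MQRankSum": info["MappingQualityRankSum"],
                    "ReadPosRankSum": info["ReadPosRankSum"],
                },
                "ad": (depth - alt_depth, alt_depth),
            })
            truth.append({
                "sample": sample_name,
                "chrom": chrom,
                "pos": int(i + 1),
                "ref": ref,
                "alt": alt,
                "origin": origin,
                "context_class": _context_class(five, three)
                if (origin == "edit" or ref in "CG") else "n/a",
                "planted_failures": planted_failures,
                "vaf_drawn": vaf,
            })
    return rows, truth


def simulate_tissue_table(
    transcripts: list[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator,
    high_risk_ids: set[str],
) -> pd.DataFrame:
    """RefEx-style table: entries in {1, -1, 0}.

    Planted high-risk transcripts are marked 1 in the designated elevated
    tissue; other transcripts are marked 1 in a random other tissue with
    probability ``specific_fraction`` and -1 in a further tissue with
    probability ``low_fraction``.
    """
    tissues = list(config.tissues)
    others = [t for t in tissues if t != config.elevated_tissue]
    table = pd.DataFrame(
        0, index=[m.transcript_id for m in transcripts], columns=tissues,
        dtype=int,
    )
    table.index.name = "transcript_id"
    for m in transcripts:
        tid = m.transcript_id
        if tid in high_risk_ids:
            table.loc[tid, config.elevated_tissue] = 1
            continue
        if rng.random() < config.specific_fraction:
            table.loc[tid, others[rng.integers(len(others))]] = 1
        if rng.random() < config.low_fraction:
            candidates = [t for t in tissues if table.loc[tid, t] == 0]
            table.loc[tid, candidates[rng.integers(len(candidates))]] = -1
    return table


def simulate_study(
    config: SimulationConfig,
    n_cbe_samples: int = 3,
    n_control_samples: int = 3,
) -> SyntheticStudy:
    """Run the full generator chain under one seed."""
    rng = np.random.default_rng(config.seed)
    genome_arrays = simulate_genome(config, rng)
    models, tx_truth = simulate_transcripts(genome_arrays, config, rng)
    manifest = GroundTruthManifest(transcripts=tx_truth)
    calls: dict[str, list[dict]] = {}
    for k in range(n_cbe_samples):
        name = f"cbe_{k + 1}"
        rows, truth = simulate_variant_calls(
            genome_arrays, config, rng, "cbe", name
        )
        calls[name] = rows
        manifest.variants[name] = truth
    for k in range(n_control_samples):
        name = f"control_{k + 1}"
        rows, truth = simulate_variant_calls(
            genome_arrays, config, rng, "control", name
        )
        calls[name] = rows
        manifest.variants[name] = truth
    high_risk_ids = {tid for tid, t in tx_truth.items() if t["high_risk"]}
    table = simulate_tissue_table(models, config, rng, high_risk_ids)
    manifest.tissues = {
        "elevated_tissue": config.elevated_tissue,
        "high_risk_ids": sorted(high_risk_ids),
    }
    genome = {name: "".join(arr) for name, arr in genome_arrays.items()}
    return SyntheticStudy(
        config=config, genome=genome, transcripts=models, calls=calls,
        tissue_table=table, manifest=manifest,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA (+ .fai), per-sample VCFs, BED12, tissue TSV, manifest JSON."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fasta = outdir / "genome.fa"
    cio.write_fasta(study.genome, fasta)
    cio.faidx(fasta)
    paths["genome"] = fasta
    for name, rows in study.calls.items():
        p = outdir / f"{name}.vcf"
        cio.write_vcf(rows, {c: len(s) for c, s in study.genome.items()}, p,
                      sample_name=name)
        paths[name] = p
    bed = outdir / "transcripts.bed"
    cio.write_bed12(study.transcripts, bed)
    paths["transcripts"] = bed
    tissues = outdir / "tissues.tsv"
    study.tissue_table.to_csv(tissues, sep="\t")
    paths["tissues"] = tissues
    manifest = outdir / "manifest.json"
    study.manifest.to_json(manifest)
    paths["manifest"] = manifest
    config = outdir / "config.json"
    config.write_text(json.dumps(asdict(study.config), indent=1, default=list))
    paths["config"] = config
    return paths
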