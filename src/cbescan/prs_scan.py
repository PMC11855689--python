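"""Premature-stop scanning and effective substrate density (ESD).

A cytosine base editor acting on a transcript converts C to U. Within a
coding sequence, a C at the first position of CAA, CAG or CGA creates a
stop codon (TAA, TAG, TGA) when deaminated — a premature-stop-inducing
cytosine, here a PRS (potential risk substrate). No other single C->T
change can create a stop, since no stop codon carries T at its second or
third position; `brute_force_prs` verifies this exhaustively and serves as
the independent oracle for `find_prs`.

A PRS whose 40-base sequence context a classifier predicts as
off-target-prone is an *effective* PRS. Per transcript,

    ESD = n_effective / (n_prs * aa_length)

normalizes the effective count to both the number of substrates and the
protein length (in amino acids, excluding the terminal stop), making ESD a
density comparable across transcripts. 0 <= ESD <= 1/aa_length.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from ._seq import STOP_CODONS, STOP_FORMING_CODONS, revcomp
from .classifiers import Classifier
from .errors import CoordinateError, FrameError
from .variant_profile import ContextWindow, _slice_padded

__all__ = [
    "TranscriptModel",
    "CodingSequence",
    "PRSRecord",
    "ESDRecord",
    "assemble_cds",
    "find_prs",
    "brute_force_prs",
    "map_to_genome",
    "prs_context",
    "score_effective",
    "compute_esd",
    "scan_transcript",
    "esd_table",
]


@dataclass
class TranscriptModel:
    """A transcript's CDS as ordered genomic intervals.

    ``cds_intervals`` are 0-based half-open and listed 5'->3' in transcript
    orientation: ascending genomic order on the + strand, descending on the
    - strand.
    """

    transcript_id: str
    chrom: str
    strand: str  # "+" | "-"
    cds_intervals: list[tuple[int, int]]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.cds_intervals:
            raise ValueError("cds_intervals must be non-empty")
        starts = [s for s, e in self.cds_intervals]
        if self.strand == "+" and starts != sorted(starts):
            self.cds_intervals = sorted(self.cds_intervals)
        elif self.strand == "-" and starts != sorted(starts, reverse=True):
            self.cds_intervals = sorted(self.cds_intervals, reverse=True)
        for s, e in self.cds_intervals:
            if e <= s:
                raise ValueError(f"empty interval ({s}, {e})")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class CodingSequence:
    """An assembled CDS with ORF validity flags.

    By Ensembl convention the CDS includes the terminal stop codon, so
    ``aa_length`` = codons - 1 when a terminal stop is present; without one,
    ``aa_length`` = codons and ``ends_with_stop`` is False.
    """

    transcript_id: str
    sequence: str
    frame_valid: bool = True
    starts_with_atg: bool = False
    ends_with_stop: bool = False
    internal_stop_free: bool = True

    @property
    def aa_length(self) -> int:
        n_codons = len(self.sequence) // 3
        return n_codons - 1 if self.ends_with_stop else n_codons

    @property
    def is_valid_orf(self) -> bool:
        return (
            self.frame_valid
            and self.starts_with_atg
            and self.ends_with_stop
            and self.internal_stop_free
        )


@dataclass
class PRSRecord:
    """One premature-stop-inducing cytosine in a transcript."""

    transcript_id: str
    codon_index: int        # 0-based sense-codon index
    cds_offset: int         # offset of the C (= 3 * codon_index)
    codon: str              # CAA | CAG | CGA
    chrom: str | None = None
    genomic_pos: int | None = None  # 1-based position of the C's genome base
    strand: str | None = None
    context: ContextWindow | None = None
    effective: bool | None = None


@dataclass
class ESDRecord:
    """Per-transcript effective substrate density."""

    transcript_id: str
    n_prs: int
    n_effective: int
    aa_length: int
    esd: float
    classifier: str | None = None
    flags: tuple[str, ...] = ()


def assemble_cds(transcript: TranscriptModel, genome: Mapping[str, object]) -> CodingSequence:
    """Concatenate CDS exon pieces in transcript order (revcomp on -).

    Assembly never fails on an invalid ORF; the validity flags carry that
    information.
    """
    if transcript.chrom not in genome:
        raise CoordinateError(f"contig {transcript.chrom!r} not in genome")
    contig = genome[transcript.chrom]
    contig_len = len(contig)
    pieces = []
    for start, end in transcript.cds_intervals:
        if start < 0 or end > contig_len:
            raise CoordinateError(
                f"interval ({start}, {end}) outside contig {transcript.chrom} "
                f"(length {contig_len})"
            )
        piece = str(contig[start:end]).upper()
        pieces.append(revcomp(piece) if transcript.strand == "-" else piece)
    seq = "".join(pieces)
    frame_valid = len(seq) % 3 == 0
    codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    ends_with_stop = frame_valid and bool(codons) and codons[-1] in STOP_CODONS
    internal = codons[:-1] if ends_with_stop else codons
    return CodingSequence(
        transcript_id=transcript.transcript_id,
        sequence=seq,
        frame_valid=frame_valid,
        starts_with_atg=seq.startswith("ATG"),
        ends_with_stop=ends_with_stop,
        internal_stop_free=not any(c in STOP_CODONS for c in internal),
    )


def _sense_codon_count(cds: CodingSequence) -> int:
    n_codons = len(cds.sequence) // 3
    return n_codons - 1 if cds.ends_with_stop else n_codons


def find_prs(cds: CodingSequence, tolerate_frame: bool = False) -> list[PRSRecord]:
    """All PRSs in a CDS: sense codons in {CAA, CAG, CGA}, in order.

    The terminal stop codon (when present) is excluded. Non-multiple-of-3
    CDSs raise a frame error unless ``tolerate_frame`` trims trailing bases.
    """
    seq = cds.sequence
    if len(seq) % 3 != 0:
        if not tolerate_frame:
            raise FrameError(
                f"CDS {cds.transcript_id}: length {len(seq)} not divisible by 3"
            )
        seq = seq[: len(seq) - len(seq) % 3]
    records: list[PRSRecord] = []
    for codon_index in range(_sense_codon_count(cds)):
        codon = seq[3 * codon_index: 3 * codon_index + 3]
        if codon in STOP_FORMING_CODONS:
            records.append(
                PRSRecord(
                    transcript_id=cds.transcript_id,
                    codon_index=codon_index,
                    cds_offset=3 * codon_index,
                    codon=codon,
                )
            )
    return records


def brute_force_prs(cds: CodingSequence) -> list[int]:
    """Oracle: CDS offsets of every C whose C->T substitution creates a stop
    codon before the terminal stop, found by exhaustive substitute-and-translate.
    """
    seq = cds.sequence
    if len(seq) % 3 != 0:
        raise FrameError(
            f"CDS {cds.transcript_id}: length {len(seq)} not divisible by 3"
        )
    n_sense = _sense_codon_count(cds)
    baseline = str(Seq(seq).translate())[:n_sense]
    hits: list[int] = []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        mutated = str(Seq(seq[:i] + "T" + seq[i + 1:]).translate())[:n_sense]
        # a stop appears at a sense-codon position where none was before
        if any(m == "*" and b != "*" for m, b in zip(mutated, baseline)):
            hits.append(i)
    return hits


def map_to_genome(transcript: TranscriptModel, cds_offset: int) -> tuple[str, int, str]:
    """Map a CDS offset to (chrom, 1-based genomic position, strand).

    For - strand transcripts the returned coordinate is that of the genome
    base complementary to the CDS base.
    """
    if not 0 <= cds_offset < transcript.cds_length:
        raise CoordinateError(
            f"cds_offset {cds_offset} out of range for {transcript.transcript_id}"
        )
    remaining = cds_offset
    for start, end in transcript.cds_intervals:
        length = end - start
        if remaining < length:
            if transcript.strand == "+":
                pos0 = start + remaining
            else:
                pos0 = end - 1 - remaining
            return transcript.chrom, pos0 + 1, transcript.strand
        remaining -= length
    raise CoordinateError("unreachable")  # pragma: no cover


def prs_context(
    genome: Mapping[str, object],
    transcript: TranscriptModel,
    prs: PRSRecord,
    upstream: int = 20,
    downstream: int = 19,
    mode: str = "genomic",
    cds: CodingSequence | None = None,
) -> ContextWindow:
    """Sequence context of a PRS cytosine, centered on the C.

    ``genomic`` mode takes the flanks from the unspliced genome in
    transcript orientation; ``spliced`` mode takes them from the assembled
    CDS (the mRNA-side reading). Windows overhanging an edge are N-padded.
    """
    chrom, pos, strand = map_to_genome(transcript, prs.cds_offset)
    if mode == "spliced":
        if cds is None:
            cds = assemble_cds(transcript, genome)
        seq, _ = _slice_padded(cds.sequence, prs.cds_offset, upstream, downstream)
    elif mode == "genomic":
        contig = genome[transcript.chrom]
        center = pos - 1
        if strand == "+":
            seq, _ = _slice_padded(contig, center, upstream, downstream)
        else:
            seq, _ = _slice_padded(contig, center, downstream, upstream)
            seq = revcomp(seq)
    else:
        raise ValueError(f"mode must be 'genomic' or 'spliced', got {mode!r}")
    return ContextWindow(
        sequence=seq,
        site_offset=upstream,
        upstream_len=upstream,
        downstream_len=downstream,
        origin=(chrom, pos, strand),
    )


def score_effective(
    prs_records: Sequence[PRSRecord], classifier: Classifier
) -> tuple[list[PRSRecord], int]:
    """Set each record's ``effective`` flag from the classifier; return count."""
    n_effective = 0
    for rec in prs_records:
        if rec.context is None:
            raise ValueError(
                f"PRS in {rec.transcript_id} has no context window"
            )
        try:
            rec.effective = bool(classifier.predict(rec.context))
        except Exception as exc:
            raise type(exc)(
                f"classifier {classifier.name!r} failed on transcript "
                f"{rec.transcript_id}: {exc}"
            ) from exc
        n_effective += rec.effective
    return list(prs_records), n_effective


def compute_esd(
    n_effective: int, n_prs: int, aa_length: int,
    normalization: str = "multiplicative",
) -> float:
    """Effective substrate density: n_effective / (n_prs * aa_length).

    Transcripts with zero PRSs have density 0 (there is nothing to edit
    into a stop). ``normalization="additive"`` selects the alternative
    n_effective / (n_prs + aa_length) reading for sensitivity analysis.
    """
    if aa_length <= 0:
        raise ValueError(f"aa_length must be positive, got {aa_length}")
    if not 0 <= n_effective <= n_prs:
        raise ValueError(
            f"need 0 <= n_effective <= n_prs, got {n_effective}/{n_prs}"
        )
    if n_prs == 0:
        return 0.0
    if normalization == "additive":
        return n_effective / (n_prs + aa_length)
    if normalization != "multiplicative":
        raise ValueError(
            f"normalization must be multiplicative|additive, got {normalization!r}"
        )
    return n_effective / (n_prs * aa_length)


def scan_transcript(
    genome: Mapping[str, object],
    transcript: TranscriptModel,
    classifiers: Sequence[Classifier],
    upstream: int = 20,
    downstream: int = 19,
    mode: str = "genomic",
    tolerate_frame: bool = False,
) -> tuple[list[PRSRecord], list[ESDRecord]]:
    """Full per-transcript scan: assemble, find PRSs, contextualize, score.

    Returns the PRS records (contexts attached, ``effective`` left at the
    last classifier's verdict) and one ESD record per classifier.
    """
    cds = assemble_cds(transcript, genome)
    flags = tuple(
        flag
        for flag, bad in (
            ("no_start", not cds.starts_with_atg),
            ("no_terminal_stop", not cds.ends_with_stop),
            ("internal_stop", not cds.internal_stop_free),
            ("frame_trimmed", not cds.frame_valid),
        )
        if bad
    )
    prs_records = find_prs(cds, tolerate_frame=tolerate_frame)
    for rec in prs_records:
        rec.chrom, rec.genomic_pos, rec.strand = map_to_genome(
            transcript, rec.cds_offset
        )
        rec.context = prs_context(
            genome, transcript, rec, upstream, downstream, mode=mode, cds=cds
        )
    esd_records = []
    for clf in classifiers:
        _, n_eff = score_effective(prs_records, clf)
        esd_records.append(
            ESDRecord(
                transcript_id=transcript.transcript_id,
                n_prs=len(prs_records),
                n_effective=n_eff,
                aa_length=max(cds.aa_length, 1),
                esd=compute_esd(n_eff, len(prs_records), max(cds.aa_length, 1)),
                classifier=clf.name,
                flags=flags,
            )
        )
    return prs_records, esd_records


def esd_table(records: Sequence[ESDRecord]) -> pd.DataFrame:
    """ESD records as a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "classifier": r.classifier,
                "n_prs": r.n_prs,
                "n_effective": r.n_effective,
                "aa_length": r.aa_length,
                "esd": r.esd,
                "flags": ",".join(r.flags),
            }
            for r in records
        ]
    )
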