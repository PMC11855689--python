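"""Substitution profiling from variant calls.

Parses SNV calls from VCF, applies GATK-style hard filters, classifies
substitutions into the twelve ordered ref>alt classes, computes and
thresholds variant allele frequencies (VAF), extracts fixed-length sequence
context windows around substituted cytosines, and builds per-position base
count / neighbor weak-base (W = A or T) frequency profiles.

Cytosine base editors deaminate C to U on RNA; in the called substitution
spectrum this appears as C>T on the sense strand and G>A on the antisense
strand. Windows around G>A calls are therefore reverse-complemented into a
C-centered orientation by default so one motif convention serves both
strands.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seq import BASES, is_w, revcomp
from .errors import (
    InconsistentWindowError,
    InsufficientReplicatesError,
    InvalidSubstitutionError,
    MissingAnnotationError,
    UndefinedVafError,
    UnknownContigError,
)
from .stats import welch_two_tailed

__all__ = [
    "FilterThresholds",
    "SubstitutionRecord",
    "ContextWindow",
    "BaseCountMatrix",
    "FilterVerdict",
    "classify_substitution",
    "apply_hard_filters",
    "compute_vaf",
    "partition_by_vaf",
    "extract_context_window",
    "neighbor_frequencies",
    "compare_w_enrichment",
    "substitution_spectrum",
    "read_vcf_substitutions",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds for SNV quality annotations.

    Defaults follow GATK germline hard-filtering practice: a call fails if
    QD < 2, QUAL < 30, SOR > 3, FS > 60, MQ < 40, MQRankSum < -12.5 or
    ReadPosRankSum < -8. All comparisons are strict, so a value exactly at
    its threshold passes.
    """

    qd_min: float = 2.0
    qual_min: float = 30.0
    sor_max: float = 3.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not math.isfinite(value):
                raise ValueError(f"threshold {name} must be finite, got {value}")


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of hard filtering: pass, or fail with the violated criteria."""

    passed: bool
    failed_criteria: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # truthiness == passed
        return self.passed


@dataclass
class SubstitutionRecord:
    """One called single-nucleotide substitution with quality annotations.

    ``pos`` is 1-based (as in VCF). Annotations absent from the source VCF
    are ``None``; a missing annotation never triggers its filter criterion
    (GATK omits e.g. MQRankSum at sites without heterozygous reads).
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    qual: float | None = None
    qd: float | None = None
    sor: float | None = None
    fs: float | None = None
    mq: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    ref_depth: int | None = None
    alt_depth: int | None = None
    vaf: float | None = None
    filter_status: FilterVerdict | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if (
            self.ref_base not in BASES
            or self.alt_base not in BASES
            or self.ref_base == self.alt_base
        ):
            raise InvalidSubstitutionError(
                f"invalid substitution {self.ref_base}>{self.alt_base} "
                f"at {self.chrom}:{self.pos}"
            )
        if (
            self.vaf is not None
            and self.ref_depth is not None
            and self.alt_depth is not None
        ):
            total = self.ref_depth + self.alt_depth
            if total > 0 and abs(self.vaf - self.alt_depth / total) > 1e-9:
                raise ValueError(
                    f"vaf={self.vaf} inconsistent with depths "
                    f"{self.ref_depth}/{self.alt_depth}"
                )

    @property
    def substitution_class(self) -> str:
        return classify_substitution(self.ref_base, self.alt_base)[0]

    @property
    def is_c_to_u(self) -> bool:
        return classify_substitution(self.ref_base, self.alt_base)[1]


@dataclass
class ContextWindow:
    """Fixed-length sequence centered on a substituted or candidate base.

    ``site_offset`` indexes the central base; by construction it equals
    ``upstream_len``. For C-oriented windows the central base is C.
    """

    sequence: str
    site_offset: int
    upstream_len: int
    downstream_len: int
    label: str | None = None  # "positive" | "negative" | None
    origin: tuple[str, int, str] | None = None  # (chrom, 1-based pos, strand)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.upstream_len + 1 + self.downstream_len:
            raise InconsistentWindowError(
                f"window length {len(self.sequence)} != "
                f"{self.upstream_len}+1+{self.downstream_len}"
            )
        if self.site_offset != self.upstream_len:
            raise InconsistentWindowError("site_offset must equal upstream_len")

    @property
    def central_base(self) -> str:
        return self.sequence[self.site_offset]

    @property
    def five_prime_neighbor(self) -> str:
        return self.sequence[self.site_offset - 1] if self.site_offset > 0 else "N"

    @property
    def three_prime_neighbor(self) -> str:
        i = self.site_offset + 1
        return self.sequence[i] if i < len(self.sequence) else "N"

    def reverse_complement(self) -> "ContextWindow":
        origin = self.origin
        if origin is not None:
            chrom, pos, strand = origin
            origin = (chrom, pos, "-" if strand == "+" else "+")
        return ContextWindow(
            sequence=revcomp(self.sequence),
            site_offset=self.downstream_len,
            upstream_len=self.downstream_len,
            downstream_len=self.upstream_len,
            label=self.label,
            origin=origin,
        )


_ALPHABET = "ACGTN"


@dataclass
class BaseCountMatrix:
    """Per-position A/C/G/T/N counts over a set of equal-length windows."""

    counts: pd.DataFrame  # index = alphabet, columns = 0..L-1
    n_windows: int

    @classmethod
    def from_windows(cls, windows: Sequence[ContextWindow]) -> "BaseCountMatrix":
        if not windows:
            raise InconsistentWindowError("empty window set")
        length = len(windows[0].sequence)
        if any(len(w.sequence) != length for w in windows):
            raise InconsistentWindowError("windows have mixed lengths")
        mat = np.zeros((len(_ALPHABET), length), dtype=np.int64)
        index = {b: i for i, b in enumerate(_ALPHABET)}
        for w in windows:
            for j, base in enumerate(w.sequence):
                mat[index.get(base.upper(), 4), j] += 1
        counts = pd.DataFrame(mat, index=list(_ALPHABET), columns=range(length))
        return cls(counts=counts, n_windows=len(windows))

    def fraction(self, bases: str, position: int) -> float:
        """Fraction of windows with one of *bases* at *position*."""
        sub = self.counts.loc[list(bases), position].sum()
        return float(sub) / self.n_windows


_CLASS_LABELS = {
    (r, a): f"{r}-to-{a}" for r in BASES for a in BASES if r != a
}


def classify_substitution(ref_base: str, alt_base: str) -> tuple[str, bool]:
    """Classify a substitution into one of the 12 ordered ref>alt classes.

    Returns ``(label, is_c_to_u)`` where the flag is true for the two
    classes that evidence C-to-U deamination: C>T on the called strand and
    G>A (its complement on the opposite strand).
    """
    key = (ref_base, alt_base)
    if key not in _CLASS_LABELS:
        raise InvalidSubstitutionError(f"not a substitution: {ref_base}>{alt_base}")
    return _CLASS_LABELS[key], key in {("C", "T"), ("G", "A")}


# criterion name -> (record attribute, threshold attribute, direction)
# direction "lt": fail when value < threshold; "gt": fail when value > threshold
_CRITERIA: tuple[tuple[str, str, str, str], ...] = (
    ("QualByDepth", "qd", "qd_min", "lt"),
    ("QUAL", "qual", "qual_min", "lt"),
    ("StrandOddsRatio", "sor", "sor_max", "gt"),
    ("FisherStrand", "fs", "fs_max", "gt"),
    ("RMSMappingQuality", "mq", "mq_min", "lt"),
    ("MappingQualityRankSum", "mq_rank_sum", "mq_rank_sum_min", "lt"),
    ("ReadPosRankSum", "read_pos_rank_sum", "read_pos_rank_sum_min", "lt"),
)


def apply_hard_filters(
    record: SubstitutionRecord,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterVerdict:
    """Evaluate the hard-filter criteria on one record.

    A record fails iff at least one annotation strictly violates its
    threshold. Missing (None) annotations never trigger their criterion.
    """
    failed: list[str] = []
    for name, attr, thr_attr, direction in _CRITERIA:
        value = getattr(record, attr)
        if value is None:
            continue
        threshold = getattr(thresholds, thr_attr)
        if (direction == "lt" and value < threshold) or (
            direction == "gt" and value > threshold
        ):
            failed.append(name)
    return FilterVerdict(passed=not failed, failed_criteria=tuple(failed))


def compute_vaf(ref_depth: int, alt_depth: int) -> float:
    """Variant allele frequency: alt reads over total reads at the site."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        raise UndefinedVafError("zero total depth")
    return alt_depth / total


def partition_by_vaf(
    records: Iterable[SubstitutionRecord], cutoff: float = 0.8
) -> tuple[list[SubstitutionRecord], list[SubstitutionRecord]]:
    """Split records into (VAF >= cutoff, VAF < cutoff); boundary goes high."""
    high: list[SubstitutionRecord] = []
    low: list[SubstitutionRecord] = []
    for rec in records:
        if rec.vaf is None:
            raise MissingAnnotationError(f"record {rec.chrom}:{rec.pos} lacks VAF")
        (high if rec.vaf >= cutoff else low).append(rec)
    return high, low


def _slice_padded(contig, center: int, upstream: int, downstream: int) -> tuple[str, bool]:
    """N-padded slice of length upstream+1+downstream around 0-based center."""
    contig_len = len(contig)
    start = center - upstream
    end = center + downstream + 1
    left_pad = max(0, -start)
    right_pad = max(0, end - contig_len)
    core = str(contig[max(0, start):min(end, contig_len)]).upper()
    return "N" * left_pad + core + "N" * right_pad, bool(left_pad or right_pad)


def extract_context_window(
    genome: Mapping[str, object],
    chrom: str,
    pos: int,
    upstream: int,
    downstream: int,
    orient_to_c: bool = True,
    drop_padded: bool = False,
) -> ContextWindow | None:
    """Extract a fixed-length window around a 1-based genomic position.

    Windows overhanging contig ends are N-padded to full length (or dropped,
    returning None, when ``drop_padded``). When ``orient_to_c`` is set and the
    central base is G — a G>A call, i.e. C-to-U evidence on the antisense
    strand — the window is taken from the reverse-complement strand so the
    central base is C and the requested upstream/downstream geometry holds in
    the oriented frame.
    """
    if chrom not in genome:
        raise UnknownContigError(f"contig {chrom!r} not in genome")
    contig = genome[chrom]
    center = pos - 1  # 0-based
    if not 0 <= center < len(contig):
        raise UnknownContigError(f"position {pos} outside contig {chrom}")
    central = str(contig[center:center + 1]).upper()
    strand = "+"
    if orient_to_c and central == "G":
        # mirror the slice so that after reverse-complementing the oriented
        # window has `upstream` bases 5' and `downstream` bases 3' of the C
        seq, padded = _slice_padded(contig, center, downstream, upstream)
        seq = revcomp(seq)
        strand = "-"
    else:
        seq, padded = _slice_padded(contig, center, upstream, downstream)
    if padded and drop_padded:
        return None
    return ContextWindow(
        sequence=seq,
        site_offset=upstream,
        upstream_len=upstream,
        downstream_len=downstream,
        origin=(chrom, pos, strand),
    )


def neighbor_frequencies(
    windows: Sequence[ContextWindow],
) -> tuple[BaseCountMatrix, float, float]:
    """Base-count matrix plus the W (A/T) fractions at the 5' and 3' neighbors.

    All windows must have the same geometry and a C central base.
    """
    matrix = BaseCountMatrix.from_windows(windows)
    offsets = {w.site_offset for w in windows}
    if len(offsets) != 1:
        raise InconsistentWindowError("windows have mixed site offsets")
    off = offsets.pop()
    for w in windows:
        if w.central_base != "C":
            raise InconsistentWindowError(
                f"central base {w.central_base!r} is not C"
            )
    w5 = matrix.fraction("AT", off - 1)
    w3 = matrix.fraction("AT", off + 1)
    return matrix, w5, w3


def compare_w_enrichment(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Welch's t-test on per-sample neighbor W fractions."""
    if len(fractions_a) < 2 or len(fractions_b) < 2:
        raise InsufficientReplicatesError(
            "need at least 2 samples per group for Welch's t-test"
        )
    return welch_two_tailed(fractions_a, fractions_b)


def substitution_spectrum(
    records: Iterable[SubstitutionRecord],
) -> pd.DataFrame:
    """Tabulate substitution classes: class, count, fraction (all 12 rows)."""
    counts = {label: 0 for label in _CLASS_LABELS.values()}
    n = 0
    for rec in records:
        counts[rec.substitution_class] += 1
        n += 1
    rows = [
        {"class": label, "count": c, "fraction": (c / n if n else 0.0)}
        for label, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def read_vcf_substitutions(
    path: str,
    sample: str | None = None,
) -> list[SubstitutionRecord]:
    """Read SNV records from a VCF v4.x file (plain or bgzipped).

    Multi-allelic rows are decomposed into one record per alternate allele.
    Non-SNV alleles (indels, symbolic) are skipped. VAF is computed from the
    first sample's AD field when present.
    """
    from cyvcf2 import VCF

    records: list[SubstitutionRecord] = []
    vcf = VCF(path)
    sample_name = sample or (vcf.samples[0] if vcf.samples else None)
    sample_idx = vcf.samples.index(sample_name) if sample_name else None
    for variant in vcf:
        ref = variant.REF.upper()
        if len(ref) != 1 or ref not in BASES:
            continue
        info = variant.INFO
        ad = None
        if sample_idx is not None:
            try:
                ad_arr = variant.format("AD")
                if ad_arr is not None:
                    ad = ad_arr[sample_idx]
            except KeyError:
                ad = None
        for alt_i, alt in enumerate(variant.ALT):
            alt = alt.upper()
            if len(alt) != 1 or alt not in BASES:
                continue
            ref_depth = alt_depth = vaf = None
            if ad is not None and len(ad) > alt_i + 1:
                ref_depth = int(ad[0])
                alt_depth = int(ad[alt_i + 1])
                if ref_depth >= 0 and alt_depth >= 0 and ref_depth + alt_depth > 0:
                    vaf = compute_vaf(ref_depth, alt_depth)
                else:
                    ref_depth = alt_depth = None
            records.append(
                SubstitutionRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref_base=ref,
                    alt_base=alt,
                    qual=variant.QUAL,
                    qd=info.get("QD"),
                    sor=info.get("SOR"),
                    fs=info.get("FS"),
                    mq=info.get("MQ"),
                    mq_rank_sum=info.get("MQRankSum"),
                    read_pos_rank_sum=info.get("ReadPosRankSum"),
                    ref_depth=ref_depth,
                    alt_depth=alt_depth,
                    vaf=vaf,
                    sample=sample_name,
                )
            )
    vcf.close()
    return records


def intersect_positions(
    *record_lists: Sequence[SubstitutionRecord],
) -> list[SubstitutionRecord]:
    """Records from the first list whose (chrom, pos, ref, alt) key occurs
    in every other list. Plumbing for multi-sample consensus call sets.
    """
    if not record_lists:
        return []

    def key(r: SubstitutionRecord):
        return (r.chrom, r.pos, r.ref_base, r.alt_base)

    common = set(map(key, record_lists[0]))
    for other in record_lists[1:]:
        common &= set(map(key, other))
    return [r for r in record_lists[0] if key(r) in common]


def filter_records(
    records: Iterable[SubstitutionRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[SubstitutionRecord], list[SubstitutionRecord]]:
    """Apply hard filters, returning (passing, failing) with verdicts set."""
    passing: list[SubstitutionRecord] = []
    failing: list[SubstitutionRecord] = []
    for rec in records:
        verdict = apply_hard_filters(rec, thresholds)
        rec = replace(rec, filter_status=verdict)
        (passing if verdict.passed else failing).append(rec)
    return passing, failing
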