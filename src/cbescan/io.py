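"""Format readers and writers shared by the CLI subcommands.

FASTA is read through pyfaidx (random access) or Biopython (streaming
windows); VCF is read through cyvcf2 (see ``variant_profile``); transcript
models come from BED12 or GTF CDS features (via gffutils). Tabular outputs
are TSV with one header line preceded by a '#' provenance comment; the
high-risk transcript list is additionally exportable as CSV.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .prs_scan import TranscriptModel
from .variant_profile import ContextWindow

__all__ = [
    "read_genome",
    "write_fasta",
    "faidx",
    "write_vcf",
    "write_bed12",
    "read_bed12",
    "read_gtf_cds",
    "read_transcripts",
    "write_windows_fasta",
    "read_windows_fasta",
    "write_tsv",
    "write_provenance",
]

_VCF_INFO_HEADER = """\
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric Odds Ratio of 2x2 contingency table to detect strand bias">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher's exact test to detect strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Z-score From Wilcoxon rank sum test of Alt vs. Ref read mapping qualities">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles in the order listed">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
"""


def read_genome(path: str | Path):
    """Open a genome FASTA for random access (pyfaidx; builds .fai if absent)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def faidx(path: str | Path) -> None:
    """Build the .fai sidecar index for a FASTA file."""
    from pyfaidx import Fasta

    Fasta(str(path)).close()


def write_vcf(
    rows: Sequence[dict],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    sample_name: str = "sample",
) -> None:
    """Write minimal single-sample VCF v4.2 with the hard-filter INFO keys.

    Each row: chrom, pos (1-based), ref, alt, qual, info (dict of INFO
    key -> float), ad ((ref_depth, alt_depth)).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_name}\n"
        )
        for row in rows:
            info = ";".join(f"{k}={v:g}" for k, v in row["info"].items())
            ref_d, alt_d = row["ad"]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{row['qual']:g}\t.\t{info}\tGT:AD:DP\t"
                f"0/1:{ref_d},{alt_d}:{ref_d + alt_d}\n"
            )


def write_bed12(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript CDS models as BED12 (blocks = CDS intervals)."""
    with open(path, "w") as fh:
        for m in models:
            blocks = sorted(m.cds_intervals)
            start = blocks[0][0]
            end = blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks) + ","
            starts = ",".join(str(s - start) for s, e in blocks) + ","
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.transcript_id}\t0\t{m.strand}\t"
                f"{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read transcript CDS models from BED12 (blocks taken as CDS intervals)."""
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{line_no}: BED12 needs 12 fields")
            chrom, start, _end, name, _score, strand = fields[:6]
            try:
                start = int(start)
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(
                    f"{path}:{line_no}: blockCount disagrees with block lists"
                )
            intervals = [
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            models.append(TranscriptModel(
                transcript_id=name, chrom=chrom, strand=strand,
                cds_intervals=intervals,
            ))
    return models


def read_gtf_cds(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from GTF CDS features (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="merge", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        tids = cds.attributes.get("transcript_id", ["?"])
        for tid in tids:
            entry = per_tx.setdefault(
                tid,
                {"chrom": cds.seqid, "strand": cds.strand, "intervals": [],
                 "gene": (cds.attributes.get("gene_id") or [None])[0]},
            )
            entry["intervals"].append((cds.start - 1, cds.end))
    return [
        TranscriptModel(
            transcript_id=tid, chrom=e["chrom"], strand=e["strand"],
            cds_intervals=e["intervals"], gene_id=e["gene"],
        )
        for tid, e in per_tx.items()
    ]


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Dispatch on extension: .bed -> BED12, .gtf/.gff -> GTF CDS features."""
    suffix = Path(path).suffix.lower()
    if suffix in (".bed", ".bed12"):
        return read_bed12(path)
    if suffix in (".gtf", ".gff"):
        return read_gtf_cds(path)
    raise FormatError(f"unrecognized transcript-model format: {path}")


def write_windows_fasta(windows: Iterable[ContextWindow], path: str | Path) -> None:
    """One record per window; header encodes chrom:pos:strand:label."""
    records = []
    for i, w in enumerate(windows):
        chrom, pos, strand = w.origin if w.origin else ("NA", 0, "NA")
        name = f"{chrom}:{pos}:{strand}:{w.label or 'unset'}"
        records.append(SeqRecord(Seq(w.sequence), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_windows_fasta(
    path: str | Path, upstream: int | None = None
) -> list[ContextWindow]:
    """Read windows written by :func:`write_windows_fasta`.

    ``upstream`` defaults to the symmetric center (len//2), matching the
    20+1+19 and 50+1+50 window geometries used throughout.
    """
    windows: list[ContextWindow] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        up = len(seq) // 2 if upstream is None else upstream
        parts = rec.id.split(":")
        origin = None
        label = None
        if len(parts) == 4:
            chrom, pos, strand, label = parts
            label = None if label == "unset" else label
            try:
                origin = (chrom, int(pos), strand)
            except ValueError:
                origin = None
        windows.append(ContextWindow(
            sequence=seq, site_offset=up, upstream_len=up,
            downstream_len=len(seq) - up - 1, label=label, origin=origin,
        ))
    return windows


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str = "",
              index: bool = False, sep: str = "\t") -> None:
    """TSV with a single '#' provenance comment line above the header."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep=sep, index=index)


def write_provenance(outdir: str | Path, config: Mapping, seed: int | None = None) -> Path:
    """Drop a provenance record (config echo + version + seed) beside outputs."""
    from . import __version__

    record = {
        "tool": "cbescan",
        "version": __version__,
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dict(config).items()},
    }
    path = Path(outdir) / "provenance.json"
    path.write_text(json.dumps(record, indent=1, default=str))
    return path
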