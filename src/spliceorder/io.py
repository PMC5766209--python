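"""Format readers and writers.

Annotation comes in as GTF (via gffutils), BED12, or a UCSC knownGene-style
table; alignments as SAM/BAM (via pysam) or the plain-text synthetic reads
TSV; circles as BED3; intron sequences as FASTA (via Biopython); motifs as
a two-column TSV. All tables written by the package start with '#'
provenance comment lines and use "NA" for missing values, and every writer
round-trips through its reader.

All coordinates are converted to 0-based half-open on read (GTF is 1-based
inclusive on disk; BED and knownGene already match).
"""
from __future__ import annotations

import datetime
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_models import (
    AdjacentIntronPair,
    CategoryLabel,
    CircleRecord,
    GeneModel,
    GenomicInterval,
    Intron,
    build_gene_models,
)
from .order_inference import OrderDistribution, PairOrderCounts, ReadPairRecord

logger = logging.getLogger(__name__)

DIALECTS = ("gtf", "bed12", "knowngene")


class FormatError(ValueError):
    """Malformed input record (message carries the 1-based line number)."""


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def provenance_header(params: dict | None = None) -> list[str]:
    from . import __version__

    lines = [
        f"# spliceorder {__version__}",
        f"# written {datetime.datetime.now().isoformat(timespec='seconds')}",
    ]
    for k, v in sorted((params or {}).items()):
        lines.append(f"# {k}={v}")
    return lines


def write_table(df: pd.DataFrame, path: str, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in provenance_header(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str, dialect: str = "gtf") -> list[GeneModel]:
    if dialect == "gtf":
        raw = _read_gtf(path)
    elif dialect == "bed12":
        raw = _read_bed12(path)
    elif dialect == "knowngene":
        raw = _read_knowngene(path)
    else:
        raise ValueError(
            f"unknown annotation dialect {dialect!r}; supported: {', '.join(DIALECTS)}"
        )
    models = build_gene_models(raw)
    if not models:
        logger.warning("no gene models parsed from %s", path)
    return models


def _read_gtf(path: str):
    """GTF exon lines grouped by transcript_id (ensembl/UCSC attribute
    styles), exons sorted regardless of file order."""
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        rec = grouped.setdefault(
            tid, {"gene": gid, "chrom": feat.seqid, "strand": feat.strand, "spans": []}
        )
        rec["spans"].append((feat.start - 1, feat.end))  # GTF is 1-based inclusive
    return [
        (tid, rec["gene"], rec["chrom"], rec["strand"], rec["spans"])
        for tid, rec in grouped.items()
    ]


def _read_bed12(path: str):
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
            if len(sizes) != len(starts):
                raise FormatError(f"{path}:{ln}: blockSizes/blockStarts length mismatch")
            spans = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            out.append((name, name, chrom, strand, spans))
    return out


def _read_knowngene(path: str):
    """UCSC knownGene-style table: name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{ln}: knownGene needs >= 10 fields")
            try:
                name, chrom, strand = f[0], f[1], f[2]
                starts = [int(x) for x in f[8].rstrip(",").split(",")]
                ends = [int(x) for x in f[9].rstrip(",").split(",")]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
            if len(starts) != len(ends):
                raise FormatError(f"{path}:{ln}: exonStarts/exonEnds length mismatch")
            out.append((name, name, chrom, strand, list(zip(starts, ends))))
    return out


# ---------------------------------------------------------------------------
# circles, intron lists, sequences, motifs
# ---------------------------------------------------------------------------

def read_bed3_circles(path: str) -> list[CircleRecord]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED3 needs 3 fields")
            try:
                out.append(CircleRecord(f[0], int(f[1]), int(f[2])))
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
    return out


def read_bed6_introns(path: str) -> list[Intron]:
    """BED6 intron list; the name field is transcript_id or
    transcript_id.index."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{ln}: BED6 needs 6 fields")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
            tid, _, idx = name.rpartition(".")
            if tid and idx.isdigit():
                transcript, index = tid, int(idx)
            else:
                transcript, index = name, 0
            out.append(
                Intron(GenomicInterval(chrom, start, end, strand), transcript, index)
            )
    return out


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_motifs(path: str):
    """Two-column TSV (motif, rbp_name), optional header."""
    from .feature_analysis import MotifRecord

    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if ln == 1 and f[0].lower() in ("motif", "sequence"):
                continue
            if len(f) < 2:
                raise FormatError(f"{path}:{ln}: motif TSV needs 2 fields")
            out.append(MotifRecord(f[0], f[1]))
    return out


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Reference-aligned blocks, split only at N (intron skip) operations;
    deletions stay inside a block."""
    BAM_CMATCH, BAM_CINS, BAM_CDEL, BAM_CREF_SKIP = 0, 1, 2, 3
    BAM_CEQUAL, BAM_CDIFF = 7, 8
    blocks = []
    start = cur = pos
    for op, length in cigartuples:
        if op in (BAM_CMATCH, BAM_CDEL, BAM_CEQUAL, BAM_CDIFF):
            cur += length
        elif op == BAM_CREF_SKIP:
            if cur > start:
                blocks.append((start, cur))
            cur += length
            start = cur
    if cur > start:
        blocks.append((start, cur))
    return tuple(blocks)


def read_alignments(
    path: str,
    min_mapq: int = 10,
    require_proper: bool = True,
) -> list[ReadPairRecord]:
    """Read SAM/BAM into paired block records.

    Primary alignments only; pairs are joined by read name on the same
    chromosome. Junction gaps come from the alignment's N (skip) segments.
    """
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    pending: dict[str, object] = {}
    out: list[ReadPairRecord] = []
    with pysam.AlignmentFile(path, mode) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if require_proper and not aln.is_proper_pair:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            if mate.reference_name != aln.reference_name:
                continue
            first, second = (mate, aln) if mate.is_read1 else (aln, mate)
            out.append(
                ReadPairRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    mate1_blocks=_blocks_from_cigar(
                        first.reference_start, first.cigartuples
                    ),
                    mate2_blocks=_blocks_from_cigar(
                        second.reference_start, second.cigartuples
                    ),
                )
            )
    if pending:
        logger.info("%d unpaired alignments dropped", len(pending))
    return out


def _fmt_blocks(blocks: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def _parse_blocks(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for span in text.split(","):
        s, _, e = span.partition("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_reads_tsv(records: Iterable[ReadPairRecord], path: str, params: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "chrom": [r.chrom for r in records],
            "mate1_blocks": [_fmt_blocks(r.mate1_blocks) for r in records],
            "mate2_blocks": [_fmt_blocks(r.mate2_blocks) for r in records],
        }
    )
    write_table(df, path, params)


def read_reads_tsv(path: str) -> list[ReadPairRecord]:
    df = read_table(path)
    return [
        ReadPairRecord(
            read_id=str(r.read_id),
            chrom=str(r.chrom),
            mate1_blocks=_parse_blocks(r.mate1_blocks),
            mate2_blocks=_parse_blocks(r.mate2_blocks),
        )
        for r in df.itertuples(index=False)
    ]


def write_sam(
    records: Iterable[ReadPairRecord],
    chrom_lengths: dict[str, int],
    path: str,
) -> None:
    """Plain-text SAM for the synthetic reads (junction gaps become N cigar
    operations) so the alignment-reading path can be exercised."""
    records = list(records)

    def cigar(blocks: Sequence[tuple[int, int]]) -> str:
        parts = []
        for i, (s, e) in enumerate(blocks):
            if i:
                parts.append(f"{s - blocks[i - 1][1]}N")
            parts.append(f"{e - s}M")
        return "".join(parts)

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in records:
            for mate_i, blocks in enumerate((r.mate1_blocks, r.mate2_blocks)):
                other = r.mate2_blocks if mate_i == 0 else r.mate1_blocks
                flag = 0x1 | 0x2 | (0x40 if mate_i == 0 else 0x80)
                seq_len = sum(e - s for s, e in blocks)
                fh.write(
                    "\t".join(
                        [
                            r.read_id,
                            str(flag),
                            r.chrom,
                            str(blocks[0][0] + 1),
                            "60",
                            cigar(blocks),
                            "=",
                            str(other[0][0] + 1),
                            "0",
                            "A" * seq_len,
                            "I" * seq_len,
                        ]
                    )
                    + "\n"
                )


def write_bed12(models: Iterable[GeneModel], path: str) -> None:
    """Gene models as BED12 (exon blocks in genomic order)."""
    with open(path, "w") as fh:
        for m in models:
            spans = sorted((e.start, e.end) for e in m.exons)
            start, end = spans[0][0], spans[-1][1]
            sizes = ",".join(str(e - s) for s, e in spans)
            starts = ",".join(str(s - start) for s, _ in spans)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(start),
                        str(end),
                        m.transcript_id,
                        "0",
                        m.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(spans)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# pairs / counts / histogram tables
# ---------------------------------------------------------------------------

def write_pairs_tsv(
    pairs: Sequence[AdjacentIntronPair], path: str, params: dict | None = None
) -> None:
    rows = []
    for p in pairs:
        rows.append(
            {
                "pair_id": p.pair_id,
                "chrom": p.chrom,
                "strand": p.strand,
                "up_start": p.upstream.interval.start,
                "up_end": p.upstream.interval.end,
                "exon_start": p.internal_exon.start,
                "exon_end": p.internal_exon.end,
                "down_start": p.downstream.interval.start,
                "down_end": p.downstream.interval.end,
                "unique": p.unique,
                "categories": ",".join(sorted(c.value for c in p.categories)) or None,
                "transcripts": ",".join(p.transcript_ids),
                "up_indices": ",".join(str(c[1]) for c in p.contribs),
                "n_introns": ",".join(str(c[2]) for c in p.contribs),
            }
        )
    write_table(pd.DataFrame(rows), path, params)


def read_pairs_tsv(path: str) -> list[AdjacentIntronPair]:
    df = read_table(path)
    out = []
    for r in df.itertuples(index=False):
        tids = str(r.transcripts).split(",") if pd.notna(r.transcripts) else ["?"]
        idxs = [int(x) for x in str(r.up_indices).split(",")]
        nins = [int(x) for x in str(r.n_introns).split(",")]
        up = Intron(
            GenomicInterval(r.chrom, int(r.up_start), int(r.up_end), r.strand),
            tids[0],
            idxs[0],
        )
        down = Intron(
            GenomicInterval(r.chrom, int(r.down_start), int(r.down_end), r.strand),
            tids[0],
            idxs[0] + 1,
        )
        cats = set()
        if pd.notna(r.categories):
            cats = {CategoryLabel(c) for c in str(r.categories).split(",")}
        out.append(
            AdjacentIntronPair(
                pair_id=r.pair_id,
                chrom=r.chrom,
                strand=r.strand,
                upstream=up,
                internal_exon=GenomicInterval(
                    r.chrom, int(r.exon_start), int(r.exon_end), r.strand
                ),
                downstream=down,
                unique=bool(r.unique) if pd.notna(r.unique) else None,
                categories=cats,
                contribs=list(zip(tids, idxs, nins)),
            )
        )
    return out


def write_counts_tsv(
    counts: Sequence[PairOrderCounts], path: str, params: dict | None = None
) -> None:
    df = pd.DataFrame(
        {
            "pair_id": [c.pair_id for c in counts],
            "n_upstream_first": [c.n_upstream_first for c in counts],
            "n_downstream_first": [c.n_downstream_first for c in counts],
            "fraction_downstream_first": [c.fraction_downstream_first for c in counts],
            "passes_depth": [c.passes_depth for c in counts],
        }
    )
    write_table(df, path, params)


def read_counts_tsv(path: str) -> list[PairOrderCounts]:
    df = read_table(path)
    out = []
    for r in df.itertuples(index=False):
        c = PairOrderCounts(
            r.pair_id, int(r.n_upstream_first), int(r.n_downstream_first)
        )
        c.passes_depth = bool(r.passes_depth) if pd.notna(r.passes_depth) else None
        out.append(c)
    return out


def write_histogram_tsv(
    dist: OrderDistribution, path: str, params: dict | None = None
) -> None:
    df = pd.DataFrame(
        {
            "bin_lo": dist.bin_edges[:-1],
            "bin_hi": dist.bin_edges[1:],
            "count": dist.counts,
        }
    )
    write_table(df, path, params)


def read_histogram_tsv(path: str) -> OrderDistribution:
    df = read_table(path)
    edges = np.concatenate([df["bin_lo"].to_numpy(), [df["bin_hi"].iloc[-1]]])
    return OrderDistribution(bin_edges=edges, counts=df["count"].to_numpy())
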