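"""Classify paired-end alignments into order-of-splicing evidence.

A read pair is an *intermediate read* for an adjacent intron pair when one
mate spans the exon-exon junction left by the removal of one intron of the
pair (its alignment gap exactly matches that intron) while the other mate
lies inside the still-retained neighboring intron. Such a pair witnesses a
partially spliced molecule and reveals which intron was removed first.

Per-pair counts give the fraction of intermediate reads supporting
downstream-before-upstream removal; pairs with enough reads are binned into
the genome-wide order distribution and extreme pairs are called
"always-first". An intron observed to splice after both its neighbors is a
*local slowpoke* — a candidate for dependency on neighboring splicing.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .gene_models import AdjacentIntronPair, GenomicInterval, Intron


class Call(str, Enum):
    UPSTREAM_FIRST = "upstream_first"
    DOWNSTREAM_FIRST = "downstream_first"
    UNINFORMATIVE = "uninformative"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class ReadPairRecord:
    """Aligned blocks of the two mates of a paired-end read.

    A mate with >= 2 blocks spans one or more junction gaps.
    """

    read_id: str
    chrom: str
    mate1_blocks: tuple[tuple[int, int], ...]
    mate2_blocks: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class OrderEvidence:
    pair_id: str
    call: Call


@dataclass
class PairOrderCounts:
    pair_id: str
    n_upstream_first: int = 0
    n_downstream_first: int = 0
    passes_depth: bool | None = None

    @property
    def total(self) -> int:
        return self.n_upstream_first + self.n_downstream_first

    @property
    def fraction_downstream_first(self) -> float | None:
        if self.total == 0:
            return None
        return self.n_downstream_first / self.total


@dataclass
class OrderDistribution:
    """Histogram of per-pair downstream-first fractions over [0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class IntronOrderCall:
    intron: Intron
    callable: bool
    after_upstream_neighbor: bool | None = None
    after_downstream_neighbor: bool | None = None

    @property
    def local_slowpoke(self) -> bool:
        return bool(
            self.callable and self.after_upstream_neighbor and self.after_downstream_neighbor
        )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def junction_gaps(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Gaps between consecutive aligned blocks of one mate."""
    return [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]


def _blocks_overlap(blocks: Sequence[tuple[int, int]], iv: GenomicInterval) -> int:
    return sum(max(0, min(e, iv.end) - max(s, iv.start)) for s, e in blocks)


def _gap_matches(
    blocks: Sequence[tuple[int, int]], iv: GenomicInterval, slop: int
) -> bool:
    return any(
        abs(gs - iv.start) <= slop and abs(ge - iv.end) <= slop
        for gs, ge in junction_gaps(blocks)
    )


def classify_read_pair(
    record: ReadPairRecord,
    pair: AdjacentIntronPair,
    min_overlap: int = 1,
    junction_slop: int = 0,
) -> OrderEvidence:
    """Call a single read pair against a single adjacent intron pair.

    upstream_first: one mate's gap equals the upstream intron and the other
    mate overlaps the downstream intron by >= min_overlap nt (the upstream
    intron is gone, the downstream one is still present). downstream_first is
    the mirror case. Mate order never matters. Anything else — including a
    contradictory read matching both directions — is uninformative.
    """
    if record.chrom != pair.chrom:
        return OrderEvidence(pair.pair_id, Call.UNINFORMATIVE)
    up_iv, down_iv = pair.upstream.interval, pair.downstream.interval
    m1, m2 = record.mate1_blocks, record.mate2_blocks

    def _supports(spliced: GenomicInterval, retained: GenomicInterval) -> bool:
        return (
            _gap_matches(m1, spliced, junction_slop)
            and _blocks_overlap(m2, retained) >= min_overlap
        ) or (
            _gap_matches(m2, spliced, junction_slop)
            and _blocks_overlap(m1, retained) >= min_overlap
        )

    up_first = _supports(up_iv, down_iv)
    down_first = _supports(down_iv, up_iv)
    if up_first and not down_first:
        return OrderEvidence(pair.pair_id, Call.UPSTREAM_FIRST)
    if down_first and not up_first:
        return OrderEvidence(pair.pair_id, Call.DOWNSTREAM_FIRST)
    return OrderEvidence(pair.pair_id, Call.UNINFORMATIVE)


def classify_reads(
    records: Iterable[ReadPairRecord],
    pairs: Sequence[AdjacentIntronPair],
    min_overlap: int = 1,
    junction_slop: int = 0,
) -> Iterator[OrderEvidence]:
    """Stream evidence for all pairs, indexing pairs by their intron intervals.

    A read whose junction matches an intron shared by two adjacent pairs is
    evaluated (and may count) once per pair it informs.
    """
    by_intron: dict[tuple, list[AdjacentIntronPair]] = defaultdict(list)
    for p in pairs:
        for iv in (p.upstream.interval, p.downstream.interval):
            by_intron[(p.chrom, iv.start, iv.end)].append(p)

    for rec in records:
        candidates: dict[str, AdjacentIntronPair] = {}
        for blocks in (rec.mate1_blocks, rec.mate2_blocks):
            for gap in junction_gaps(blocks):
                for p in by_intron.get((rec.chrom, gap[0], gap[1]), []):
                    candidates[p.pair_id] = p
        for p in candidates.values():
            ev = classify_read_pair(rec, p, min_overlap=min_overlap, junction_slop=junction_slop)
            if ev.call is not Call.UNINFORMATIVE:
                yield ev


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def accumulate_counts(
    evidence: Iterable[OrderEvidence],
    pairs: Sequence[AdjacentIntronPair] | None = None,
) -> list[PairOrderCounts]:
    """Per-pair totals; uninformative calls are not counted. If ``pairs`` is
    given, zero-count entries are emitted for every pair."""
    ups: Counter = Counter()
    downs: Counter = Counter()
    seen: list[str] = []
    seen_set: set[str] = set()
    for ev in evidence:
        if ev.pair_id not in seen_set:
            seen_set.add(ev.pair_id)
            seen.append(ev.pair_id)
        if ev.call is Call.UPSTREAM_FIRST:
            ups[ev.pair_id] += 1
        elif ev.call is Call.DOWNSTREAM_FIRST:
            downs[ev.pair_id] += 1
    ids = [p.pair_id for p in pairs] if pairs is not None else seen
    return [PairOrderCounts(pid, ups[pid], downs[pid]) for pid in ids]


def apply_depth_filter(
    counts: Iterable[PairOrderCounts], min_reads: int = 10
) -> list[PairOrderCounts]:
    """Retain pairs with >= min_reads intermediate reads; sets passes_depth
    on every input."""
    retained = []
    for c in counts:
        c.passes_depth = c.total >= min_reads
        if c.passes_depth:
            retained.append(c)
    return retained


def bin_distribution(fractions: Iterable[float], n_bins: int = 20) -> OrderDistribution:
    """Equal-width bins over [0, 1]; the last bin is right-closed so a
    fraction of exactly 1.0 is counted."""
    fr = np.asarray(list(fractions), dtype=float)
    if fr.size and (fr.min() < 0 or fr.max() > 1):
        raise ValueError("fractions must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(fr, bins=edges)
    return OrderDistribution(bin_edges=edges, counts=counts)


def call_always_first(
    counts: Iterable[PairOrderCounts], threshold: float = 0.95
) -> dict[str, str | None]:
    """Per pair: 'downstream' if fraction_downstream_first >= threshold,
    'upstream' if <= 1 - threshold, else None."""
    out: dict[str, str | None] = {}
    for c in counts:
        f = c.fraction_downstream_first
        if f is None:
            out[c.pair_id] = None
        elif f >= threshold:
            out[c.pair_id] = "downstream"
        elif f <= 1.0 - threshold:
            out[c.pair_id] = "upstream"
        else:
            out[c.pair_id] = None
    return out


def call_local_slowpokes(
    pairs: Sequence[AdjacentIntronPair],
    counts: Iterable[PairOrderCounts],
    models_by_tid: Mapping[str, "object"],
    threshold: float = 0.95,
    min_reads: int = 10,
) -> list[IntronOrderCall]:
    """Call introns that splice after both neighbors.

    All fractions follow the single transcription-order convention
    (fraction_downstream_first for the pair in transcription order): intron i
    splices after its upstream neighbor when pair (i-1, i) has fraction
    <= 1 - threshold, and after its downstream neighbor when pair (i, i+1)
    has fraction >= threshold. Terminal introns (one neighbor) are reported
    as not callable.
    """
    frac: dict[str, float] = {}
    for c in counts:
        f = c.fraction_downstream_first
        if f is not None and c.total >= min_reads:
            frac[c.pair_id] = f

    # pair_id lookup by (transcript, upstream index)
    pair_at: dict[tuple[str, int], str] = {}
    for p in pairs:
        for tid, idx, _ in p.contribs:
            pair_at[(tid, idx)] = p.pair_id

    out: list[IntronOrderCall] = []
    for model in models_by_tid.values():
        n = model.n_introns
        for intron in model.introns:
            i = intron.index
            if i == 1 or i == n:
                out.append(IntronOrderCall(intron, callable=False))
                continue
            left = pair_at.get((model.transcript_id, i - 1))   # pair (i-1, i)
            right = pair_at.get((model.transcript_id, i))      # pair (i, i+1)
            if left not in frac or right not in frac:
                out.append(IntronOrderCall(intron, callable=False))
                continue
            after_up = frac[left] <= 1.0 - threshold
            after_down = frac[right] >= threshold
            out.append(
                IntronOrderCall(
                    intron,
                    callable=True,
                    after_upstream_neighbor=after_up,
                    after_downstream_neighbor=after_down,
                )
            )
    return out
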