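"""Gene models, intron derivation, and adjacent intron-pair annotation.

A transcript's introns are the gaps between its exons, ordered in the
direction of transcription (descending genomic coordinate on the minus
strand). Two consecutive introns separated by one internal exon form an
*adjacent intron pair* — the unit at which the order of intron removal is
measured. This module derives pairs from annotation, flags pairs whose four
splice sites are unique genome-wide, and attaches structural /
alternative-splicing category labels (positional first/middle/last, exon
skipping, alternative 5'/3' splice sites, circRNA flanks, circle-candidate
prediction).

All coordinates are BED-style: 0-based, half-open.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class CategoryLabel(str, Enum):
    """Category labels attachable to an adjacent intron pair."""

    FIRST = "first"
    MIDDLE = "middle"
    LAST = "last"
    SKIP_BEFORE = "skip_before"
    SKIP_INTERNAL = "skip_internal"
    SKIP_AFTER = "skip_after"
    MULTI_SKIP_FLANK = "multi_skip_flank"
    MULTI_SKIP_MIDDLE = "multi_skip_middle"
    ALT5_FLANK = "alt5_flank"
    ALT3_FLANK = "alt3_flank"
    CIRCLE_BEFORE = "circle_before"
    CIRCLE_AFTER = "circle_after"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


POSITIONAL_LABELS = frozenset(
    {CategoryLabel.FIRST, CategoryLabel.MIDDLE, CategoryLabel.LAST}
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Intron:
    """One intron of one transcript, indexed in transcription order (1-based)."""

    interval: GenomicInterval
    transcript_id: str
    index: int

    @property
    def ss5(self) -> int:
        """Genomic coordinate of the donor (5') splice site."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end

    @property
    def ss3(self) -> int:
        """Genomic coordinate of the acceptor (3') splice site."""
        iv = self.interval
        return iv.end if iv.strand == "+" else iv.start

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class GeneModel:
    """One transcript: exons in transcription order, introns derived."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    introns: list[Intron] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.introns:
            self.introns = _derive_introns(self)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)


def _derive_introns(model: GeneModel) -> list[Intron]:
    """Gaps between consecutive exons, numbered in transcription order."""
    exons = model.exons
    introns: list[Intron] = []
    for i in range(len(exons) - 1):
        a, b = exons[i], exons[i + 1]
        if model.strand == "+":
            start, end = a.end, b.start
        else:
            start, end = b.end, a.start
        introns.append(
            Intron(
                interval=GenomicInterval(model.chrom, start, end, model.strand),
                transcript_id=model.transcript_id,
                index=i + 1,
            )
        )
    return introns


@dataclass
class AdjacentIntronPair:
    """Two consecutive introns of a transcript flanking one internal exon.

    Identical coordinate pairs contributed by several isoforms are merged;
    ``contribs`` records (transcript_id, upstream intron index, transcript
    intron count) for every contributing isoform.
    """

    pair_id: str
    chrom: str
    strand: str
    upstream: Intron
    internal_exon: GenomicInterval
    downstream: Intron
    unique: bool | None = None
    categories: set[CategoryLabel] = field(default_factory=set)
    contribs: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def transcript_ids(self) -> list[str]:
        return [c[0] for c in self.contribs]


@dataclass(frozen=True)
class CircleRecord:
    """Back-splice junction span (same half-open convention as introns)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("circle start must be < end")


@dataclass(frozen=True)
class SkipEvent:
    """An annotated skipping intron and the inclusion-isoform run it shadows."""

    skip_intron: GenomicInterval
    inclusion_transcript: str
    intron_run: tuple[GenomicInterval, ...]
    skipped_exons: tuple[GenomicInterval, ...]


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_gene_models(
    transcripts: Iterable[tuple[str, str, str, str, Sequence[tuple[int, int]]]],
) -> list[GeneModel]:
    """Build GeneModels from raw transcript records.

    Parameters
    ----------
    transcripts
        Iterable of ``(transcript_id, gene_id, chrom, strand, exon_spans)``
        with exon spans as 0-based half-open ``(start, end)`` tuples in any
        order. Transcripts with overlapping exons are skipped with a warning.
    """
    models: list[GeneModel] = []
    for tid, gid, chrom, strand, spans in transcripts:
        if not spans:
            logger.warning("transcript %s has no exons; skipped", tid)
            continue
        spans = sorted(spans)
        if any(spans[i][1] > spans[i + 1][0] for i in range(len(spans) - 1)):
            logger.warning("transcript %s has overlapping exons; skipped", tid)
            continue
        if strand == "-":
            spans = spans[::-1]
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in spans]
        models.append(GeneModel(tid, gid, chrom, strand, exons))
    return models


def make_pair_id(chrom: str, strand: str, up: GenomicInterval, down: GenomicInterval) -> str:
    return f"{chrom}:{up.start}-{up.end}|{down.start}-{down.end}({strand})"


def enumerate_adjacent_pairs(models: Iterable[GeneModel]) -> list[AdjacentIntronPair]:
    """One pair per consecutive intron couple; identical coordinate pairs from
    different isoforms are merged with all contributing transcripts recorded."""
    by_key: dict[tuple, AdjacentIntronPair] = {}
    for model in models:
        for i in range(model.n_introns - 1):
            up, down = model.introns[i], model.introns[i + 1]
            internal = model.exons[i + 1]
            key = (
                model.chrom,
                model.strand,
                up.interval.start,
                up.interval.end,
                down.interval.start,
                down.interval.end,
            )
            pair = by_key.get(key)
            if pair is None:
                pair = AdjacentIntronPair(
                    pair_id=make_pair_id(model.chrom, model.strand, up.interval, down.interval),
                    chrom=model.chrom,
                    strand=model.strand,
                    upstream=up,
                    internal_exon=internal,
                    downstream=down,
                )
                by_key[key] = pair
            pair.contribs.append((model.transcript_id, up.index, model.n_introns))
    return list(by_key.values())


# ---------------------------------------------------------------------------
# uniqueness
# ---------------------------------------------------------------------------

def _site_keys(intron: Intron) -> tuple[tuple, tuple]:
    iv = intron.interval
    return (
        (iv.chrom, iv.strand, "5", intron.ss5),
        (iv.chrom, iv.strand, "3", intron.ss3),
    )


def flag_unique_introns(
    pairs: Iterable[AdjacentIntronPair],
    all_introns: Iterable[Intron],
    scope: str = "transcript",
    transcript_to_gene: Mapping[str, str] | None = None,
) -> list[AdjacentIntronPair]:
    """Set ``unique`` on each pair: true iff all four splice sites of the pair
    occur exactly once among all annotated introns.

    ``scope='transcript'`` (default, strict) counts every transcript's intron
    instance, so an identical intron annotated in two isoforms of the same
    gene is non-unique. ``scope='gene'`` collapses identical introns within a
    gene first (requires ``transcript_to_gene``).
    """
    counts: Counter = Counter()
    if scope == "gene":
        if transcript_to_gene is None:
            raise ValueError("scope='gene' requires transcript_to_gene mapping")
        seen: set[tuple] = set()
        for intron in all_introns:
            iv = intron.interval
            gene = transcript_to_gene[intron.transcript_id]
            dedup = (gene, iv.chrom, iv.strand, iv.start, iv.end)
            if dedup in seen:
                continue
            seen.add(dedup)
            for k in _site_keys(intron):
                counts[k] += 1
    elif scope == "transcript":
        for intron in all_introns:
            for k in _site_keys(intron):
                counts[k] += 1
    else:
        raise ValueError(f"unknown uniqueness scope {scope!r}")

    pairs = list(pairs)
    for pair in pairs:
        keys = _site_keys(pair.upstream) + _site_keys(pair.downstream)
        pair.unique = all(counts[k] == 1 for k in keys)
    return pairs


# ---------------------------------------------------------------------------
# positional categories
# ---------------------------------------------------------------------------

def assign_positional_category(
    pair: AdjacentIntronPair, model: GeneModel
) -> CategoryLabel | None:
    """first / middle / last for one pair within one transcript.

    Transcripts with <= 2 introns are excluded (no label). The pair of intron
    indices (1,2) is 'first', (n-1,n) is 'last', anything else 'middle'.
    """
    n = model.n_introns
    if n <= 2:
        return None
    up_index = None
    for tid, idx, _ in pair.contribs:
        if tid == model.transcript_id:
            up_index = idx
            break
    if up_index is None:
        # fall back to coordinate match
        for intr in model.introns:
            if intr.interval == pair.upstream.interval:
                up_index = intr.index
                break
    if up_index is None:
        raise ValueError(f"pair {pair.pair_id} not found in {model.transcript_id}")
    if up_index == 1:
        return CategoryLabel.FIRST
    if up_index == n - 1:
        return CategoryLabel.LAST
    return CategoryLabel.MIDDLE


def assign_positional_categories(
    pairs: Iterable[AdjacentIntronPair], models: Iterable[GeneModel]
) -> None:
    """Label every pair from its deepest contributing isoform (most introns;
    ties broken by transcript_id) so first/middle/last stay mutually
    exclusive per pair."""
    by_tid = {m.transcript_id: m for m in models}
    for pair in pairs:
        best = None
        for tid, _, n in pair.contribs:
            if tid in by_tid and (best is None or (n, tid) > (best[1], best[0])):
                best = (tid, n)
        if best is None:
            continue
        label = assign_positional_category(pair, by_tid[best[0]])
        if label is not None:
            pair.categories -= POSITIONAL_LABELS
            pair.categories.add(label)


# ---------------------------------------------------------------------------
# exon skipping
# ---------------------------------------------------------------------------

def find_skippable_exons(
    models: Sequence[GeneModel], max_skipped: int = 2
) -> list[SkipEvent]:
    """Find annotated introns whose splice sites exactly shadow a consecutive
    intron run of another (inclusion) isoform.

    An intron I is a skipping intron iff some transcript has consecutive
    introns A..B (spanning 1..max_skipped internal exons) with
    ss5(I) == ss5(A) and ss3(I) == ss3(B).
    """
    # all annotated introns keyed by (chrom, strand, ss5, ss3)
    annotated: set[tuple] = set()
    intron_by_sites: dict[tuple, GenomicInterval] = {}
    for m in models:
        for intr in m.introns:
            iv = intr.interval
            key = (iv.chrom, iv.strand, intr.ss5, intr.ss3)
            annotated.add(key)
            intron_by_sites[key] = iv

    events: list[SkipEvent] = []
    for m in models:
        for i in range(m.n_introns):
            for n_skip in range(1, max_skipped + 1):
                j = i + n_skip
                if j >= m.n_introns:
                    break
                a, b = m.introns[i], m.introns[j]
                key = (m.chrom, m.strand, a.ss5, b.ss3)
                if key not in annotated:
                    continue
                run = tuple(intr.interval for intr in m.introns[i : j + 1])
                skip_iv = intron_by_sites[key]
                if skip_iv in run:
                    continue  # the "skip intron" is one of the run itself
                skipped = tuple(m.exons[i + 1 : j + 1])
                events.append(
                    SkipEvent(
                        skip_intron=skip_iv,
                        inclusion_transcript=m.transcript_id,
                        intron_run=run,
                        skipped_exons=skipped,
                    )
                )
    return events


def apply_skip_labels(
    pairs: Iterable[AdjacentIntronPair],
    models: Sequence[GeneModel],
    events: Iterable[SkipEvent] | None = None,
    max_skipped: int = 2,
) -> list[SkipEvent]:
    """Attach skip_* / multi_skip_* labels to the inclusion isoform's pairs.

    Single-exon events: the pair flanking the skipped exon is skip_internal,
    its transcription-order neighbors skip_before / skip_after. Multi-exon
    events: pairs wholly inside the shadowed intron run are
    multi_skip_middle; pairs joining a run-boundary intron to an outside
    neighbor are multi_skip_flank.
    """
    if events is None:
        events = find_skippable_exons(models, max_skipped=max_skipped)
    by_tid = {m.transcript_id: m for m in models}
    pair_index: dict[tuple, AdjacentIntronPair] = {}
    for p in pairs:
        key = (
            p.chrom,
            p.strand,
            p.upstream.interval.start,
            p.upstream.interval.end,
            p.downstream.interval.start,
            p.downstream.interval.end,
        )
        pair_index[key] = p

    def _lookup(model: GeneModel, i: int, j: int) -> AdjacentIntronPair | None:
        a, b = model.introns[i].interval, model.introns[j].interval
        return pair_index.get((model.chrom, model.strand, a.start, a.end, b.start, b.end))

    for ev in events:
        model = by_tid[ev.inclusion_transcript]
        run_ivs = list(ev.intron_run)
        # locate the run inside the model (transcription-order indices)
        first_idx = next(
            k for k, intr in enumerate(model.introns) if intr.interval == run_ivs[0]
        )
        last_idx = first_idx + len(run_ivs) - 1
        single = len(ev.skipped_exons) == 1
        if single:
            inner = _lookup(model, first_idx, last_idx)
            if inner:
                inner.categories.add(CategoryLabel.SKIP_INTERNAL)
            if first_idx > 0:
                before = _lookup(model, first_idx - 1, first_idx)
                if before:
                    before.categories.add(CategoryLabel.SKIP_BEFORE)
            if last_idx < model.n_introns - 1:
                after = _lookup(model, last_idx, last_idx + 1)
                if after:
                    after.categories.add(CategoryLabel.SKIP_AFTER)
        else:
            for k in range(first_idx, last_idx):
                mid = _lookup(model, k, k + 1)
                if mid:
                    mid.categories.add(CategoryLabel.MULTI_SKIP_MIDDLE)
            if first_idx > 0:
                flank = _lookup(model, first_idx - 1, first_idx)
                if flank:
                    flank.categories.add(CategoryLabel.MULTI_SKIP_FLANK)
            if last_idx < model.n_introns - 1:
                flank = _lookup(model, last_idx, last_idx + 1)
                if flank:
                    flank.categories.add(CategoryLabel.MULTI_SKIP_FLANK)
    return list(events)


# ---------------------------------------------------------------------------
# alternative splice sites
# ---------------------------------------------------------------------------

def collapse_alt_ss(
    all_introns: Iterable[Intron],
) -> tuple[list[list[GenomicInterval]], list[list[GenomicInterval]], dict[str, set[GenomicInterval]]]:
    """Group introns by shared 3'ss (alt-5' groups) and shared 5'ss (alt-3'
    groups); the representative of each group is its shortest intron.

    Returns (alt5_groups, alt3_groups, representatives) where representatives
    maps 'alt5'/'alt3' to the set of representative intron intervals.
    """
    by_ss3: dict[tuple, set[GenomicInterval]] = defaultdict(set)
    by_ss5: dict[tuple, set[GenomicInterval]] = defaultdict(set)
    for intron in all_introns:
        iv = intron.interval
        by_ss3[(iv.chrom, iv.strand, intron.ss3)].add(iv)
        by_ss5[(iv.chrom, iv.strand, intron.ss5)].add(iv)

    alt5_groups = [sorted(g, key=lambda iv: (len(iv), iv.start)) for g in by_ss3.values() if len(g) >= 2]
    alt3_groups = [sorted(g, key=lambda iv: (len(iv), iv.start)) for g in by_ss5.values() if len(g) >= 2]
    reps = {
        "alt5": {g[0] for g in alt5_groups},
        "alt3": {g[0] for g in alt3_groups},
    }
    return alt5_groups, alt3_groups, reps


def apply_alt_ss_labels(
    pairs: Iterable[AdjacentIntronPair],
    representatives: Mapping[str, set[GenomicInterval]],
) -> None:
    """Pairs containing a group-representative intron get alt5_flank /
    alt3_flank labels."""
    for pair in pairs:
        members = (pair.upstream.interval, pair.downstream.interval)
        if any(iv in representatives["alt5"] for iv in members):
            pair.categories.add(CategoryLabel.ALT5_FLANK)
        if any(iv in representatives["alt3"] for iv in members):
            pair.categories.add(CategoryLabel.ALT3_FLANK)


# ---------------------------------------------------------------------------
# circles
# ---------------------------------------------------------------------------

def match_circles(
    circles: Iterable[CircleRecord],
    pairs: Iterable[AdjacentIntronPair],
    slop: int = 0,
) -> tuple[list[AdjacentIntronPair], list[AdjacentIntronPair], int]:
    """Match back-splice spans to pair boundaries.

    A *before* pair has its upstream intron ending exactly where the circle
    begins (in transcription direction); an *after* pair has its downstream
    intron beginning exactly where the circle ends. Matching is exact
    coordinate equality (`slop` nucleotides of tolerance optional). Circles
    matching no pair are counted and dropped.
    """
    pairs = list(pairs)
    before_index: dict[tuple, list[AdjacentIntronPair]] = defaultdict(list)
    after_index: dict[tuple, list[AdjacentIntronPair]] = defaultdict(list)
    for p in pairs:
        up_iv, down_iv = p.upstream.interval, p.downstream.interval
        if p.strand == "+":
            # circle genomic start abuts upstream intron end; genomic end
            # abuts downstream intron start
            before_index[(p.chrom, up_iv.end, "start")].append(p)
            after_index[(p.chrom, down_iv.start, "end")].append(p)
        else:
            # transcription runs right-to-left: circle's transcription-first
            # boundary is its genomic end
            before_index[(p.chrom, up_iv.start, "end")].append(p)
            after_index[(p.chrom, down_iv.end, "start")].append(p)

    before_pairs: list[AdjacentIntronPair] = []
    after_pairs: list[AdjacentIntronPair] = []
    n_unmatched = 0
    for c in circles:
        hit = False
        for d in range(-slop, slop + 1):
            for p in before_index.get((c.chrom, c.start + d, "start"), []):
                before_pairs.append(p)
                p.categories.add(CategoryLabel.CIRCLE_BEFORE)
                hit = True
            for p in before_index.get((c.chrom, c.end + d, "end"), []):
                before_pairs.append(p)
                p.categories.add(CategoryLabel.CIRCLE_BEFORE)
                hit = True
            for p in after_index.get((c.chrom, c.end + d, "end"), []):
                after_pairs.append(p)
                p.categories.add(CategoryLabel.CIRCLE_AFTER)
                hit = True
            for p in after_index.get((c.chrom, c.start + d, "start"), []):
                after_pairs.append(p)
                p.categories.add(CategoryLabel.CIRCLE_AFTER)
                hit = True
        if not hit:
            n_unmatched += 1
    if n_unmatched:
        logger.info("%d circles matched no pair boundary", n_unmatched)
    return before_pairs, after_pairs, n_unmatched


# ---------------------------------------------------------------------------
# circle candidate prediction
# ---------------------------------------------------------------------------

def predict_circle_candidates(
    models: Iterable[GeneModel],
    min_flank_len: int = 10_000,
    exon_whitelist: set[tuple[str, int, int]] | None = None,
) -> list[tuple[str, GenomicInterval]]:
    """Internal exons whose two flanking introns are both >= min_flank_len nt.

    An optional whitelist of (chrom, start, end) exon keys stands in for the
    conserved-start-site criterion. Returns (transcript_id, exon) tuples.
    """
    out: list[tuple[str, GenomicInterval]] = []
    for m in models:
        for i in range(1, len(m.exons) - 1):
            up, down = m.introns[i - 1], m.introns[i]
            if len(up) < min_flank_len or len(down) < min_flank_len:
                continue
            exon = m.exons[i]
            if exon_whitelist is not None and (exon.chrom, exon.start, exon.end) not in exon_whitelist:
                continue
            out.append((m.transcript_id, exon))
    return out


def is_circle_negative(
    model: GeneModel, exon_index: int, max_flank_len: int = 250
) -> bool:
    """Negative-prediction predicate: both flanking introns short (< max_flank_len nt).

    ``exon_index`` is the 0-based transcription-order index of an internal exon.
    """
    if exon_index <= 0 or exon_index >= len(model.exons) - 1:
        raise ValueError("exon has no two flanking introns")
    up, down = model.introns[exon_index - 1], model.introns[exon_index]
    return len(up) < max_flank_len and len(down) < max_flank_len
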