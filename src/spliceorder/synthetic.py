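"""Synthetic co-transcriptional splicing data for end-to-end testing.

Two layers:

* A molecule-level generator: a synthetic gene model is laid out on a
  synthetic chromosome, molecules are transcribed at a fixed elongation rate,
  and each fully transcribed intron (whose dependency parents, if any, have
  been removed) splices after an exponential waiting time. Paired-end
  intermediate reads are then emitted — one mate spanning the exon-exon
  junction of the removed intron, one mate inside the retained neighbor —
  so the classification pipeline can be exercised against known truth.

* A pair-level cohort generator that draws genome-like pair geometry, read
  depths, and per-pair order outcomes directly from the kinetic law, with an
  optional fraction of dependency-forced pairs. This is the fast path for
  cohort-scale experiments (null calibration, excess-detection power).

Read emission is keyed on the per-molecule order event: a molecule that
removed one intron of a pair before the other passed through exactly one
intermediate state, and it is that state that may be captured as a read.
Sampling molecules rather than steady-state intermediate abundance keeps the
read-level downstream-first fraction an unbiased estimate of the order
probability (abundance sampling would weight intermediates by their dwell
times — the steady-state square law — which is not the quantity the order
statistic measures). Snapshot harvesting is still available for inspecting
molecule states.
"""
from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel, GenomicInterval, Intron, enumerate_adjacent_pairs
from .kinetic_model import (
    KineticParams,
    draw_splicing_rate,
    p_upstream_first,
    transcription_delay,
)
from .order_inference import ReadPairRecord

SYNTH_CHROM = "synth1"


@dataclass
class SyntheticLocusSpec:
    """Layout, kinetics, dependencies and read-emission settings of one locus.

    ``dependencies`` holds directed edges (i, j), 1-based intron indices in
    transcription order, meaning intron j cannot splice until intron i has
    been removed. The graph must be acyclic.
    """

    exon_lengths: Sequence[int]
    intron_lengths: Sequence[int]
    true_rates: Sequence[float] | None = None  # introns/min; None -> draw
    dependencies: frozenset[tuple[int, int]] = frozenset()
    n_molecules: int = 1000
    harvest: str = "steady_state"  # or "endpoint"
    endpoint_time: float | None = None  # minutes, for harvest="endpoint"
    read_length: int = 100  # per mate
    capture_rate: float = 1.0
    background_rate: float = 0.0
    txn_rate: float = 3.87  # kb/min
    transcript_id: str = "synthT1"
    gene_id: str = "synthG1"
    offset: int = 0  # genomic offset of the locus on the synthetic chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need |introns| = |exons| - 1")
        self.dependencies = frozenset(tuple(e) for e in self.dependencies)
        n = len(self.intron_lengths)
        for i, j in self.dependencies:
            if not (1 <= i <= n and 1 <= j <= n and i != j):
                raise ValueError(f"bad dependency edge ({i}, {j})")
        # raises CycleError on a cyclic graph
        ts = graphlib.TopologicalSorter(self._parents())
        tuple(ts.static_order())

    def _parents(self) -> dict[int, set[int]]:
        parents: dict[int, set[int]] = {i: set() for i in range(1, len(self.intron_lengths) + 1)}
        for i, j in self.dependencies:
            parents[j].add(i)
        return parents

    @property
    def n_introns(self) -> int:
        return len(self.intron_lengths)


@dataclass
class MoleculeState:
    """Snapshot of one molecule at harvest time."""

    molecule_id: int
    birth_time: float
    spliced: tuple[bool, ...]
    transcribed_up_to: int


@dataclass
class SimulatedMolecules:
    """Per-molecule intron completion times (absolute minutes since birth)."""

    model: GeneModel
    spec: SyntheticLocusSpec
    rates: np.ndarray  # per intron, introns/min
    completion: np.ndarray  # (n_molecules, n_introns)
    birth_times: np.ndarray  # (n_molecules,)
    harvest_time: float


def resolve_rates(
    spec: SyntheticLocusSpec, params: KineticParams, rng: np.random.Generator
) -> np.ndarray:
    if spec.true_rates is not None:
        rates = np.asarray(spec.true_rates, dtype=float)
        if rates.shape != (spec.n_introns,) or (rates <= 0).any():
            raise ValueError("true_rates must be positive, one per intron")
        return rates
    return np.atleast_1d(draw_splicing_rate(params, rng, size=spec.n_introns))


def generate_locus(spec: SyntheticLocusSpec) -> GeneModel:
    """Deterministic gene model on the synthetic chromosome: exons and
    introns laid out end to end from ``spec.offset``, plus strand."""
    pos = spec.offset
    exons: list[GenomicInterval] = []
    for i, elen in enumerate(spec.exon_lengths):
        exons.append(GenomicInterval(SYNTH_CHROM, pos, pos + elen, "+"))
        pos += elen
        if i < spec.n_introns:
            pos += spec.intron_lengths[i]
    return GeneModel(spec.transcript_id, spec.gene_id, SYNTH_CHROM, "+", exons)


def simulate_molecules(
    model: GeneModel,
    spec: SyntheticLocusSpec,
    rng: np.random.Generator,
    params: KineticParams | None = None,
    rates: np.ndarray | None = None,
) -> SimulatedMolecules:
    """Event-driven co-transcriptional splicing of n_molecules transcripts.

    The polymerase advances at spec.txn_rate; intron i becomes eligible when
    fully transcribed and all its dependency parents are removed, then
    completes after an Exp(rate_i) waiting time. Because eligibility is a
    max over parent completion times and the waiting times are memoryless,
    completion times can be computed intron-by-intron in topological order.
    """
    if rates is None:
        rates = resolve_rates(spec, params or KineticParams(), rng)
    n_mol, n_int = spec.n_molecules, spec.n_introns
    txn_nt_per_min = spec.txn_rate * 1000.0

    # time (since molecule birth) at which each intron is fully transcribed
    t_txn = np.empty(n_int)
    pos = 0
    for i in range(n_int):
        pos += spec.exon_lengths[i] + spec.intron_lengths[i]
        t_txn[i] = pos / txn_nt_per_min
    total_len = pos + spec.exon_lengths[-1]
    total_txn_time = total_len / txn_nt_per_min

    parents = spec._parents()
    order = list(graphlib.TopologicalSorter(parents).static_order())
    completion = np.empty((n_mol, n_int))
    for idx in order:  # 1-based intron index
        ready = np.full(n_mol, t_txn[idx - 1])
        for p in parents[idx]:
            ready = np.maximum(ready, completion[:, p - 1])
        completion[:, idx - 1] = ready + rng.exponential(1.0 / rates[idx - 1], size=n_mol)

    # harvest window: continuous initiation over >= 10x the slowest expected
    # completion for steady state, or a fixed endpoint for debugging
    expected_slowest = total_txn_time + np.sum(1.0 / rates)
    if spec.harvest == "steady_state":
        window = 10.0 * expected_slowest
        births = rng.uniform(0.0, window, size=n_mol)
        harvest_time = window
    elif spec.harvest == "endpoint":
        harvest_time = (
            spec.endpoint_time if spec.endpoint_time is not None else expected_slowest
        )
        births = np.zeros(n_mol)
    else:
        raise ValueError(f"unknown harvest mode {spec.harvest!r}")

    return SimulatedMolecules(
        model=model,
        spec=spec,
        rates=np.asarray(rates, dtype=float),
        completion=completion,
        birth_times=births,
        harvest_time=harvest_time,
    )


def harvest_states(sim: SimulatedMolecules) -> list[MoleculeState]:
    """Molecule snapshots at the harvest time (dependency- and
    transcription-consistent by construction)."""
    spec = sim.spec
    txn_nt_per_min = spec.txn_rate * 1000.0
    total_len = sum(spec.exon_lengths) + sum(spec.intron_lengths)
    out = []
    for m in range(spec.n_molecules):
        age = sim.harvest_time - sim.birth_times[m]
        transcribed = int(min(total_len, max(0.0, age * txn_nt_per_min)))
        spliced = tuple(bool(sim.completion[m, i] <= age) for i in range(spec.n_introns))
        out.append(MoleculeState(m, float(sim.birth_times[m]), spliced, transcribed))
    return out


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def _junction_blocks(
    model: GeneModel, intron_idx: int, read_length: int
) -> tuple[tuple[int, int], ...]:
    """Two aligned blocks flanking the removed intron, split exactly at its
    boundaries, up to read_length/2 in each flanking exon."""
    left_exon = model.exons[intron_idx]
    right_exon = model.exons[intron_idx + 1]
    half = max(1, read_length // 2)
    l_len = min(half, len(left_exon))
    r_len = min(read_length - l_len, len(right_exon))
    return (
        (left_exon.end - l_len, left_exon.end),
        (right_exon.start, right_exon.start + r_len),
    )


def _intronic_mate(
    intron: GenomicInterval, read_length: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    if len(intron) <= read_length:
        return ((intron.start, intron.end),)  # truncated to the intron
    start = int(rng.integers(intron.start, intron.end - read_length + 1))
    return ((start, start + read_length),)


def emit_read_pairs(
    sim: SimulatedMolecules, rng: np.random.Generator
) -> list[ReadPairRecord]:
    """Emit intermediate read pairs from molecule order events.

    For every adjacent pair and every molecule, the intron removed first
    defines the intermediate the molecule passed through; with probability
    capture_rate a read pair is emitted: a junction mate split at the removed
    intron's boundaries plus a mate placed uniformly in the retained intron.
    Uninformative exonic background pairs are added at background_rate per
    molecule when requested.
    """
    model, spec = sim.model, sim.spec
    records: list[ReadPairRecord] = []
    for pair_i in range(spec.n_introns - 1):
        up_done = sim.completion[:, pair_i]
        down_done = sim.completion[:, pair_i + 1]
        captured = rng.random(spec.n_molecules) < spec.capture_rate
        for m in np.nonzero(captured)[0]:
            if up_done[m] < down_done[m]:
                spliced_idx, retained = pair_i, model.introns[pair_i + 1].interval
            else:
                spliced_idx, retained = pair_i + 1, model.introns[pair_i].interval
            jm = _junction_blocks(model, spliced_idx, spec.read_length)
            im = _intronic_mate(retained, spec.read_length, rng)
            mates = (jm, im) if rng.random() < 0.5 else (im, jm)
            records.append(
                ReadPairRecord(
                    read_id=f"{spec.transcript_id}:p{pair_i + 1}:m{m}",
                    chrom=model.chrom,
                    mate1_blocks=mates[0],
                    mate2_blocks=mates[1],
                )
            )
    if spec.background_rate > 0:
        n_bg = rng.binomial(spec.n_molecules, min(1.0, spec.background_rate))
        for b in range(n_bg):
            exon = model.exons[int(rng.integers(len(model.exons)))]
            half = max(1, min(spec.read_length, len(exon)))
            s = int(rng.integers(exon.start, exon.end - half + 1))
            block = ((s, s + half),)
            records.append(
                ReadPairRecord(
                    read_id=f"{spec.transcript_id}:bg{b}",
                    chrom=model.chrom,
                    mate1_blocks=block,
                    mate2_blocks=block,
                )
            )
    return records


def truth_report(
    spec: SyntheticLocusSpec, rates: np.ndarray | None = None
) -> pd.DataFrame:
    """Analytic expected downstream-first fraction per adjacent pair.

    A direct dependency between the pair's introns forces the fraction to 0
    (upstream must go first) or 1. Pairs whose introns carry any other
    dependency are flagged ``dependent`` with no closed form. Otherwise the
    closed-form kinetic probability applies.
    """
    if rates is None:
        if spec.true_rates is None:
            raise ValueError("need resolved rates (spec.true_rates or rates argument)")
        rates = np.asarray(spec.true_rates, dtype=float)
    rows = []
    for i in range(spec.n_introns - 1):
        up, down = i + 1, i + 2
        forced = None
        if (up, down) in spec.dependencies:
            forced = 0.0
        elif (down, up) in spec.dependencies:
            forced = 1.0
        other_deps = any(
            (pi in (up, down) or j in (up, down))
            and (pi, j) not in ((up, down), (down, up))
            for pi, j in spec.dependencies
        )
        if forced is not None:
            expected = forced
            dependent = True
        elif other_deps:
            expected = np.nan
            dependent = True
        else:
            delay = transcription_delay(
                spec.exon_lengths[i + 1], spec.intron_lengths[i + 1], spec.txn_rate
            )
            expected = 1.0 - p_upstream_first(rates[i], rates[i + 1], delay)
            dependent = False
        rows.append(
            {
                "pair_index": i + 1,
                "upstream_intron": up,
                "downstream_intron": down,
                "expected_fraction_downstream_first": expected,
                "dependent": dependent,
            }
        )
    return pd.DataFrame(rows)


def parse_locus_spec(path: str) -> SyntheticLocusSpec:
    """Parse a key=value locus spec file.

    Recognized keys: exon_lengths, intron_lengths (comma-separated nt),
    rates (comma-separated introns/min, optional), dependencies
    (comma-separated ``i>j`` edges), n_molecules, seed, read_length,
    capture_rate, background_rate, txn_rate, harvest, endpoint_time,
    transcript_id, gene_id, offset.
    """
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()

    def ints(key: str) -> list[int]:
        return [int(x) for x in kv[key].split(",") if x]

    kwargs: dict = {
        "exon_lengths": ints("exon_lengths"),
        "intron_lengths": ints("intron_lengths"),
    }
    if kv.get("rates"):
        kwargs["true_rates"] = [float(x) for x in kv["rates"].split(",") if x]
    if kv.get("dependencies"):
        edges = set()
        for edge in kv["dependencies"].split(","):
            i, _, j = edge.partition(">")
            edges.add((int(i), int(j)))
        kwargs["dependencies"] = frozenset(edges)
    for key, conv in (
        ("n_molecules", int),
        ("seed", int),
        ("read_length", int),
        ("offset", int),
        ("capture_rate", float),
        ("background_rate", float),
        ("txn_rate", float),
        ("endpoint_time", float),
        ("harvest", str),
        ("transcript_id", str),
        ("gene_id", str),
    ):
        if key in kv:
            kwargs[key] = conv(kv[key])
    return SyntheticLocusSpec(**kwargs)


# ---------------------------------------------------------------------------
# pair-level cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(
    n_pairs: int,
    params: KineticParams,
    rng: np.random.Generator,
    dep_fraction: float = 0.0,
    min_reads: int = 10,
    mean_extra_depth: float = 15.0,
    exon_len_median: float = 140.0,
    exon_len_sigma: float = 0.55,
    intron_len_median: float = 1500.0,
    intron_len_sigma: float = 1.1,
) -> pd.DataFrame:
    """Genome-like cohort of adjacent intron pairs with observed fractions.

    Geometry is lognormal (hg19-like medians: internal exons ~140 nt, introns
    ~1.5 kb with a long tail); read depth is min_reads plus a geometric tail
    (mean mean_extra_depth), emulating the retained >= min_reads population.
    A ``dep_fraction`` of pairs is dependency-forced: their order is
    deterministic (direction 50/50), the synthetic analogue of introns that
    require a neighboring splicing event. All other pairs follow the kinetic
    law exactly.

    Returns a DataFrame with pair geometry, depth, truth
    (``p_downstream_first``, ``forced``) and the observed
    ``fraction_downstream_first``.
    """
    exon_len = np.round(
        rng.lognormal(np.log(exon_len_median), exon_len_sigma, size=n_pairs)
    ).astype(int).clip(min=30)
    up_len = np.round(
        rng.lognormal(np.log(intron_len_median), intron_len_sigma, size=n_pairs)
    ).astype(int).clip(min=70)
    down_len = np.round(
        rng.lognormal(np.log(intron_len_median), intron_len_sigma, size=n_pairs)
    ).astype(int).clip(min=70)
    n_reads = min_reads + rng.geometric(1.0 / (1.0 + mean_extra_depth), size=n_pairs) - 1

    k_up = draw_splicing_rate(params, rng, size=n_pairs)
    k_down = draw_splicing_rate(params, rng, size=n_pairs)
    delay = transcription_delay(exon_len, down_len, params.txn_rate)
    p_down = 1.0 - p_upstream_first(k_up, k_down, delay)

    forced = np.zeros(n_pairs, dtype=int)  # 0 free, +1 forced downstream-first, -1 upstream
    if dep_fraction > 0:
        n_forced = int(round(dep_fraction * n_pairs))
        idx = rng.choice(n_pairs, size=n_forced, replace=False)
        direction = rng.random(n_forced) < 0.5
        forced[idx[direction]] = 1
        forced[idx[~direction]] = -1
        p_down = np.where(forced == 1, 1.0, np.where(forced == -1, 0.0, p_down))

    frac = rng.binomial(n_reads, p_down) / n_reads
    return pd.DataFrame(
        {
            "pair_id": [f"synth_pair_{i}" for i in range(n_pairs)],
            "exon_len": exon_len,
            "up_intron_len": up_len,
            "down_intron_len": down_len,
            "n_reads": n_reads,
            "k_up": k_up,
            "k_down": k_down,
            "p_downstream_first": p_down,
            "forced": forced,
            "fraction_downstream_first": frac,
        }
    )
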