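"""End-to-end pipeline: pairs -> classification -> counts -> filter ->
histogram -> kinetic null -> excess test -> category reports."""
from __future__ import annotations

import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from . import gene_models as gm
from . import io as sio
from . import order_inference as oi
from .feature_analysis import category_histograms, length_difference_analysis
from .kinetic_model import KineticParams, excess_test, simulate_null_distribution

logger = logging.getLogger(__name__)


def pair_geometry_table(
    pairs: Sequence[gm.AdjacentIntronPair],
    counts: Sequence[oi.PairOrderCounts],
    unique_only: bool = True,
) -> pd.DataFrame:
    """Geometry + depth table for the null simulator: one row per retained
    pair with internal-exon and downstream-intron lengths and observed
    read depth."""
    by_id = {p.pair_id: p for p in pairs}
    rows = []
    for c in counts:
        p = by_id.get(c.pair_id)
        if p is None or c.total == 0:
            continue
        if unique_only and not p.unique:
            continue
        rows.append(
            {
                "pair_id": c.pair_id,
                "exon_len": len(p.internal_exon),
                "up_intron_len": len(p.upstream.interval),
                "down_intron_len": len(p.downstream.interval),
                "n_reads": c.total,
                "fraction_downstream_first": c.fraction_downstream_first,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    models: Sequence[gm.GeneModel],
    records: Sequence[oi.ReadPairRecord],
    out_dir: str,
    circles: Sequence[gm.CircleRecord] | None = None,
    min_reads: int = 10,
    n_bins: int = 20,
    threshold: float = 0.95,
    params: KineticParams | None = None,
    seed: int = 0,
    n_null_reps: int = 100,
    unique_only_null: bool = True,
) -> dict:
    """Run every stage and write one TSV per stage into ``out_dir``.

    Deterministic for a given seed. Returns the in-memory results
    (pairs, counts, histograms, excess-test result, calls).
    """
    params = params or KineticParams()
    os.makedirs(out_dir, exist_ok=True)
    prov = {
        "min_reads": min_reads,
        "n_bins": n_bins,
        "threshold": threshold,
        "rate_mean": params.rate_mean,
        "rate_sd": params.rate_sd,
        "txn_rate": params.txn_rate,
        "seed": seed,
    }

    # annotation-level structure and categories
    pairs = gm.enumerate_adjacent_pairs(models)
    all_introns = [i for m in models for i in m.introns]
    gm.flag_unique_introns(pairs, all_introns)
    gm.assign_positional_categories(pairs, models)
    gm.apply_skip_labels(pairs, list(models))
    _, _, reps = gm.collapse_alt_ss(all_introns)
    gm.apply_alt_ss_labels(pairs, reps)
    if circles:
        gm.match_circles(circles, pairs)
    sio.write_pairs_tsv(pairs, os.path.join(out_dir, "pairs.tsv"), prov)

    # read classification and counting
    evidence = oi.classify_reads(records, pairs)
    counts = oi.accumulate_counts(evidence, pairs)
    retained = oi.apply_depth_filter(counts, min_reads=min_reads)
    sio.write_counts_tsv(counts, os.path.join(out_dir, "counts.tsv"), prov)

    fractions = [c.fraction_downstream_first for c in retained]
    observed = oi.bin_distribution(fractions, n_bins=n_bins)
    sio.write_histogram_tsv(observed, os.path.join(out_dir, "hist_observed.tsv"), prov)

    # kinetic null and excess test
    geom = pair_geometry_table(pairs, retained, unique_only=unique_only_null)
    result = None
    null = None
    if len(geom) >= 2:
        null = simulate_null_distribution(
            geom, params, n_bins=n_bins, seed=seed, n_reps=n_null_reps
        )
        sio.write_histogram_tsv(null, os.path.join(out_dir, "hist_null.tsv"), prov)
        obs_unique = oi.bin_distribution(
            geom["fraction_downstream_first"], n_bins=n_bins
        )
        try:
            result = excess_test(obs_unique, null)
        except ValueError as e:
            logger.warning("excess test skipped: %s", e)
            result = None
    if result is not None:
        sio.write_table(
            pd.DataFrame(
                [
                    {
                        "chi_square": result.chi_square,
                        "df": result.df,
                        "p_value": result.p_value,
                        "first_bin_excess": result.first_bin_excess,
                        "last_bin_excess": result.last_bin_excess,
                    }
                ]
            ),
            os.path.join(out_dir, "excess_test.tsv"),
            prov,
        )
    if null is None:
        logger.warning("too few unique retained pairs for the null simulation")

    # calls
    af_calls = oi.call_always_first(retained, threshold=threshold)
    calls_df = pd.DataFrame(
        {"pair_id": list(af_calls), "always_first": [af_calls[k] for k in af_calls]}
    )
    sio.write_table(calls_df, os.path.join(out_dir, "calls.tsv"), prov)

    models_by_tid = {m.transcript_id: m for m in models}
    slowpokes = oi.call_local_slowpokes(
        pairs, counts, models_by_tid, threshold=threshold, min_reads=min_reads
    )
    sp_df = pd.DataFrame(
        {
            "transcript_id": [s.intron.transcript_id for s in slowpokes],
            "intron_index": [s.intron.index for s in slowpokes],
            "callable": [s.callable for s in slowpokes],
            "after_upstream_neighbor": [s.after_upstream_neighbor for s in slowpokes],
            "after_downstream_neighbor": [s.after_downstream_neighbor for s in slowpokes],
            "local_slowpoke": [s.local_slowpoke for s in slowpokes],
        }
    )
    sio.write_table(sp_df, os.path.join(out_dir, "slowpokes.tsv"), prov)

    # category histograms and length analysis
    cat_hists = category_histograms(retained, pairs, n_bins=n_bins)
    for label, dist in cat_hists.items():
        if dist.total > 0:
            sio.write_histogram_tsv(
                dist, os.path.join(out_dir, f"hist_category_{label}.tsv"), prov
            )
    if len(geom):
        length_df = length_difference_analysis(geom, always_threshold=threshold)
        sio.write_table(length_df, os.path.join(out_dir, "length_analysis.tsv"), prov)

    return {
        "pairs": pairs,
        "counts": counts,
        "retained": retained,
        "observed": observed,
        "null": null,
        "excess": result,
        "always_first": af_calls,
        "slowpokes": slowpokes,
        "category_histograms": cat_hists,
    }
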