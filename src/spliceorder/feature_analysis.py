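"""Sequence- and category-level correlates of splicing order.

Covers the intron length-difference analysis (does the longer intron of a
pair tend to splice second?), RNA-binding-protein motif density enrichment
between always-first and always-last introns, and per-category order
histograms (skipping, alternative splice sites, first/middle/last, circle
flanks) against the all-pairs background.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_models import AdjacentIntronPair, CategoryLabel
from .order_inference import OrderDistribution, PairOrderCounts, bin_distribution


@dataclass(frozen=True)
class MotifRecord:
    """One RBP binding motif (ACGT alphabet; U accepted and mapped to T)."""

    motif: str
    rbp_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", self.motif.upper().replace("U", "T"))
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        if not set(self.motif) <= set("ACGT"):
            raise ValueError(f"motif {self.motif!r} has non-ACGT(U) characters")


# ---------------------------------------------------------------------------
# length analysis
# ---------------------------------------------------------------------------

def length_difference_analysis(
    pair_table: pd.DataFrame,
    bin_width: int = 500,
    lo: int = -10_000,
    hi: int = 10_000,
    always_threshold: float = 0.95,
) -> pd.DataFrame:
    """Fraction of downstream-always-first pairs per intron length-difference bin.

    The difference is upstream length minus downstream length, so negative
    means a longer downstream intron. Outer bins are open-ended. Expects
    columns ``up_intron_len``, ``down_intron_len``,
    ``fraction_downstream_first`` (depth-filtered pairs only).

    Returns one row per bin: diff_lo, diff_hi (inf at the edges), n_pairs,
    frac_downstream_always_first (NaN when the bin is empty).
    """
    diff = (
        pair_table["up_intron_len"].to_numpy()
        - pair_table["down_intron_len"].to_numpy()
    )
    frac = pair_table["fraction_downstream_first"].to_numpy(dtype=float)
    inner = np.arange(lo, hi + bin_width, bin_width)
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    idx = np.digitize(diff, edges) - 1  # 0 .. len(edges)-2
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        hit = float(np.mean(frac[mask] >= always_threshold)) if n else np.nan
        rows.append(
            {
                "diff_lo": edges[b],
                "diff_hi": edges[b + 1],
                "n_pairs": n,
                "frac_downstream_always_first": hit,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motif density
# ---------------------------------------------------------------------------

def motif_density(sequence: str, motif: str | MotifRecord, overlapping: bool = False) -> float:
    """Exact-match motif density: matches per nt of sequence.

    Non-overlapping counting by default; ``overlapping=True`` counts every
    start position (regex lookahead). A sequence shorter than the motif has
    density 0.
    """
    pat = motif.motif if isinstance(motif, MotifRecord) else motif.upper().replace("U", "T")
    seq = sequence.upper().replace("U", "T")
    if len(seq) < len(pat) or not seq:
        return 0.0
    if overlapping:
        n = len(re.findall(f"(?={re.escape(pat)})", seq))
    else:
        n = seq.count(pat)
    return n / len(seq)


def motif_enrichment(
    first_sequences: Mapping[str, str],
    last_sequences: Mapping[str, str],
    motifs: Iterable[MotifRecord],
    overlapping: bool = False,
    fdr: float = 0.05,
    min_group: int = 5,
) -> pd.DataFrame:
    """Per-motif density comparison between always-first and always-last introns.

    Mann-Whitney rank-sum on per-intron densities, Benjamini-Hochberg
    correction across the motif panel. The effect sign reports whether the
    motif is denser in first- or last-splicing introns. Groups smaller than
    ``min_group`` are flagged low-power.

    Returns a DataFrame with motif, rbp_name, mean densities, the U
    statistic, raw and BH-adjusted p-values, enrichment direction and a
    significance flag at the requested FDR.
    """
    motifs = list(motifs)
    if not first_sequences or not last_sequences:
        raise ValueError("both intron groups must be non-empty")
    low_power = len(first_sequences) < min_group or len(last_sequences) < min_group

    rows = []
    for m in motifs:
        d_first = np.array(
            [motif_density(s, m, overlapping) for s in first_sequences.values()]
        )
        d_last = np.array(
            [motif_density(s, m, overlapping) for s in last_sequences.values()]
        )
        if np.all(d_first == d_first[0]) and np.all(d_last == d_first[0]):
            stat, p = np.nan, 1.0  # constant densities carry no rank information
        else:
            stat, p = stats.mannwhitneyu(d_first, d_last, alternative="two-sided")
        rows.append(
            {
                "motif": m.motif,
                "rbp_name": m.rbp_name,
                "density_first": float(d_first.mean()),
                "density_last": float(d_last.mean()),
                "statistic": float(stat) if stat == stat else np.nan,
                "p_value": float(p),
                "enriched_in": "first"
                if d_first.mean() > d_last.mean()
                else ("last" if d_last.mean() > d_first.mean() else "none"),
                "low_power": low_power,
            }
        )
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out


# ---------------------------------------------------------------------------
# category histograms
# ---------------------------------------------------------------------------

def category_histograms(
    counts: Sequence[PairOrderCounts],
    pairs: Sequence[AdjacentIntronPair],
    n_bins: int = 20,
) -> dict[str, OrderDistribution]:
    """One order histogram per category label plus the all-pairs background.

    A pair carrying several labels contributes to every matching histogram.
    Labels with no pairs yield empty histograms (logged).
    """
    import logging

    frac_by_id = {
        c.pair_id: c.fraction_downstream_first
        for c in counts
        if c.fraction_downstream_first is not None
    }
    by_label: dict[str, list[float]] = {label.value: [] for label in CategoryLabel}
    background: list[float] = []
    for p in pairs:
        f = frac_by_id.get(p.pair_id)
        if f is None:
            continue
        background.append(f)
        for label in p.categories:
            by_label[CategoryLabel(label).value].append(f)

    out = {"all": bin_distribution(background, n_bins)}
    for label, fr in by_label.items():
        if not fr:
            logging.getLogger(__name__).warning("category %s has no pairs", label)
        out[label] = bin_distribution(fr, n_bins)
    return out
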