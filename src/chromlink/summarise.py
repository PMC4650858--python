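"""Dataset-level summaries, per-feature interaction summaries and
virtual-4C viewpoint profiles.

The per-feature summary follows an anchor-wise accumulation rule: the
total for a feature sums pair counts once per anchor overlapping the
feature, so a pair whose BOTH anchors hit the same feature contributes
twice. This matches summing the PET counts of all anchors overlapping a
feature's region and is stated prominently because the per-pair
alternative gives different totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import DISTAL, _class_rank, _require_annotated, pair_label
from .model import (
    FeatureSet,
    GenomicRange,
    InteractionSet,
    ValidationError,
    calculate_distances,
    is_cis,
)


@dataclass
class DatasetSummary:
    """Whole-dataset statistics behind the four summary panels."""

    n_interactions: int
    n_cis: int
    n_trans: int
    pct_cis: float
    pct_trans: float
    type_counts: Optional[Dict[str, int]]
    distance_quantiles: Dict[str, float]
    count_histogram: Dict[int, int]


def summarize_dataset(iset: InteractionSet) -> DatasetSummary:
    """Counts, cis/trans proportions, interaction-type counts (when
    annotated), cis-distance quantiles (midpoint convention) and the
    supporting-count histogram."""
    n = len(iset)
    cis = is_cis(iset)
    n_cis = sum(cis)
    n_trans = n - n_cis
    pct_cis = 100.0 * n_cis / n if n else 0.0
    pct_trans = 100.0 * n_trans / n if n else 0.0
    type_counts: Optional[Dict[str, int]] = None
    if iset.annotations is not None:
        from .annotate import interaction_types

        type_counts = {}
        for label in interaction_types(iset):
            type_counts[label] = type_counts.get(label, 0) + 1
    dists = [
        d for d in calculate_distances(iset, "midpoint") if d is not None
    ]
    quantiles: Dict[str, float] = {}
    if dists:
        arr = np.asarray(dists, dtype=float)
        quantiles = {
            "min": float(arr.min()),
            "q25": float(np.percentile(arr, 25)),
            "median": float(np.percentile(arr, 50)),
            "q75": float(np.percentile(arr, 75)),
            "max": float(arr.max()),
        }
    histogram: Dict[int, int] = {}
    for c in iset.counts:
        histogram[c] = histogram.get(c, 0) + 1
    return DatasetSummary(
        n_interactions=n,
        n_cis=n_cis,
        n_trans=n_trans,
        pct_cis=pct_cis,
        pct_trans=pct_trans,
        type_counts=type_counts,
        distance_quantiles=quantiles,
        count_histogram=histogram,
    )


def write_dataset_summary(summary: DatasetSummary, path) -> None:
    """Flat key/value TSV of a DatasetSummary."""
    rows = [
        ("n_interactions", summary.n_interactions),
        ("n_cis", summary.n_cis),
        ("n_trans", summary.n_trans),
        ("pct_cis", summary.pct_cis),
        ("pct_trans", summary.pct_trans),
    ]
    for k, v in sorted(summary.distance_quantiles.items()):
        rows.append((f"distance_{k}", v))
    if summary.type_counts is not None:
        for k, v in sorted(summary.type_counts.items()):
            rows.append((f"type_{k}", v))
    for k in sorted(summary.count_histogram):
        rows.append((f"count_{k}", summary.count_histogram[k]))
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")


@dataclass
class FeatureSummary:
    """Interaction totals and partner counts for one feature.

    ``n_interactions_total`` is the anchor-wise sum of supporting counts;
    ``type_totals`` splits it by canonical interaction-type label;
    ``partner_counts`` gives, per node class, the number of distinct
    partner feature ids (partners classed by their own node class; the
    feature itself is not its own partner).
    """

    feature_id: str
    n_interactions_total: int = 0
    type_totals: Dict[str, int] = field(default_factory=dict)
    partner_counts: Dict[str, int] = field(default_factory=dict)


def summarize_by_features(
    iset: InteractionSet, features: FeatureSet
) -> list:
    """Per-feature interaction summaries over one annotated feature set.

    For every pair and every anchor side overlapping a feature of
    ``features``, the pair's count is added to that feature's total and to
    its per-type total (anchor-wise accumulation), and the OTHER anchor's
    feature ids are recorded as partners under that anchor's node class.
    """
    ann = _require_annotated(iset)
    if features.name not in ann.feature_order:
        raise ValidationError(
            f"feature set {features.name!r} was not among the annotation "
            f"sets {ann.feature_order}"
        )
    rank = _class_rank(ann)
    summaries = {fid: FeatureSummary(fid) for fid in features.ids}
    partner_sets: Dict[str, Dict[str, set]] = {
        fid: {} for fid in summaries
    }
    for i in range(len(iset)):
        label = pair_label(
            ann.one[i].node_class, ann.two[i].node_class, rank
        )
        for here, there in ((ann.one[i], ann.two[i]), (ann.two[i], ann.one[i])):
            for fid in here.ids_for(features.name):
                s = summaries[fid]
                s.n_interactions_total += iset.counts[i]
                s.type_totals[label] = (
                    s.type_totals.get(label, 0) + iset.counts[i]
                )
                pclass = there.node_class
                if pclass != DISTAL:
                    for pid in there.ids_for(pclass):
                        if pid != fid:
                            partner_sets[fid].setdefault(pclass, set()).add(pid)
    out = []
    for fid in features.ids:
        s = summaries[fid]
        s.partner_counts = {
            c: len(ids) for c, ids in sorted(partner_sets[fid].items())
        }
        out.append(s)
    return out


def feature_summaries_to_frame(summaries: Sequence[FeatureSummary]) -> pd.DataFrame:
    """Flat table: one row per feature, type totals and partner counts as
    ``total_<label>`` / ``partners_<class>`` columns."""
    type_labels = sorted({l for s in summaries for l in s.type_totals})
    classes = sorted({c for s in summaries for c in s.partner_counts})
    rows = []
    for s in summaries:
        row = {
            "feature_id": s.feature_id,
            "n_interactions_total": s.n_interactions_total,
        }
        for l in type_labels:
            row[f"total_{l}"] = s.type_totals.get(l, 0)
        for c in classes:
            row[f"partners_{c}"] = s.partner_counts.get(c, 0)
        rows.append(row)
    cols = (
        ["feature_id", "n_interactions_total"]
        + [f"total_{l}" for l in type_labels]
        + [f"partners_{c}" for c in classes]
    )
    return pd.DataFrame(rows, columns=cols)


def rank_features(
    summaries, by: str, top_n: Optional[int] = None
) -> pd.DataFrame:
    """Features ranked by a summary column, descending.

    ``summaries`` is a list of :class:`FeatureSummary` or the frame from
    :func:`feature_summaries_to_frame`. Ties are broken by feature_id,
    lexicographically ascending, so the ranking is deterministic.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = feature_summaries_to_frame(summaries)
    if by not in df.columns:
        raise KeyError(
            f"unknown ranking column {by!r}; available: {list(df.columns)}"
        )
    df = df.sort_values(
        [by, "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n)
    return df


@dataclass
class ViewpointProfile:
    """Virtual-4C profile: partner interaction signal around a viewpoint."""

    viewpoint: GenomicRange
    bins: list  # (chrom, start, end), 1-based closed, sorted, non-overlapping
    signal: np.ndarray


def viewpoint(
    iset: InteractionSet,
    region: GenomicRange,
    window: GenomicRange,
    bin_width: int,
    mode: str = "overlap",
) -> ViewpointProfile:
    """Virtual-4C profile of interactions involving ``region``.

    Pairs with at least one anchor overlapping ``region`` are selected;
    for each, the OTHER anchor (both anchors when both overlap the
    region) deposits the pair's supporting count into the window bins. In
    ``overlap`` mode the full count lands in every bin the partner anchor
    overlaps (a coverage-style view); in ``midpoint`` mode it lands once,
    in the bin containing the partner midpoint, which conserves totals.
    Bins of ``bin_width`` tile ``window`` left to right; the last bin is
    truncated at the window end.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"mode must be 'overlap' or 'midpoint', got {mode!r}")
    bins = []
    pos = window.start
    while pos <= window.end:
        bins.append((window.chrom, pos, min(pos + bin_width - 1, window.end)))
        pos += bin_width
    signal = np.zeros(len(bins), dtype=np.int64)

    def deposit(partner: GenomicRange, count: int) -> None:
        if partner.chrom != window.chrom:
            return
        if mode == "midpoint":
            mid = partner.midpoint
            if window.start <= mid <= window.end:
                signal[(mid - window.start) // bin_width] += count
            return
        first = max(0, (partner.start - window.start) // bin_width)
        last = (partner.end - window.start) // bin_width
        for b in range(first, min(last, len(bins) - 1) + 1):
            _, bs, be = bins[b]
            if partner.start <= be and partner.end >= bs:
                signal[b] += count

    for i in range(len(iset)):
        a, b = iset.anchor_one[i], iset.anchor_two[i]
        hit1, hit2 = a.overlaps(region), b.overlaps(region)
        if hit1:
            deposit(b, iset.counts[i])
        if hit2:
            deposit(a, iset.counts[i])
    return ViewpointProfile(viewpoint=region, bins=bins, signal=signal)
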