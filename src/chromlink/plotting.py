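"""Summary panels, viewpoint profiles and arc diagrams.

Every figure is backed by a plain data table produced by a ``*_data``
function; rendering adds no computation, so tests (and users) can target
the numbers rather than pixels. Rendered SVGs carry their backing numbers
as text so they can be checked after the fact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import GenomicRange, InteractionSet, calculate_distances
from .summarise import ViewpointProfile, summarize_dataset

FORMATS = ("png", "svg", "pdf")

_DATA_MARKER = "CHROMLINK_DATA"


def _distance_bins(dists, log_bins: bool = True, n_bins: int = 20):
    """Histogram bin edges for interaction distances.

    Distances span orders of magnitude, so log10-spaced bins are the
    default; zero distances are lumped into the first bin.
    """
    arr = np.asarray([d for d in dists if d is not None], dtype=float)
    if len(arr) == 0:
        return np.array([0.0, 1.0]), np.array([0])
    if log_bins:
        lo = max(1.0, arr[arr > 0].min()) if (arr > 0).any() else 1.0
        hi = max(arr.max(), lo + 1)
        edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
        edges[0] = 0.0  # first bin absorbs zero/short distances
    else:
        edges = np.linspace(0, arr.max() + 1, n_bins + 1)
    counts, edges = np.histogram(arr, bins=edges)
    return edges, counts


def summary_plot_data(
    iset: InteractionSet, log_bins: bool = True
) -> Dict[str, pd.DataFrame]:
    """The four summary tables: cis/trans proportions, interaction-type
    proportions, distance histogram, supporting-count histogram.

    Numbers are identical to :func:`chromlink.summarise.summarize_dataset`;
    on an unannotated set the type table is empty and flagged via its
    ``annotated`` attribute being absent from the rows.
    """
    s = summarize_dataset(iset)
    cis_trans = pd.DataFrame(
        {
            "label": ["cis", "trans"],
            "count": [s.n_cis, s.n_trans],
            "percentage": [s.pct_cis, s.pct_trans],
        }
    )
    if s.type_counts is not None:
        labels = sorted(s.type_counts)
        total = max(1, s.n_interactions)
        types = pd.DataFrame(
            {
                "label": labels,
                "count": [s.type_counts[l] for l in labels],
                "percentage": [100.0 * s.type_counts[l] / total for l in labels],
            }
        )
    else:
        types = pd.DataFrame(columns=["label", "count", "percentage"])
    edges, counts = _distance_bins(
        calculate_distances(iset, "midpoint"), log_bins=log_bins
    )
    distance = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
        }
    )
    values = sorted(s.count_histogram)
    count_hist = pd.DataFrame(
        {
            "supporting_count": values,
            "frequency": [s.count_histogram[v] for v in values],
        }
    )
    return {
        "cis_trans": cis_trans,
        "types": types,
        "distance_histogram": distance,
        "count_histogram": count_hist,
    }


def _check_format(fmt: str) -> None:
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; allowed: {FORMATS}")


def _embed_data(fig, payload: str) -> None:
    # Invisible-but-present text node; svg.fonttype='none' keeps it as
    # literal text in SVG output so it can be parsed back.
    fig.text(0.001, 0.001, f"{_DATA_MARKER}|{payload}", fontsize=1, alpha=0.0)


def _save(fig, path, fmt: str) -> None:
    # Suppress embedded timestamps so repeated runs are byte-identical.
    metadata = None
    if fmt == "svg":
        metadata = {"Date": None}
    elif fmt == "pdf":
        metadata = {"CreationDate": None}
    with matplotlib.rc_context({"svg.fonttype": "none", "svg.hashsalt": "chromlink"}):
        fig.savefig(str(path), format=fmt, metadata=metadata)
    plt.close(fig)


def _donut(ax, labels, counts, title: str) -> None:
    if sum(counts) == 0:
        ax.text(0.5, 0.5, "no data", ha="center", va="center")
        ax.set_axis_off()
    else:
        ax.pie(
            counts,
            labels=list(labels),
            wedgeprops={"width": 0.4},
            startangle=90,
        )
    ax.set_title(title)


def render_summary(
    iset: InteractionSet, path, format: str = "png", data_out=None
) -> Dict[str, pd.DataFrame]:
    """Render the 2x2 summary figure (cis/trans donut, type donut,
    distance histogram, supporting-count histogram) and return the
    backing tables. ``data_out`` optionally dumps them to one TSV."""
    _check_format(format)
    data = summary_plot_data(iset)
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    _donut(
        axes[0, 0],
        data["cis_trans"].label,
        data["cis_trans"]["count"].tolist(),
        "cis / trans interactions",
    )
    if len(data["types"]):
        _donut(
            axes[0, 1],
            data["types"].label,
            data["types"]["count"].tolist(),
            "interaction types",
        )
    else:
        axes[0, 1].text(0.5, 0.5, "not annotated", ha="center", va="center")
        axes[0, 1].set_axis_off()
        axes[0, 1].set_title("interaction types")
    dh = data["distance_histogram"]
    if dh["count"].sum() > 0:
        axes[1, 0].bar(
            dh.bin_left,
            dh["count"],
            width=(dh.bin_right - dh.bin_left),
            align="edge",
        )
        axes[1, 0].set_xscale("symlog")
    axes[1, 0].set_title("interaction distances (bp)")
    ch = data["count_histogram"]
    if len(ch):
        axes[1, 1].bar(ch.supporting_count, ch.frequency)
    axes[1, 1].set_title("reads supporting each interaction")
    payload = (
        f"cis={data['cis_trans']['count'][0]};"
        f"trans={data['cis_trans']['count'][1]};"
        f"pct_cis={data['cis_trans']['percentage'][0]!r};"
        f"n_types={len(data['types'])}"
    )
    _embed_data(fig, payload)
    fig.tight_layout()
    _save(fig, path, format)
    if data_out is not None:
        _dump_tables(data, data_out)
    return data


def _dump_tables(data: Dict[str, pd.DataFrame], path) -> None:
    with open(path, "w") as fh:
        for name, df in data.items():
            fh.write(f"# {name}\n")
            df.to_csv(fh, sep="\t", index=False)


@dataclass
class ArcTrackSpec:
    """Data behind an arc diagram of interactions in a genomic window.

    ``arcs`` has one row per drawn pair: x1/x2 are anchor midpoints (a
    trans partner's x is pinned to the window edge and the row flagged),
    ``height`` drives the curve height, ``category`` the colour.
    """

    window: GenomicRange
    arcs: pd.DataFrame
    feature_tracks: Optional[Dict[str, object]] = None


def arc_plot_data(
    iset: InteractionSet,
    window: GenomicRange,
    height_by: str = "counts",
    color_by: Optional[str] = None,
    feature_tracks: Optional[Dict[str, object]] = None,
) -> ArcTrackSpec:
    """Arc rows for all pairs with >= 1 anchor overlapping ``window``.

    ``height_by`` is ``counts`` or ``neg_log10_fdr`` (requires an ``fdr``
    metadata column; an FDR of 0 is mapped to the maximum finite height in
    the window plus one, and flagged). ``color_by="type"`` labels arcs
    with the interaction type (requires annotation).
    """
    if height_by not in ("counts", "neg_log10_fdr"):
        raise ValueError(
            f"height_by must be 'counts' or 'neg_log10_fdr', got {height_by!r}"
        )
    if height_by == "neg_log10_fdr" and "fdr" not in iset.metadata:
        raise KeyError("height_by='neg_log10_fdr' requires an 'fdr' metadata column")
    categories: Optional[list] = None
    if color_by == "type":
        from .annotate import interaction_types

        categories = interaction_types(iset)
    rows = []
    from .model import overlaps_region

    included = overlaps_region(iset, window, "either")
    for i in range(len(iset)):
        if not included[i]:
            continue
        a, b = iset.anchor_one[i], iset.anchor_two[i]
        trans = a.chrom != b.chrom
        x1 = a.midpoint if a.chrom == window.chrom else None
        x2 = b.midpoint if b.chrom == window.chrom else None
        # a trans partner (or an off-window-chromosome anchor) is pinned
        # to the nearer window edge
        if x1 is None:
            x1 = window.end
        if x2 is None:
            x2 = window.end
        if height_by == "counts":
            height = float(iset.counts[i])
            fdr_zero = False
        else:
            fdr = float(iset.metadata["fdr"][i])
            fdr_zero = fdr == 0.0
            height = math.inf if fdr_zero else -math.log10(fdr)
        rows.append(
            {
                "pair_index": i,
                "x1": x1,
                "x2": x2,
                "height": height,
                "category": categories[i] if categories else "",
                "trans": trans,
                "fdr_zero": fdr_zero,
            }
        )
    arcs = pd.DataFrame(
        rows,
        columns=[
            "pair_index", "x1", "x2", "height", "category", "trans", "fdr_zero",
        ],
    )
    if len(arcs) and arcs.fdr_zero.any():
        finite = arcs.height[~arcs.fdr_zero]
        ceiling = float(finite.max()) if len(finite) else 0.0
        arcs.loc[arcs.fdr_zero, "height"] = ceiling + 1.0
    return ArcTrackSpec(window=window, arcs=arcs, feature_tracks=feature_tracks)


def _palette(labels) -> Dict[str, tuple]:
    cmap = plt.get_cmap("tab10")
    return {l: cmap(i % 10) for i, l in enumerate(sorted(set(labels)))}


def render_arcs(
    spec: ArcTrackSpec,
    path,
    format: str = "png",
    log_height: bool = False,
    data_out=None,
) -> None:
    """Render an arc diagram from an :class:`ArcTrackSpec`.

    One quadratic arc per spec row, height linear in the height value by
    default (``log_height`` switches to log1p). Category colours come from
    a fixed palette indexed by sorted label order, so they are stable
    across calls. Trans pairs are drawn as a vertical stub at the
    in-window anchor.
    """
    _check_format(format)
    fig, ax = plt.subplots(figsize=(10, 4))
    colors = _palette(spec.arcs.category) if len(spec.arcs) else {}
    for _, row in spec.arcs.iterrows():
        h = math.log1p(row.height) if log_height else row.height
        color = colors.get(row.category, "tab:blue")
        if row.trans:
            line = ax.plot(
                [row.x1, row.x1], [0, h], color="dimgray", linestyle="--"
            )[0]
            line.set_gid(f"chromlink-arc-{row.pair_index}")
            continue
        xs = np.linspace(row.x1, row.x2, 50)
        mid = (row.x1 + row.x2) / 2
        half = max(abs(row.x2 - row.x1) / 2, 0.5)
        ys = h * (1 - ((xs - mid) / half) ** 2)
        line = ax.plot(xs, ys, color=color)[0]
        line.set_gid(f"chromlink-arc-{row.pair_index}")
    if spec.feature_tracks:
        y = -0.08
        for name, fs in spec.feature_tracks.items():
            for rng in fs.ranges:
                if rng.chrom == spec.window.chrom and rng.overlaps(spec.window):
                    ax.plot([rng.start, rng.end], [y, y], lw=4)
            ax.text(spec.window.start, y, name, fontsize=7, va="bottom")
            y -= 0.08
    ax.set_xlim(spec.window.start, spec.window.end)
    ax.set_xlabel(f"{spec.window.chrom} position (bp)")
    ax.set_ylabel("height")
    _embed_data(fig, f"n_arcs={len(spec.arcs)}")
    fig.tight_layout()
    _save(fig, path, format)
    if data_out is not None:
        spec.arcs.to_csv(data_out, sep="\t", index=False)


def render_viewpoint(
    profile: ViewpointProfile, path, format: str = "png", data_out=None
) -> None:
    """Render a viewpoint profile as a step plot."""
    _check_format(format)
    fig, ax = plt.subplots(figsize=(10, 3))
    lefts = [b[1] for b in profile.bins]
    widths = [b[2] - b[1] + 1 for b in profile.bins]
    ax.bar(lefts, profile.signal, width=widths, align="edge")
    ax.axvspan(
        profile.viewpoint.start, profile.viewpoint.end,
        color="tab:red", alpha=0.2,
    )
    ax.set_xlabel(f"{profile.bins[0][0]} position (bp)" if profile.bins else "")
    ax.set_ylabel("summed supporting counts")
    _embed_data(fig, f"total={int(np.sum(profile.signal))}")
    fig.tight_layout()
    _save(fig, path, format)
    if data_out is not None:
        with open(data_out, "w") as fh:
            fh.write("chrom\tstart\tend\tsignal\n")
            for (c, s, e), v in zip(profile.bins, profile.signal):
                fh.write(f"{c}\t{s}\t{e}\t{v}\n")
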