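"""Readers and writers for interaction interchange formats.

Supported dialects: bedpe (0-based half-open, 10+ columns), bed12 export
(UCSC), HOMER interaction tables (header-named columns, 1-based closed),
ChIA-PET-tool tables (fixed 9-column layout), weighted edge lists, feature
BED/TSV tables, TSS tables, and tag pairs from bedpe or SAM/BAM.

All internal coordinates are 1-based closed; each format keeps its native
convention on disk and is converted at this boundary.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

from .model import (
    FeatureSet,
    GenomicRange,
    InteractionSet,
    ValidationError,
    is_cis,
)
from .tags import TagPair


class ParseError(ValueError):
    """Raised on malformed input; message carries the 1-based line number."""


def _coerce_column(values: list) -> list:
    """Infer int, then float, else string for a metadata column."""
    try:
        return [int(v) for v in values]
    except ValueError:
        pass
    try:
        return [float(v) for v in values]
    except ValueError:
        return list(values)


def _strand_in(s: str) -> str:
    return s if s in ("+", "-") else "*"


def _strand_out(s: str) -> str:
    return s if s in ("+", "-") else "."


# ---------------------------------------------------------------------------
# bedpe


def read_bedpe(
    path,
    extra_columns: Optional[Sequence[str]] = None,
    counts_column: Optional[int] = None,
) -> InteractionSet:
    """Read a bedpe file into an :class:`InteractionSet`.

    The first ten columns are chrom1, start1, end1, chrom2, start2, end2,
    name, score, strand1, strand2; bedpe coordinates are 0-based half-open
    and are shifted to 1-based closed. The score column becomes the
    supporting count (must be a positive integer unless ``counts_column``
    points elsewhere; a non-integer score falls back to 1 with a warning).
    Columns beyond ten become metadata; their names come from a leading
    ``#``-comment header when present, else from ``extra_columns``, else
    ``extra_1`` ...
    """
    a1, a2, counts = [], [], []
    extra_rows: list = []
    header_names: Optional[list] = None
    non_integer_scores = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header_names = line.lstrip("#").strip().split("\t")
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 10 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                s1, e1 = int(fields[1]), int(fields[2])
                s2, e2 = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate ({exc})"
                ) from None
            a1.append(
                GenomicRange(fields[0], s1 + 1, e1, _strand_in(fields[8]))
            )
            a2.append(
                GenomicRange(fields[3], s2 + 1, e2, _strand_in(fields[9]))
            )
            if counts_column is not None:
                count_field = fields[counts_column]
            else:
                count_field = fields[7]
            try:
                c = int(count_field)
                if c < 1:
                    raise ValueError
            except ValueError:
                if counts_column is not None:
                    raise ValidationError(
                        f"{path}: line {lineno}: counts column value "
                        f"{count_field!r} is not a positive integer"
                    ) from None
                non_integer_scores += 1
                c = 1
            counts.append(c)
            extra_rows.append(fields[10:])
    if non_integer_scores:
        warnings.warn(
            f"{path}: {non_integer_scores} line(s) had a non-integer score; "
            "counts set to 1 (pass counts_column to override)",
            stacklevel=2,
        )
    n_extra = max((len(r) for r in extra_rows), default=0)
    metadata = {}
    if n_extra:
        if header_names is not None and len(header_names) >= 10 + n_extra:
            names = header_names[10 : 10 + n_extra]
        elif extra_columns is not None:
            names = list(extra_columns)[:n_extra]
        else:
            names = [f"extra_{i + 1}" for i in range(n_extra)]
        for j, name in enumerate(names):
            col = [r[j] if j < len(r) else "" for r in extra_rows]
            metadata[name] = _coerce_column(col)
    return InteractionSet(a1, a2, counts, metadata)


_BEDPE_HEADER = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_bedpe(iset: InteractionSet, path) -> None:
    """Write bedpe, deterministically sorted, metadata as extra columns.

    Coordinates are converted back to 0-based half-open; counts go in the
    score column; a ``#`` comment line names every column including the
    metadata columns, so :func:`read_bedpe` round-trips them.
    """
    srt = iset.sort()
    meta_names = list(srt.metadata)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BEDPE_HEADER + meta_names) + "\n")
        for i in range(len(srt)):
            a, b = srt.anchor_one[i], srt.anchor_two[i]
            fields = [
                a.chrom, str(a.start - 1), str(a.end),
                b.chrom, str(b.start - 1), str(b.end),
                ".", str(srt.counts[i]),
                _strand_out(a.strand), _strand_out(b.strand),
            ]
            fields += [
                _format_value(srt.metadata[m][i]) for m in meta_names
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# HOMER interaction tables


def _find_column(header_lc: list, *needles: str, skip: int = 0) -> int:
    """Index of the (skip+1)-th header column containing all needles."""
    found = 0
    for i, name in enumerate(header_lc):
        if all(n in name for n in needles):
            if found == skip:
                return i
            found += 1
    raise ParseError(
        "missing required column matching "
        + " + ".join(repr(n) for n in needles)
    )


def read_homer_interactions(path) -> InteractionSet:
    """Read a HOMER interaction table.

    Columns are located by header name (case-insensitive substring match),
    not by position: the two chr/start/end triplets become the anchors
    (HOMER coordinates are taken as 1-based closed), "Interaction Reads"
    becomes the supporting count, and distance / expected reads / Z-score /
    LogP / FDR columns, where present, become metadata.
    """
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        return InteractionSet([], [], [])
    header = lines[0].split("\t")
    header_lc = [h.lower() for h in header]
    try:
        c1 = _find_column(header_lc, "chr")
        c2 = _find_column(header_lc, "chr", skip=1)
        s1 = _find_column(header_lc, "start")
        s2 = _find_column(header_lc, "start", skip=1)
        e1 = _find_column(header_lc, "end")
        e2 = _find_column(header_lc, "end", skip=1)
        reads = _find_column(header_lc, "interaction reads")
    except ParseError as exc:
        raise ParseError(f"{path}: header: {exc}") from None
    meta_cols = {}
    for key, needles in [
        ("distance", ("distance",)),
        ("expected_reads", ("expected reads",)),
        ("z_score", ("z-score",)),
        ("logp", ("logp",)),
        ("fdr", ("fdr",)),
    ]:
        try:
            meta_cols[key] = _find_column(header_lc, *needles)
        except ParseError:
            pass
    a1, a2, counts = [], [], []
    meta_raw = {k: [] for k in meta_cols}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        try:
            a1.append(
                GenomicRange(fields[c1], int(fields[s1]), int(fields[e1]))
            )
            a2.append(
                GenomicRange(fields[c2], int(fields[s2]), int(fields[e2]))
            )
            counts.append(int(fields[reads]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        for k, j in meta_cols.items():
            meta_raw[k].append(fields[j])
    metadata = {k: _coerce_column(v) for k, v in meta_raw.items()}
    return InteractionSet(a1, a2, counts, metadata)


# ---------------------------------------------------------------------------
# ChIA-PET tool tables


def read_chiapet_tool(path, zero_based: bool = False) -> InteractionSet:
    """Read a ChIA-PET-tool style table.

    Fixed 9-column tab layout: chrom1, start1, end1, chrom2, start2, end2,
    pet_count, p_value, fdr. Coordinates are 1-based closed unless
    ``zero_based`` is set (then 0-based half-open). A leading ``#`` header
    line is permitted and ignored.
    """
    off = 1 if zero_based else 0
    a1, a2, counts, pvals, fdrs = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 columns, got "
                    f"{len(fields)}"
                )
            try:
                a1.append(
                    GenomicRange(
                        fields[0], int(fields[1]) + off, int(fields[2])
                    )
                )
                a2.append(
                    GenomicRange(
                        fields[3], int(fields[4]) + off, int(fields[5])
                    )
                )
                counts.append(int(fields[6]))
                pvals.append(float(fields[7]))
                fdrs.append(float(fields[8]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return InteractionSet(a1, a2, counts, {"p_value": pvals, "fdr": fdrs})


# ---------------------------------------------------------------------------
# bed12 export


def export_bed12(iset: InteractionSet, path, score_transform=None) -> int:
    """Export cis pairs as bed12 lines (one two-block line per pair).

    Trans pairs and cis pairs whose anchors overlap cannot be represented
    as a valid bed12 block pair; they are skipped and their total is
    reported via a warning and the return value. The score column is the
    supporting count clamped to [0, 1000] (per the BED spec); raw counts
    are preserved in the name field as ``int<i>_<counts>``.
    """
    skipped = 0
    with open(path, "w") as fh:
        for i in range(len(iset)):
            a, b = iset.anchor_one[i], iset.anchor_two[i]
            if a.chrom != b.chrom or a.overlaps(b):
                skipped += 1
                continue
            first, second = (a, b) if a.start <= b.start else (b, a)
            chrom_start = first.start - 1  # 0-based
            chrom_end = second.end
            c = iset.counts[i]
            score = c if score_transform is None else score_transform(c)
            score = max(0, min(1000, int(score)))
            sizes = f"{first.width},{second.width}"
            starts = f"0,{second.start - 1 - chrom_start}"
            fh.write(
                "\t".join(
                    [
                        a.chrom, str(chrom_start), str(chrom_end),
                        f"int{i}_{c}", str(score), ".",
                        str(chrom_start), str(chrom_end), "0",
                        "2", sizes, starts,
                    ]
                )
                + "\n"
            )
    if skipped:
        warnings.warn(
            f"export_bed12: skipped {skipped} pair(s) that are trans or "
            "have overlapping anchors",
            stacklevel=2,
        )
    return skipped


# ---------------------------------------------------------------------------
# graph export


def export_graph(iset: InteractionSet, path, node_by: str = "anchor") -> dict:
    """Export the interactions as a weighted edge list TSV.

    Nodes are deduplicated anchor coordinate strings (``chrom:start-end``)
    or, with ``node_by="feature_id"`` on an annotated set, the anchors'
    node classes' feature identifiers (anchors with no feature id use
    ``distal:<coords>``). Parallel pairs between the same unordered node
    pair are merged by summing weights; metadata of the first occurrence
    is kept. Returns ``{"nodes": n, "edges": m}``.
    """
    if node_by not in ("anchor", "feature_id"):
        raise ValueError(f"node_by must be 'anchor' or 'feature_id', got {node_by!r}")
    if node_by == "feature_id" and iset.annotations is None:
        raise ValidationError(
            "node_by='feature_id' requires an annotated InteractionSet"
        )

    def node_label(anchor: GenomicRange, ann) -> str:
        if node_by == "anchor":
            return str(anchor)
        ids = ann.ids_for(ann.node_class) if ann.node_class != "distal" else ()
        if ids:
            return ";".join(sorted(ids))
        return f"distal:{anchor}"

    meta_names = list(iset.metadata)
    edges: dict = {}
    nodes = set()
    for i in range(len(iset)):
        ann1 = iset.annotations.one[i] if iset.annotations else None
        ann2 = iset.annotations.two[i] if iset.annotations else None
        n1 = node_label(iset.anchor_one[i], ann1)
        n2 = node_label(iset.anchor_two[i], ann2)
        nodes.update((n1, n2))
        key = (n1, n2) if n1 <= n2 else (n2, n1)
        if key in edges:
            edges[key][0] += iset.counts[i]
        else:
            edges[key] = [
                iset.counts[i],
                [iset.metadata[m][i] for m in meta_names],
            ]
    with open(path, "w") as fh:
        fh.write("\t".join(["node1", "node2", "weight"] + meta_names) + "\n")
        for (n1, n2) in sorted(edges):
            weight, meta = edges[(n1, n2)]
            fields = [n1, n2, str(weight)] + [_format_value(v) for v in meta]
            fh.write("\t".join(fields) + "\n")
    return {"nodes": len(nodes), "edges": len(edges)}


# ---------------------------------------------------------------------------
# feature sets and TSS tables


def read_features_bed(path, name: str) -> FeatureSet:
    """Feature set from a BED file (0-based half-open; column 4 = id)."""
    ranges, ids = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            ranges.append(GenomicRange(fields[0], start + 1, end))
            ids.append(fields[3] if len(fields) > 3 else f"{name}_{lineno}")
    return FeatureSet(name, ranges, ids)


def read_features_tsv(path, name: str) -> FeatureSet:
    """Feature set from a 4-column TSV: chrom, start, end, id (1-based closed)."""
    ranges, ids = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 columns"
                )
            try:
                ranges.append(
                    GenomicRange(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            ids.append(fields[3])
    return FeatureSet(name, ranges, ids)


def read_tss_table(path) -> list:
    """TSS rows as (chrom, position, id, strand) tuples.

    3-column TSV chrom, tss_position, id with an optional 4th strand
    column; positions 1-based.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 columns"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            strand = fields[3] if len(fields) > 3 and fields[3] in ("+", "-") else "*"
            rows.append((fields[0], pos, fields[2], strand))
    return rows


# ---------------------------------------------------------------------------
# tag pairs


def read_tag_pairs_bedpe(path) -> list:
    """Tag pairs from bedpe; strands (columns 9-10) must be definite."""
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 10 columns"
                )
            if fields[8] not in ("+", "-") or fields[9] not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: tag pairs require definite "
                    f"strands, got {fields[8]!r}/{fields[9]!r}"
                )
            try:
                end1 = GenomicRange(
                    fields[0], int(fields[1]) + 1, int(fields[2]), fields[8]
                )
                end2 = GenomicRange(
                    fields[3], int(fields[4]) + 1, int(fields[5]), fields[9]
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            pairs.append(TagPair(end1, end2))
    return pairs


def write_tag_pairs_bedpe(pairs, path) -> None:
    """Write tag pairs as 10-column bedpe (0-based half-open)."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                "\t".join(
                    [
                        p.end1.chrom, str(p.end1.start - 1), str(p.end1.end),
                        p.end2.chrom, str(p.end2.start - 1), str(p.end2.end),
                        ".", "1", p.end1.strand, p.end2.strand,
                    ]
                )
                + "\n"
            )


def read_tag_pairs_sam(path, min_mapq: int = 0) -> list:
    """Tag pairs from paired records in a SAM/BAM file.

    Only mapped, primary, properly paired records are used; mates are
    joined by query name. Alignment-level QC beyond ``min_mapq`` is out of
    scope here and belongs upstream.
    """
    import pysam

    pending: dict = {}
    pairs = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.mate_is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or not rec.is_paired
                or rec.mapping_quality < min_mapq
            ):
                continue
            rng = GenomicRange(
                rec.reference_name,
                rec.reference_start + 1,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
            )
            if rec.query_name in pending:
                mate = pending.pop(rec.query_name)
                first, second = (mate, rng) if rec.is_read2 else (rng, mate)
                pairs.append(TagPair(first, second))
            else:
                pending[rec.query_name] = rng
    return pairs


# ---------------------------------------------------------------------------
# profile / table export


def write_bedgraph(profile, path) -> None:
    """Write a viewpoint profile as bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for (chrom, start, end), value in zip(profile.bins, profile.signal):
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{_format_value(value)}\n")
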