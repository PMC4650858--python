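"""Anchor annotation and interaction classification.

Each anchor is annotated with every feature it overlaps and receives a
single node class: the name of the first feature set, in a user-defined
priority order, with at least one overlap, or "distal" when it overlaps
nothing. Interactions are then classified by the unordered pair of their
anchors' classes, e.g. "promoter:enhancer".
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import (
    AnnotatedAnchor,
    Annotations,
    FeatureSet,
    GenomicRange,
    InteractionSet,
    ValidationError,
)

DISTAL = "distal"


class _FeatureIndex:
    """Per-chromosome vectorised overlap lookup for one feature set."""

    def __init__(self, fs: FeatureSet) -> None:
        self.by_chrom: dict = {}
        for rng, fid in zip(fs.ranges, fs.ids):
            self.by_chrom.setdefault(rng.chrom, ([], [], []))
            s, e, ids = self.by_chrom[rng.chrom]
            s.append(rng.start)
            e.append(rng.end)
            ids.append(fid)
        self.by_chrom = {
            c: (np.array(s), np.array(e), ids)
            for c, (s, e, ids) in self.by_chrom.items()
        }

    def overlapping_ids(self, anchor: GenomicRange) -> tuple:
        """Ids of all overlapped features, deduplicated, first-seen order."""
        entry = self.by_chrom.get(anchor.chrom)
        if entry is None:
            return ()
        starts, ends, ids = entry
        hits = (starts <= anchor.end) & (ends >= anchor.start)
        seen = set()
        out = []
        for i in np.flatnonzero(hits):
            fid = ids[i]
            if fid not in seen:
                seen.add(fid)
                out.append(fid)
        return tuple(out)


def _check_feature_sets(feature_sets: Sequence[FeatureSet]) -> None:
    names = [fs.name for fs in feature_sets]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate feature-set name(s): {dupes}")
    if DISTAL in names:
        raise ValidationError("'distal' is reserved and cannot name a feature set")


def annotate(
    iset: InteractionSet, feature_sets: Sequence[FeatureSet]
) -> InteractionSet:
    """Annotate every anchor on both sides with classes and feature ids.

    ``feature_sets`` is an ORDERED list; order encodes priority. An anchor
    overlapping several sets is classed by the first-listed one, but the
    overlapped ids of EVERY set are recorded (close features cannot always
    be disambiguated, so no arbitrary single winner is chosen among
    same-class overlaps either). Overlap means >= 1 shared base.

    Returns a new annotated set; the input is left untouched.
    """
    _check_feature_sets(feature_sets)
    indexes = [(fs.name, _FeatureIndex(fs)) for fs in feature_sets]

    def annotate_anchor(anchor: GenomicRange) -> AnnotatedAnchor:
        ids = {name: idx.overlapping_ids(anchor) for name, idx in indexes}
        node_class = DISTAL
        for name, _ in indexes:
            if ids[name]:
                node_class = name
                break
        return AnnotatedAnchor(node_class=node_class, feature_ids=ids)

    ann = Annotations(
        feature_order=[fs.name for fs in feature_sets],
        one=[annotate_anchor(a) for a in iset.anchor_one],
        two=[annotate_anchor(a) for a in iset.anchor_two],
    )
    return InteractionSet(
        iset.anchor_one, iset.anchor_two, iset.counts, iset.metadata,
        annotations=ann,
    )


def reset_annotations(iset: InteractionSet) -> InteractionSet:
    """Strip all anchor annotations; annotate(reset(x), fs) == annotate(x, fs)."""
    return InteractionSet(
        iset.anchor_one, iset.anchor_two, iset.counts, iset.metadata
    )


def _require_annotated(iset: InteractionSet) -> Annotations:
    if iset.annotations is None:
        raise ValidationError(
            "InteractionSet is not annotated; call annotate() first"
        )
    return iset.annotations


def _class_rank(ann: Annotations) -> dict:
    rank = {name: i for i, name in enumerate(ann.feature_order)}
    rank[DISTAL] = len(ann.feature_order)
    return rank


def pair_label(class_a: str, class_b: str, rank: dict) -> str:
    """Canonical "classA:classB" with classes ordered by feature priority,
    distal last."""
    a, b = sorted((class_a, class_b), key=lambda c: (rank[c], c))
    return f"{a}:{b}"


def interaction_types(iset: InteractionSet) -> list:
    """Canonical class-pair label for every interaction.

    Labels are symmetric in the two sides: (promoter, enhancer) and
    (enhancer, promoter) both yield "promoter:enhancer".
    """
    ann = _require_annotated(iset)
    rank = _class_rank(ann)
    return [
        pair_label(a.node_class, b.node_class, rank)
        for a, b in zip(ann.one, ann.two)
    ]


def is_type(iset: InteractionSet, class_a: str, class_b: str) -> list:
    """Elementwise: is the unordered class pair (class_a, class_b)?"""
    ann = _require_annotated(iset)
    known = set(ann.feature_order) | {DISTAL}
    for c in (class_a, class_b):
        if c not in known:
            raise ValidationError(
                f"unknown class {c!r}; known classes: {sorted(known)}"
            )
    want = frozenset((class_a, class_b))
    return [
        frozenset((a.node_class, b.node_class)) == want
        for a, b in zip(ann.one, ann.two)
    ]


def is_pp(iset: InteractionSet) -> list:
    """Promoter:promoter interactions."""
    return is_type(iset, "promoter", "promoter")


def is_pd(iset: InteractionSet) -> list:
    """Promoter:distal interactions."""
    return is_type(iset, "promoter", DISTAL)


def is_dd(iset: InteractionSet) -> list:
    """Distal:distal interactions."""
    return is_type(iset, DISTAL, DISTAL)


def is_pt(iset: InteractionSet) -> list:
    """Promoter:transcribed ("t") interactions."""
    return is_type(iset, "promoter", "t")


def promoters_from_tss(
    tss_rows: Sequence, flank: int = 2500, name: str = "promoter"
) -> FeatureSet:
    """Promoter windows [TSS - flank, TSS + flank] around a TSS table.

    ``tss_rows`` holds (chrom, position, id) or (chrom, position, id,
    strand) tuples. The default 2.5 kb flank matches the usual
    promoter-window convention for TSS-based annotation. Windows are
    clipped at position 1.
    """
    ranges, ids = [], []
    for row in tss_rows:
        chrom, pos, fid = row[0], int(row[1]), row[2]
        ranges.append(GenomicRange(chrom, max(1, pos - flank), pos + flank))
        ids.append(fid)
    return FeatureSet(name, ranges, ids)
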