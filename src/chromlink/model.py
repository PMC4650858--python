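"""Core data model for chromatin interaction data.

An interaction dataset is a series of pairs of genomic regions ("anchors")
plus per-pair data such as supporting read counts, p-values and FDRs.
Coordinates are 1-based and fully closed throughout the in-memory model;
BED-family I/O converts at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

VALID_STRANDS = ("+", "-", "*")

DISTANCE_METHODS = ("midpoint", "outer", "inner")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicRange:
    """A genomic interval with 1-based closed coordinates.

    ``start`` and ``end`` are both included in the interval, so a
    single-base range has ``start == end`` and width 1.
    """

    chrom: str
    start: int
    end: int
    strand: str = "*"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be a non-empty string")
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"strand must be one of {VALID_STRANDS}, got {self.strand!r}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRange") -> bool:
        """True when the two ranges share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class AnnotatedAnchor:
    """Annotation of one anchor: its node class and overlapped feature ids.

    ``node_class`` is the name of the first feature set, in priority order,
    that the anchor overlaps, or ``"distal"`` if it overlaps none.
    ``feature_ids`` records, for every feature set (not only the winning
    one), the identifiers of all overlapped features, without duplicates.
    """

    node_class: str
    feature_ids: Mapping[str, tuple]

    def ids_for(self, set_name: str) -> tuple:
        return tuple(self.feature_ids.get(set_name, ()))


@dataclass
class FeatureSet:
    """A named class of genomic features, each carrying an identifier."""

    name: str
    ranges: list
    ids: list

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("FeatureSet name must be non-empty")
        if len(self.ranges) != len(self.ids):
            raise ValidationError(
                f"FeatureSet {self.name!r}: {len(self.ranges)} ranges but "
                f"{len(self.ids)} ids"
            )

    def __len__(self) -> int:
        return len(self.ranges)


@dataclass
class Annotations:
    """Per-anchor annotations for both sides of an interaction set."""

    feature_order: list
    one: list
    two: list


class InteractionSet:
    """Parallel lists of anchor pairs with supporting counts and metadata.

    The central container: ``anchor_one[i]`` interacts with
    ``anchor_two[i]``, supported by ``counts[i]`` reads/PETs, with optional
    named per-pair ``metadata`` columns (p-values, FDRs, anything else,
    carried opaquely) and, once :func:`chromlink.annotate.annotate` has
    been applied, per-anchor class annotations.
    """

    def __init__(
        self,
        anchor_one: Sequence[GenomicRange],
        anchor_two: Sequence[GenomicRange],
        counts: Sequence[int],
        metadata: Optional[Mapping[str, Sequence]] = None,
        annotations: Optional[Annotations] = None,
    ) -> None:
        self.anchor_one = list(anchor_one)
        self.anchor_two = list(anchor_two)
        self.counts = [int(c) for c in counts]
        self.metadata = {k: list(v) for k, v in (metadata or {}).items()}
        self.annotations = annotations
        self._validate()

    def _validate(self) -> None:
        n = len(self.anchor_one)
        if len(self.anchor_two) != n:
            raise ValidationError(
                f"anchor_two has length {len(self.anchor_two)}, expected {n} "
                "(anchor_one)"
            )
        if len(self.counts) != n:
            raise ValidationError(
                f"counts has length {len(self.counts)}, expected {n}"
            )
        for name, col in self.metadata.items():
            if len(col) != n:
                raise ValidationError(
                    f"metadata column {name!r} has length {len(col)}, "
                    f"expected {n}"
                )
        if "counts" in self.metadata:
            raise ValidationError("metadata may not use the reserved name 'counts'")
        for i, c in enumerate(self.counts):
            if c < 1:
                raise ValidationError(f"counts must be >= 1; index {i} has {c}")
        if self.annotations is not None:
            if len(self.annotations.one) != n or len(self.annotations.two) != n:
                raise ValidationError("annotations must cover every pair")

    def __len__(self) -> int:
        return len(self.anchor_one)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionSet):
            return NotImplemented
        return (
            self.anchor_one == other.anchor_one
            and self.anchor_two == other.anchor_two
            and self.counts == other.counts
            and self.metadata == other.metadata
        )

    def __repr__(self) -> str:
        cols = ", ".join(self.metadata) or "none"
        return (
            f"InteractionSet({len(self)} pairs, metadata: {cols}, "
            f"annotated: {self.annotations is not None})"
        )

    # -- tabular views -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Flat per-pair table: anchor coordinates, counts and metadata."""
        data = {
            "chrom1": [a.chrom for a in self.anchor_one],
            "start1": [a.start for a in self.anchor_one],
            "end1": [a.end for a in self.anchor_one],
            "strand1": [a.strand for a in self.anchor_one],
            "chrom2": [a.chrom for a in self.anchor_two],
            "start2": [a.start for a in self.anchor_two],
            "end2": [a.end for a in self.anchor_two],
            "strand2": [a.strand for a in self.anchor_two],
            "counts": list(self.counts),
        }
        for name, col in self.metadata.items():
            data[name] = list(col)
        return pd.DataFrame(data)

    # -- selection -----------------------------------------------------

    def take(self, indices: Sequence[int]) -> "InteractionSet":
        """New set containing the pairs at ``indices`` (order as given)."""
        ann = None
        if self.annotations is not None:
            ann = Annotations(
                feature_order=list(self.annotations.feature_order),
                one=[self.annotations.one[i] for i in indices],
                two=[self.annotations.two[i] for i in indices],
            )
        return InteractionSet(
            [self.anchor_one[i] for i in indices],
            [self.anchor_two[i] for i in indices],
            [self.counts[i] for i in indices],
            {k: [v[i] for i in indices] for k, v in self.metadata.items()},
            annotations=ann,
        )

    def sort(self) -> "InteractionSet":
        """Deterministic order: (chrom1, start1, end1, chrom2, start2, end2),
        chromosomes compared lexicographically."""
        order = sorted(
            range(len(self)),
            key=lambda i: (
                self.anchor_one[i].chrom,
                self.anchor_one[i].start,
                self.anchor_one[i].end,
                self.anchor_two[i].chrom,
                self.anchor_two[i].start,
                self.anchor_two[i].end,
            ),
        )
        return self.take(order)


def make_interaction_set(
    anchor_one: Sequence[GenomicRange],
    anchor_two: Sequence[GenomicRange],
    counts: Sequence[int],
    metadata: Optional[Mapping[str, Sequence]] = None,
) -> InteractionSet:
    """Build a validated :class:`InteractionSet`, preserving pair order."""
    return InteractionSet(anchor_one, anchor_two, counts, metadata)


def is_cis(iset: InteractionSet) -> list:
    """Elementwise: do both anchors lie on the same chromosome?"""
    return [
        a.chrom == b.chrom for a, b in zip(iset.anchor_one, iset.anchor_two)
    ]


def is_trans(iset: InteractionSet) -> list:
    """Elementwise complement of :func:`is_cis`."""
    return [not c for c in is_cis(iset)]


def calculate_distances(
    iset: InteractionSet, method: str = "midpoint"
) -> list:
    """Per-pair anchor-to-anchor distance in bp; ``None`` for trans pairs.

    Conventions (strand is ignored):

    * ``midpoint`` — ``|mid1 - mid2|`` with ``mid = (start + end) // 2``.
    * ``inner`` — gap between the closest edges,
      ``max(0, later start - earlier end)``; 0 for overlapping anchors.
    * ``outer`` — full span, ``later end - earlier start + 1``.
    """
    if method not in DISTANCE_METHODS:
        raise ValueError(
            f"unknown distance method {method!r}; allowed: "
            + ", ".join(DISTANCE_METHODS)
        )
    out = []
    for a, b in zip(iset.anchor_one, iset.anchor_two):
        if a.chrom != b.chrom:
            out.append(None)
            continue
        if method == "midpoint":
            out.append(abs(a.midpoint - b.midpoint))
        elif method == "inner":
            first, second = (a, b) if a.start <= b.start else (b, a)
            out.append(max(0, second.start - first.end))
        else:  # outer
            out.append(max(a.end, b.end) - min(a.start, b.start) + 1)
    return out


def overlaps_region(
    iset: InteractionSet, region: GenomicRange, which: str = "either"
) -> list:
    """Per-pair: does the pair overlap ``region``?

    ``which`` selects the anchor(s) tested: ``one``, ``two``, ``either``
    (OR) or ``both`` (AND). Overlap means >= 1 shared base under the
    1-based closed convention.
    """
    if which not in ("either", "both", "one", "two"):
        raise ValueError(
            f"which must be one of either/both/one/two, got {which!r}"
        )
    o1 = [a.overlaps(region) for a in iset.anchor_one]
    o2 = [a.overlaps(region) for a in iset.anchor_two]
    if which == "one":
        return o1
    if which == "two":
        return o2
    if which == "both":
        return [x and y for x, y in zip(o1, o2)]
    return [x or y for x, y in zip(o1, o2)]


# Spelling used by the R-style predicate strings accepted by subset():
# logical keywords and anchor accessors are rewritten to pandas syntax.
_PREDICATE_REWRITES = [
    (re.compile(r"\bAND\b"), "and"),
    (re.compile(r"\bOR\b"), "or"),
    (re.compile(r"\bNOT\b"), "not"),
    (re.compile(r"chrom\(\s*anchor_one\s*\)"), "chrom1"),
    (re.compile(r"chrom\(\s*anchor_two\s*\)"), "chrom2"),
]


def _evaluate_predicate(
    iset: InteractionSet,
    predicate: Union[str, Callable, Sequence[bool]],
) -> list:
    if callable(predicate):
        mask = [bool(predicate(i)) for i in range(len(iset))]
        return mask
    if isinstance(predicate, str):
        expr = predicate
        for pat, repl in _PREDICATE_REWRITES:
            expr = pat.sub(repl, expr)
        df = iset.to_dataframe()
        unquoted = re.sub(r"'[^']*'|\"[^\"]*\"", "", expr)
        names = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", unquoted))
        keywords = {"and", "or", "not", "True", "False", "in"}
        unknown = names - set(df.columns) - keywords
        if unknown:
            raise KeyError(
                f"predicate references unknown column(s): "
                + ", ".join(sorted(unknown))
            )
        if len(df) == 0:
            return []
        result = df.eval(expr)
        return [bool(x) for x in result]
    mask = [bool(x) for x in predicate]
    if len(mask) != len(iset):
        raise ValidationError(
            f"boolean mask has length {len(mask)}, expected {len(iset)}"
        )
    return mask


def subset(
    iset: InteractionSet,
    predicate: Union[str, Callable, Sequence[bool]],
) -> InteractionSet:
    """Pairs for which ``predicate`` holds, order and annotations preserved.

    ``predicate`` may be a boolean mask, a callable of the pair index, or a
    string expression over ``counts``, metadata columns and the anchor
    coordinate columns (``chrom1``, ``start1`` ... ``strand2``), e.g.
    ``"counts > 2 and fdr < 0.05"``. ``AND``/``OR``/``NOT`` and
    ``chrom(anchor_one)``/``chrom(anchor_two)`` are also accepted.
    """
    mask = _evaluate_predicate(iset, predicate)
    return iset.take([i for i, m in enumerate(mask) if m])
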