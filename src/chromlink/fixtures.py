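"""Seeded synthetic data: tag pairs with a known self-ligation structure,
interaction sets, feature sets, and on-disk files in every supported
dialect.

Everything here is a pure function of a :class:`FixtureConfig`; the same
seed gives byte-identical output. The generators emulate the gross
statistical features of ChIA-PET/Hi-C interaction data — a short-range
self-ligation population with an opposite-strand excess, a heavy-tailed
inter-ligation distance law, long-tailed supporting counts — not
biological structure such as TADs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .io import write_bedpe, write_tag_pairs_bedpe
from .model import FeatureSet, GenomicRange, InteractionSet, ValidationError
from .tags import TagPair


def _default_chrom_sizes() -> Dict[str, int]:
    return {"chr1": 5_000_000, "chr2": 4_000_000, "chr3": 3_000_000}


def _default_feature_spec() -> Dict[str, Tuple[int, Tuple[int, int]]]:
    # class -> (how many, (min width, max width)); order encodes priority
    return {
        "promoter": (30, (1_000, 3_000)),
        "enhancer": (40, (500, 1_500)),
        "ctcf": (25, (200, 500)),
    }


@dataclass
class FixtureConfig:
    """All knobs of the synthetic-data generators, with study defaults.

    The tag-pair generator mixes self-ligation pairs (distance uniform
    below ``self_ligation_distance``, opposite strands with probability
    ``self_opposite_prob``) with inter-ligation pairs (truncated-Pareto
    distances, strands uniform over the four configurations).
    """

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(default_factory=_default_chrom_sizes)

    # tag pairs
    n_tag_pairs: int = 20_000
    self_ligation_distance: int = 5_000
    self_fraction: float = 0.5
    self_opposite_prob: float = 0.95
    read_length: int = 50
    inter_distance_min: int = 1_000
    inter_distance_max: int = 2_000_000
    inter_distance_alpha: float = 0.8
    tag_duplicate_fraction: float = 0.0

    # interactions
    n_interactions: int = 1_000
    trans_fraction: float = 0.1
    anchor_width_range: Tuple[int, int] = (1_000, 5_000)
    count_geom_p: float = 0.4
    hub_extra_interactions: int = 0

    # features
    feature_spec: Dict[str, Tuple[int, Tuple[int, int]]] = field(
        default_factory=_default_feature_spec
    )
    inject_overlaps: bool = False

    def __post_init__(self) -> None:
        for name in ("self_fraction", "trans_fraction", "self_opposite_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if not self.chrom_sizes:
            raise ValidationError("chrom_sizes must be non-empty")
        if self.self_ligation_distance >= min(self.chrom_sizes.values()):
            raise ValidationError(
                "self_ligation_distance must be smaller than the smallest "
                "chromosome"
            )
        if not 0 < self.count_geom_p <= 1:
            raise ValidationError("count_geom_p must be in (0,1]")


def _rng(config: FixtureConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def _pick_chrom(rng, chrom_sizes: Dict[str, int], min_size: int = 0) -> str:
    names = [c for c, s in chrom_sizes.items() if s > min_size]
    sizes = np.array([chrom_sizes[c] for c in names], dtype=float)
    return names[rng.choice(len(names), p=sizes / sizes.sum())]


def _pareto_distance(rng, config: FixtureConfig) -> int:
    """Truncated-Pareto inter-ligation distance (inverse-CDF sampling)."""
    a = config.inter_distance_alpha
    lo = float(config.inter_distance_min) ** -a
    hi = float(config.inter_distance_max) ** -a
    u = rng.random()
    return int(round((lo - u * (lo - hi)) ** (-1.0 / a)))


def generate_tag_pairs(config: FixtureConfig) -> list:
    """Deterministic list of TagPairs from the self/inter-ligation mixture."""
    rng = _rng(config)
    pairs = []
    L = config.read_length
    for _ in range(config.n_tag_pairs):
        is_self = rng.random() < config.self_fraction
        if is_self:
            dist = int(rng.integers(0, max(1, config.self_ligation_distance)))
            opposite = rng.random() < config.self_opposite_prob
        else:
            dist = _pareto_distance(rng, config)
            opposite = rng.random() < 0.5
        chrom = _pick_chrom(rng, config.chrom_sizes, min_size=dist + 2 * L + 2)
        size = config.chrom_sizes[chrom]
        p1 = int(rng.integers(1, size - dist - L))
        p2 = p1 + dist
        if opposite:
            s1, s2 = ("+", "-") if rng.random() < 0.5 else ("-", "+")
        else:
            s1 = s2 = "+" if rng.random() < 0.5 else "-"
        pairs.append(
            TagPair(
                GenomicRange(chrom, p1, p1 + L - 1, s1),
                GenomicRange(chrom, p2, p2 + L - 1, s2),
            )
        )
    if config.tag_duplicate_fraction > 0:
        n_dup = int(round(config.tag_duplicate_fraction * len(pairs)))
        for _ in range(n_dup):
            src = pairs[int(rng.integers(0, config.n_tag_pairs))]
            if rng.random() < 0.5:  # swapped end order, same canonical pair
                pairs.append(TagPair(src.end2, src.end1))
            else:
                pairs.append(src)
    return pairs


def _random_anchor(rng, config: FixtureConfig, chrom: Optional[str] = None) -> GenomicRange:
    wlo, whi = config.anchor_width_range
    width = int(rng.integers(wlo, whi + 1))
    if chrom is None:
        chrom = _pick_chrom(rng, config.chrom_sizes, min_size=width + 2)
    size = config.chrom_sizes[chrom]
    start = int(rng.integers(1, max(2, size - width)))
    return GenomicRange(chrom, start, start + width - 1)


def generate_interactions(
    config: FixtureConfig,
    feature_sets: Optional[Sequence[FeatureSet]] = None,
) -> Tuple[InteractionSet, dict]:
    """A random InteractionSet plus its ground truth.

    Anchors are placed uniformly; pairs are trans with probability
    ``trans_fraction``; supporting counts follow a shifted geometric
    distribution (support >= 1); p_value/fdr metadata are random but
    recorded. With ``hub_extra_interactions > 0`` and feature sets given,
    one "hub" promoter receives that many extra promoter:enhancer
    interactions, recorded in the ground truth.
    """
    rng = _rng(config)
    a1, a2, counts = [], [], []
    pvals, fdrs, truth_trans = [], [], []
    for _ in range(config.n_interactions):
        first = _random_anchor(rng, config)
        trans = rng.random() < config.trans_fraction and len(config.chrom_sizes) > 1
        if trans:
            others = [c for c in config.chrom_sizes if c != first.chrom]
            second = _random_anchor(
                rng, config, chrom=others[int(rng.integers(0, len(others)))]
            )
        else:
            second = _make_cis_partner(rng, config, first)
        a1.append(first)
        a2.append(second)
        counts.append(int(rng.geometric(config.count_geom_p)))
        p = float(rng.random()) ** 3
        pvals.append(p)
        fdrs.append(min(1.0, p * float(rng.uniform(1.0, 5.0))))
        truth_trans.append(trans)
    truth: dict = {
        "seed": config.seed,
        "n_interactions": config.n_interactions,
        "trans": truth_trans,
        "hub_feature_id": None,
    }
    if config.hub_extra_interactions > 0:
        if not feature_sets:
            raise ValidationError(
                "hub_extra_interactions requires feature_sets"
            )
        by_name = {fs.name: fs for fs in feature_sets}
        if "promoter" not in by_name or "enhancer" not in by_name:
            raise ValidationError(
                "hub planting needs 'promoter' and 'enhancer' feature sets"
            )
        promoters, enhancers = by_name["promoter"], by_name["enhancer"]
        hub_idx = int(rng.integers(0, len(promoters)))
        truth["hub_feature_id"] = promoters.ids[hub_idx]
        hub_range = promoters.ranges[hub_idx]
        for _ in range(config.hub_extra_interactions):
            enh_idx = int(rng.integers(0, len(enhancers)))
            a1.append(hub_range)
            a2.append(enhancers.ranges[enh_idx])
            counts.append(int(rng.geometric(config.count_geom_p)))
            p = float(rng.random()) ** 3
            pvals.append(p)
            fdrs.append(min(1.0, p * float(rng.uniform(1.0, 5.0))))
            truth_trans.append(hub_range.chrom != enhancers.ranges[enh_idx].chrom)
    iset = InteractionSet(
        a1, a2, counts, {"p_value": pvals, "fdr": fdrs}
    )
    return iset, truth


def _make_cis_partner(rng, config: FixtureConfig, first: GenomicRange) -> GenomicRange:
    size = config.chrom_sizes[first.chrom]
    wlo, whi = config.anchor_width_range
    width = int(rng.integers(wlo, whi + 1))
    offset = _pareto_distance(rng, config)
    direction = 1 if rng.random() < 0.5 else -1
    start = first.start + direction * offset
    start = max(1, min(start, max(1, size - width)))
    return GenomicRange(first.chrom, start, start + width - 1)


def generate_feature_sets(config: FixtureConfig) -> list:
    """Ordered feature sets per ``feature_spec`` (order = priority).

    Ids are ``<class>_<k>`` (1-based). With ``inject_overlaps``, the first
    feature of each non-first class is moved to overlap the first feature
    of the first class, exercising the priority rules.
    """
    rng = _rng(config)
    sets = []
    for name, (n, (wlo, whi)) in config.feature_spec.items():
        ranges, ids = [], []
        for k in range(1, n + 1):
            width = int(rng.integers(wlo, whi + 1))
            chrom = _pick_chrom(rng, config.chrom_sizes, min_size=width + 2)
            start = int(rng.integers(1, config.chrom_sizes[chrom] - width))
            ranges.append(GenomicRange(chrom, start, start + width - 1))
            ids.append(f"{name}_{k}")
        sets.append(FeatureSet(name, ranges, ids))
    if config.inject_overlaps and len(sets) > 1 and len(sets[0]):
        target = sets[0].ranges[0]
        for fs in sets[1:]:
            if not fs.ranges:
                continue
            width = fs.ranges[0].width
            start = max(1, target.midpoint - width // 2)
            fs.ranges[0] = GenomicRange(
                target.chrom, start, start + width - 1
            )
    return sets


# ---------------------------------------------------------------------------
# dialect writers (fixtures only; the library itself only READS these)


_HOMER_HEADER = [
    "InteractionID",
    "chr(1)", "start(1)", "end(1)", "strand(1)",
    "chr(2)", "start(2)", "end(2)", "strand(2)",
    "Interaction Reads", "Expected Reads", "Z-score", "LogP", "FDR",
]


def write_homer_fixture(iset: InteractionSet, path) -> None:
    """Write a synthetic HOMER-dialect interaction table (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HOMER_HEADER) + "\n")
        for i in range(len(iset)):
            a, b = iset.anchor_one[i], iset.anchor_two[i]
            p = float(iset.metadata.get("p_value", [0.5] * len(iset))[i])
            fdr = float(iset.metadata.get("fdr", [0.5] * len(iset))[i])
            logp = float(np.log(max(p, 1e-300)))
            fh.write(
                "\t".join(
                    [
                        f"interaction_{i + 1}",
                        a.chrom, str(a.start), str(a.end), "+",
                        b.chrom, str(b.start), str(b.end), "+",
                        str(iset.counts[i]),
                        repr(round(iset.counts[i] / 2.0, 3)),
                        "1.0", repr(logp), repr(fdr),
                    ]
                )
                + "\n"
            )


def write_chiapet_fixture(iset: InteractionSet, path) -> None:
    """Write a synthetic ChIA-PET-tool-dialect table (1-based closed)."""
    n = len(iset)
    pvals = iset.metadata.get("p_value", [0.5] * n)
    fdrs = iset.metadata.get("fdr", [0.5] * n)
    with open(path, "w") as fh:
        for i in range(n):
            a, b = iset.anchor_one[i], iset.anchor_two[i]
            fh.write(
                "\t".join(
                    [
                        a.chrom, str(a.start), str(a.end),
                        b.chrom, str(b.start), str(b.end),
                        str(iset.counts[i]),
                        repr(float(pvals[i])), repr(float(fdrs[i])),
                    ]
                )
                + "\n"
            )


def write_feature_bed(fs: FeatureSet, path) -> None:
    """Write a feature set as BED (0-based half-open, id in column 4)."""
    with open(path, "w") as fh:
        for rng_, fid in zip(fs.ranges, fs.ids):
            fh.write(f"{rng_.chrom}\t{rng_.start - 1}\t{rng_.end}\t{fid}\n")


def write_fixture_files(config: FixtureConfig, directory) -> dict:
    """Generate everything and write one file per supported dialect.

    Writes tag pairs (bedpe), interactions (bedpe, HOMER dialect,
    ChIA-PET-tool dialect), one BED per feature class, a ground-truth JSON
    and a manifest TSV. Returns the manifest as a dict; reading each file
    back reproduces the in-memory objects.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tags = generate_tag_pairs(config)
    feature_sets = generate_feature_sets(config)
    iset, truth = generate_interactions(config, feature_sets)
    iset = iset.sort()

    manifest = {}

    tags_path = directory / "tag_pairs.bedpe"
    write_tag_pairs_bedpe(tags, tags_path)
    manifest["tag_pairs_bedpe"] = str(tags_path)

    bedpe_path = directory / "interactions.bedpe"
    write_bedpe(iset, bedpe_path)
    manifest["interactions_bedpe"] = str(bedpe_path)

    homer_path = directory / "interactions_homer.txt"
    write_homer_fixture(iset, homer_path)
    manifest["interactions_homer"] = str(homer_path)

    chiapet_path = directory / "interactions_chiapet.txt"
    write_chiapet_fixture(iset, chiapet_path)
    manifest["interactions_chiapet"] = str(chiapet_path)

    for fs in feature_sets:
        p = directory / f"features_{fs.name}.bed"
        write_feature_bed(fs, p)
        manifest[f"features_{fs.name}_bed"] = str(p)

    truth_path = directory / "ground_truth.json"
    truth_out = dict(truth)
    truth_out.update(
        {
            "self_ligation_distance": config.self_ligation_distance,
            "self_fraction": config.self_fraction,
            "n_tag_pairs": len(tags),
            "feature_order": [fs.name for fs in feature_sets],
        }
    )
    with open(truth_path, "w") as fh:
        json.dump(truth_out, fh, indent=1)
    manifest["ground_truth"] = str(truth_path)

    manifest_path = directory / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("role\tpath\n")
        for role in sorted(manifest):
            fh.write(f"{role}\t{manifest[role]}\n")
    manifest["manifest"] = str(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# flat key=value config files


def load_config(path) -> FixtureConfig:
    """FixtureConfig from a flat ``key = value`` file.

    ``chrom_sizes`` uses ``chr1:5000000,chr2:4000000``; ``feature_spec``
    uses ``promoter:30:1000:3000,enhancer:40:500:1500``; booleans are
    true/false; everything else is int or float by inspection.
    """
    kwargs: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}: bad config line {raw!r}")
            key, value = (x.strip() for x in line.split("=", 1))
            if key == "chrom_sizes":
                kwargs[key] = {
                    part.split(":")[0]: int(part.split(":")[1])
                    for part in value.split(",")
                }
            elif key == "feature_spec":
                spec = {}
                for part in value.split(","):
                    name, n, wlo, whi = part.split(":")
                    spec[name] = (int(n), (int(wlo), int(whi)))
                kwargs[key] = spec
            elif key == "anchor_width_range":
                lo, hi = value.split(":")
                kwargs[key] = (int(lo), int(hi))
            elif value.lower() in ("true", "false"):
                kwargs[key] = value.lower() == "true"
            else:
                try:
                    kwargs[key] = int(value)
                except ValueError:
                    kwargs[key] = float(value)
    return FixtureConfig(**kwargs)
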