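"""Detection of recombination warm spots and their genomic context.

A warm spot is a 0.5-7 kb region in which every inter-SNP interval's rho is
at least ``fold_threshold`` times the chromosome-arm background (the
length-weighted mean rho of the whole arm).  Detected spots are annotated
with overlapping genes and with the pairwise population comparisons whose
divergent regions they intersect.
"""

from __future__ import annotations

import numpy as np
from intervaltree import IntervalTree

from .core import (
    DivergentRegionSet,
    GeneAnnotation,
    IntervalRateMap,
    RhoscapeError,
    WarmSpot,
    merge_intervals,
)

FOLD_THRESHOLD = 10.0
MIN_LEN = 500
MAX_LEN = 7_000


def chromosome_background(rate_map: IntervalRateMap) -> float:
    """Length-weighted mean rho/bp over the whole arm."""
    lengths = rate_map.lengths
    total = lengths.sum()
    if total <= 0:
        raise RhoscapeError(f"{rate_map.arm}: empty map")
    return float((rate_map.rho * lengths).sum() / total)


def scan_warmspots(
    rate_map: IntervalRateMap,
    fold_threshold: float = FOLD_THRESHOLD,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    strict: bool = False,
) -> list[WarmSpot]:
    """Scan an interval map for warm spots.

    Maximal runs of consecutive (abutting) intervals whose rho all meet the
    threshold are formed; runs shorter than ``min_len`` are discarded, runs
    longer than ``max_len`` are split left-to-right at interval boundaries
    into segments of at most ``max_len`` (a single interval longer than
    ``max_len`` is cut at exactly ``max_len``), and each retained segment is
    re-checked against ``min_len``.  ``strict`` demands rho strictly greater
    than the threshold instead of >=.
    """
    if fold_threshold <= 1:
        raise RhoscapeError("fold_threshold must exceed 1")
    background = chromosome_background(rate_map)
    cutoff = fold_threshold * background
    above = rate_map.rho > cutoff if strict else rate_map.rho >= cutoff

    spots: list[WarmSpot] = []
    i, n = 0, len(rate_map)
    while i < n:
        if not above[i]:
            i += 1
            continue
        # maximal run of consecutive abutting above-threshold intervals
        j = i
        while (
            j + 1 < n
            and above[j + 1]
            and rate_map.starts[j + 1] == rate_map.ends[j]
        ):
            j += 1
        run = list(range(i, j + 1))
        spots.extend(
            _segments_from_run(rate_map, run, background, min_len, max_len)
        )
        i = j + 1
    spots.sort(key=lambda s: s.start)
    return spots


def _segments_from_run(
    rate_map: IntervalRateMap,
    run: list[int],
    background: float,
    min_len: int,
    max_len: int,
) -> list[WarmSpot]:
    """Split one above-threshold run into reported segments."""
    segments: list[tuple[int, int]] = []  # (start, end) in bp
    seg_start = int(rate_map.starts[run[0]])
    seg_end = seg_start
    for idx in run:
        s, e = int(rate_map.starts[idx]), int(rate_map.ends[idx])
        if e - s > max_len:
            # flush current segment, then cut the oversized interval itself
            if seg_end > seg_start:
                segments.append((seg_start, seg_end))
            pos = s
            while e - pos > max_len:
                segments.append((pos, pos + max_len))
                pos += max_len
            seg_start, seg_end = pos, e
        elif seg_end - seg_start + (e - s) > max_len:
            segments.append((seg_start, seg_end))
            seg_start, seg_end = s, e
        else:
            seg_end = e
    if seg_end > seg_start:
        segments.append((seg_start, seg_end))

    out = []
    for start, end in segments:
        if not (min_len <= end - start <= max_len):
            continue
        mask = (rate_map.starts < end) & (rate_map.ends > start)
        overlap = np.minimum(rate_map.ends[mask], end) - np.maximum(
            rate_map.starts[mask], start
        )
        mean_rho = float(
            (rate_map.rho[mask] * overlap).sum() / overlap.sum()
        )
        out.append(
            WarmSpot(
                arm=rate_map.arm,
                start=start,
                end=end,
                mean_rho=mean_rho,
                fold=mean_rho / background,
            )
        )
    return out


def annotate_genes(spots: list[WarmSpot], annotation: GeneAnnotation) -> list[WarmSpot]:
    """Attach overlapping gene names in genomic order.

    "Intergenic" is appended whenever any part of the spot is covered by no
    gene; a spot overlapping nothing gets ["Intergenic"] alone.
    """
    for spot in spots:
        genes = annotation.genes_on(spot.arm)
        hit = [
            (name, g_start, g_end)
            for (name, g_start, g_end) in genes
            if g_start < spot.end and g_end > spot.start
        ]
        hit.sort(key=lambda g: (g[1], g[2]))
        labels = [name for name, _s, _e in hit]
        covered = merge_intervals(
            [(max(s, spot.start), min(e, spot.end)) for _n, s, e in hit]
        )
        covered_bp = sum(e - s for s, e in covered)
        if covered_bp < spot.length:
            labels.append("Intergenic")
        spot.genes = labels
    return spots


def overlap_divergent(
    spots: list[WarmSpot], sets: list[DivergentRegionSet]
) -> list[WarmSpot]:
    """Attach every comparison label whose regions share >= 1 bp with a spot."""
    trees = {}
    for rset in sets:
        tree = IntervalTree()
        for s, e in rset.intervals:
            tree[s:e] = rset.comparison
        trees[rset.comparison] = tree
    for spot in spots:
        labels = [
            label for label, tree in trees.items() if tree.overlap(spot.start, spot.end)
        ]
        # render in the canonical comparison order
        order = {"C vs W": 0, "C vs T": 1, "W vs T": 2}
        spot.divergent_overlaps = sorted(labels, key=lambda l: order[l])
    return spots
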