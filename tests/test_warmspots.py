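"""Warm-spot scanning, gene annotation and divergent-region overlap."""

import numpy as np
import pytest

from rhoscape.core import (
    DivergentRegionSet,
    GeneAnnotation,
    IntervalRateMap,
    RhoscapeError,
    WarmSpot,
)
from rhoscape.warmspots import (
    annotate_genes,
    chromosome_background,
    overlap_divergent,
    scan_warmspots,
)
from tests.conftest import random_interval_map


def oracle_scan(rate_map, fold_threshold=10.0, min_len=500, max_len=7000):
    """Exhaustive oracle: enumerate maximal above-threshold runs, then filter.

    Runs are collected as lists of bp pieces (closing on any below-threshold
    or non-abutting interval); each run is split greedily left-to-right into
    bp segments of at most ``max_len`` (oversized single pieces cut at
    exactly ``max_len``), then length-filtered.
    """
    lengths = rate_map.lengths
    background = float((rate_map.rho * lengths).sum() / lengths.sum())
    cutoff = fold_threshold * background

    runs: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for s, e, r in zip(rate_map.starts, rate_map.ends, rate_map.rho):
        s, e = int(s), int(e)
        if r >= cutoff:
            if current and current[-1][1] != s:
                runs.append(current)
                current = []
            current.append((s, e))
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    spots = []
    for run in runs:
        segments = []
        seg_s = seg_e = run[0][0]
        for s, e in run:
            if e - s > max_len:
                if seg_e > seg_s:
                    segments.append((seg_s, seg_e))
                pos = s
                while e - pos > max_len:
                    segments.append((pos, pos + max_len))
                    pos += max_len
                seg_s, seg_e = pos, e
            elif (seg_e - seg_s) + (e - s) > max_len:
                segments.append((seg_s, seg_e))
                seg_s, seg_e = s, e
            else:
                seg_e = e
        if seg_e > seg_s:
            segments.append((seg_s, seg_e))
        spots.extend((s, e) for s, e in segments if min_len <= e - s <= max_len)
    return sorted(spots)


class TestBackground:
    def test_uniform_map(self):
        m = IntervalRateMap("2L", "", starts=[0, 100], ends=[100, 300], rho=[0.5, 0.5])
        assert chromosome_background(m) == pytest.approx(0.5)

    def test_length_weighted(self):
        m = IntervalRateMap("2L", "", starts=[0, 100], ends=[100, 400], rho=[1.0, 5.0])
        assert chromosome_background(m) == pytest.approx(4.0)


def _flat_map_with_run(run_start=20_000, run_end=21_000, elevated=0.02,
                       background=0.001, span=100_000, piece=500):
    """Uniform map with one elevated run, pieces every `piece` bp."""
    bounds = sorted({0, run_start, run_end, span} | {
        p for p in range(0, span, piece)
    })
    starts, ends, rho = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        starts.append(a)
        ends.append(b)
        rho.append(elevated if run_start <= a and b <= run_end else background)
    return IntervalRateMap("2L", "", starts=starts, ends=ends, rho=rho)


class TestScanner:
    def test_uniform_map_has_no_spots(self):
        m = IntervalRateMap("2L", "", starts=[0, 1000], ends=[1000, 2000], rho=[1.0, 1.0])
        assert scan_warmspots(m) == []

    def test_single_run_detected_with_exact_boundaries(self):
        m = _flat_map_with_run()
        spots = scan_warmspots(m)
        assert len(spots) == 1
        sp = spots[0]
        assert (sp.start, sp.end, sp.length) == (20_000, 21_000, 1000)
        assert sp.fold == pytest.approx(0.02 / chromosome_background(m))
        assert sp.fold > 10

    def test_run_shorter_than_min_len_discarded(self):
        m = _flat_map_with_run(run_start=20_000, run_end=20_400)
        assert scan_warmspots(m) == []

    def test_long_run_split_at_interval_boundaries(self):
        # one 1463-bp piece abutting a 6246-bp piece: split yields both,
        # mirroring two published abutting entries (1463 + 6246 = 7709 > 7000)
        m = IntervalRateMap(
            "2R", "",
            starts=[0, 25_266_512, 25_267_975, 25_274_221],
            ends=[25_266_512, 25_267_975, 25_274_221, 27_000_000],
            rho=[0.001, 0.05, 0.05, 0.001],
        )
        spots = scan_warmspots(m)
        assert [(s.start, s.end, s.length) for s in spots] == [
            (25_266_512, 25_267_975, 1463),
            (25_267_975, 25_274_221, 6246),
        ]

    def test_max_len_boundary_inclusive(self):
        m = _flat_map_with_run(run_start=20_000, run_end=27_000, span=1_000_000)
        spots = scan_warmspots(m)
        assert len(spots) == 1 and spots[0].length == 7000

    def test_fold_threshold_at_most_one_rejected(self):
        m = _flat_map_with_run()
        with pytest.raises(RhoscapeError, match="exceed 1"):
            scan_warmspots(m, fold_threshold=1.0)

    def test_strict_mode_excludes_equality(self):
        m = IntervalRateMap(
            "2L", "",
            starts=[0, 50_000, 51_000],
            ends=[50_000, 51_000, 102_000],
            rho=[0.001, 0.0, 0.001],
        )
        # craft rho so one piece sits exactly at 10x background
        bg = chromosome_background(m)
        rho = m.rho.copy()
        rho[1] = 10 * chromosome_background(
            IntervalRateMap("2L", "", starts=m.starts, ends=m.ends, rho=rho)
        )
        # iterate once more so the elevated piece is exactly 10x final background
        for _ in range(50):
            m2 = IntervalRateMap("2L", "", starts=m.starts, ends=m.ends, rho=rho)
            rho[1] = 10 * chromosome_background(m2)
        m2 = IntervalRateMap("2L", "", starts=m.starts, ends=m.ends, rho=rho)
        assert len(scan_warmspots(m2, strict=False)) == 1
        assert scan_warmspots(m2, strict=True) == []

    @pytest.mark.parametrize("seed", range(40))
    def test_equals_exhaustive_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        m = random_interval_map(rng, n_intervals=80, gaps=bool(seed % 2))
        # sprinkle elevated pieces to create candidate runs
        rho = m.rho.copy()
        hot = rng.random(len(rho)) < 0.15
        rho[hot] *= 40
        m = IntervalRateMap(m.arm, m.population, m.starts, m.ends, rho)
        got = [(s.start, s.end) for s in scan_warmspots(m)]
        assert got == oracle_scan(m)

    def test_monotone_in_fold_threshold(self, rng):
        m = random_interval_map(rng, 80)
        rho = m.rho.copy()
        rho[rng.random(len(rho)) < 0.2] *= 30
        m = IntervalRateMap(m.arm, m.population, m.starts, m.ends, rho)
        counts = [len(scan_warmspots(m, fold_threshold=f)) for f in (5, 8, 10, 15, 25)]
        assert counts == sorted(counts, reverse=True)

    def test_monotone_in_length_window(self, rng):
        m = random_interval_map(rng, 80)
        rho = m.rho.copy()
        rho[rng.random(len(rho)) < 0.2] *= 30
        m = IntervalRateMap(m.arm, m.population, m.starts, m.ends, rho)
        narrow = len(scan_warmspots(m, min_len=800, max_len=4000))
        wide = len(scan_warmspots(m, min_len=500, max_len=7000))
        assert wide >= narrow

    def test_reported_lengths_within_bounds(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            m = random_interval_map(r, 60)
            rho = m.rho.copy()
            rho[r.random(len(rho)) < 0.25] *= 35
            m = IntervalRateMap(m.arm, m.population, m.starts, m.ends, rho)
            for sp in scan_warmspots(m):
                assert sp.length == sp.end - sp.start
                assert 500 <= sp.length <= 7000


class TestAnnotateGenes:
    def _ann(self):
        return GeneAnnotation(
            genes=[("geneA", "2L", 100, 400), ("geneB", "2L", 600, 900)],
            exons=[],
        )

    def test_spot_outside_genes_is_intergenic(self):
        spots = [WarmSpot("2L", 1000, 1600, 0.1, 15.0)]
        annotate_genes(spots, self._ann())
        assert spots[0].genes == ["Intergenic"]
        assert spots[0].genes_label() == "Intergenic"

    def test_two_genes_with_gap_lists_both_plus_intergenic(self):
        spots = [WarmSpot("2L", 200, 800, 0.1, 15.0)]
        annotate_genes(spots, self._ann())
        assert spots[0].genes == ["geneA", "geneB", "Intergenic"]

    def test_matches_per_bp_labeling_oracle(self, rng):
        genes = []
        pos = 0
        for i in range(10):
            pos += int(rng.integers(100, 500))
            end = pos + int(rng.integers(100, 800))
            genes.append((f"g{i}", "2L", pos, end))
            pos = end
        ann = GeneAnnotation(genes=genes, exons=[])
        for _ in range(20):
            start = int(rng.integers(0, pos - 700))
            spot = WarmSpot("2L", start, start + 700, 0.1, 15.0)
            annotate_genes([spot], ann)
            # per-bp oracle
            per_bp = {}
            for name, _a, s, e in [(n, a, s, e) for n, a, s, e in genes]:
                for bp in range(max(s, spot.start), min(e, spot.end)):
                    per_bp[bp] = name
            expected = []
            for name, _arm, s, e in genes:
                if any(per_bp.get(bp) == name for bp in range(spot.start, spot.end)):
                    expected.append(name)
            if len(per_bp) < spot.length:
                expected.append("Intergenic")
            assert spot.genes == expected

    def test_fully_contained_spot_no_intergenic(self):
        spots = [WarmSpot("2L", 150, 350, 0.1, 15.0)]
        annotate_genes(spots, self._ann())
        assert spots[0].genes == ["geneA"]


class TestOverlapDivergent:
    def test_no_sets_renders_none(self):
        spots = [WarmSpot("2L", 100, 600, 0.1, 15.0)]
        overlap_divergent(spots, [])
        assert spots[0].divergent_overlaps == []
        assert spots[0].divergent_label() == "None"

    def test_single_bp_overlap_attaches_label(self):
        spots = [WarmSpot("2L", 100, 600, 0.1, 15.0)]
        sets = [DivergentRegionSet("C vs W", ((599, 700),))]
        overlap_divergent(spots, sets)
        assert spots[0].divergent_overlaps == ["C vs W"]

    def test_abutting_interval_does_not_attach(self):
        spots = [WarmSpot("2L", 100, 600, 0.1, 15.0)]
        sets = [DivergentRegionSet("C vs W", ((600, 700),))]
        overlap_divergent(spots, sets)
        assert spots[0].divergent_label() == "None"

    def test_labels_rendered_in_canonical_order(self):
        spots = [WarmSpot("2L", 100, 600, 0.1, 15.0)]
        sets = [
            DivergentRegionSet("W vs T", ((0, 200),)),
            DivergentRegionSet("C vs T", ((500, 900),)),
        ]
        overlap_divergent(spots, sets)
        assert spots[0].divergent_label() == "C vs T, W vs T"

    def test_matches_brute_force_intersection(self, rng):
        spots = [
            WarmSpot("2L", int(s), int(s) + 600, 0.1, 15.0)
            for s in rng.integers(0, 50_000, size=15)
        ]
        sets = []
        for label in ("C vs W", "C vs T", "W vs T"):
            ivs = []
            for _ in range(5):
                a = int(rng.integers(0, 50_000))
                ivs.append((a, a + int(rng.integers(100, 2000))))
            sets.append(DivergentRegionSet(label, tuple(ivs)))
        overlap_divergent(spots, sets)
        for sp in spots:
            expected = sorted(
                {
                    rset.comparison
                    for rset in sets
                    for s, e in rset.intervals
                    if s < sp.end and e > sp.start
                },
                key=["C vs W", "C vs T", "W vs T"].index,
            )
            assert sp.divergent_overlaps == expected
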