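"""The synthetic study system: known structure in, same structure out."""

import dataclasses

import numpy as np
import pytest

from rhoscape.core import RhoscapeError, WarmSpot
from rhoscape.synthetic import (
    SyntheticConfig,
    gen_correlated_tracks,
    gen_divergent_regions,
    gen_feature_tracks,
    gen_gene_annotation,
    gen_interval_map,
)
from rhoscape.wavelet import decompose_track, scale_pearson
from rhoscape.windowing import log_transform


def _config(**kw) -> SyntheticConfig:
    defaults = dict(
        arm_lengths={"2L": 3_200_000},
        n_scales=6,
        per_scale_weights=(0.5,) * 6,
        seed=11,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def _detail_correlations(config, n_pop=2):
    """Per-scale Pearson correlation of the two populations' log-track details."""
    tracks = gen_correlated_tracks(config, n_populations=n_pop)
    arm = next(iter(tracks))
    d = [decompose_track(log_transform(t)) for t in tracks[arm][:2]]
    return scale_pearson(d[0], d[1]), d


class TestCorrelatedTracks:
    def test_full_sharing_gives_identical_details(self):
        cfg = _config(per_scale_weights=(1.0,) * 6)
        corr, d = _detail_correlations(cfg)
        for s in range(1, 7):
            np.testing.assert_allclose(d[0].details[s], d[1].details[s], atol=1e-9)
            assert corr[s] == pytest.approx(1.0)

    def test_zero_sharing_gives_near_zero_tau(self):
        from tests.conftest import brute_kendall_b

        cfg = _config(
            arm_lengths={"2L": 25_000 * 4096}, per_scale_weights=(0.0,) * 6, seed=5
        )
        _corr, d = _detail_correlations(cfg)
        for s in range(1, 7):
            n_coef = len(d[0].details[s])
            if n_coef >= 64:
                tau = brute_kendall_b(d[0].details[s][:256], d[1].details[s][:256])
                assert abs(tau) < 3 / np.sqrt(min(n_coef, 256))

    def test_weight_recovery_mean_over_seeds(self):
        """Mean per-scale detail correlation over replicate seeds ~= w_s."""
        w = 0.6
        estimates = {s: [] for s in range(1, 7)}
        for seed in range(10):
            cfg = _config(
                arm_lengths={"2L": 25_000 * 4096},
                per_scale_weights=(w,) * 6,
                seed=seed,
            )
            corr, d = _detail_correlations(cfg)
            for s in range(1, 7):
                if len(d[0].details[s]) >= 64:
                    estimates[s].append(corr[s])
        for s, vals in estimates.items():
            if vals:
                assert np.mean(vals) == pytest.approx(w, abs=0.1)

    def test_values_strictly_positive_and_mean_scaled(self):
        cfg = _config(background_rho=0.02)
        tracks = gen_correlated_tracks(cfg, 3)
        for t in tracks["2L"]:
            assert np.all(t.values > 0)
            assert t.values.mean() == pytest.approx(0.02, rel=1e-9)

    def test_bad_weight_rejected(self):
        with pytest.raises(RhoscapeError, match=r"\[0, 1\]"):
            _config(per_scale_weights=(1.5,) * 6).validate()

    def test_arm_shorter_than_dyadic_range_rejected(self):
        with pytest.raises(RhoscapeError, match="2\\^n_scales"):
            _config(arm_lengths={"2L": 1_000_000}).validate()


class TestIntervalMap:
    def test_constant_base_gives_constant_rho(self):
        from tests.conftest import constant_track

        cfg = _config()
        m = gen_interval_map(cfg, constant_track(0.01, n_bins=128))
        np.testing.assert_allclose(m.rho, 0.01)
        assert m.span == (0, 128 * 25_000)

    def test_warm_spot_overwrites_exactly(self):
        from tests.conftest import constant_track

        cfg = _config(warm_spots=(("2L", 20_000, 21_000, 15.0),))
        m = gen_interval_map(cfg, constant_track(0.01, n_bins=128))
        inside = (m.starts >= 20_000) & (m.ends <= 21_000)
        np.testing.assert_allclose(m.rho[inside], 0.15)
        np.testing.assert_allclose(m.rho[~inside], 0.01)
        # spot boundaries are forced SNP positions: no interval straddles them
        assert not np.any((m.starts < 20_000) & (m.ends > 20_000))
        assert not np.any((m.starts < 21_000) & (m.ends > 21_000))

    def test_same_seed_identical_maps(self, tmp_path):
        from rhoscape.track_io import write_ldhelmet_post

        cfg = _config(seed=7)
        tracks = gen_correlated_tracks(cfg, 1)
        m1 = gen_interval_map(cfg, tracks["2L"][0])
        m2 = gen_interval_map(cfg, tracks["2L"][0])
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_ldhelmet_post(m1, p1)
        write_ldhelmet_post(m2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sorted_nonoverlapping_gap_free(self):
        cfg = _config(seed=3)
        tracks = gen_correlated_tracks(cfg, 1)
        m = gen_interval_map(cfg, tracks["2L"][0])
        assert np.all(m.starts[1:] == m.ends[:-1])  # gap-free
        assert np.all(m.rho > 0)

    def test_spot_outside_span_rejected(self):
        from tests.conftest import constant_track

        cfg = _config(warm_spots=(("2L", 3_100_000, 3_101_000, 15.0),))
        with pytest.raises(RhoscapeError, match="outside"):
            gen_interval_map(cfg, constant_track(0.01, n_bins=64))  # span 1.6 Mb


class TestFeatureTracks:
    def _rate(self, n=512, seed=1):
        rng = np.random.default_rng(seed)
        from rhoscape.core import WindowedTrack

        return WindowedTrack("2L", 25_000, values=rng.gamma(2, 0.01, n), units="rho/bp")

    def test_zero_coupling_near_zero_correlation(self):
        cfg = _config(diversity_coupling=0.0, arm_lengths={"2L": 25_000 * 4096})
        div, _g, _d = gen_feature_tracks(cfg, self._rate(4096))
        r = np.corrcoef(div.values, self._rate(4096).values)[0, 1]
        assert abs(r) < 3 / np.sqrt(4096)

    def test_full_coupling_rank_correlation_one(self):
        from scipy import stats

        cfg = _config(diversity_coupling=1.0)
        rate = self._rate(256)
        div, _g, _d = gen_feature_tracks(cfg, rate)
        assert stats.spearmanr(div.values, rate.values).statistic == pytest.approx(1.0)

    def test_half_coupling_recovered_over_seeds(self):
        cfg0 = _config(diversity_coupling=0.5, arm_lengths={"2L": 25_000 * 4096})
        rs = []
        for seed in range(20):
            cfg = dataclasses.replace(cfg0, seed=seed)
            rate = self._rate(4096, seed=seed)
            div, _g, _d = gen_feature_tracks(cfg, rate)
            rs.append(np.corrcoef(div.values, rate.values)[0, 1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.08)

    def test_ranges_and_positivity(self):
        cfg = _config()
        div, gene, depth = gen_feature_tracks(cfg, self._rate())
        assert np.all(div.values > 0)
        assert np.all((gene.values >= 0) & (gene.values <= 1))
        assert np.all(depth.values > 0)

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(RhoscapeError, match="diversity_coupling"):
            _config(diversity_coupling=1.2).validate()


def _spots(n, arm="2L", spacing=150_000, length=2_000):
    return [
        WarmSpot(arm=arm, start=spacing * (i + 1), end=spacing * (i + 1) + length,
                 mean_rho=0.1, fold=15.0)
        for i in range(n)
    ]


class TestDivergentRegions:
    def _covered(self, spots, sets_per_arm):
        """Brute-force: which spots intersect >= 1 interval of any set."""
        covered = []
        for sp in spots:
            hit = any(
                s < sp.end and e > sp.start
                for rset in sets_per_arm.get(sp.arm, [])
                for s, e in rset.intervals
            )
            covered.append(hit)
        return covered

    def test_fraction_zero_no_overlap(self):
        cfg = _config(divergent_overlap_fraction=0.0)
        spots = _spots(8)
        sets = gen_divergent_regions(cfg, spots)
        assert not any(self._covered(spots, sets))

    def test_fraction_one_all_covered(self):
        cfg = _config(divergent_overlap_fraction=1.0)
        spots = _spots(8)
        sets = gen_divergent_regions(cfg, spots)
        assert all(self._covered(spots, sets))

    def test_fraction_half_exact_count(self):
        cfg = _config(divergent_overlap_fraction=0.5, arm_lengths={"2L": 4_000_000})
        spots = _spots(20)
        sets = gen_divergent_regions(cfg, spots)
        assert sum(self._covered(spots, sets)) == 10

    def test_labels_closed_and_intervals_sorted(self):
        cfg = _config(divergent_overlap_fraction=0.7)
        sets = gen_divergent_regions(cfg, _spots(10))
        for rsets in sets.values():
            labels = [r.comparison for r in rsets]
            assert labels == ["C vs W", "C vs T", "W vs T"]
            for r in rsets:
                assert list(r.intervals) == sorted(r.intervals)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(RhoscapeError, match="fraction"):
            _config(divergent_overlap_fraction=1.5).validate()


class TestGeneAnnotation:
    def test_exons_inside_genes_and_deterministic(self):
        cfg = _config(seed=9)
        g1 = gen_gene_annotation(cfg)
        g2 = gen_gene_annotation(cfg)
        assert g1.genes == g2.genes and g1.exons == g2.exons
        genes = g1.genes_on("2L")
        for s, e in g1.exons_on("2L"):
            assert any(gs <= s and e <= ge for _n, gs, ge in genes)
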