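"""Synthetic recombination landscapes with known multiscale structure.

Every downstream stage (windowing, wavelet correlation, warm-spot scanning,
divergent-region overlap) is exercised on data from this module, so the
generative model is chosen to make the quantities those stages estimate
*known by construction*:

* Log-rate tracks are built by inverse orthonormal Haar synthesis.  At each
  dyadic scale ``s`` the detail coefficients of population ``p`` are
  ``d_p = sqrt(w_s) * z_shared + sqrt(1 - w_s) * z_p`` with independent
  standard normals, so the expected per-scale correlation between any two
  populations is exactly ``w_s``.  Scales coarser than the configured range
  are fully shared, mimicking broad-scale conservation of the landscape.
* Tracks are exponentiated and scaled to a target mean rho/bp, so the
  downstream log transform recovers a near-Gaussian field.
* Piecewise-constant interval maps are built over a Poisson SNP process;
  configured warm spots overwrite covered intervals at a known fold over the
  arm background, with spot boundaries forced onto SNP positions so exact
  recovery is well defined.
* Divergent-region sets cover a configured fraction of the injected spots.

What this does not emulate: coalescent noise in the rate estimates, real
gene structure, or selection; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .core import (
    COMPARISON_LABELS,
    DivergentRegionSet,
    GeneAnnotation,
    IntervalRateMap,
    RhoscapeError,
    WarmSpot,
    WindowedTrack,
)

DEFAULT_ARMS = {"2L": 23_000_000, "2R": 23_000_000, "3L": 23_000_000,
                "3R": 23_000_000, "X": 23_000_000}

# substream codes keep every stage's randomness independent of the others
_STREAMS = {"tracks": 1, "snps": 2, "features": 3, "divergent": 4, "genes": 5}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Defaults emulate three experimentally evolved populations scored on five
    chromosome arms: 25-kb analysis bins, SNP density matching a Watterson
    theta of about 0.001/bp, and per-scale sharing that rises from fine to
    broad scales (fine-scale divergence, broad-scale conservation).
    ``log_sd`` sets the standard deviation of the log-rate field; the
    default 0.5 gives realistic smooth heterogeneity in which 10-fold
    exceedances of the arm mean essentially never arise from the background
    field, so every warm spot in a synthetic map is an injected one.
    """

    arm_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ARMS))
    bin_bp: int = 25_000
    n_scales: int = 6
    per_scale_weights: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    diversity_coupling: float = 0.5
    background_rho: float = 0.01
    log_sd: float = 0.5
    snp_density: float = 0.001
    warm_spots: tuple[tuple[str, int, int, float], ...] = ()
    divergent_overlap_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if any(l <= 0 for l in self.arm_lengths.values()):
            raise RhoscapeError("arm lengths must be positive")
        if self.bin_bp <= 0:
            raise RhoscapeError("bin_bp must be positive")
        if len(self.per_scale_weights) != self.n_scales:
            raise RhoscapeError(
                f"need {self.n_scales} per-scale weights, got {len(self.per_scale_weights)}"
            )
        if any(not (0.0 <= w <= 1.0) for w in self.per_scale_weights):
            raise RhoscapeError("per-scale weights must lie in [0, 1]")
        if not (-1.0 <= self.diversity_coupling <= 1.0):
            raise RhoscapeError("diversity_coupling must lie in [-1, 1]")
        if self.snp_density <= 0:
            raise RhoscapeError("snp_density must be positive")
        if self.log_sd <= 0:
            raise RhoscapeError("log_sd must be positive")
        if not (0.0 <= self.divergent_overlap_fraction <= 1.0):
            raise RhoscapeError("divergent_overlap_fraction must lie in [0, 1]")
        min_len = self.bin_bp * (1 << self.n_scales)
        for arm, length in self.arm_lengths.items():
            if length < min_len:
                raise RhoscapeError(
                    f"arm {arm}: length {length} < bin_bp * 2^n_scales = {min_len}"
                )
        for arm, start, end, fold in self.warm_spots:
            if arm not in self.arm_lengths:
                raise RhoscapeError(f"warm spot on unknown arm {arm}")
            if not (0 <= start < end <= self.arm_lengths[arm]):
                raise RhoscapeError(f"warm spot ({arm}, {start}, {end}) outside arm")
            if fold <= 1:
                raise RhoscapeError("warm-spot fold must exceed 1")

    def rng(self, stream: str, *keys: int) -> np.random.Generator:
        """Deterministic substream: one generator per (stage, arm, population)."""
        return np.random.default_rng([self.seed, _STREAMS[stream], *keys])

    def spots_on(self, arm: str) -> list[tuple[int, int, float]]:
        return [(s, e, f) for a, s, e, f in self.warm_spots if a == arm]


# ---------------------------------------------------------------------------
# correlated log-rate tracks
# ---------------------------------------------------------------------------

def _synthesize_field(
    rng_shared: np.random.Generator,
    rng_pop: list[np.random.Generator],
    n_bins: int,
    n_scales: int,
    weights: tuple[float, ...],
) -> list[np.ndarray]:
    """Inverse-Haar synthesis of one log field per population."""
    m = int(np.ceil(np.log2(n_bins)))
    n_pop = len(rng_pop)
    # details[s] has 2^(m-s) coefficients; scales above n_scales fully shared
    per_pop_details: list[list[np.ndarray]] = [[] for _ in range(n_pop)]
    for s in range(1, m + 1):
        n_coef = 1 << (m - s)
        z_shared = rng_shared.standard_normal(n_coef)
        w = weights[s - 1] if s <= n_scales else 1.0
        for p in range(n_pop):
            z_p = rng_pop[p].standard_normal(n_coef)
            per_pop_details[p].append(
                np.sqrt(w) * z_shared + np.sqrt(1.0 - w) * z_p
            )
    fields = []
    for p in range(n_pop):
        coeffs = [np.zeros(1)] + per_pop_details[p][::-1]
        field_full = pywt.waverec(coeffs, "haar", mode="periodization")
        fields.append(field_full[:n_bins])
    return fields


def gen_correlated_tracks(
    config: SyntheticConfig, n_populations: int = 3
) -> dict[str, list[WindowedTrack]]:
    """Generate per-arm rho/bp tracks with known per-scale correlation.

    Returns ``{arm: [track for population 0, 1, ...]}``.  Each track is the
    exponentiated log field rescaled so its arm mean equals
    ``background_rho``; values are therefore strictly positive.
    """
    config.validate()
    out: dict[str, list[WindowedTrack]] = {}
    for arm_idx, (arm, arm_len) in enumerate(sorted(config.arm_lengths.items())):
        n_bins = arm_len // config.bin_bp
        rng_shared = config.rng("tracks", arm_idx, 1000)
        rng_pop = [config.rng("tracks", arm_idx, p) for p in range(n_populations)]
        fields = _synthesize_field(
            rng_shared, rng_pop, n_bins, config.n_scales, config.per_scale_weights
        )
        tracks = []
        for p, log_field in enumerate(fields):
            raw = np.exp(config.log_sd * log_field)
            raw *= config.background_rho / raw.mean()
            tracks.append(
                WindowedTrack(arm=arm, window_bp=config.bin_bp, values=raw,
                              units="rho/bp")
            )
        out[arm] = tracks
    return out


# ---------------------------------------------------------------------------
# interval maps over a Poisson SNP process
# ---------------------------------------------------------------------------

def gen_interval_map(
    config: SyntheticConfig,
    base_track: WindowedTrack,
    population: str = "pop0",
    population_index: int = 0,
) -> IntervalRateMap:
    """Piecewise-constant rho map over Poisson-distributed SNP positions.

    Inter-SNP intervals take the rho of the 25-kb bin covering their
    midpoint.  Configured warm spots on this arm overwrite covered intervals
    with ``fold * arm background`` (the mean of the base track); spot
    boundaries are forced onto SNP positions so the overwrite is exact.
    """
    config.validate()
    vals = base_track.values
    if np.any(np.isnan(vals)) or np.any(vals <= 0):
        raise RhoscapeError("base track must be positive everywhere")
    arm = base_track.arm
    span = len(base_track) * base_track.window_bp
    spots = config.spots_on(arm)
    for s, e, _f in spots:
        if e > span:
            raise RhoscapeError(f"warm spot ({s}, {e}) outside generated span {span}")

    arm_idx = sorted(config.arm_lengths).index(arm) if arm in config.arm_lengths else 0
    rng = config.rng("snps", arm_idx, population_index)
    n_snps = rng.poisson(config.snp_density * span)
    positions = np.unique(rng.integers(0, span, size=n_snps))
    forced = np.array(
        sorted({0, span} | {p for s, e, _f in spots for p in (s, e)}), dtype=np.int64
    )
    positions = np.unique(np.concatenate([positions, forced]))

    starts = positions[:-1]
    ends = positions[1:]
    mids = (starts + ends) // 2
    bins = np.clip(mids // base_track.window_bp, 0, len(vals) - 1)
    rho = vals[bins].astype(float)

    background = float(vals.mean())
    for s, e, fold in spots:
        inside = (starts >= s) & (ends <= e)
        rho[inside] = fold * background
    return IntervalRateMap(
        arm=arm, population=population, starts=starts, ends=ends, rho=rho
    )


# ---------------------------------------------------------------------------
# feature tracks
# ---------------------------------------------------------------------------

def gen_feature_tracks(
    config: SyntheticConfig,
    rate_track: WindowedTrack,
    population_index: int = 0,
) -> tuple[WindowedTrack, WindowedTrack, WindowedTrack]:
    """Nucleotide diversity, gene content and read depth coupled to the rate.

    Diversity is a linear blend ``alpha * standardized(rate) +
    sqrt(1 - alpha^2) * noise`` (alpha = ``diversity_coupling``) shifted
    positive onto a pi-like scale, so its Pearson correlation with the rate
    track has expectation alpha and, at alpha = 1, its rank correlation with
    the rate is exactly 1.  Gene content is an independent logistic field in
    [0, 1]; read depth is positive and weakly coupled to diversity.
    """
    config.validate()
    vals = rate_track.values
    if np.any(np.isnan(vals)):
        raise RhoscapeError("rate track must be defined on all bins")
    alpha = config.diversity_coupling
    n = len(vals)
    arm_idx = (
        sorted(config.arm_lengths).index(rate_track.arm)
        if rate_track.arm in config.arm_lengths
        else 0
    )
    rng = config.rng("features", arm_idx, population_index)

    z_rate = (vals - vals.mean()) / (vals.std() or 1.0)
    noise = rng.standard_normal(n)
    raw = alpha * z_rate + np.sqrt(1.0 - alpha ** 2) * noise
    # linear, strictly increasing map onto a pi-like positive scale
    diversity_vals = 1e-3 * (raw - raw.min() + 0.1)

    gene_raw = rng.standard_normal(n)
    gene_vals = 1.0 / (1.0 + np.exp(-(0.8 * gene_raw - 0.5)))

    z_div = (raw - raw.mean()) / (raw.std() or 1.0)
    depth_vals = 30.0 + 2.0 * (0.3 * z_div + np.sqrt(1 - 0.3 ** 2) * rng.standard_normal(n))

    mk = lambda v, units: WindowedTrack(
        arm=rate_track.arm, window_bp=rate_track.window_bp, values=v, units=units
    )
    return mk(diversity_vals, "pi"), mk(gene_vals, "proportion"), mk(depth_vals, "depth")


# ---------------------------------------------------------------------------
# divergent regions
# ---------------------------------------------------------------------------

DIVERGENT_GRANULARITY = 100_000  # sliding-window resolution of divergence scans


def gen_divergent_regions(
    config: SyntheticConfig, spots: list[WarmSpot], n_background: int = 5
) -> dict[str, list[DivergentRegionSet]]:
    """Divergent-region sets that cover a known fraction of warm spots.

    Exactly ``round(fraction * n_spots)`` spots (seed-deterministic choice)
    are covered by a 100-kb-aligned interval assigned to one of the three
    comparisons; coverage intervals are trimmed so they never touch an
    unselected spot.  ``n_background`` additional 100-kb intervals per arm
    and comparison are placed uniformly at random avoiding all spots.
    """
    config.validate()
    frac = config.divergent_overlap_fraction
    by_arm: dict[str, list[WarmSpot]] = {}
    for sp in spots:
        by_arm.setdefault(sp.arm, []).append(sp)

    n_cover = int(round(frac * len(spots)))
    rng = config.rng("divergent", 0)
    order = rng.permutation(len(spots))
    covered_ids = set(order[:n_cover].tolist())

    arms = sorted(set(by_arm) | set(config.arm_lengths))
    out: dict[str, list[DivergentRegionSet]] = {}
    flat = list(spots)
    g = DIVERGENT_GRANULARITY
    for arm in arms:
        arm_len = config.arm_lengths.get(arm)
        if arm_len is None:
            arm_len = max((sp.end for sp in by_arm.get(arm, [])), default=g) + g
        arm_spots = sorted(by_arm.get(arm, []), key=lambda s: s.start)
        intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in COMPARISON_LABELS}
        for idx, sp in enumerate(flat):
            if sp.arm != arm or idx not in covered_ids:
                continue
            lo = (sp.start // g) * g
            hi = -(-sp.end // g) * g
            # trim so the coverage interval avoids every unselected spot
            for jdx, other in enumerate(flat):
                if other.arm != arm or jdx == idx or jdx in covered_ids:
                    continue
                if other.end <= sp.start:
                    lo = max(lo, other.end)
                elif other.start >= sp.end:
                    hi = min(hi, other.start)
            label = COMPARISON_LABELS[int(rng.integers(0, 3))]
            intervals[label].append((lo, min(hi, arm_len)))
        # background intervals avoiding all spots
        blocked = [(sp.start, sp.end) for sp in arm_spots]
        for label in COMPARISON_LABELS:
            placed = 0
            attempts = 0
            while placed < n_background and attempts < 200:
                attempts += 1
                start = int(rng.integers(0, max(1, arm_len - g)))
                start = (start // g) * g
                end = min(start + g, arm_len)
                if any(s < end and e > start for s, e in blocked):
                    continue
                if any(s < end and e > start for s, e in intervals[label]):
                    continue
                intervals[label].append((start, end))
                placed += 1
        out[arm] = [
            DivergentRegionSet(comparison=label, intervals=tuple(sorted(ivs)))
            for label, ivs in intervals.items()
        ]
    return out


# ---------------------------------------------------------------------------
# toy gene models
# ---------------------------------------------------------------------------

def gen_gene_annotation(
    config: SyntheticConfig,
    mean_gene_bp: int = 8_000,
    mean_gap_bp: int = 8_000,
    exons_per_gene: int = 3,
) -> GeneAnnotation:
    """Toy gene models tiling each arm, with exons inside genes.

    Sizes roughly echo a compact insect genome (genes and intergenic gaps of
    a few kb); this is plumbing for the annotation stage, not a gene model.
    """
    config.validate()
    genes: list[tuple[str, str, int, int]] = []
    exons: list[tuple[str, int, int]] = []
    for arm_idx, (arm, arm_len) in enumerate(sorted(config.arm_lengths.items())):
        rng = config.rng("genes", arm_idx)
        pos = int(rng.integers(0, mean_gap_bp))
        gene_no = 0
        while pos < arm_len - mean_gene_bp:
            length = int(rng.exponential(mean_gene_bp)) + 500
            end = min(pos + length, arm_len)
            gene_no += 1
            name = f"CG{arm_idx}{gene_no:04d}"
            genes.append((name, arm, pos, end))
            for _ in range(exons_per_gene):
                ex_len = max(100, int(rng.exponential((end - pos) / 6)))
                ex_start = int(rng.integers(pos, max(pos + 1, end - ex_len)))
                exons.append((arm, ex_start, min(ex_start + ex_len, end)))
            pos = end + int(rng.exponential(mean_gap_bp)) + 200
    return GeneAnnotation(genes=genes, exons=exons)
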