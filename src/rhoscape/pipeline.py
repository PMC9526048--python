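"""End-to-end orchestration: synthetic generation or real-input ingestion
through windowing, map comparison, wavelet statistics and warm-spot calling.

A single :class:`RunConfig` drives the whole run; every stage writes its
table under the output directory and a manifest records the configuration,
package versions and row counts needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import map_compare, synthetic, track_io, warmspots, wavelet, windowing
from .core import RhoscapeError, WindowedTrack

logger = logging.getLogger("rhoscape")

POPULATIONS = ("Cold", "Warm", "Temp")

#: Genetic map length assumed per arm when converting rho/bp to cM/Mb in
#: synthetic mode (a typical long-arm value for a compact dipteran genome).
DEFAULT_ARM_CM = 50.0


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | real
    synthetic_config: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    input_paths: dict = field(default_factory=dict)  # real mode
    anova_windows: tuple[int, ...] = (50_000, 100_000, 200_000, 500_000)
    empirical_windows: tuple[int, ...] = (100_000, 200_000)
    wavelet_bin: int = 25_000
    fold_threshold: float = 10.0
    min_spot_len: int = 500
    max_spot_len: int = 7_000
    alpha: float = 0.01
    family_size: int = 15
    arm_cm: float = DEFAULT_ARM_CM
    outdir: str = "results/run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic_config", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if syn:
            if "per_scale_weights" in syn:
                syn["per_scale_weights"] = tuple(syn["per_scale_weights"])
            if "warm_spots" in syn:
                syn["warm_spots"] = tuple(tuple(s) for s in syn["warm_spots"])
            cfg.synthetic_config = synthetic.SyntheticConfig(**syn)
        for name in ("anova_windows", "empirical_windows"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable problems; empty iff the config is valid."""
    problems = []
    if config.mode not in ("synthetic", "real"):
        problems.append(f"mode: must be 'synthetic' or 'real', got {config.mode!r}")
    for name in ("anova_windows", "empirical_windows"):
        sizes = getattr(config, name)
        bad = [w for w in sizes if w <= 0 or w % 1000 != 0]
        if bad:
            problems.append(f"{name}: window sizes must be positive multiples of 1000, got {bad}")
    if not (0 < config.alpha < 1):
        problems.append(f"alpha: must lie in (0, 1), got {config.alpha}")
    if config.fold_threshold <= 1:
        problems.append(f"fold_threshold: must exceed 1, got {config.fold_threshold}")
    if not (0 < config.min_spot_len <= config.max_spot_len):
        problems.append("min_spot_len/max_spot_len: need 0 < min <= max")
    if config.family_size < 1:
        problems.append(f"family_size: must be >= 1, got {config.family_size}")
    if config.mode == "synthetic":
        try:
            config.synthetic_config.validate()
        except RhoscapeError as exc:
            problems.append(f"synthetic_config: {exc}")
    else:
        for key in ("maps", "genes_gff", "divergent_bed"):
            if key not in config.input_paths:
                problems.append(f"input_paths: missing required key {key!r}")
    return problems


def _default_injected_spots(config: synthetic.SyntheticConfig, n_per_arm: int = 1,
                            fold: float = 15.0) -> tuple[tuple[str, int, int, float], ...]:
    """One mid-arm injected warm spot per arm when the user configured none."""
    spots = []
    rng = config.rng("divergent", 99)
    for arm, arm_len in sorted(config.arm_lengths.items()):
        for k in range(n_per_arm):
            start = int(rng.integers(arm_len // 4, arm_len // 2))
            length = int(rng.integers(600, 6900))
            spots.append((arm, start, start + length, fold))
    return tuple(spots)


def run_full(config: RunConfig) -> dict:
    """Run every stage, writing TSV tables and a manifest under ``outdir``.

    Deterministic given the seed.  A failure confined to one arm is logged
    and that arm is skipped; the run report counts skipped arms.
    """
    problems = validate_config(config)
    if problems:
        raise RhoscapeError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if config.mode == "synthetic":
        maps, aux = _generate_synthetic_inputs(config, outdir)
    else:
        maps, aux = _ingest_real_inputs(config)

    report = {"mode": config.mode, "seed": config.seed, "skipped_arms": []}
    corr_rows, anova_rows, scale_rows, model_rows, spot_rows = [], [], [], [], []
    arms = sorted({arm for per_pop in maps.values() for arm in per_pop})

    for arm in arms:
        t_arm = time.time()
        try:
            _analyze_arm(
                arm, config, maps, aux,
                corr_rows, anova_rows, scale_rows, model_rows, spot_rows,
            )
        except RhoscapeError as exc:
            logger.warning("arm %s failed and was skipped: %s", arm, exc)
            report["skipped_arms"].append(arm)
        logger.info("arm %s analyzed in %.2fs", arm, time.time() - t_arm)

    tables = {
        "correlations.tsv": pd.DataFrame(corr_rows),
        "anova.tsv": pd.DataFrame(anova_rows),
        "scale_correlations.tsv": pd.DataFrame(scale_rows),
        "scale_models.tsv": pd.DataFrame(model_rows),
        "warmspots.tsv": pd.DataFrame(spot_rows),
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False)
        report[name] = int(len(df))

    manifest = {
        "config": _config_dict(config),
        "versions": _versions(),
        "counts": {k: report[k] for k in tables},
        "skipped_arms": report["skipped_arms"],
        "runtime_s": round(time.time() - t0, 3),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    report["outdir"] = str(outdir)
    return report


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------

def _generate_synthetic_inputs(config: RunConfig, outdir: Path):
    """Generate maps, features, genes and divergent sets; write them to disk.

    Injected warm spots are partitioned round-robin across the three
    populations, so each detected spot belongs to exactly one population's
    map (spot locations are population-specific in this study system).
    """
    syn = dataclasses.replace(config.synthetic_config, seed=config.seed)
    if not syn.warm_spots:
        syn = dataclasses.replace(syn, warm_spots=_default_injected_spots(syn))
    tracks = synthetic.gen_correlated_tracks(syn, n_populations=len(POPULATIONS))

    per_pop_spots = {pop: [] for pop in POPULATIONS}
    for i, spot in enumerate(syn.warm_spots):
        per_pop_spots[POPULATIONS[i % len(POPULATIONS)]].append(spot)
    pop_configs = {
        pop: dataclasses.replace(syn, warm_spots=tuple(per_pop_spots[pop]))
        for pop in POPULATIONS
    }

    maps: dict[str, dict[str, object]] = {pop: {} for pop in POPULATIONS}
    features: dict[tuple[str, str], tuple] = {}
    raw_dir = outdir / "synthetic_inputs"
    raw_dir.mkdir(exist_ok=True)
    for arm in sorted(tracks):
        for p, pop in enumerate(POPULATIONS):
            base = tracks[arm][p]
            rate_map = synthetic.gen_interval_map(
                pop_configs[pop], base, population=pop, population_index=p
            )
            maps[pop][arm] = rate_map
            features[(pop, arm)] = synthetic.gen_feature_tracks(
                syn, base, population_index=p
            )
            track_io.write_ldhelmet_post(rate_map, raw_dir / f"{pop}_{arm}.txt")
            track_io.write_window_track(base, raw_dir / f"{pop}_{arm}_rho25kb.tsv")

    genes = synthetic.gen_gene_annotation(syn)
    track_io.write_gff_genes(genes, raw_dir / "genes.gff3")

    all_spots = [
        warmspots.WarmSpot(arm=a, start=s, end=e, mean_rho=np.nan, fold=f)
        for (a, s, e, f) in syn.warm_spots
    ]
    divergent = synthetic.gen_divergent_regions(syn, all_spots)
    track_io.write_bed(divergent, raw_dir / "divergent.bed")

    with open(raw_dir / "manifest.txt", "w") as fh:
        for k, v in sorted(_config_dict(config)["synthetic_config"].items()):
            fh.write(f"{k}\t{v}\n")

    aux = {
        "features": features,
        "genes": genes,
        "divergent": divergent,
        "empirical": _pseudo_empirical(maps, config),
        "injected": syn.warm_spots,
    }
    return maps, aux


def _pseudo_empirical(maps, config: RunConfig) -> dict[int, dict[str, WindowedTrack]]:
    """Synthetic stand-in for an externally measured cM/Mb reference map.

    The cross-population mean rho track per arm, converted to cM/Mb — a
    reference every population's map should correlate with.
    """
    out: dict[int, dict[str, WindowedTrack]] = {}
    for window_bp in config.empirical_windows:
        out[window_bp] = {}
        arms = sorted({arm for per_pop in maps.values() for arm in per_pop})
        for arm in arms:
            tracks = [
                windowing.window_average(maps[pop][arm], window_bp)
                for pop in maps
                if arm in maps[pop]
            ]
            n = min(len(t) for t in tracks)
            mean_vals = np.nanmean([t.values[:n] for t in tracks], axis=0)
            mean_track = WindowedTrack(
                arm=arm, window_bp=window_bp, values=mean_vals, units="rho/bp"
            )
            out[window_bp][arm] = windowing.rho_to_cm_mb(mean_track, config.arm_cm)
    return out


def _ingest_real_inputs(config: RunConfig):
    """Read user-supplied maps/annotations for a real-data run."""
    paths = config.input_paths
    maps: dict[str, dict[str, object]] = {}
    for pop, per_arm in paths["maps"].items():
        maps[pop] = {}
        for arm, p in per_arm.items():
            maps[pop][arm] = track_io.read_ldhelmet_post(p, arm=arm, population=pop)
    genes = track_io.read_gff_genes(paths["genes_gff"])
    divergent = track_io.read_bed(paths["divergent_bed"])
    empirical: dict[int, dict[str, WindowedTrack]] = {}
    for window_bp_s, per_arm in paths.get("empirical", {}).items():
        window_bp = int(window_bp_s)
        empirical[window_bp] = {
            arm: track_io.read_window_track(p) for arm, p in per_arm.items()
        }
    features = {}
    for key, per_arm in paths.get("feature_tracks", {}).items():
        for arm, p in per_arm.items():
            features[(key, arm)] = track_io.read_window_track(p)
    aux = {
        "features": features,
        "genes": genes,
        "divergent": divergent,
        "empirical": empirical,
        "injected": (),
        "real_features": True,
    }
    return maps, aux


# ---------------------------------------------------------------------------
# per-arm analysis
# ---------------------------------------------------------------------------

def _analyze_arm(arm, config, maps, aux, corr_rows, anova_rows, scale_rows,
                 model_rows, spot_rows):
    pops = [pop for pop in maps if arm in maps[pop]]

    # empirical comparison: Spearman of each converted map vs the reference
    for window_bp in config.empirical_windows:
        reference = aux["empirical"].get(window_bp, {}).get(arm)
        if reference is None:
            continue
        for pop in pops:
            track = windowing.window_average(maps[pop][arm], window_bp)
            converted = windowing.rho_to_cm_mb(track, config.arm_cm)
            n = min(len(converted), len(reference))
            conv = converted.with_values(converted.values[:n])
            ref = reference.with_values(reference.values[:n])
            res = map_compare.spearman_windows(
                conv, ref, family_size=config.family_size, population=pop
            )
            corr_rows.append(
                dict(arm=arm, population=pop, window_bp=window_bp, rho=res.rho,
                     p_raw=res.p_raw, p_adjusted=res.p_adjusted,
                     n_windows=res.n_windows)
            )

    # cross-population ANOVA + Tukey at conventional scales
    for window_bp in config.anova_windows:
        tracks = {pop: windowing.window_average(maps[pop][arm], window_bp) for pop in pops}
        if len(tracks) < 2:
            continue
        res = map_compare.anova_populations(tracks, alpha=0.05)
        row = dict(arm=arm, window_bp=window_bp, F=res.F, p=res.p)
        for pop, m in res.group_means.items():
            row[f"mean_{pop}"] = m
        row["tukey"] = "; ".join(
            f"{pair}: diff={d:.3g}, p={p:.3g}" for pair, d, p in res.tukey
        )
        anova_rows.append(row)

    # wavelet statistics on log-transformed 25-kb tracks
    decomps = {}
    for pop in pops:
        track = windowing.window_average(maps[pop][arm], config.wavelet_bin)
        decomps[pop] = wavelet.decompose_track(windowing.log_transform(track))
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    for a, b in pairs:
        for sc in wavelet.scale_correlation(decomps[a], decomps[b], alpha=config.alpha):
            scale_rows.append(
                dict(arm=arm, comparison=f"{a} vs {b}", scale_bp=sc.scale_bp,
                     tau=sc.tau, p=sc.p, n_coef=sc.n_coef,
                     significant_1pct=sc.significant_1pct, low_power=sc.low_power)
            )

    feature_decomps = _feature_decompositions(arm, config, aux, pops)
    for pop in pops:
        covs = dict(feature_decomps.get(pop, {}))
        for other in pops:
            if other != pop:
                covs[other] = decomps[other]
        if not covs:
            continue
        for lm in wavelet.scale_linear_model(decomps[pop], covs):
            for name, (est, sign, nlp) in lm.coefficients.items():
                model_rows.append(
                    dict(arm=arm, population=pop, scale_bp=lm.scale_bp,
                         covariate=name, estimate=est, sign=sign,
                         neg_log10_p=nlp, adj_r2=lm.adj_r2, n_coef=lm.n_coef)
                )

    # warm spots
    divergent_sets = aux["divergent"].get(arm, [])
    for pop in pops:
        spots = warmspots.scan_warmspots(
            maps[pop][arm],
            fold_threshold=config.fold_threshold,
            min_len=config.min_spot_len,
            max_len=config.max_spot_len,
        )
        warmspots.annotate_genes(spots, aux["genes"])
        warmspots.overlap_divergent(spots, divergent_sets)
        for sp in spots:
            spot_rows.append(
                dict(population=pop, arm=arm, start=sp.start, end=sp.end,
                     length=sp.length, mean_rho=sp.mean_rho, fold=sp.fold,
                     genes=sp.genes_label(), divergent=sp.divergent_label())
            )


def _feature_decompositions(arm, config, aux, pops):
    """Log-transform and decompose the per-population feature tracks."""
    out: dict[str, dict[str, object]] = {}
    features = aux["features"]
    if aux.get("real_features"):
        shared = {}
        for (key, f_arm), track in features.items():
            if f_arm == arm:
                shared[key] = wavelet.decompose_track(windowing.log_transform(track))
        return {pop: dict(shared) for pop in pops}
    for p, pop in enumerate(pops):
        entry = features.get((pop, arm))
        if entry is None:
            continue
        diversity, gene_content, depth = entry
        out[pop] = {
            "diversity": wavelet.decompose_track(windowing.log_transform(diversity)),
            "gene_content": wavelet.decompose_track(windowing.log_transform(gene_content)),
            "read_depth": wavelet.decompose_track(windowing.log_transform(depth)),
        }
    return out


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["synthetic_config"] = dataclasses.asdict(config.synthetic_config)
    sc = d["synthetic_config"]
    sc["per_scale_weights"] = list(sc["per_scale_weights"])
    sc["warm_spots"] = [list(s) for s in sc["warm_spots"]]
    for name in ("anova_windows", "empirical_windows"):
        d[name] = list(d[name])
    return d


def _versions() -> dict:
    import pywt
    import scipy
    import statsmodels

    from . import __version__

    return {
        "rhoscape": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "pywavelets": pywt.__version__,
        "statsmodels": statsmodels.__version__,
    }
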