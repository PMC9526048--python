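"""Window-level statistical comparison of recombination maps.

Two families of analyses live here:

* Spearman rank correlation between a converted LD-based map and an
  empirical cM/Mb map at a common window size, with Bonferroni adjustment
  across the family of (arm x population) tests.
* One-way ANOVA of window rates across the three populations at conventional
  window sizes, with Tukey's HSD post hoc on the three pairwise contrasts.

Windows are treated as exchangeable observations, which is anti-conservative
under spatial autocorrelation; no correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import RhoscapeError, WindowedTrack


@dataclass
class CorrelationResult:
    arm: str
    window_bp: int
    rho: float
    p_raw: float
    p_adjusted: float
    n_windows: int
    population: str = ""
    mean_snps_per_window: float | None = None


@dataclass
class AnovaResult:
    arm: str
    window_bp: int
    F: float
    p: float
    group_means: dict[str, float]
    tukey: list[tuple[str, float, float]] = field(default_factory=list)


def _complete_pairs(a: WindowedTrack, b: WindowedTrack) -> tuple[np.ndarray, np.ndarray]:
    if a.arm != b.arm:
        raise RhoscapeError(f"arm mismatch: {a.arm} vs {b.arm}")
    if a.window_bp != b.window_bp or a.start_offset != b.start_offset:
        raise RhoscapeError("tracks must share window size and offset")
    n = min(len(a), len(b))
    x, y = a.values[:n], b.values[:n]
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def spearman_windows(
    a: WindowedTrack, b: WindowedTrack, family_size: int = 1, population: str = ""
) -> CorrelationResult:
    """Spearman's rho between two aligned window tracks.

    Missing windows are dropped pairwise.  The p-value uses the t
    approximation on n-2 df; ``p_adjusted`` is the Bonferroni-corrected value
    ``min(1, family_size * p)``.
    """
    x, y = _complete_pairs(a, b)
    if len(x) < 3:
        raise RhoscapeError(f"{a.arm}: fewer than 3 complete window pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise RhoscapeError(f"{a.arm}: zero rank variance in one track")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(
        arm=a.arm,
        window_bp=a.window_bp,
        rho=float(rho),
        p_raw=float(p),
        p_adjusted=float(min(1.0, family_size * p)),
        n_windows=int(len(x)),
        population=population,
    )


def summarize_correlations(results: list[CorrelationResult]) -> dict[str, float]:
    """Per-arm mean Spearman's rho across populations, to 2 decimals.

    Raises if one arm's group mixes window sizes.
    """
    if not results:
        raise RhoscapeError("no correlation results to summarize")
    by_arm: dict[str, list[CorrelationResult]] = {}
    for r in results:
        by_arm.setdefault(r.arm, []).append(r)
    out: dict[str, float] = {}
    for arm, rs in by_arm.items():
        if len({r.window_bp for r in rs}) > 1:
            raise RhoscapeError(f"{arm}: mixed window sizes in one summary group")
        out[arm] = round(float(np.mean([r.rho for r in rs])), 2)
    return out


def anova_populations(
    tracks: dict[str, WindowedTrack], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA of window rates across populations on one arm.

    Tukey's HSD pairwise contrasts (studentized-range distribution,
    Tukey-Kramer for unequal n) are reported only when the omnibus test is
    significant at ``alpha``.
    """
    labels = list(tracks)
    groups = []
    for label in labels:
        v = tracks[label].values
        v = v[~np.isnan(v)]
        if len(v) < 2:
            raise RhoscapeError(f"population {label}: fewer than 2 windows")
        groups.append(v)
    arms = {t.arm for t in tracks.values()}
    if len(arms) > 1:
        raise RhoscapeError(f"tracks from different arms: {sorted(arms)}")
    window_bp = {t.window_bp for t in tracks.values()}
    if len(window_bp) > 1:
        raise RhoscapeError("tracks have different window sizes")
    F, p = stats.f_oneway(*groups)
    result = AnovaResult(
        arm=next(iter(arms)),
        window_bp=next(iter(window_bp)),
        F=float(F),
        p=float(p),
        group_means={lab: float(np.mean(g)) for lab, g in zip(labels, groups)},
    )
    if p < alpha:
        data = np.concatenate(groups)
        codes = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])
        hsd = pairwise_tukeyhsd(data, codes, alpha=alpha)
        for row in hsd.summary().data[1:]:
            g1, g2, meandiff = row[0], row[1], float(row[2])
            p_adj = float(row[3])
            result.tukey.append((f"{g1} vs {g2}", meandiff, p_adj))
    return result
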