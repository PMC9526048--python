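"""Orthonormal Haar multiscale decomposition and all scale-wise statistics.

A length-2^n track decomposes into detail coefficients at scales s = 1..n
(scale 1 finest, 2^(n-1) coefficients; scale s spans ``bin_bp * 2^s``) plus a
single top smooth coefficient.  The transform is unitary, so energy is
conserved exactly and detail coefficients at distinct scales are orthogonal
— the property that lets per-scale correlations and regressions be read as
independent views of the same pair of tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats

from .core import RhoscapeError, WindowedTrack

#: Scales with fewer detail coefficients than this are reported as undefined.
MIN_COEF_FOR_STATS = 4
#: Significance calls on fewer coefficients than this are flagged low-power.
LOW_POWER_N = 10


@dataclass
class WaveletDecomposition:
    """Haar detail coefficients per scale plus the top smooth coefficient."""

    n_levels: int
    details: dict[int, np.ndarray]  # scale s -> 2^(n_levels - s) coefficients
    smooth: float
    bin_bp: int = 25_000

    def scale_bp(self, s: int) -> int:
        return self.bin_bp * (2 ** s)

    def energy(self) -> float:
        return float(sum((d ** 2).sum() for d in self.details.values()) + self.smooth ** 2)

    def scales(self) -> list[int]:
        return sorted(self.details)


@dataclass
class ScaleCorrelation:
    scale_bp: int
    tau: float  # NaN when undefined
    p: float
    n_coef: int
    significant_1pct: bool
    low_power: bool = False


@dataclass
class ScaleLinearModel:
    scale_bp: int
    coefficients: dict[str, tuple[float, int, float]]  # name -> (estimate, sign, -log10 p)
    adj_r2: float
    n_coef: int
    rank_deficient: bool = False
    undefined: bool = False


def truncate_pow2(track: WindowedTrack) -> WindowedTrack:
    """Mean-impute missing windows, then keep the first 2^n observations.

    Truncation keeps the telomere-proximal end of the arm; imputation with
    the track mean preserves series length and biases correlations toward
    zero rather than away from it.
    """
    vals = track.values.copy()
    observed = vals[~np.isnan(vals)]
    if len(observed) < 2:
        raise RhoscapeError(f"{track.arm}: fewer than 2 non-missing observations")
    vals[np.isnan(vals)] = observed.mean()
    n = 1 << int(np.floor(np.log2(len(vals))))
    return track.with_values(vals[:n])


def haar_dwt(values: np.ndarray, bin_bp: int = 25_000) -> WaveletDecomposition:
    """Full-depth unitary Haar transform of a length-2^n series.

    At each level adjacent pairs (a, b) map to smooth (a+b)/sqrt(2) and
    detail (a-b)/sqrt(2); the pyramid is run to a single smooth coefficient.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 or (n & (n - 1)) != 0:
        raise RhoscapeError(f"series length {n} is not a power of two >= 2")
    if np.any(np.isnan(x)):
        raise RhoscapeError("series contains missing values; impute first")
    n_levels = int(np.log2(n))
    coeffs = pywt.wavedec(x, "haar", mode="periodization", level=n_levels)
    details = {s: np.asarray(coeffs[n_levels - s + 1]) for s in range(1, n_levels + 1)}
    return WaveletDecomposition(
        n_levels=n_levels,
        details=details,
        smooth=float(coeffs[0][0]),
        bin_bp=bin_bp,
    )


def haar_idwt(decomp: WaveletDecomposition) -> np.ndarray:
    """Exact inverse of :func:`haar_dwt`."""
    n = decomp.n_levels
    coeffs = [np.array([decomp.smooth])] + [decomp.details[s] for s in range(n, 0, -1)]
    return pywt.waverec(coeffs, "haar", mode="periodization")


def decompose_track(track: WindowedTrack) -> WaveletDecomposition:
    """Convenience: truncate to 2^n, transform, tagging the track's bin size."""
    t = truncate_pow2(track)
    return haar_dwt(t.values, bin_bp=t.window_bp)


def power_spectrum(decomp: WaveletDecomposition) -> dict[int, float]:
    """Per-scale mean squared detail coefficient (wavelet power)."""
    return {
        decomp.scale_bp(s): float((d ** 2).mean()) for s, d in decomp.details.items()
    }


def scale_correlation(
    a: WaveletDecomposition, b: WaveletDecomposition, alpha: float = 0.01
) -> list[ScaleCorrelation]:
    """Kendall's tau-b between detail coefficients, scale by scale.

    p-values use the tie-corrected normal approximation.  Scales with fewer
    than 4 coefficients, or with zero variance on either side, are reported
    with NaN tau.
    """
    if a.n_levels != b.n_levels:
        raise RhoscapeError(
            f"decomposition shape mismatch: {a.n_levels} vs {b.n_levels} levels"
        )
    out = []
    for s in a.scales():
        da, db = a.details[s], b.details[s]
        if len(da) != len(db):
            raise RhoscapeError(f"scale {s}: coefficient count mismatch")
        n_coef = len(da)
        if n_coef < MIN_COEF_FOR_STATS or np.all(da == da[0]) or np.all(db == db[0]):
            out.append(
                ScaleCorrelation(a.scale_bp(s), np.nan, np.nan, n_coef, False, True)
            )
            continue
        tau, p = stats.kendalltau(da, db, variant="b", method="asymptotic")
        out.append(
            ScaleCorrelation(
                scale_bp=a.scale_bp(s),
                tau=float(tau),
                p=float(p),
                n_coef=n_coef,
                significant_1pct=bool(p < alpha),
                low_power=n_coef < LOW_POWER_N,
            )
        )
    return out


def scale_pearson(a: WaveletDecomposition, b: WaveletDecomposition) -> dict[int, float]:
    """Pearson correlation of detail coefficients per scale (NaN if degenerate)."""
    out = {}
    for s in a.scales():
        da, db = a.details[s], b.details[s]
        if len(da) < 2 or np.std(da) == 0 or np.std(db) == 0:
            out[s] = np.nan
        else:
            out[s] = float(np.corrcoef(da, db)[0, 1])
    return out


def scale_linear_model(
    target: WaveletDecomposition, covariates: dict[str, WaveletDecomposition]
) -> list[ScaleLinearModel]:
    """Per-scale OLS of target detail coefficients on covariate details.

    Reports each coefficient as (estimate, sign, -log10 p from a two-sided
    t-test) together with the adjusted r^2.  Scales with too few
    coefficients for the design are reported undefined; collinear designs
    are flagged rank-deficient rather than fatal.
    """
    import statsmodels.api as sm

    names = list(covariates)
    for name, c in covariates.items():
        if c.n_levels != target.n_levels:
            raise RhoscapeError(f"covariate {name}: decomposition shape mismatch")
    out = []
    for s in target.scales():
        y = target.details[s]
        n_coef = len(y)
        scale_bp = target.scale_bp(s)
        if n_coef <= len(names) + 1:
            out.append(ScaleLinearModel(scale_bp, {}, np.nan, n_coef, undefined=True))
            continue
        X = np.column_stack([covariates[name].details[s] for name in names])
        Xc = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            out.append(
                ScaleLinearModel(scale_bp, {}, np.nan, n_coef, rank_deficient=True)
            )
            continue
        fit = sm.OLS(y, Xc).fit()
        coefs: dict[str, tuple[float, int, float]] = {}
        for j, name in enumerate(names, start=1):
            est = float(fit.params[j])
            p = float(fit.pvalues[j])
            # cap at the numerical ceiling instead of emitting inf
            neg_log10_p = 300.0 if p <= 1e-300 else -np.log10(p)
            coefs[name] = (est, int(np.sign(est)) or 1, float(neg_log10_p))
        out.append(
            ScaleLinearModel(
                scale_bp=scale_bp,
                coefficients=coefs,
                adj_r2=float(fit.rsquared_adj),
                n_coef=n_coef,
            )
        )
    return out
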