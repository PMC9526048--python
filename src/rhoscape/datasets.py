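"""Bundled reference tables.

Small published summary tables for the three temperature-evolved
*D. melanogaster* populations (Cold, Warm, Temp):

* per-arm Spearman correlations between the LD-based maps and an empirical
  cM/Mb map at 100-kb and 200-kb windows, and
* the warm-spot catalog (coordinates, genes, divergent-comparison overlaps).

These are inputs for aggregation checks — e.g. per-arm mean correlations and
warm-spot bookkeeping — not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .map_compare import CorrelationResult

_PKG = "rhoscape"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_map_correlations(window_bp: int = 200_000) -> pd.DataFrame:
    """Published per-arm, per-population Spearman rho values vs the empirical map."""
    if window_bp not in (100_000, 200_000):
        raise ValueError("published correlations exist at 100-kb and 200-kb windows")
    return _read(f"map_correlations_{window_bp // 1000}kb.tsv")


def correlation_results(window_bp: int = 200_000) -> list[CorrelationResult]:
    """The published correlation table as CorrelationResult records."""
    df = load_map_correlations(window_bp)
    out = []
    for _, row in df.iterrows():
        for pop in ("Cold", "Warm", "Temp"):
            out.append(
                CorrelationResult(
                    arm=row["arm"], window_bp=int(row["window_bp"]),
                    rho=float(row[pop]), p_raw=float("nan"),
                    p_adjusted=float("nan"), n_windows=3, population=pop,
                )
            )
    return out


def load_published_warmspots() -> pd.DataFrame:
    """Published warm-spot catalog (0-based end-exclusive coordinates)."""
    return _read("warmspots_published.tsv")
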