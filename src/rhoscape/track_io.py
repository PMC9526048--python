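"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* LD-estimator text maps: whitespace-separated ``left_snp right_snp mean
  p0.025 p0.500 p0.975`` rows after any header lines (a line whose first
  token is non-numeric is treated as header).  The ``mean`` column is the
  rho/bp point estimate; credible-interval columns are ignored.
* Window tracks: TSV with columns ``arm  start  value``; the token ``NA``
  marks a missing window.  A leading ``# units=...`` comment records units.
* Divergent regions: BED4, name column holding one of the closed comparison
  labels ("C vs W", "C vs T", "W vs T").
* Gene models: GFF3 ``gene``/``exon`` features (1-based inclusive on disk,
  converted to 0-based end-exclusive internally).

Readers validate rather than repair: any invariant violation raises
:class:`~rhoscape.core.RhoscapeError` naming the file and line.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from .core import (
    COMPARISON_LABELS,
    DivergentRegionSet,
    GeneAnnotation,
    IntervalRateMap,
    RhoscapeError,
    WindowedTrack,
)

MISSING_TOKEN = "NA"

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_numeric(token: str) -> bool:
    return bool(_NUMERIC_RE.match(token))


# ---------------------------------------------------------------------------
# LD-estimator piecewise-constant maps
# ---------------------------------------------------------------------------

def read_ldhelmet_post(path, arm: str = "", population: str = "") -> IntervalRateMap:
    """Parse an LDhelmet-style post-processed text map into an interval map.

    Adjacent SNP positions become half-open intervals ``[left_snp,
    right_snp)`` carrying the posterior-mean rho/bp.
    """
    path = Path(path)
    starts, ends, rho = [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not _is_numeric(tokens[0]):
                continue  # header / version banner
            if len(tokens) < 3:
                raise RhoscapeError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(tokens)}"
                )
            left, right = int(float(tokens[0])), int(float(tokens[1]))
            mean = float(tokens[2])
            if right <= left:
                raise RhoscapeError(
                    f"{path}:{lineno}: right_snp {right} <= left_snp {left}"
                )
            if mean < 0:
                raise RhoscapeError(f"{path}:{lineno}: negative rho {mean}")
            if starts and left < ends[-1]:
                raise RhoscapeError(
                    f"{path}:{lineno}: interval starting at {left} overlaps or "
                    f"precedes previous interval ending at {ends[-1]}"
                )
            starts.append(left)
            ends.append(right)
            rho.append(mean)
    if not starts:
        raise RhoscapeError(f"{path}: no data rows")
    return IntervalRateMap(
        arm=arm or path.stem,
        population=population,
        starts=np.array(starts),
        ends=np.array(ends),
        rho=np.array(rho),
    )


def write_ldhelmet_post(rate_map: IntervalRateMap, path) -> None:
    """Write an interval map back out in the estimator's text dialect.

    Credible-interval columns are filled with the point estimate since the
    map carries none.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("left_snp right_snp mean p0.025 p0.500 p0.975\n")
        for s, e, r in zip(rate_map.starts, rate_map.ends, rate_map.rho):
            fh.write(f"{int(s)} {int(e)} {r:.10g} {r:.10g} {r:.10g} {r:.10g}\n")


# ---------------------------------------------------------------------------
# Window tracks
# ---------------------------------------------------------------------------

def write_window_track(track: WindowedTrack, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# units={track.units}\n")
        fh.write("arm\tstart\tvalue\n")
        for start, v in zip(track.window_starts(), track.values):
            val = MISSING_TOKEN if np.isnan(v) else f"{v:.12g}"
            fh.write(f"{track.arm}\t{int(start)}\t{val}\n")


def read_window_track(path) -> WindowedTrack:
    """Read a window-track TSV; window width is inferred from row spacing."""
    path = Path(path)
    units = "rho/bp"
    arms: list[str] = []
    starts: list[int] = []
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"units=(\S+)", line)
                if m:
                    units = m.group(1)
                continue
            tokens = line.split("\t")
            if tokens[0] == "arm":
                continue  # column header
            if len(tokens) != 3:
                raise RhoscapeError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            arm, start_s, val_s = tokens
            try:
                start = int(start_s)
            except ValueError as exc:
                raise RhoscapeError(f"{path}:{lineno}: bad start {start_s!r}") from exc
            value = np.nan if val_s == MISSING_TOKEN else float(val_s)
            arms.append(arm)
            starts.append(start)
            values.append(value)
    if not starts:
        raise RhoscapeError(f"{path}: no data rows")
    if len(set(arms)) > 1:
        raise RhoscapeError(f"{path}: mixed arms in a single track file: {sorted(set(arms))}")
    spacing = np.diff(starts)
    if len(starts) > 1:
        if np.any(spacing <= 0):
            raise RhoscapeError(f"{path}: window starts are not strictly increasing")
        if len(set(spacing.tolist())) > 1:
            raise RhoscapeError(
                f"{path}: non-uniform window spacing {sorted(set(spacing.tolist()))}"
            )
        window_bp = int(spacing[0])
    else:
        window_bp = 1  # single window: width unknowable from spacing
    return WindowedTrack(
        arm=arms[0],
        window_bp=window_bp,
        values=np.array(values),
        units=units,
        start_offset=int(starts[0]),
    )


# ---------------------------------------------------------------------------
# BED divergent regions
# ---------------------------------------------------------------------------

def read_bed(path) -> dict[str, list[DivergentRegionSet]]:
    """Read BED4 divergent regions, grouped per arm.

    Returns a mapping ``arm -> [DivergentRegionSet per comparison present]``.
    The BED name column must be one of the closed comparison labels.
    """
    path = Path(path)
    per_arm: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tokens = line.split("\t")
            if len(tokens) < 4:
                raise RhoscapeError(f"{path}:{lineno}: BED4 requires 4 columns")
            arm, start_s, end_s, label = tokens[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise RhoscapeError(
                    f"{path}:{lineno}: malformed coordinates {start_s!r}, {end_s!r}"
                ) from exc
            if end <= start:
                raise RhoscapeError(f"{path}:{lineno}: end {end} <= start {start}")
            if label not in COMPARISON_LABELS:
                raise RhoscapeError(
                    f"{path}:{lineno}: unknown comparison label {label!r}; "
                    f"allowed labels: {', '.join(COMPARISON_LABELS)}"
                )
            per_arm.setdefault(arm, {}).setdefault(label, []).append((start, end))
    out: dict[str, list[DivergentRegionSet]] = {}
    for arm, by_label in per_arm.items():
        out[arm] = [
            DivergentRegionSet(comparison=label, intervals=tuple(ivs))
            for label, ivs in sorted(by_label.items())
        ]
    return out


def write_bed(sets_per_arm: dict[str, list[DivergentRegionSet]], path) -> None:
    path = Path(path)
    rows = []
    for arm, sets in sets_per_arm.items():
        for rset in sets:
            for s, e in rset.intervals:
                rows.append((arm, s, e, rset.comparison))
    rows.sort()
    with path.open("w") as fh:
        for arm, s, e, label in rows:
            fh.write(f"{arm}\t{s}\t{e}\t{label}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"(?:^|;)\s*(Name|ID|gene_id)=([^;]+)")


def _gene_name(attrs: str, fallback: str) -> str:
    found = dict(_ATTR_RE.findall(attrs))
    for key in ("Name", "ID", "gene_id"):
        if key in found:
            return found[key]
    return fallback


def read_gff_genes(path) -> GeneAnnotation:
    """Read ``gene`` and ``exon`` features from GFF3.

    GFF3 is 1-based inclusive; internal coordinates are 0-based
    end-exclusive, so a GFF3 gene ``1..100`` becomes ``(0, 100)``.  Exons not
    contained in any gene on the same arm are dropped with a warning.
    """
    path = Path(path)
    genes: list[tuple[str, str, int, int]] = []
    raw_exons: list[tuple[str, int, int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise RhoscapeError(f"{path}:{lineno}: GFF3 requires 9 columns")
            seqid, _src, ftype, start_s, end_s = fields[0], fields[1], fields[2], fields[3], fields[4]
            if ftype not in ("gene", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise RhoscapeError(
                    f"{path}:{lineno}: malformed coordinates {start_s!r}, {end_s!r}"
                ) from exc
            if end1 < start1:
                raise RhoscapeError(f"{path}:{lineno}: end {end1} < start {start1}")
            start, end = start1 - 1, end1  # to 0-based end-exclusive
            if ftype == "gene":
                genes.append((_gene_name(fields[8], f"gene_{lineno}"), seqid, start, end))
            else:
                raw_exons.append((seqid, start, end, lineno))

    exons: list[tuple[str, int, int]] = []
    for seqid, start, end, lineno in raw_exons:
        inside = any(
            g_arm == seqid and g_start <= start and end <= g_end
            for (_n, g_arm, g_start, g_end) in genes
        )
        if inside:
            exons.append((seqid, start, end))
        else:
            warnings.warn(
                f"{path}:{lineno}: exon ({seqid}:{start}-{end}) lies in no gene; dropped",
                stacklevel=2,
            )
    return GeneAnnotation(genes=genes, exons=exons)


def write_gff_genes(annotation: GeneAnnotation, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for name, arm, start, end in sorted(annotation.genes, key=lambda g: (g[1], g[2])):
            fh.write(
                f"{arm}\ttoy\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={name};Name={name}\n"
            )
        for arm, start, end in sorted(annotation.exons):
            fh.write(f"{arm}\ttoy\texon\t{start + 1}\t{end}\t.\t+\t.\tParent=.\n")
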