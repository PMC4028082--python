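"""Normalization and matrix assembly.

Coverage vectors go through two normalization steps before plotting. First,
length equalisation: variable-length bodies are resampled to a common column
count either by fitting a natural cubic spline through all points and
evaluating it at equal intervals (default), or by binning into near-equal
contiguous intervals and averaging. Second, depth normalization: vectors are
scaled by the library size to Reads Per Million mapped reads (RPM). A
signal/control BAM pair is combined as a per-position log2 RPM ratio with a
pseudocount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from . import coverage as _cov
from .regions import RegionSet

DEFAULT_POINT_COLUMNS = 2001
DEFAULT_BODY_COLUMNS = 1001
DEFAULT_BP_PER_FLANK_COLUMN = 5
DEFAULT_PSEUDOCOUNT_RPM = 0.1


@dataclass
class CoverageMatrix:
    """Regions x positions matrix of normalized enrichment."""

    matrix: np.ndarray
    row_ids: list[str]
    col_coords: np.ndarray
    axis_labels: tuple[str, str, str]
    sample_id: str
    normalization: str  # "rpm" | "log2ratio" | "raw"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != len(self.row_ids):
            raise ValueError("row count must equal number of row_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix must contain finite values only")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ProfileCurve:
    """Per-position mean and standard error across regions."""

    mean: np.ndarray
    sem: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sem = np.asarray(self.sem, dtype=np.float64)
        if self.mean.shape != self.sem.shape:
            raise ValueError("mean and sem must have equal length")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")


def normalize_length(vec, npoints: int, method: str = "spline") -> np.ndarray:
    """Resample a vector to ``npoints`` values.

    ``spline``: an interpolating natural cubic spline through the
    ``(index, value)`` pairs, evaluated at ``npoints`` equally spaced
    abscissae spanning ``[0, len - 1]`` (endpoints are preserved).
    ``bin``: the vector is split into ``npoints`` contiguous near-equal
    intervals and each is replaced by its arithmetic mean.
    """
    arr = np.asarray(vec, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if npoints < 2:
        raise ValueError("npoints must be >= 2")
    if method == "spline":
        spline = CubicSpline(np.arange(arr.size), arr, bc_type="natural")
        return spline(np.linspace(0, arr.size - 1, npoints))
    if method == "bin":
        if npoints > arr.size:
            raise ValueError("bin method cannot upsample: npoints > len(vec)")
        return np.array([chunk.mean() for chunk in np.array_split(arr, npoints)])
    raise ValueError(f"unknown method {method!r}; use 'spline' or 'bin'")


def rpm_scale(vec, library_size: int) -> np.ndarray:
    """Scale raw coverage to Reads Per Million mapped reads."""
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    return np.asarray(vec, dtype=np.float64) * (1e6 / library_size)


def log2_ratio(signal_rpm, control_rpm, pseudocount: float = DEFAULT_PSEUDOCOUNT_RPM):
    """Per-position ``log2((signal + p) / (control + p))``.

    The pseudocount ``p`` is in RPM units, so the ratio is invariant to
    sequencing depth.
    """
    s = np.asarray(signal_rpm, dtype=np.float64)
    c = np.asarray(control_rpm, dtype=np.float64)
    if s.shape != c.shape:
        raise ValueError("signal and control must have identical shape")
    if pseudocount <= 0 and (np.any(s == 0) or np.any(c == 0)):
        raise ValueError("pseudocount must be positive when zeros are present")
    return np.log2((s + pseudocount) / (c + pseudocount))


def profile_stats(matrix, trim_fraction: float = 0.0) -> ProfileCurve:
    """Column-wise (optionally trimmed) mean and SEM.

    With ``trim_fraction`` t, the smallest and largest ``floor(n * t)`` values
    of each column are removed (symmetric two-sided trim) before computing
    the mean and ``SEM = sd / sqrt(n_kept)`` over the survivors.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    data = matrix.matrix if isinstance(matrix, CoverageMatrix) else np.asarray(matrix)
    n = data.shape[0]
    k = int(np.floor(n * trim_fraction))
    kept = np.sort(data, axis=0)[k:n - k]
    m = kept.shape[0]
    mean = kept.mean(axis=0)
    if m < 2:
        warnings.warn("fewer than 2 values per column after trimming; SEM set to 0",
                      stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = kept.std(axis=0, ddof=1) / np.sqrt(m)
    return ProfileCurve(mean=mean, sem=sem, n_regions=m)


def smooth_profile(curve, window: int):
    """Moving-average smoothing with an odd window.

    At the edges the window is truncated to the available positions, so the
    output has the same length as the input and a window of 1 is the
    identity. Accepts a :class:`ProfileCurve` (mean and SEM are smoothed
    alike) or a plain array.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if isinstance(curve, ProfileCurve):
        return ProfileCurve(
            mean=smooth_profile(curve.mean, window),
            sem=smooth_profile(curve.sem, window),
            n_regions=curve.n_regions,
        )
    arr = np.asarray(curve, dtype=np.float64)
    if window == 1:
        return arr.copy()
    half = window // 2
    out = np.empty_like(arr)
    for i in range(arr.size):
        lo, hi = max(0, i - half), min(arr.size, i + half + 1)
        out[i] = arr[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def _downsample(vec: np.ndarray, columns: int) -> np.ndarray:
    """Bin-average a per-base vector to a fixed column count (no upsampling)."""
    if vec.size <= columns:
        return vec
    return normalize_length(vec, columns, method="bin")


def _flank_columns(flank: int, bp_per_column: int) -> int:
    return 0 if flank <= 0 else max(1, min(flank, round(flank / bp_per_column)))


def assemble_matrix(
    bam: str | Path,
    regions: RegionSet,
    *,
    control_bam: str | Path | None = None,
    fraglen: int = _cov.DEFAULT_FRAGLEN,
    control_fraglen: int | None = None,
    method: str = "spline",
    point_columns: int = DEFAULT_POINT_COLUMNS,
    body_columns: int = DEFAULT_BODY_COLUMNS,
    bp_per_flank_column: int = DEFAULT_BP_PER_FLANK_COLUMN,
    chunk_size: int = _cov.DEFAULT_CHUNK_SIZE,
    min_mapq: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_RPM,
    rnaseq: bool = False,
    store=None,
    sample_id: str | None = None,
    library_sizes: dict | None = None,
) -> CoverageMatrix:
    """Full extraction pipeline: fetch -> coverage -> equalise -> RPM
    (-> log2 ratio for a BAM pair).

    Point regions (uniform width ``2 * flank``) are covered at single-base
    resolution and bin-averaged down to at most ``point_columns`` columns, so
    length normalization is skipped. Interval regions have their bodies
    resampled to ``body_columns`` with ``method`` while flanks keep a fixed
    resolution of ``bp_per_flank_column`` bp per column. In RNA-seq mode
    (``rnaseq=True``, gene-body regions only) bodies are spliced exonic
    coverage of the representative isoform.

    ``library_sizes`` may carry precomputed totals keyed by BAM path to skip
    the counting pass.
    """
    region_list = list(regions)
    lib_cache = dict(library_sizes or {})

    def lib(path) -> int:
        key = str(path)
        if key not in lib_cache:
            lib_cache[key] = _cov.library_size(path, min_mapq=min_mapq)
        return lib_cache[key]

    def one_sample(path, fl) -> np.ndarray:
        alns = _cov.chunked_fetch(
            path, region_list, chunk_size=chunk_size, min_mapq=min_mapq,
            pad=fl, with_blocks=rnaseq,
        )
        rows = []
        for region, hits in zip(region_list, alns):
            if region.anchor_kind == "point":
                cov = _cov.region_coverage(hits, region.interval, fraglen=fl)
                rows.append(_downsample(cov, point_columns))
            elif rnaseq:
                if store is None or region.gene_id not in store.genes:
                    raise ValueError(
                        "RNA-seq mode needs an annotation store with the "
                        f"gene for region {region.display_id!r}")
                tx = store.genes[region.gene_id].rep
                cov = _cov.spliced_coverage(hits, tx, flank=region.flank)
                rows.append(_split_body_flanks(
                    cov, region.flank, method, body_columns, bp_per_flank_column))
            else:
                cov = _cov.region_coverage(hits, region.extent, fraglen=fl)
                rows.append(_split_body_flanks(
                    cov, region.flank, method, body_columns, bp_per_flank_column))
        if not rows:
            raise ValueError("region set is empty; nothing to plot")
        widths = {r.size for r in rows}
        if len(widths) != 1:
            raise AssertionError(f"inconsistent row widths {widths}")
        return rpm_scale(np.vstack(rows), lib(path))

    fl = fraglen
    signal = one_sample(bam, fl)
    if control_bam is not None:
        control = one_sample(control_bam, control_fraglen or fl)
        data = log2_ratio(signal, control, pseudocount)
        normalization = "log2ratio"
    else:
        data = signal
        normalization = "rpm"

    first = region_list[0]
    flank = first.flank if first.anchor_kind == "interval" else (
        first.interval.length // 2)
    ncol = data.shape[1]
    if first.anchor_kind == "point":
        col_coords = np.linspace(-flank, flank, ncol)
    else:
        fc = _flank_columns(flank, bp_per_flank_column)
        body = ncol - 2 * fc
        col_coords = np.concatenate([
            np.linspace(-flank, 0, fc, endpoint=False),
            np.linspace(0, 1, body),
            1 + np.linspace(0, flank, fc + 1)[1:] / max(flank, 1),
        ]) if fc else np.linspace(0, 1, body)

    return CoverageMatrix(
        matrix=data,
        row_ids=[r.display_id for r in region_list],
        col_coords=col_coords,
        axis_labels=regions.axis_labels,
        sample_id=sample_id or Path(str(bam)).stem,
        normalization=normalization,
        params={
            "fraglen": fraglen,
            "flank": flank,
            "method": method,
            "point_columns": point_columns,
            "body_columns": body_columns,
            "bp_per_flank_column": bp_per_flank_column,
            "pseudocount": pseudocount,
            "rnaseq": rnaseq,
            "kind": regions.kind,
            "library_size": lib_cache[str(bam)],
        },
    )


def _split_body_flanks(cov, flank, method, body_columns, bp_per_flank_column):
    """Equalise the body of an oriented [flank5 | body | flank3] vector.

    Every row must come out at ``body_columns + 2 * flank_columns`` wide, so
    bodies shorter than the target are upsampled (linearly for the bin
    method, which cannot upsample on its own).
    """
    fc = _flank_columns(flank, bp_per_flank_column)
    if flank > 0:
        left, body, right = cov[:flank], cov[flank:cov.size - flank], cov[cov.size - flank:]
    else:
        left = right = np.zeros(0)
        body = cov
    if body.size < 2:
        body_n = np.full(body_columns, body[0] if body.size else 0.0)
    elif method == "bin" and body.size < body_columns:
        body_n = np.interp(
            np.linspace(0, body.size - 1, body_columns), np.arange(body.size), body)
    else:
        body_n = normalize_length(body, body_columns, method)
    parts = []
    if fc:
        parts.append(_downsample_exact(left, fc))
    parts.append(body_n)
    if fc:
        parts.append(_downsample_exact(right, fc))
    return np.concatenate(parts)


def _downsample_exact(vec, columns):
    if vec.size == columns:
        return vec
    if columns == 1:
        return np.array([vec.mean()])
    return normalize_length(vec, columns, method="bin")
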