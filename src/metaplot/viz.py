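"""Rendering: average profiles with SEM shading, ranked heatmaps with
saturation clipping, multi-panel grids, and the replot archive.

The replot archive is a single zip file holding every coverage matrix,
profile curve, ranking and parameter of a run, so figures can be re-rendered
with different visual options without touching the BAM files again.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .ranking import RankResult
from .transform import CoverageMatrix, ProfileCurve, smooth_profile

ARCHIVE_FORMAT_VERSION = 1
DEFAULT_SATURATION = (0.02, 0.98)
DEFAULT_SEQUENTIAL_CMAP = "Reds"
DEFAULT_DIVERGING_CMAP = "RdBu_r"
COLOR_CYCLE = ("red", "blue", "darkgreen", "orange", "purple", "brown",
               "magenta", "teal")


def _axis_ticks(ax, n_cols: int, axis_labels) -> None:
    left, mid, right = axis_labels
    ax.set_xticks([0, (n_cols - 1) / 2, n_cols - 1])
    ax.set_xticklabels([left, mid, right])


def render_avgprofile(
    curves: list[ProfileCurve],
    out_path: str | Path,
    *,
    labels: list[str] | None = None,
    colors: list[str | None] | None = None,
    axis_labels: tuple[str, str, str] = ("L", "", "R"),
    shade: bool = True,
    smooth_window: int = 1,
    ylim: tuple[float, float] | None = None,
    ylabel: str = "RPM",
    title: str = "",
    ax=None,
) -> Path | None:
    """One axis with one coloured mean curve per sample, optional
    semi-transparent SEM shading, and L / anchor / R tick labels."""
    if not curves:
        raise ValueError("need at least one curve")
    lengths = {c.mean.size for c in curves}
    if len(lengths) != 1:
        raise ValueError(f"curve lengths differ: {sorted(lengths)}")
    labels = labels or [f"sample {i + 1}" for i in range(len(curves))]
    colors = colors or [None] * len(curves)

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(5, 4))
    for i, (curve, label) in enumerate(zip(curves, labels)):
        color = colors[i] or COLOR_CYCLE[i % len(COLOR_CYCLE)]
        c = smooth_profile(curve, smooth_window) if smooth_window > 1 else curve
        x = np.arange(c.mean.size)
        ax.plot(x, c.mean, color=color, label=label, lw=1.5)
        if shade:
            ax.fill_between(x, c.mean - c.sem, c.mean + c.sem,
                            color=color, alpha=0.25, linewidth=0)
    _axis_ticks(ax, curves[0].mean.size, axis_labels)
    ax.set_ylabel(ylabel)
    if ylim:
        ax.set_ylim(*ylim)
    if title:
        ax.set_title(title, fontsize=10)
    ax.legend(fontsize=8, frameon=False)
    if own_fig:
        fig.tight_layout()
        fig.savefig(out_path)
        plt.close(fig)
        return Path(out_path)
    return None


def _color_limits(data: np.ndarray, normalization: str, saturation) -> tuple[float, float]:
    lo, hi = np.quantile(data, saturation[0]), np.quantile(data, saturation[1])
    if normalization == "log2ratio":
        # diverging scale centred at 0 for signal/control ratios
        v = max(abs(lo), abs(hi)) or 1.0
        return -v, v
    if lo == hi:
        hi = lo + 1.0
    return lo, hi


def render_heatmap(
    matrix: CoverageMatrix,
    rank: RankResult | None,
    out_path: str | Path,
    *,
    saturation: tuple[float, float] = DEFAULT_SATURATION,
    cmap: str | None = None,
    title: str = "",
    ax=None,
) -> Path | None:
    """Rows in rank order top-to-bottom, colour range clipped at the
    saturation quantiles; BAM-pair (log2 ratio) matrices get a diverging
    colormap centred at zero."""
    if matrix.n_regions == 0 or matrix.n_columns == 0:
        raise ValueError("cannot render an empty matrix")
    order = rank.order if rank is not None else np.arange(matrix.n_regions)
    data = matrix.matrix[order]
    vmin, vmax = _color_limits(matrix.matrix, matrix.normalization, saturation)
    if cmap is None:
        cmap = (DEFAULT_DIVERGING_CMAP if matrix.normalization == "log2ratio"
                else DEFAULT_SEQUENTIAL_CMAP)
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(np.clip(data, vmin, vmax), aspect="auto", cmap=cmap,
              vmin=vmin, vmax=vmax, interpolation="nearest")
    _axis_ticks(ax, matrix.n_columns, matrix.axis_labels)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.n_regions} regions")
    if title:
        ax.set_title(title, fontsize=10)
    if own_fig:
        fig.tight_layout()
        fig.savefig(out_path)
        plt.close(fig)
        return Path(out_path)
    return None


def render_grid(
    panels: list[list[CoverageMatrix | None]],
    ranks: list[list[RankResult | None]],
    out_path: str | Path,
    *,
    titles: list[list[str]] | None = None,
    saturation: tuple[float, float] = DEFAULT_SATURATION,
    cmap: str | None = None,
) -> Path:
    """Heatmap grid: one row per unique region set, one column per BAM;
    empty cells are left blank; panels in one figure share a common height."""
    nrows, ncols = len(panels), max(len(r) for r in panels)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 4 * nrows), squeeze=False)
    for r in range(nrows):
        for c in range(ncols):
            ax = axes[r][c]
            m = panels[r][c] if c < len(panels[r]) else None
            if m is None:
                ax.axis("off")
                continue
            title = titles[r][c] if titles else ""
            render_heatmap(m, ranks[r][c], out_path, saturation=saturation,
                           cmap=cmap, title=title, ax=ax)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)


def render_corrgram(result, out_path: str | Path) -> Path:
    """Matrix view of pairwise Pearson correlations between samples."""
    ids = list(result.pearson.index)
    fig, ax = plt.subplots(figsize=(1 + len(ids), 1 + len(ids)))
    im = ax.imshow(result.pearson.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(ids)), ids, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(ids)), ids, fontsize=8)
    for i in range(len(ids)):
        for j in range(len(ids)):
            ax.text(j, i, f"{result.pearson.values[i, j]:.2f}",
                    ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)


# ---------------------------------------------------------------------------
# Replot archive
# ---------------------------------------------------------------------------

class ArchiveVersionError(ValueError):
    pass


@dataclass
class ReplotBundle:
    """Everything needed to re-render a figure without the BAM files."""

    matrices: list[CoverageMatrix]
    curves: list[ProfileCurve]
    rank: RankResult | None
    params: dict = field(default_factory=dict)


def _np_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, np.asarray(arr))
    return buf.getvalue()


def _np_load(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    return np.load(io.BytesIO(zf.read(name)), allow_pickle=False)


def write_replot_archive(path: str | Path, bundle: ReplotBundle) -> Path:
    """Lossless single-file dump of matrices, curves, ranking and params."""
    manifest: dict = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "params": bundle.params,
        "matrices": [],
        "curves": [],
        "rank": None,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, m in enumerate(bundle.matrices):
            zf.writestr(f"matrix_{i}.npy", _np_bytes(m.matrix))
            zf.writestr(f"coords_{i}.npy", _np_bytes(m.col_coords))
            manifest["matrices"].append({
                "row_ids": m.row_ids,
                "axis_labels": list(m.axis_labels),
                "sample_id": m.sample_id,
                "normalization": m.normalization,
                "params": m.params,
            })
        for i, c in enumerate(bundle.curves):
            zf.writestr(f"curve_{i}_mean.npy", _np_bytes(c.mean))
            zf.writestr(f"curve_{i}_sem.npy", _np_bytes(c.sem))
            manifest["curves"].append({"n_regions": c.n_regions})
        if bundle.rank is not None:
            zf.writestr("rank_order.npy", _np_bytes(bundle.rank.order))
            manifest["rank"] = {"method": bundle.rank.method,
                                "has_scores": bundle.rank.scores is not None}
            if bundle.rank.scores is not None:
                zf.writestr("rank_scores.npy", _np_bytes(bundle.rank.scores))
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
    return Path(path)


def read_replot_archive(path: str | Path) -> ReplotBundle:
    with zipfile.ZipFile(path, "r") as zf:
        manifest = json.loads(zf.read("manifest.json"))
        version = manifest.get("format_version")
        if version != ARCHIVE_FORMAT_VERSION:
            raise ArchiveVersionError(
                f"archive format {version} unsupported; this build reads "
                f"format {ARCHIVE_FORMAT_VERSION}")
        matrices = []
        for i, meta in enumerate(manifest["matrices"]):
            matrices.append(CoverageMatrix(
                matrix=_np_load(zf, f"matrix_{i}.npy"),
                row_ids=list(meta["row_ids"]),
                col_coords=_np_load(zf, f"coords_{i}.npy"),
                axis_labels=tuple(meta["axis_labels"]),
                sample_id=meta["sample_id"],
                normalization=meta["normalization"],
                params=meta["params"],
            ))
        curves = [
            ProfileCurve(
                mean=_np_load(zf, f"curve_{i}_mean.npy"),
                sem=_np_load(zf, f"curve_{i}_sem.npy"),
                n_regions=meta["n_regions"],
            )
            for i, meta in enumerate(manifest["curves"])
        ]
        rank = None
        if manifest["rank"] is not None:
            scores = (_np_load(zf, "rank_scores.npy")
                      if manifest["rank"]["has_scores"] else None)
            rank = RankResult(order=_np_load(zf, "rank_order.npy"),
                              method=manifest["rank"]["method"], scores=scores)
    return ReplotBundle(matrices=matrices, curves=curves, rank=rank,
                        params=manifest["params"])
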