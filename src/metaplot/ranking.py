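"""Region ranking for heatmaps and the pairwise sample corrgram.

Six ranking algorithms order heatmap rows by enrichment: ``total`` (row
sum, the default), ``max`` (row maximum, for sharp peaks), ``prod``
(product of per-sample row sums, for marks acting in concert), ``diff``
(difference of row sums between two samples, for mutually exclusive
marks), ``pca`` (projection on the first principal component across all
samples) and ``hc`` (hierarchical clustering leaf order). ``none`` keeps
the input order, for externally ranked region lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr, spearmanr

from .transform import CoverageMatrix

RANK_METHODS = ("total", "hc", "max", "prod", "diff", "pca", "none")


@dataclass
class RankResult:
    """A row ordering: permutation indices plus per-row scores (when the
    method is score-based)."""

    order: np.ndarray
    method: str
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.intp)
        n = self.order.size
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of row indices")


def _as_list(matrices) -> list[CoverageMatrix]:
    if isinstance(matrices, CoverageMatrix):
        return [matrices]
    return list(matrices)


def _stable_descending(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by score descending; ties keep original row order."""
    return np.lexsort((np.arange(scores.size), -scores))


def rank_regions(matrices, method: str, pair: tuple[int, int] | None = None) -> RankResult:
    """Rank rows shared by one or more coverage matrices.

    All matrices must carry identical ``row_ids``. ``diff`` needs exactly two
    designated samples — either two matrices or an explicit ``pair`` of
    indices. The PCA score sign is fixed so the scores sum to a non-negative
    value (the orientation of a principal component is arbitrary).
    """
    mats = _as_list(matrices)
    if not mats:
        raise ValueError("need at least one matrix")
    if method not in RANK_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; valid: {RANK_METHODS}")
    row_ids = mats[0].row_ids
    for m in mats[1:]:
        if m.row_ids != row_ids:
            raise ValueError("matrices must share identical row_ids")
    n = len(row_ids)
    rowsums = np.column_stack([m.matrix.sum(axis=1) for m in mats])

    if method == "none":
        return RankResult(order=np.arange(n), method=method)
    if method == "total":
        scores = rowsums.sum(axis=1)
    elif method == "max":
        scores = np.column_stack([m.matrix.max(axis=1) for m in mats]).max(axis=1)
    elif method == "prod":
        scores = rowsums.prod(axis=1)
    elif method == "diff":
        if pair is None:
            if len(mats) != 2:
                raise ValueError(
                    "diff ranking needs exactly 2 samples (or an explicit pair)")
            pair = (0, 1)
        i, j = pair
        scores = rowsums[:, i] - rowsums[:, j]
    elif method == "pca":
        X = np.hstack([m.matrix for m in mats])
        Xc = X - X.mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[0]
        if scores.sum() < 0:
            scores = -scores
    elif method == "hc":
        X = np.hstack([m.matrix for m in mats])
        if n < 2:
            return RankResult(order=np.arange(n), method=method)
        Z = linkage(X, method="complete", metric="euclidean")
        return RankResult(order=np.asarray(leaves_list(Z)), method=method)
    return RankResult(order=_stable_descending(scores), method=method, scores=scores)


def pairwise_corrgram(matrices, sample_ids: list[str] | None = None) -> "CorrgramResult":
    """All pairwise Pearson and Spearman correlations between samples.

    Each region is reduced to its row sum per sample before correlating, so
    samples are compared on per-region total enrichment. Zero-variance
    samples yield NA coefficients with a warning.
    """
    mats = _as_list(matrices)
    if len(mats) < 2:
        raise ValueError("corrgram needs at least 2 samples")
    row_ids = mats[0].row_ids
    for m in mats[1:]:
        if m.row_ids != row_ids:
            raise ValueError("matrices must share identical row_ids")
    ids = sample_ids or [m.sample_id for m in mats]
    R = np.column_stack([m.matrix.sum(axis=1) for m in mats])
    k = len(mats)
    pear = np.eye(k)
    pear_p = np.zeros((k, k))
    spear = np.eye(k)
    spear_p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if R[:, i].std() == 0 or R[:, j].std() == 0:
                warnings.warn(
                    f"zero-variance sample in pair ({ids[i]}, {ids[j]}); "
                    "correlation undefined", stacklevel=2)
                r = p = rho = sp = np.nan
            else:
                r, p = pearsonr(R[:, i], R[:, j])
                rho, sp = spearmanr(R[:, i], R[:, j])
            pear[i, j] = pear[j, i] = r
            pear_p[i, j] = pear_p[j, i] = p
            spear[i, j] = spear[j, i] = rho
            spear_p[i, j] = spear_p[j, i] = sp
    mk = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return CorrgramResult(mk(pear), mk(pear_p), mk(spear), mk(spear_p))


@dataclass
class CorrgramResult:
    pearson: pd.DataFrame
    pearson_p: pd.DataFrame
    spearman: pd.DataFrame
    spearman_p: pd.DataFrame

    def to_tsv(self, path) -> None:
        """Long-format TAB table of all coefficients and p-values."""
        rows = []
        ids = list(self.pearson.index)
        for i, a in enumerate(ids):
            for b in ids[i:]:
                rows.append((
                    a, b,
                    self.pearson.loc[a, b], self.pearson_p.loc[a, b],
                    self.spearman.loc[a, b], self.spearman_p.loc[a, b],
                ))
        pd.DataFrame(
            rows,
            columns=["sample_a", "sample_b", "pearson_r", "pearson_p",
                     "spearman_rho", "spearman_p"],
        ).to_csv(path, sep="\t", index=False)
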