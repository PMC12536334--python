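"""Cross-matrix occurrence comparison: set algebra, scaling, PCA and HCA.

The campaign yields chemical occurrence profiles in three very different
matrices — grab water samples, passive-sampler sorbent disks, and
invertebrate tissue.  This module asks how those profiles relate:
which compounds are seen where (Venn-style set algebra on detection and
quantification), whether replicate profiles cluster by matrix
(per-replicate min-max scaling followed by PCA and hierarchical
clustering), and whether concentrations in one matrix linearly track
another (paired OLS with the slope t-test).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .campaign_io import BLANK_MATRICES, PSD_MATRICES, month_of


@dataclass(frozen=True)
class OccurrenceSets:
    """Detected / quantified compound sets for one matrix.

    ``detected`` includes everything at least seen above the LOD
    (quantified or detected_below_loq); ``quantified`` only compounds with
    a usable concentration.  ``quantified <= detected`` always holds.
    """

    detected: frozenset[str]
    quantified: frozenset[str]

    def __post_init__(self) -> None:
        if not self.quantified <= self.detected:
            raise ValueError("quantified must be a subset of detected")


def occurrence_sets(measurements: pd.DataFrame) -> dict[str, OccurrenceSets]:
    """Detection/quantification sets per matrix, plus the sorbent union ``psd_any``."""
    out: dict[str, OccurrenceSets] = {}
    samples = measurements[~measurements["matrix"].isin(BLANK_MATRICES)]
    for matrix, grp in samples.groupby("matrix"):
        quantified = frozenset(grp.loc[grp["censor"] == "quantified", "compound_id"])
        detected = quantified | frozenset(
            grp.loc[grp["censor"] == "detected_below_loq", "compound_id"]
        )
        out[matrix] = OccurrenceSets(detected=detected, quantified=quantified)
    psd = [out[m] for m in PSD_MATRICES if m in out]
    if psd:
        out["psd_any"] = OccurrenceSets(
            detected=frozenset().union(*(s.detected for s in psd)),
            quantified=frozenset().union(*(s.quantified for s in psd)),
        )
    return out


def venn_counts(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive-region cardinalities of a three-set Venn diagram.

    Keys are tuples of the set names defining each of the 7 regions (the
    singletons are the "only" regions); values sum to the size of the
    union.
    """
    if len(sets) != 3:
        raise ValueError("venn_counts needs exactly three named sets")
    names = list(sets)
    as_sets = {k: set(v) for k, v in sets.items()}
    counts: dict[tuple[str, ...], int] = {}
    for r in (1, 2, 3):
        for combo in combinations(names, r):
            inside = set.intersection(*(as_sets[n] for n in combo))
            outside = set.union(
                set(), *(as_sets[n] for n in names if n not in combo)
            )
            counts[combo] = len(inside - outside)
    return counts


# --------------------------------------------------------------------------
# replicate-profile matrix, scaling
# --------------------------------------------------------------------------


def profile_matrix(measurements: pd.DataFrame) -> pd.DataFrame:
    """Wide replicate x compound value matrix for scaling/ordination.

    Rows are indexed by (matrix, month, replicate); entries are quantified
    values, with censored/absent observations as NaN.  Blank rows are
    excluded.
    """
    samples = measurements[~measurements["matrix"].isin(BLANK_MATRICES)].copy()
    samples["month"] = samples["timepoint"].map(month_of)
    quant = samples[samples["censor"] == "quantified"]
    wide = quant.pivot_table(
        index=["matrix", "month", "replicate"],
        columns="compound_id",
        values="value",
        aggfunc="mean",
    )
    # carry rows that exist only as censored observations
    all_rows = samples.set_index(["matrix", "month", "replicate"]).index.unique()
    return wide.reindex(all_rows).sort_index()


def minmax_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row (measurement replicate) onto [0, 1].

    Missing/censored entries are zero-filled first (a non-detect is a
    genuine low for an occurrence profile), then each row maps through
    (x - min) / (max - min); constant rows map to all zeros.  Idempotent.
    """
    if matrix.size == 0:
        raise ValueError("cannot scale an empty matrix")
    filled = matrix.fillna(0.0)
    lo = filled.min(axis=1)
    span = filled.max(axis=1) - lo
    span_safe = span.replace(0.0, 1.0)
    scaled = filled.sub(lo, axis=0).div(span_safe, axis=0)
    scaled[span == 0.0] = 0.0
    return scaled


# --------------------------------------------------------------------------
# ordination and clustering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # compounds x components
    explained_variance_pct: np.ndarray
    top_compounds: tuple[str, ...]


def pca(scaled: pd.DataFrame, n_components: int = 2, top_k: int = 10) -> PcaResult:
    """Centered PCA of the scaled profile matrix (covariance basis).

    Components are orthonormal with non-increasing explained variance;
    each component's sign is fixed so its largest-magnitude loading is
    positive.  ``top_compounds`` are the ``top_k`` compounds with the
    largest absolute loading across the retained components.
    """
    if scaled.shape[0] < 2 or scaled.shape[1] < 2:
        raise ValueError("pca needs at least 2 rows and 2 columns")
    n_components = min(n_components, scaled.shape[0] - 1, scaled.shape[1])
    X = scaled.to_numpy(dtype=float)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # columns = components
    # deterministic sign: largest |loading| positive per component
    for j in range(loadings.shape[1]):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=scaled.index, columns=cols)
    loadings_df = pd.DataFrame(loadings, index=scaled.columns, columns=cols)
    magnitude = loadings_df.abs().max(axis=1).sort_values(ascending=False)
    top = tuple(magnitude.index[: min(top_k, len(magnitude))])
    return PcaResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_pct=model.explained_variance_ratio_ * 100.0,
        top_compounds=top,
    )


@dataclass(frozen=True)
class HcaResult:
    """Agglomerative clustering of replicate profiles.

    ``linkage`` is the scipy merge table (node ids, heights); ``labels``
    the flat cluster assignment at the requested cut.
    """

    linkage: np.ndarray
    labels: np.ndarray
    index: tuple[Hashable, ...]
    metric: str
    method: str

    def co_clustered(self, i: int, j: int, height: float | None = None) -> bool:
        """Are rows i and j in the same flat cluster when cutting at ``height``?"""
        if height is None:
            return bool(self.labels[i] == self.labels[j])
        labels = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return bool(labels[i] == labels[j])


def hierarchical_clustering(
    scaled: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "ward",
    n_clusters: int = 2,
) -> HcaResult:
    """Ward/Euclidean agglomerative clustering of the scaled rows (deterministic)."""
    if scaled.shape[0] < 2:
        Z = np.empty((0, 4))
        return HcaResult(
            linkage=Z,
            labels=np.ones(scaled.shape[0], dtype=int),
            index=tuple(scaled.index),
            metric=metric,
            method=method,
        )
    dist = pdist(scaled.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return HcaResult(
        linkage=Z,
        labels=labels,
        index=tuple(scaled.index),
        metric=metric,
        method=method,
    )


# --------------------------------------------------------------------------
# paired inter-matrix regression
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def linear_matrix_correlation(x, y) -> LinearFit:
    """OLS of paired concentrations (compound x month pairing done upstream).

    The p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need >= 3 aligned pairs")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def pair_concentrations(
    measurements: pd.DataFrame, matrix_a: str, matrix_b: str
) -> pd.DataFrame:
    """Monthly-mean quantified values of two matrices paired by compound x month."""
    quant = measurements[measurements["censor"] == "quantified"].copy()
    quant["month"] = quant["timepoint"].map(month_of)
    means = (
        quant.groupby(["compound_id", "month", "matrix"])["value"].mean().unstack()
    )
    if matrix_a not in means.columns or matrix_b not in means.columns:
        return pd.DataFrame(columns=[matrix_a, matrix_b])
    paired = means[[matrix_a, matrix_b]].dropna()
    return paired.reset_index()
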