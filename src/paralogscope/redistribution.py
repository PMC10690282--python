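"""Redistribution scores: centroid distances between genetic backgrounds.

For each GFP-tagged gene, the 128-feature vectors of all its cells —
pooled across replicates — are averaged into one centroid per background
(wild-type vs paralog deletion). The Euclidean distance between the two
centroids is the gene's redistribution score: it captures combined changes
of subcellular localization and abundance. A classification threshold is
selected by ROC analysis against labeled true cases and random-pair
negative controls, choosing the cut with minimal false-positive rate
(ties: maximal TPR, then smallest threshold); genes strictly above the
threshold are called redistributed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class StrainCentroid:
    """Mean feature vector over all cells of one (gene, background) strain."""

    gene: str
    background: str
    centroid: np.ndarray
    n_cells: int


@dataclass(frozen=True)
class RedistributionResult:
    gene: str
    paralog: str
    score: float
    threshold: float
    redistributed: bool


def strain_centroid(
    features: np.ndarray | Sequence, gene: str = "", background: str = "wild-type"
) -> StrainCentroid:
    """Coordinate-wise mean of the member feature vectors.

    Cells are pooled across replicates: each cell contributes equally,
    regardless of which replicate it came from.
    """
    mat = np.asarray(
        [f.values if hasattr(f, "values") else f for f in features], dtype=np.float64
    )
    if mat.size == 0:
        raise ValueError("cannot compute a centroid of zero cells")
    return StrainCentroid(
        gene=gene, background=background, centroid=mat.mean(axis=0), n_cells=mat.shape[0]
    )


def redistribution_score(wt: StrainCentroid, deletion: StrainCentroid) -> float:
    """Euclidean distance between wild-type and deletion centroids."""
    if wt.centroid.shape != deletion.centroid.shape:
        raise ValueError("centroid dimensions differ")
    return float(np.linalg.norm(wt.centroid - deletion.centroid))


def select_threshold(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, pd.DataFrame]:
    """ROC threshold selection: minimal FPR, then maximal TPR, then smallest.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores plus sentinels below and above all scores, so no data point ever
    equals the threshold under the strict-greater classification rule.
    Returns the selected threshold and the full ROC table for audit.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    uniq = np.unique(np.concatenate([pos, neg]))
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    rows = []
    for t in candidates:
        rows.append(
            {
                "threshold": float(t),
                "tpr": float((pos > t).mean()),
                "fpr": float((neg > t).mean()),
            }
        )
    roc = pd.DataFrame(rows)
    order = roc.sort_values(
        by=["fpr", "tpr", "threshold"], ascending=[True, False, True]
    )
    return float(order.iloc[0]["threshold"]), roc


def classify_redistributed(score: float, threshold: float) -> bool:
    """Strictly-greater comparison against the selected threshold."""
    return score > threshold


def score_strains(
    centroids: Mapping[str, Mapping[str, StrainCentroid]],
    paralog_of: Mapping[str, str],
    threshold: float,
) -> list[RedistributionResult]:
    """Score and classify every gene with both backgrounds present."""
    results = []
    for gene, by_bg in centroids.items():
        if "wild-type" not in by_bg or "deletion" not in by_bg:
            continue
        s = redistribution_score(by_bg["wild-type"], by_bg["deletion"])
        results.append(
            RedistributionResult(
                gene=gene,
                paralog=paralog_of.get(gene, ""),
                score=s,
                threshold=threshold,
                redistributed=classify_redistributed(s, threshold),
            )
        )
    return results


@dataclass(frozen=True)
class PCAView:
    """Two-component embedding of z-scored features for visualization."""

    embedding: np.ndarray
    variance_fractions: tuple[float, float]
    centroid_arrow: np.ndarray  # (2, 2): wt centroid -> deletion centroid
    kept_columns: np.ndarray


def pca_view(
    features: np.ndarray, backgrounds: Sequence[str]
) -> PCAView:
    """Z-score the pooled features, project onto the top two PCs.

    Used for visualization only; redistribution scores are computed on the
    raw features. Constant coordinates are dropped with a warning. The sign
    of each component is fixed by making its largest-magnitude loading
    positive, so the embedding is deterministic.
    """
    x = np.asarray(features, dtype=np.float64)
    bgs = np.asarray(backgrounds)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 cells for a PCA view")
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) before PCA")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant features")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=2, svd_solver="full")
    emb = pca.fit_transform(z)
    for j in range(2):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            emb[:, j] *= -1
    var = pca.explained_variance_ratio_
    arrow = np.stack(
        [emb[bgs == "wild-type"].mean(axis=0), emb[bgs == "deletion"].mean(axis=0)]
    )
    return PCAView(
        embedding=emb,
        variance_fractions=(float(var[0]), float(var[1])),
        centroid_arrow=arrow,
        kept_columns=np.nonzero(keep)[0],
    )


def pair_response_summary(
    results: Iterable[RedistributionResult],
) -> tuple[dict[tuple[str, str], str], Counter]:
    """Categorize each paralog pair as both / one / none responding.

    Pairs with only one member scored are flagged ``incomplete``. Returns
    the per-pair category map and the category counts.
    """
    by_gene = {r.gene: r for r in results}
    categories: dict[tuple[str, str], str] = {}
    for r in by_gene.values():
        key = tuple(sorted((r.gene, r.paralog)))
        if key in categories:
            continue
        other = by_gene.get(r.paralog)
        if other is None:
            categories[key] = "incomplete"
        else:
            n = int(r.redistributed) + int(other.redistributed)
            categories[key] = {2: "both", 1: "one", 0: "none"}[n]
    return categories, Counter(categories.values())


def results_to_frame(results: Iterable[RedistributionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "paralog": r.paralog,
                "background_pair": "wild-type/deletion",
                "score": r.score,
                "threshold": r.threshold,
                "redistributed": r.redistributed,
            }
            for r in results
        ]
    )
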