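"""Protein abundance quantification and compensation/dependency calls.

The abundance score of a strain condition is the mean raw pixel intensity
over every pixel of every cell frame in that condition. Relative abundance
change between paralog-deletion and wild-type backgrounds is the difference
of log2 scores with a pseudocount of 1; significance comes from a two-sided
Mann-Whitney U test on per-cell mean intensities, corrected across genes
with the Benjamini-Hochberg step-up procedure. A gene is called increased
when lfc >= 0.2 with q < 0.05, decreased when lfc <= -0.2 with q < 0.05.

The final biological call combines abundance and localization: compensation
means increased abundance or relocalization into the paralog's wild-type
compartment; dependency means decreased abundance or relocalization to a
compartment that is neither the protein's own nor its paralog's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

LFC_THRESHOLD = 0.2
Q_THRESHOLD = 0.05

#: largest combined sample size for which the exact U distribution is used
EXACT_MAX_N = 12


@dataclass(frozen=True)
class AbundanceResult:
    gene: str
    paralog: str
    score_wt: float
    score_del: float
    lfc: float
    p: float
    q: float
    direction: str


def abundance_score(frames: Sequence) -> float:
    """Grand mean raw intensity over all pixels of all frames.

    Pixel-weighted: with 64 x 64 frames every frame contributes equally,
    but the definition is the mean over the pooled pixels, not a
    mean of per-frame means.
    """
    stacks = [
        np.asarray(f.pixels if hasattr(f, "pixels") else f, dtype=np.float64)
        for f in frames
    ]
    if not stacks:
        raise ValueError("abundance score of zero frames is undefined")
    total = sum(s.sum() for s in stacks)
    npix = sum(s.size for s in stacks)
    return float(total / npix)


def log2_fold_change(score_wt: float, score_del: float) -> float:
    """log2(score_del + 1) - log2(score_wt + 1): deletion minus wild-type,
    so positive values flag compensation candidates."""
    if score_wt < 0 or score_del < 0:
        raise ValueError("abundance scores must be nonnegative")
    return float(np.log2(score_del + 1.0) - np.log2(score_wt + 1.0))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact (full permutation distribution of U) when the combined sample size
    is at most 12 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1, returned in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_abundance(
    lfc: float,
    q: float,
    lfc_thresh: float = LFC_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
) -> str:
    """Direction call: increased / decreased / none."""
    if q < q_thresh and lfc >= lfc_thresh:
        return "increased"
    if q < q_thresh and lfc <= -lfc_thresh:
        return "decreased"
    return "none"


def call_comp_dep(
    direction: str,
    relocalized_to: str | None,
    own_wt_compartment: str | None = None,
    paralog_wt_compartment: str | None = None,
) -> tuple[str, list[str]]:
    """Combine abundance direction and relocalization into the final call.

    Compensation: abundance increased, or relocalization into the paralog's
    wild-type compartment. Dependency: abundance decreased, or
    relocalization to a compartment distinct from both the protein's own and
    its paralog's wild-type compartments. When evidence points both ways the
    primary call is ``conflict`` and both flags are returned with a warning
    entry.
    """
    flags: list[str] = []
    comp = direction == "increased" or (
        relocalized_to is not None and relocalized_to == paralog_wt_compartment
    )
    dep = direction == "decreased" or (
        relocalized_to is not None
        and relocalized_to not in (own_wt_compartment, paralog_wt_compartment)
    )
    if comp:
        flags.append("compensation")
    if dep:
        flags.append("dependency")
    if comp and dep:
        return "conflict", flags
    if comp:
        return "compensation", flags
    if dep:
        return "dependency", flags
    return "none", flags


def abundance_analysis(
    per_gene: dict[str, dict],
) -> list[AbundanceResult]:
    """Full abundance workflow over a screen.

    ``per_gene`` maps gene -> {"paralog": str, "cells_wt": per-cell means,
    "cells_del": per-cell means, "score_wt": float, "score_del": float}.
    Computes lfc and raw p per gene, applies BH across the whole set, and
    classifies direction.
    """
    genes = sorted(per_gene)
    lfcs, ps = [], []
    for g in genes:
        rec = per_gene[g]
        lfcs.append(log2_fold_change(rec["score_wt"], rec["score_del"]))
        ps.append(rank_sum_test(rec["cells_wt"], rec["cells_del"]))
    qs = bh_adjust(ps)
    results = []
    for g, lfc, p, q in zip(genes, lfcs, ps, qs):
        rec = per_gene[g]
        results.append(
            AbundanceResult(
                gene=g,
                paralog=rec.get("paralog", ""),
                score_wt=float(rec["score_wt"]),
                score_del=float(rec["score_del"]),
                lfc=float(lfc),
                p=float(p),
                q=float(q),
                direction=classify_abundance(lfc, q),
            )
        )
    return results
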