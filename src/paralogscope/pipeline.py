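"""End-to-end screen orchestration: images in, classification tables out.

Runs the stages in method order: background-reference subtraction over the
whole dataset, per-image log standardization, segmentation (oracle or
intensity backend), 64 x 64 frame extraction (raw frames for abundance,
normalized frames for features), 128-feature extraction, replicate QC,
per-strain centroids and redistribution scores with ROC threshold
selection, abundance statistics with BH correction, and pair-level
compensation/dependency summaries. Deterministic given config and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import preprocessing as pp
from . import redistribution as rd
from . import segmentation as seg
from . import single_cell as sc
from .synthetic import Scene


@dataclass
class RunConfig:
    """Pipeline thresholds and backend selection.

    Every threshold defaults to the screen's published operating point:
    watershed seeds at probability 0.8 and boundaries at 0.5, cell areas
    within [256, 8192] px, redistribution called above score 4.73 when no
    control pairs are supplied, abundance hits at |lfc| >= 0.2 with
    q < 0.05, colocalization at Jaccard >= 50, and ER/cytoplasm reporter
    quantiles 0.975 / 0.973.
    """

    seed_thresh: float = 0.8
    boundary_thresh: float = 0.5
    min_area: int = 256
    max_area: int = 8192
    lfc_thresh: float = 0.2
    q_thresh: float = 0.05
    jaccard_thresh: float = 50.0
    er_quantile: float = 0.975
    cyto_quantile: float = 0.973
    redistribution_threshold: float = 4.73
    min_cells_per_replicate: int = 50
    segmentation_backend: str = "oracle"  # "oracle" | "intensity"
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ScreenResult:
    """Result bundle: every reported number is recomputable from the tables."""

    redistribution: pd.DataFrame
    abundance: pd.DataFrame
    pair_summary: pd.DataFrame
    roc: pd.DataFrame | None
    threshold: float
    audit: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, directory: str) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.redistribution.to_csv(
            os.path.join(directory, "redistribution.tsv"), sep="\t", index=False
        )
        self.abundance.to_csv(
            os.path.join(directory, "abundance.tsv"), sep="\t", index=False
        )
        self.pair_summary.to_csv(
            os.path.join(directory, "pair_summary.tsv"), sep="\t", index=False
        )
        if self.roc is not None:
            self.roc.to_csv(os.path.join(directory, "roc.tsv"), sep="\t", index=False)
        self.audit.to_csv(os.path.join(directory, "audit.tsv"), sep="\t", index=False)
        with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)


def _segment(scene: Scene, normalized: np.ndarray, config: RunConfig) -> seg.CellLabelMap:
    if config.segmentation_backend == "oracle":
        prob = seg.reference_probability_map(truth_labels=scene.truth_labels)
    elif config.segmentation_backend == "intensity":
        prob = seg.reference_probability_map(image=normalized)
    else:
        raise ValueError(f"unknown backend {config.segmentation_backend!r}")
    return seg.watershed_postprocess(
        prob,
        seed_thresh=config.seed_thresh,
        boundary_thresh=config.boundary_thresh,
        min_area=config.min_area,
        max_area=config.max_area,
    )


def run_screen(
    scenes: Sequence[Scene],
    metadata: pd.DataFrame,
    config: RunConfig | None = None,
    positive_genes: Sequence[str] = (),
    negative_genes: Sequence[str] = (),
) -> ScreenResult:
    """Execute the full screen on an in-memory panel.

    ``metadata`` rows align with ``scenes`` (columns strain, gene, paralog,
    background, replicate, field). If ``positive_genes`` and
    ``negative_genes`` are given, the redistribution threshold is selected
    by minimal-FPR ROC analysis on those genes' scores; otherwise the
    configured fixed threshold applies.
    """
    config = config or RunConfig()
    if len(scenes) != len(metadata):
        raise ValueError("one metadata row per scene required")

    # 1. dataset-wide background reference
    ref = pp.estimate_background_reference([s.image for s in scenes])

    # 2-5. per-scene processing, accumulated per (gene, background)
    feats, cell_means, pixel_sums, rep_counts = _accumulate(
        scenes, metadata, config, ref, dropped=set()
    )

    # 6. replicate-level QC (membership only; audit logged)
    retained, audit = pp.filter_replicates(
        rep_counts, min_cells=config.min_cells_per_replicate
    )
    dropped = {
        (strain, rep)
        for strain, reps in rep_counts.items()
        for rep in reps
        if rep not in retained.get(strain, set())
    }
    if dropped:
        feats, cell_means, pixel_sums, _ = _accumulate(
            scenes, metadata, config, ref, dropped
        )

    # 7. centroids + scores
    centroids: dict[str, dict[str, rd.StrainCentroid]] = {}
    for (gene, background), blocks in feats.items():
        mat = np.vstack(blocks)
        centroids.setdefault(gene, {})[background] = rd.StrainCentroid(
            gene=gene, background=background, centroid=mat.mean(axis=0),
            n_cells=mat.shape[0],
        )
    paralog_of = dict(zip(metadata["gene"], metadata["paralog"]))
    scores = {
        gene: rd.redistribution_score(bg["wild-type"], bg["deletion"])
        for gene, bg in centroids.items()
        if "wild-type" in bg and "deletion" in bg
    }

    roc = None
    if positive_genes and negative_genes:
        threshold, roc = rd.select_threshold(
            [scores[g] for g in positive_genes if g in scores],
            [scores[g] for g in negative_genes if g in scores],
        )
    else:
        threshold = config.redistribution_threshold

    results = rd.score_strains(centroids, paralog_of, threshold)
    redist_table = rd.results_to_frame(results)

    # 9. abundance statistics
    per_gene = {}
    for gene in scores:
        kw, kd = (gene, "wild-type"), (gene, "deletion")
        if kw not in pixel_sums or kd not in pixel_sums:
            continue
        sw = sum(t for t, _ in pixel_sums[kw]) / sum(n for _, n in pixel_sums[kw])
        sd_ = sum(t for t, _ in pixel_sums[kd]) / sum(n for _, n in pixel_sums[kd])
        per_gene[gene] = {
            "paralog": paralog_of.get(gene, ""),
            "score_wt": sw,
            "score_del": sd_,
            "cells_wt": cell_means[kw],
            "cells_del": cell_means[kd],
        }
    ab_results = ab.abundance_analysis(per_gene)
    ab_table = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "paralog": r.paralog,
                "score_wt": r.score_wt,
                "score_del": r.score_del,
                "lfc": r.lfc,
                "p": r.p,
                "q": r.q,
                "direction": r.direction,
            }
            for r in ab_results
        ]
    )

    # 10. pair-level summary
    categories, counts = rd.pair_response_summary(results)
    pair_table = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "category": cat}
            for (a, b), cat in sorted(categories.items())
        ]
    )

    manifest = {
        "config": dataclasses.asdict(config),
        "n_scenes": len(scenes),
        "n_genes_scored": len(scores),
        "threshold": float(threshold),
        "threshold_source": "roc" if roc is not None else "config",
        "pair_counts": dict(counts),
    }
    return ScreenResult(
        redistribution=redist_table,
        abundance=ab_table,
        pair_summary=pair_table,
        roc=roc,
        threshold=float(threshold),
        audit=audit.to_frame(),
        manifest=manifest,
    )


def _accumulate(scenes, metadata, config, ref, dropped):
    """Per-scene segmentation/feature accumulation, skipping dropped replicates."""
    feats: dict[tuple[str, str], list[np.ndarray]] = {}
    cell_means: dict[tuple[str, str], list[float]] = {}
    pixel_sums: dict[tuple[str, str], list[tuple[float, int]]] = {}
    rep_counts: dict[str, dict[int, int]] = {}
    for scene, (_, row) in zip(scenes, metadata.iterrows()):
        rep_counts.setdefault(row["strain"], {}).setdefault(row["replicate"], 0)
        if (row["strain"], row["replicate"]) in dropped:
            continue
        raw = pp.subtract_background(scene.image, ref)
        try:
            norm = pp.log_standardize(raw).values
        except pp.DegenerateImageError:
            continue
        labels = _segment(scene, norm, config)
        raw_frames = sc.extract_frames(raw, labels.labels, strain_ref=row["strain"])
        if not raw_frames:
            continue
        norm_stack = np.stack(
            [f.pixels for f in sc.extract_frames(norm, labels.labels)]
        )
        key = (row["gene"], row["background"])
        feats.setdefault(key, []).append(sc.reference_features_batch(norm_stack))
        cell_means.setdefault(key, []).extend(
            sc.per_cell_mean_intensity(f) for f in raw_frames
        )
        pixel_sums.setdefault(key, []).append(
            (float(sum(f.pixels.sum() for f in raw_frames)),
             int(sum(f.pixels.size for f in raw_frames)))
        )
        rep_counts[row["strain"]][row["replicate"]] += len(raw_frames)
    return feats, cell_means, pixel_sums, rep_counts


def make_report(result: ScreenResult) -> dict:
    """Count breakdowns derived entirely from the result tables."""
    report: dict = {}
    if result.redistribution.empty:
        report["warning"] = "empty result bundle"
        report["n_genes"] = 0
        return report
    red = result.redistribution
    report["n_genes"] = int(len(red))
    report["n_redistributed"] = int(red["redistributed"].sum())
    report["threshold"] = float(result.threshold)
    report["pair_categories"] = (
        result.pair_summary["category"].value_counts().to_dict()
        if not result.pair_summary.empty
        else {}
    )
    if not result.abundance.empty:
        report["abundance_directions"] = (
            result.abundance["direction"].value_counts().to_dict()
        )
    return report
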