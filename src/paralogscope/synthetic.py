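"""Synthetic single-plane micrographs with ground truth for pipeline testing.

Generates fields of non-overlapping elliptical yeast-like cells on a noisy
background, with GFP intensity laid out according to parametric subcellular
localization rules (cytoplasm, nucleus, ER, mitochondria, vacuole, Golgi,
punctate). Deletion-background effects are programmed explicitly: a log2
abundance fold change and/or a fractional relocalization of signal into a
target compartment. Every scene carries its ground-truth label map and
per-cell records, so downstream segmentation, feature-extraction and
statistics stages can be validated against known truth.

All randomness flows from one integer seed through numpy Generator streams;
identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

LOCALIZATION_CLASSES = (
    "cytoplasm",
    "nucleus",
    "ER",
    "mitochondria",
    "vacuole",
    "Golgi",
    "punctate",
)

#: metadata table column order, fixed for interchange with the pipeline
METADATA_COLUMNS = (
    "strain",
    "gene",
    "paralog",
    "background",
    "replicate",
    "field",
    "path_gfp",
    "path_reporter",
    "path_truth",
)


class ScenePackingError(RuntimeError):
    """Raised when the requested cells cannot be packed into the field."""


@dataclass(frozen=True)
class EffectSpec:
    """Programmed deletion-background effect for one GFP-tagged gene.

    ``abundance_lfc`` is the log2 fold change of the programmed per-cell mean
    intensity relative to the wild-type background; ``reloc_fraction`` is the
    fraction of foreground signal moved into the ``reloc_target`` compartment's
    render region. The wild-type background carries null effects by invariant.
    """

    gene: str
    background: str = "wild-type"
    abundance_lfc: float = 0.0
    reloc_fraction: float = 0.0
    reloc_target: str | None = None

    def __post_init__(self) -> None:
        if self.background not in ("wild-type", "deletion"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.background == "wild-type" and (
            self.abundance_lfc != 0.0 or self.reloc_fraction != 0.0
        ):
            raise ValueError("wild-type background must carry null effects")
        if not 0.0 <= self.reloc_fraction <= 1.0:
            raise ValueError("reloc_fraction must lie in [0, 1]")
        if self.reloc_fraction > 0.0 and self.reloc_target is None:
            raise ValueError("reloc_fraction > 0 requires a reloc_target")
        if self.reloc_target is not None and self.reloc_target not in LOCALIZATION_CLASSES:
            raise ValueError(f"unknown reloc_target {self.reloc_target!r}")


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth record for one rendered cell."""

    cell_id: int
    centroid: tuple[float, float]
    area: int
    localization: str
    abundance: float


@dataclass
class Scene:
    """One synthetic micrograph with its ground truth.

    ``image`` is the GFP channel, ``reporter_image`` an optional second
    (ER-reporter) channel of identical geometry, ``truth_labels`` the integer
    label map (0 = background, cells labeled consecutively from 1).
    """

    image: np.ndarray
    truth_labels: np.ndarray
    cell_truth: list[CellTruth]
    reporter_image: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.truth_labels.shape:
            raise ValueError("image and truth_labels must share a shape")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian background plus optional shot-noise term.

    ``shot_factor`` scales a multiplicative Poisson-like term whose standard
    deviation grows with the square root of the noise-free intensity.
    """

    background_mean: float = 100.0
    background_sd: float = 5.0
    shot_factor: float = 0.0

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(background_mean=0.0, background_sd=0.0, shot_factor=0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Field-level defaults emulating a single-plane high-content screen.

    Defaults follow the acquisition regime the pipeline targets: four fields
    per well with a few dozen cells each, single z-plane, cell areas within
    the segmentation size gates.
    """

    shape: tuple[int, int] = (360, 360)
    n_cells: int = 45
    area_range: tuple[float, float] = (400.0, 1600.0)
    base_abundance: float = 200.0
    reporter_abundance: float = 150.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    max_place_tries: int = 5000

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["shape"] = list(self.shape)
        data["area_range"] = list(self.area_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["shape"] = tuple(data["shape"])
        data["area_range"] = tuple(data["area_range"])
        data["noise"] = NoiseModel(**data["noise"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Localization render rules
# ---------------------------------------------------------------------------
# Each rule maps the cell-intrinsic elliptical radius rho (0 at center, 1 at
# the membrane) and polar angle phi to a nonnegative relative weight, and
# reports a "core" mask marking the compartment's signature region. Weights
# are later normalized so their sum equals the cell's pixel area, making the
# programmed abundance the cell's mean foreground intensity.


def _rule_cytoplasm(rho, phi, rng):
    w = np.where(rho <= 1.0, 1.0, 0.0)
    w[rho < 0.4] = 0.2  # dim vacuole lumen
    core = (rho <= 1.0) & (rho >= 0.4)
    return w, core


def _rule_nucleus(rho, phi, rng):
    w = np.where(rho <= 1.0, 0.1, 0.0)
    core = rho < 0.3
    w[core] = 1.0
    return w, core


def _rule_er(rho, phi, rng):
    w = np.where(rho <= 1.0, 0.05, 0.0)
    core = ((rho >= 0.25) & (rho <= 0.45)) | ((rho >= 0.85) & (rho <= 1.0))
    w[core] = 1.0
    return w, core


def _rule_mitochondria(rho, phi, rng):
    phase = rng.uniform(0, 2 * np.pi)
    w = np.where(rho <= 1.0, 0.05, 0.0)
    core = (rho >= 0.35) & (rho <= 0.9) & (np.sin(3 * phi + phase) > 0.2)
    w[core] = 1.0
    return w, core


def _rule_vacuole(rho, phi, rng):
    w = np.where(rho <= 1.0, 0.05, 0.0)
    core = (rho >= 0.35) & (rho <= 0.55)
    w[core] = 1.0
    return w, core


def _foci_rule(rho, phi, rng, n_foci, focus_radius=0.18):
    w = np.where(rho <= 1.0, 0.03, 0.0)
    core = np.zeros_like(rho, dtype=bool)
    # foci placed in the cell-intrinsic (rho, phi) frame for determinism
    x = rho * np.cos(phi)
    y = rho * np.sin(phi)
    for _ in range(n_foci):
        fr = rng.uniform(0.2, 0.65)
        fp = rng.uniform(0, 2 * np.pi)
        fx, fy = fr * np.cos(fp), fr * np.sin(fp)
        core |= (x - fx) ** 2 + (y - fy) ** 2 <= focus_radius**2
    core &= rho <= 1.0
    w[core] = 1.0
    return w, core


def _rule_golgi(rho, phi, rng):
    return _foci_rule(rho, phi, rng, n_foci=3)


def _rule_punctate(rho, phi, rng):
    return _foci_rule(rho, phi, rng, n_foci=6, focus_radius=0.14)


_RENDER_RULES = {
    "cytoplasm": _rule_cytoplasm,
    "nucleus": _rule_nucleus,
    "ER": _rule_er,
    "mitochondria": _rule_mitochondria,
    "vacuole": _rule_vacuole,
    "Golgi": _rule_golgi,
    "punctate": _rule_punctate,
}


def render_cell_weights(
    localization: str,
    rho: np.ndarray,
    phi: np.ndarray,
    rng: np.random.Generator,
    reloc_fraction: float = 0.0,
    reloc_target: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative intensity weights for one cell, normalized to mean 1 inside.

    With a programmed relocalization, a fraction ``reloc_fraction`` of the
    total weight is placed inside the target compartment's core region and the
    remainder follows the native rule outside that region, so the fraction of
    foreground intensity recovered over the target core equals the programmed
    fraction exactly. Returns ``(weights, target_core_mask)``.
    """
    if localization not in _RENDER_RULES:
        raise ValueError(f"unknown localization class {localization!r}")
    interior = rho <= 1.0
    area = int(interior.sum())
    if area == 0:
        return np.zeros_like(rho), np.zeros_like(rho, dtype=bool)
    own_w, _ = _RENDER_RULES[localization](rho, phi, rng)
    if reloc_fraction <= 0.0 or reloc_target is None:
        w = own_w * (area / own_w.sum())
        return w, np.zeros_like(rho, dtype=bool)
    tgt_w, tgt_core = _RENDER_RULES[reloc_target](rho, phi, rng)
    own_w = own_w.copy()
    own_w[tgt_core] = 0.0
    tgt_w = np.where(tgt_core, tgt_w, 0.0)
    f = float(reloc_fraction)
    w = np.zeros_like(rho)
    if own_w.sum() > 0:
        w += own_w * ((1.0 - f) * area / own_w.sum())
    if tgt_w.sum() > 0:
        w += tgt_w * (f * area / tgt_w.sum())
    return w, tgt_core


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------


def _place_ellipses(n_cells, shape, area_range, rng, max_tries):
    """Rejection-sample non-overlapping, fully-interior ellipses.

    Overlap is forbidden via a conservative bounding-circle test on the
    semi-major axes, which also guarantees disjoint rasters.
    """
    placed = []  # (cy, cx, a, b, theta)
    h, wd = shape
    for _ in range(n_cells):
        for attempt in range(max_tries):
            area = rng.uniform(*area_range)
            aspect = rng.uniform(1.0, 1.8)
            a = np.sqrt(area * aspect / np.pi)  # semi-major
            b = area / (np.pi * a)
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(a + 1, h - a - 2)
            cx = rng.uniform(a + 1, wd - a - 2)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (a + pa) ** 2
                for (py, px, pa, _, _) in placed
            ):
                placed.append((cy, cx, a, b, theta))
                break
        else:
            raise ScenePackingError(
                f"could not place cell {len(placed) + 1} of {n_cells} in a "
                f"{h}x{wd} field after {max_tries} tries"
            )
    return placed


def generate_scene(
    n_cells: int,
    localization: str | Sequence[str],
    effect: EffectSpec | None = None,
    noise: NoiseModel | None = None,
    shape: tuple[int, int] = (360, 360),
    seed: int | np.random.SeedSequence = 0,
    area_range: tuple[float, float] = (400.0, 1600.0),
    base_abundance: float = 200.0,
    reporter: bool = False,
    reporter_abundance: float = 150.0,
    max_place_tries: int = 5000,
) -> Scene:
    """Render one synthetic field of cells.

    Per-pixel intensity is background + programmed abundance x render-rule
    weight + noise. ``effect`` scales abundance by ``2**abundance_lfc`` and
    applies the programmed relocalization. ``localization`` is one class name
    for all cells or a per-cell sequence. The optional ``reporter`` channel
    renders the ER rule, emulating an ER-marker second channel.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("field must be at least 64x64")
    effect = effect or EffectSpec(gene="none")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    if isinstance(localization, str):
        loc_per_cell = [localization] * n_cells
    else:
        loc_per_cell = list(localization)
        if len(loc_per_cell) != n_cells:
            raise ValueError("need one localization class per cell")

    image = np.zeros(shape, dtype=np.float64)
    reporter_img = np.zeros(shape, dtype=np.float64) if reporter else None
    labels = np.zeros(shape, dtype=np.int32)
    truth: list[CellTruth] = []

    abundance = base_abundance * 2.0**effect.abundance_lfc
    placed = _place_ellipses(n_cells, shape, area_range, rng, max_place_tries)

    for k, (cy, cx, a, b, theta) in enumerate(placed, start=1):
        r0 = max(int(np.floor(cy - a)) - 1, 0)
        r1 = min(int(np.ceil(cy + a)) + 2, shape[0])
        c0 = max(int(np.floor(cx - a)) - 1, 0)
        c1 = min(int(np.ceil(cx + a)) + 2, shape[1])
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dy, dx = rr - cy, cc - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        phi = np.arctan2(v / b, u / a)
        interior = rho <= 1.0
        w, _ = render_cell_weights(
            loc_per_cell[k - 1], rho, phi, rng,
            reloc_fraction=effect.reloc_fraction,
            reloc_target=effect.reloc_target,
        )
        image[r0:r1, c0:c1] += abundance * w
        labels[r0:r1, c0:c1][interior] = k
        if reporter_img is not None:
            rep_w, _ = _RENDER_RULES["ER"](rho, phi, rng)
            rep_w = rep_w * (interior.sum() / rep_w.sum())
            reporter_img[r0:r1, c0:c1] += reporter_abundance * rep_w
        ys, xs = np.nonzero(interior)
        truth.append(
            CellTruth(
                cell_id=k,
                centroid=(float(ys.mean()) + r0, float(xs.mean()) + c0),
                area=int(interior.sum()),
                localization=loc_per_cell[k - 1],
                abundance=float(abundance),
            )
        )

    for img in filter(lambda x: x is not None, (image, reporter_img)):
        if noise.background_mean or noise.background_sd:
            img += rng.normal(noise.background_mean, noise.background_sd, shape)
        if noise.shot_factor:
            img += rng.normal(0.0, 1.0, shape) * noise.shot_factor * np.sqrt(
                np.clip(img, 0, None)
            )
        np.clip(img, 0, None, out=img)

    return Scene(
        image=image.astype(np.float32),
        truth_labels=labels,
        cell_truth=truth,
        reporter_image=None if reporter_img is None else reporter_img.astype(np.float32),
    )


# ---------------------------------------------------------------------------
# Strain panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParalogPair:
    """One whole-genome-duplication pair with programmed deletion effects.

    ``effect_a``/``effect_b`` describe how the GFP-tagged gene responds in
    the paralog-deletion background; the corresponding wild-type strains are
    generated with null effects automatically. Null control pairs carry null
    deletion effects too.
    """

    gene_a: str
    gene_b: str
    localization_a: str
    localization_b: str
    effect_a: EffectSpec | None = None
    effect_b: EffectSpec | None = None

    def deletion_effect(self, gene: str) -> EffectSpec:
        eff = self.effect_a if gene == self.gene_a else self.effect_b
        if eff is None:
            return EffectSpec(gene=gene, background="deletion")
        return eff


def generate_strain_panel(
    pairs: Sequence[ParalogPair],
    replicates: int = 3,
    fields_per_replicate: int = 4,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    reporter: bool = False,
) -> tuple[list[Scene], pd.DataFrame]:
    """Render the full strain panel for a list of paralog pairs.

    Each pair contributes four strain units (each gene tagged, in wild-type
    and in paralog-deletion background); each strain is imaged in
    ``replicates`` x ``fields_per_replicate`` fields. Returns the scenes and
    a metadata table aligned row-for-row with them.
    """
    cfg = config or GeneratorConfig()
    if replicates < 1 or fields_per_replicate < 1:
        raise ValueError("replicates and fields_per_replicate must be >= 1")
    strains = []  # (strain_id, gene, paralog, background, localization, effect)
    seen: set[str] = set()
    for pair in pairs:
        for gene, paralog, loc in (
            (pair.gene_a, pair.gene_b, pair.localization_a),
            (pair.gene_b, pair.gene_a, pair.localization_b),
        ):
            for background in ("wild-type", "deletion"):
                strain_id = f"{gene}-GFP_{paralog}-{'wt' if background == 'wild-type' else 'del'}"
                if strain_id in seen:
                    raise ValueError(f"duplicate strain identifier {strain_id!r}")
                seen.add(strain_id)
                eff = (
                    EffectSpec(gene=gene)
                    if background == "wild-type"
                    else pair.deletion_effect(gene)
                )
                strains.append((strain_id, gene, paralog, background, loc, eff))

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(strains) * replicates * fields_per_replicate)
    scenes: list[Scene] = []
    rows = []
    i = 0
    for strain_id, gene, paralog, background, loc, eff in strains:
        for rep in range(1, replicates + 1):
            for fld in range(1, fields_per_replicate + 1):
                scene = generate_scene(
                    n_cells=cfg.n_cells,
                    localization=loc,
                    effect=eff,
                    noise=cfg.noise,
                    shape=cfg.shape,
                    seed=children[i],
                    area_range=cfg.area_range,
                    base_abundance=cfg.base_abundance,
                    reporter=reporter,
                    reporter_abundance=cfg.reporter_abundance,
                    max_place_tries=cfg.max_place_tries,
                )
                scenes.append(scene)
                rows.append(
                    {
                        "strain": strain_id,
                        "gene": gene,
                        "paralog": paralog,
                        "background": background,
                        "replicate": rep,
                        "field": fld,
                        "path_gfp": "",
                        "path_reporter": "",
                        "path_truth": "",
                    }
                )
                i += 1
    meta = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))
    return scenes, meta


def null_pair(gene_a: str, gene_b: str, localization_a: str, localization_b: str) -> ParalogPair:
    """A randomly-paired negative-control pair: deletion effects are null."""
    return ParalogPair(gene_a, gene_b, localization_a, localization_b)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def write_scene(scene: Scene, directory: str, basename: str) -> dict[str, str]:
    """Write a scene as 16-bit TIFFs; returns the written paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    p = os.path.join(directory, f"{basename}_gfp.tif")
    tifffile.imwrite(p, _to_uint16(scene.image))
    paths["path_gfp"] = p
    p = os.path.join(directory, f"{basename}_truth.tif")
    tifffile.imwrite(p, scene.truth_labels.astype(np.uint16))
    paths["path_truth"] = p
    if scene.reporter_image is not None:
        p = os.path.join(directory, f"{basename}_reporter.tif")
        tifffile.imwrite(p, _to_uint16(scene.reporter_image))
        paths["path_reporter"] = p
    else:
        paths["path_reporter"] = ""
    return paths


def write_panel(
    scenes: Iterable[Scene], metadata: pd.DataFrame, directory: str
) -> str:
    """Write all scenes plus the metadata TSV; returns the TSV path."""
    meta = metadata.copy()
    for idx, scene in zip(meta.index, scenes):
        base = f"{meta.at[idx, 'strain']}_r{meta.at[idx, 'replicate']}_f{meta.at[idx, 'field']}"
        paths = write_scene(scene, directory, base)
        for col, val in paths.items():
            meta.at[idx, col] = val
    tsv = os.path.join(directory, "metadata.tsv")
    meta.to_csv(tsv, sep="\t", index=False)
    return tsv


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta
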