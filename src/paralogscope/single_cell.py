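"""Per-cell frames and the 128-dimensional reference feature extractor.

Each detected cell is cut out as a fixed 64 x 64 frame centered on its
centroid (zero-padded at image edges). Frames of raw background-subtracted
intensities feed abundance quantification; frames of log-standardized
intensities feed feature extraction.

The reference extractor is a deterministic, documented stand-in for a
learned embedding: it emits exactly 128 features per frame, organized in
named blocks (intensity moments and quantiles, raw and mean-centered radial
profiles, angular profile, gradient statistics and orientation histogram,
binary- and intensity-weighted shape moments including Hu invariants,
autocorrelations, radial concentration, histogram entropy and top-pixel
mass concentration). The block layout is fixed and versioned: identical
frames always map to identical vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

FRAME_SIZE = 64
N_FEATURES = 128
EXTRACTOR_ID = "reference-v1"

_HALF = FRAME_SIZE // 2


@dataclass(frozen=True)
class CellFrame:
    """A 64 x 64 cutout centered on one cell's centroid."""

    pixels: np.ndarray
    cell_id: int
    strain_ref: str = ""
    centroid: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixels.shape != (FRAME_SIZE, FRAME_SIZE):
            raise ValueError(f"frame must be {FRAME_SIZE}x{FRAME_SIZE}")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 128-long feature vector with its extractor identity."""

    values: np.ndarray
    extractor_id: str = EXTRACTOR_ID

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


def extract_frames(
    image: np.ndarray,
    labels: np.ndarray,
    strain_ref: str = "",
) -> list[CellFrame]:
    """One frame per labeled object, centered on its centroid.

    The centroid is rounded to the nearest pixel and the frame spans
    [centroid - 32, centroid + 32) in each axis; parts outside the image are
    zero-padded.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError("image and labels must share a shape")
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return []
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    frames = []
    h, w = image.shape
    for cid, (cy, cx) in zip(ids, centroids):
        rc, cc = int(np.rint(cy)), int(np.rint(cx))
        r0, r1 = rc - _HALF, rc + _HALF
        c0, c1 = cc - _HALF, cc + _HALF
        frame = np.zeros((FRAME_SIZE, FRAME_SIZE), dtype=np.float64)
        sr0, sr1 = max(r0, 0), min(r1, h)
        sc0, sc1 = max(c0, 0), min(c1, w)
        if sr0 < sr1 and sc0 < sc1:
            frame[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = image[sr0:sr1, sc0:sc1]
        frames.append(
            CellFrame(
                pixels=frame,
                cell_id=int(cid),
                strain_ref=strain_ref,
                centroid=(float(cy), float(cx)),
            )
        )
    return frames


def per_cell_mean_intensity(frame: CellFrame | np.ndarray) -> float:
    """Arithmetic mean over all 64 x 64 raw pixels of the frame."""
    pixels = frame.pixels if isinstance(frame, CellFrame) else np.asarray(frame)
    return float(pixels.mean())


# ---------------------------------------------------------------------------
# Reference feature extractor
# ---------------------------------------------------------------------------

_N_ANNULI = 16
_N_SECTORS = 16
_N_ORIENT_BINS = 8
_N_HIST_BINS = 16


def _geometry():
    c = (FRAME_SIZE - 1) / 2.0
    yy, xx = np.mgrid[0:FRAME_SIZE, 0:FRAME_SIZE]
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    ann = np.minimum((r / (_HALF / _N_ANNULI)).astype(int), _N_ANNULI - 1)
    theta = np.arctan2(dy, dx)
    sec = np.minimum(
        ((theta + np.pi) / (2 * np.pi / _N_SECTORS)).astype(int), _N_SECTORS - 1
    )
    def onehot(idx, n):
        m = np.zeros((n, FRAME_SIZE * FRAME_SIZE))
        m[idx.ravel(), np.arange(idx.size)] = 1.0
        return m, m.sum(axis=1)
    ann_m, ann_cnt = onehot(ann, _N_ANNULI)
    sec_m, sec_cnt = onehot(sec, _N_SECTORS)
    radial_gate = np.stack([(r < lim).ravel().astype(float) for lim in (8, 16, 24, 32)])
    return ann_m, ann_cnt, sec_m, sec_cnt, radial_gate, yy, xx


_ANN_M, _ANN_CNT, _SEC_M, _SEC_CNT, _RADIAL_GATE, _YY, _XX = _geometry()

# coordinate power grids for raw moments m_pq = sum x^p y^q w, p+q <= 3
_MOMENT_GRIDS = {
    (p, q): ((_XX.astype(float) ** p) * (_YY.astype(float) ** q)).ravel()
    for p in range(4)
    for q in range(4)
    if p + q <= 3
}

FEATURE_NAMES: list[str] = (
    ["mean", "sd", "skew", "kurtosis"]
    + [f"q{q:03d}" for q in (0, 5, 10, 25, 50, 75, 90, 95, 100)]
    + [f"radial_mean_{i:02d}" for i in range(_N_ANNULI)]
    + [f"radial_centered_{i:02d}" for i in range(_N_ANNULI)]
    + [f"angular_centered_{i:02d}" for i in range(_N_SECTORS)]
    + ["grad_mean", "grad_sd", "grad_q50", "grad_q90", "grad_max"]
    + [f"grad_orient_{i}" for i in range(_N_ORIENT_BINS)]
    + ["logabs_mean", "logabs_sd"]
    + ["mask_area_frac", "mask_dr", "mask_dc", "mask_mu20", "mask_mu02", "mask_mu11"]
    + [f"mask_hu{i}" for i in range(7)]
    + ["spots_area_frac", "spots_count", "spots_mean_size"]
    + [f"intensity_hu{i}" for i in range(7)]
    + [f"radial_sd_{i:02d}" for i in range(_N_ANNULI)]
    + ["acorr_01", "acorr_10", "acorr_11", "acorr_20", "acorr_02"]
    + [f"central_mass_r{lim}" for lim in (8, 16, 24, 32)]
    + ["hist_entropy"]
    + ["top_mass_1pct", "top_mass_5pct", "top_mass_10pct"]
)
assert len(FEATURE_NAMES) == N_FEATURES


def _hu_batch(weights: np.ndarray) -> np.ndarray:
    """Seven Hu invariant moments for a batch of nonnegative weight images."""
    n = weights.shape[0]
    flat = weights.reshape(n, -1)
    m = {pq: flat @ grid for pq, grid in _MOMENT_GRIDS.items()}
    m00 = m[(0, 0)]
    ok = m00 > 1e-12
    s = np.where(ok, m00, 1.0)
    xb, yb = m[(1, 0)] / s, m[(0, 1)] / s
    mu11 = m[(1, 1)] - xb * m[(0, 1)]
    mu20 = m[(2, 0)] - xb * m[(1, 0)]
    mu02 = m[(0, 2)] - yb * m[(0, 1)]
    mu30 = m[(3, 0)] - 3 * xb * m[(2, 0)] + 2 * xb**2 * m[(1, 0)]
    mu03 = m[(0, 3)] - 3 * yb * m[(0, 2)] + 2 * yb**2 * m[(0, 1)]
    mu21 = m[(2, 1)] - 2 * xb * m[(1, 1)] - yb * m[(2, 0)] + 2 * xb**2 * m[(0, 1)]
    mu12 = m[(1, 2)] - 2 * yb * m[(1, 1)] - xb * m[(0, 2)] + 2 * yb**2 * m[(1, 0)]

    def eta(mu, order):
        return mu / s ** (1 + order / 2.0)

    e20, e02, e11 = eta(mu20, 2), eta(mu02, 2), eta(mu11, 2)
    e30, e03, e21, e12 = eta(mu30, 3), eta(mu03, 3), eta(mu21, 3), eta(mu12, 3)
    a, b = e30 + e12, e21 + e03
    c, d = e30 - 3 * e12, 3 * e21 - e03
    hu = np.stack(
        [
            e20 + e02,
            (e20 - e02) ** 2 + 4 * e11**2,
            c**2 + d**2,
            a**2 + b**2,
            c * a * (a**2 - 3 * b**2) + d * b * (3 * a**2 - b**2),
            (e20 - e02) * (a**2 - b**2) + 4 * e11 * a * b,
            d * a * (a**2 - 3 * b**2) - c * b * (3 * a**2 - b**2),
        ],
        axis=1,
    )
    hu[~ok] = 0.0
    return hu


def _mask_moment_block(mask: np.ndarray) -> np.ndarray:
    """Area fraction, centroid offset, normalized second moments, Hu (13)."""
    n = mask.shape[0]
    w = mask.astype(float)
    flat = w.reshape(n, -1)
    m00 = flat.sum(axis=1)
    ok = m00 > 0
    s = np.where(ok, m00, 1.0)
    c = (FRAME_SIZE - 1) / 2.0
    dr = (flat @ (_YY.ravel().astype(float)) / s - c) / _HALF
    dc = (flat @ (_XX.ravel().astype(float)) / s - c) / _HALF
    dr[~ok] = 0.0
    dc[~ok] = 0.0
    yc = flat @ (_YY.ravel() ** 2).astype(float) / s - (dr * _HALF + c) ** 2
    xc = flat @ (_XX.ravel() ** 2).astype(float) / s - (dc * _HALF + c) ** 2
    cross = flat @ (_YY * _XX).ravel().astype(float) / s - (dr * _HALF + c) * (
        dc * _HALF + c
    )
    for arr in (yc, xc, cross):
        arr[~ok] = 0.0
    return np.column_stack(
        [
            m00 / (FRAME_SIZE * FRAME_SIZE),
            dr,
            dc,
            yc / _HALF**2,
            xc / _HALF**2,
            cross / _HALF**2,
            _hu_batch(w),
        ]
    )


def reference_features_batch(frames: np.ndarray) -> np.ndarray:
    """Feature matrix (n_frames, 128) for a stack of 64 x 64 frames.

    Pure function of the pixel values; see module docstring for the block
    layout. Raises on non-finite input.
    """
    x = np.asarray(frames, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != (FRAME_SIZE, FRAME_SIZE):
        raise ValueError(f"frames must be (n, {FRAME_SIZE}, {FRAME_SIZE})")
    if not np.all(np.isfinite(x)):
        raise ValueError("frames contain non-finite pixels")
    n = x.shape[0]
    flat = x.reshape(n, -1)
    npx = flat.shape[1]

    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    centered = flat - mean[:, None]
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = centered / safe_sd[:, None]
    skew = np.where(sd > 0, (z**3).mean(axis=1), 0.0)
    kurt = np.where(sd > 0, (z**4).mean(axis=1) - 3.0, 0.0)
    quants = np.quantile(flat, [0, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 1.0], axis=1).T

    ann_mean = (flat @ _ANN_M.T) / _ANN_CNT
    ann_sq = (flat**2 @ _ANN_M.T) / _ANN_CNT
    ann_sd = np.sqrt(np.clip(ann_sq - ann_mean**2, 0, None))
    ann_centered = ann_mean - mean[:, None]
    sec_centered = (flat @ _SEC_M.T) / _SEC_CNT - mean[:, None]

    gy, gx = np.gradient(x, axis=(1, 2))
    gmag = np.hypot(gy, gx).reshape(n, -1)
    grad_stats = np.column_stack(
        [
            gmag.mean(axis=1),
            gmag.std(axis=1),
            np.quantile(gmag, 0.5, axis=1),
            np.quantile(gmag, 0.9, axis=1),
            gmag.max(axis=1),
        ]
    )
    orient = np.arctan2(gy, gx).reshape(n, -1)
    obin = np.minimum(
        ((orient + np.pi) / (2 * np.pi / _N_ORIENT_BINS)).astype(int), _N_ORIENT_BINS - 1
    )
    ohist = np.zeros((n, _N_ORIENT_BINS))
    rows = np.repeat(np.arange(n), npx)
    np.add.at(ohist, (rows, obin.ravel()), gmag.ravel())
    tot = ohist.sum(axis=1, keepdims=True)
    ohist = np.divide(ohist, tot, out=np.zeros_like(ohist), where=tot > 0)

    la = np.log1p(np.abs(flat))
    log_stats = np.column_stack([la.mean(axis=1), la.std(axis=1)])

    mask = flat > mean[:, None]
    mask_block = _mask_moment_block(mask.reshape(n, FRAME_SIZE, FRAME_SIZE))

    spots = flat > (mean + 2 * sd)[:, None]
    spot_frac = spots.mean(axis=1)
    spot_count = np.empty(n)
    spot_size = np.empty(n)
    for i in range(n):
        lab, cnt = ndimage.label(spots[i].reshape(FRAME_SIZE, FRAME_SIZE))
        spot_count[i] = cnt / 10.0
        spot_size[i] = (spots[i].sum() / cnt / 100.0) if cnt else 0.0
    spot_block = np.column_stack([spot_frac, spot_count, spot_size])

    shifted = flat - flat.min(axis=1, keepdims=True)
    intensity_hu = _hu_batch(shifted.reshape(n, FRAME_SIZE, FRAME_SIZE))

    var = (centered**2).mean(axis=1)
    safe_var = np.where(var > 0, var, 1.0)
    c2 = centered.reshape(n, FRAME_SIZE, FRAME_SIZE)

    def acorr(dr, dc):
        a = c2[:, dr:, dc:]
        b = c2[:, : FRAME_SIZE - dr, : FRAME_SIZE - dc]
        val = (a * b).reshape(n, -1).mean(axis=1) / safe_var
        return np.where(var > 0, val, 0.0)

    acorr_block = np.column_stack(
        [acorr(0, 1), acorr(1, 0), acorr(1, 1), acorr(2, 0), acorr(0, 2)]
    )

    tot_mass = shifted.sum(axis=1)
    safe_mass = np.where(tot_mass > 0, tot_mass, 1.0)
    central = (shifted @ _RADIAL_GATE.T) / safe_mass[:, None]
    central[tot_mass <= 0] = 0.0

    rng_ = flat.max(axis=1) - flat.min(axis=1)
    norm = np.divide(
        flat - flat.min(axis=1, keepdims=True),
        np.where(rng_ > 0, rng_, 1.0)[:, None],
    )
    hb = np.minimum((norm * _N_HIST_BINS).astype(int), _N_HIST_BINS - 1)
    hist = np.zeros((n, _N_HIST_BINS))
    np.add.at(hist, (rows, hb.ravel()), 1.0)
    p = hist / npx
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)[:, None]

    srt = np.sort(shifted, axis=1)[:, ::-1]
    cums = np.cumsum(srt, axis=1)
    top = np.column_stack(
        [cums[:, max(int(npx * frac) - 1, 0)] / safe_mass for frac in (0.01, 0.05, 0.10)]
    )
    top[tot_mass <= 0] = 0.0

    out = np.column_stack(
        [
            mean,
            sd,
            skew,
            kurt,
            quants,
            ann_mean,
            ann_centered,
            sec_centered,
            grad_stats,
            ohist,
            log_stats,
            mask_block,
            spot_block,
            intensity_hu,
            ann_sd,
            acorr_block,
            central,
            entropy,
            top,
        ]
    )
    assert out.shape == (n, N_FEATURES)
    return out


def reference_features(frame: CellFrame | np.ndarray) -> FeatureVector:
    """128-feature vector for a single frame (see batch variant)."""
    pixels = frame.pixels if isinstance(frame, CellFrame) else np.asarray(frame)
    return FeatureVector(values=reference_features_batch(pixels[None])[0])
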