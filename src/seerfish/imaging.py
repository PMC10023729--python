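"""Synthetic multi-round image stacks and the image-analysis pipeline.

A stack holds R rounds of F fluorescence planes plus one reference
(phase-contrast-like) plane per round.  The pipeline mirrors multi-round
FISH image analysis: per-round translation registration by maximum
cross-correlation of the reference planes, adaptive-threshold +
watershed segmentation of the reference, per-cell intensity extraction,
per-round symbol calling against an out-of-cell background sample, and
error-correcting decoding into a taxon-labeled cell map.

The synthetic generator plants ellipse cells at known positions, renders
per-round per-channel amplitudes from the hybridization intensity model,
applies a Gaussian point-spread blur, additive noise and a per-round
(circular) drift, so every stage can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_local
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from seerfish import cellmap as cm
from seerfish.codebook import Codebook, format_barcode
from seerfish.decoding import DecodeResult, call_symbol, decode_barcodes, mark_lost
from seerfish.hybridization import SpecificityModel, simulate_intensity_stack


@dataclass
class ImageStack:
    """R rounds x (1 reference + F channels) of identically shaped 2-D images."""

    images: np.ndarray            # (R, F+1, H, W); plane 0 is the reference
    pixel_size: float = cm.DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.images.ndim != 4:
            raise ValueError("images must be a (rounds, planes, H, W) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def R(self) -> int:
        return self.images.shape[0]

    @property
    def F(self) -> int:
        return self.images.shape[1] - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[2:]

    def reference(self, round_idx: int) -> np.ndarray:
        return self.images[round_idx, 0]

    def channel(self, round_idx: int, channel_idx: int) -> np.ndarray:
        """Fluorescence plane for a 0-based channel index."""
        return self.images[round_idx, 1 + channel_idx]

    def save(self, directory) -> None:
        """One multi-page TIFF per round, planes ordered [reference, ch1..chF]."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for r in range(self.R):
            tifffile.imwrite(directory / f"round{r + 1:02d}.tif",
                             self.images[r].astype(np.float32),
                             photometric="minisblack")

    @classmethod
    def load(cls, directory, pixel_size: float = cm.DEFAULT_PIXEL_SIZE_UM) -> "ImageStack":
        directory = Path(directory)
        paths = sorted(directory.glob("round*.tif"))
        if not paths:
            raise FileNotFoundError(f"no round*.tif files under {directory}")
        planes = [tifffile.imread(p).astype(float) for p in paths]
        return cls(images=np.stack(planes), pixel_size=pixel_size)


@dataclass
class SynthConfig:
    """Parameters of the synthetic microscope.

    Amplitudes come from the hybridization intensity model (CCD-normalized
    units); the reference plane renders cells dark on a bright background.
    ``drift`` lists one (dy, dx) integer pixel shift per round, applied
    circularly to all planes of that round.
    """

    model: SpecificityModel
    shape: tuple[int, int] = (256, 256)
    pixel_size: float = cm.DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 48
    layout: str = "random"            # random | clustered
    min_sep_um: float = 3.0
    cluster_sd_um: float = 2.0
    n_parents: int = 8
    offspring_mean: float = 6.0
    a_um: float = cm.DEFAULT_A_UM
    b_um: float = cm.DEFAULT_B_UM
    drift: Sequence[tuple[int, int]] | None = None
    psf_sigma: float = 1.0
    noise_sd: float = 0.01
    shot_noise: bool = False
    ref_background: float = 0.8
    ref_cell_depth: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift is not None:
            lim = min(self.shape) / 4
            for dy, dx in self.drift:
                if abs(dy) >= lim or abs(dx) >= lim:
                    raise ValueError("drift magnitudes must stay below image size / 4")


def synthesize_stack(
    cfg: SynthConfig,
    codebook: Codebook,
) -> tuple[ImageStack, cm.CellMap, pd.DataFrame]:
    """Render a synthetic multi-round stack with known ground truth.

    Returns the stack, the planted cell map (taxa attached) and a truth
    table (cell_id, taxon, barcode).  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    taxa = list(codebook.taxa)
    if cfg.layout == "random":
        layout = cm.random_cellmap(
            cfg.n_cells, taxa, shape=cfg.shape, pixel_size=cfg.pixel_size,
            a_um=cfg.a_um, b_um=cfg.b_um, min_sep_um=cfg.min_sep_um,
            seed=int(rng.integers(2**31)))
    elif cfg.layout == "clustered":
        layout = cm.clustered_cellmap(
            cfg.n_parents, cfg.offspring_mean, cfg.cluster_sd_um, taxa,
            shape=cfg.shape, pixel_size=cfg.pixel_size,
            a_um=cfg.a_um, b_um=cfg.b_um, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown layout {cfg.layout!r}")

    n = len(layout.cells)
    R, F = codebook.R, 3
    taxon_idx = np.array([taxa.index(t) for t in layout.cells["taxon"]], dtype=int)
    if n:
        amplitudes = simulate_intensity_stack(codebook, cfg.model, taxon_idx, rng, F=F)
    else:
        amplitudes = np.zeros((0, R, F))

    footprints = [layout.cell_pixels(row) for _, row in layout.cells.iterrows()]
    drift = list(cfg.drift) if cfg.drift is not None else [(0, 0)] * R
    if len(drift) != R:
        raise ValueError(f"need one drift per round ({R}), got {len(drift)}")

    H, W = cfg.shape
    images = np.zeros((R, F + 1, H, W), dtype=float)
    for r in range(R):
        ref = np.full((H, W), cfg.ref_background)
        for rr, cc in footprints:
            ref[rr, cc] -= cfg.ref_cell_depth
        planes = [ref]
        for k in range(F):
            plane = np.zeros((H, W))
            for i, (rr, cc) in enumerate(footprints):
                plane[rr, cc] += amplitudes[i, r, k]
            planes.append(plane)
        for p, plane in enumerate(planes):
            if cfg.psf_sigma > 0:
                plane = ndi.gaussian_filter(plane, cfg.psf_sigma)
            if cfg.shot_noise:
                plane = rng.poisson(np.clip(plane, 0, None) * 1000) / 1000.0
            if cfg.noise_sd > 0:
                plane = plane + rng.normal(0, cfg.noise_sd, size=plane.shape)
            plane = np.clip(plane, 0, None)
            dy, dx = drift[r]
            images[r, p] = np.roll(plane, (dy, dx), axis=(0, 1))

    truth = pd.DataFrame({
        "cell_id": layout.cells["cell_id"],
        "taxon": layout.cells["taxon"],
        "barcode": [format_barcode(codebook.barcode_of(t))
                    for t in layout.cells["taxon"]],
    })
    stack = ImageStack(images=images, pixel_size=cfg.pixel_size)
    return stack, layout, truth


# ---------------------------------------------------------------------------
# Registration

def find_shift(reference: np.ndarray, image: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) such that ``np.roll(image, (dy, dx))`` best matches
    ``reference`` under circular cross-correlation (FFT implementation,
    exactly equivalent to the brute-force shift search)."""
    a = reference - reference.mean()
    b = image - image.mean()
    if not a.any() or not b.any():
        raise ValueError("flat (zero-variance) reference plane; cannot register")
    corr = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
    dy, dx = np.unravel_index(int(corr.argmax()), corr.shape)
    H, W = corr.shape
    if dy > H // 2:
        dy -= H
    if dx > W // 2:
        dx -= W
    return int(dy), int(dx)


def register_stack(stack: ImageStack) -> tuple[list[tuple[int, int]], ImageStack]:
    """Align every round to round 1 by maximum cross-correlation of the
    reference planes; the recovered shift is applied to all planes of the
    round.  Returns (per-round applied shifts, aligned stack)."""
    ref0 = stack.reference(0)
    shifts: list[tuple[int, int]] = []
    aligned = stack.images.copy()
    for r in range(stack.R):
        s = (0, 0) if r == 0 else find_shift(ref0, stack.reference(r))
        shifts.append(s)
        if s != (0, 0):
            aligned[r] = np.roll(stack.images[r], s, axis=(1, 2))
    return shifts, ImageStack(images=aligned, pixel_size=stack.pixel_size)


# ---------------------------------------------------------------------------
# Segmentation

@dataclass
class SegmentParams:
    min_area: int = 9             # px; smaller components discarded
    block_size: int = 31          # adaptive-threshold window, px (odd)
    contrast: float = 0.05        # required excess over the local mean
    min_distance: int = 5         # px between watershed seeds
    invert: bool = True           # cells dark on bright background
    smooth_sigma: float = 1.0     # distance-map smoothing before peak finding


def segment(reference: np.ndarray, params: SegmentParams | None = None) -> np.ndarray:
    """Adaptive local threshold + distance-transform watershed.

    Returns a labeled mask (0 background, 1..n cells).  ``invert=True``
    treats dark objects on a bright background (phase-contrast-like);
    use ``invert=False`` for an inverted universal-probe fluorescence
    reference where cells are already bright.
    """
    params = params or SegmentParams()
    img = np.asarray(reference, dtype=float)
    work = img.max() - img if params.invert else img
    local = threshold_local(work, params.block_size, method="gaussian")
    binary = work > (local + params.contrast)
    binary = ndi.binary_fill_holes(binary)
    binary = remove_small_objects(binary, max_size=params.min_area - 1)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(binary)
    smooth = ndi.gaussian_filter(dist, params.smooth_sigma) if params.smooth_sigma else dist
    coords = peak_local_max(smooth, min_distance=params.min_distance, labels=binary,
                            exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(binary)
    else:
        labels = watershed(-dist, markers, mask=binary)
    # drop under-sized fragments and relabel 1..n
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < params.min_area)
    labels[np.isin(labels, too_small)] = 0
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# Extraction

@dataclass
class CellTable:
    """Per-cell, per-round, per-channel intensity summaries from a stack."""

    cell_ids: list[int]                       # segmentation labels
    centroids_um: np.ndarray                  # (n, 2): x_um, y_um
    means: np.ndarray                         # (n, R, F)
    pixel_indices: dict[int, np.ndarray]      # label -> flat pixel indices
    background_indices: np.ndarray            # flat indices outside all cells
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)  # ellipse fits


MAX_BACKGROUND_PIXELS = 10_000
MAX_CELL_PIXELS = 400


def extract_cell_table(stack: ImageStack, labels: np.ndarray) -> CellTable:
    """Per-cell mean intensity and pixel samples for every round/channel.

    The background sample is all out-of-label pixels of the field,
    subsampled to at most 10^4 (deterministically).
    """
    if labels.shape != stack.shape:
        raise ValueError("labels shape must equal image shape")
    label_ids = [int(v) for v in np.unique(labels) if v > 0]
    n, R, F = len(label_ids), stack.R, stack.F
    means = np.zeros((n, R, F))
    pix: dict[int, np.ndarray] = {}
    sub_rng = np.random.default_rng(0)
    for i, lab in enumerate(label_ids):
        idx = np.flatnonzero(labels.ravel() == lab)
        if len(idx) > MAX_CELL_PIXELS:
            idx = np.sort(sub_rng.choice(idx, MAX_CELL_PIXELS, replace=False))
        pix[lab] = idx
    for r in range(R):
        for k in range(F):
            plane = stack.channel(r, k)
            if label_ids:
                means[:, r, k] = ndi.mean(plane, labels=labels, index=label_ids)
    bg = np.flatnonzero(labels.ravel() == 0)
    if len(bg) > MAX_BACKGROUND_PIXELS:
        bg = np.sort(sub_rng.choice(bg, MAX_BACKGROUND_PIXELS, replace=False))
    rows = []
    px = stack.pixel_size
    for prop in regionprops(labels):
        rows.append({
            "cell_id": prop.label,
            "x_um": prop.centroid[1] * px,
            "y_um": prop.centroid[0] * px,
            "a_um": prop.axis_major_length / 2 * px,
            "b_um": max(prop.axis_minor_length / 2 * px, px / 2),
            "theta": float(-prop.orientation),
            "area_px": prop.area,
        })
    regions = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "a_um",
                                          "b_um", "theta", "area_px"])
    centroids = regions[["x_um", "y_um"]].to_numpy() if n else np.empty((0, 2))
    return CellTable(cell_ids=label_ids, centroids_um=centroids, means=means,
                     pixel_indices=pix, background_indices=bg, regions=regions)


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass
class PipelineResult:
    shifts: list[tuple[int, int]]
    labels: np.ndarray
    table: CellTable
    observed: np.ndarray                      # (n, R) called symbols, 0 = dropout
    decoded: list[DecodeResult]
    cellmap: cm.CellMap                       # decoded cells; taxon "" if not identified


def run_pipeline(
    stack: ImageStack,
    codebook: Codebook,
    segment_params: SegmentParams | None = None,
    alpha: float = 0.05,
    min_hd: int | None = None,
) -> PipelineResult:
    """register -> segment -> extract -> call symbols -> decode.

    Segmentation runs on the registered round-1 reference plane.  Each
    cell/round symbol is the brightest channel significantly above the
    out-of-cell background (one-sided Welch t-test); cells dark in more
    than 3 rounds are lost; the rest are decoded with error correction.
    """
    shifts, aligned = register_stack(stack)
    labels = segment(aligned.reference(0), segment_params)
    table = extract_cell_table(aligned, labels)
    n, R = len(table.cell_ids), aligned.R
    observed = np.zeros((n, R), dtype=np.int16)
    for r in range(R):
        planes = [aligned.channel(r, k).ravel() for k in range(aligned.F)]
        bg_samples = [p[table.background_indices] for p in planes]
        for i, lab in enumerate(table.cell_ids):
            idx = table.pixel_indices[lab]
            cell_samples = [p[idx] for p in planes]
            observed[i, r] = call_symbol(cell_samples, bg_samples, alpha=alpha)

    if min_hd is None:
        min_hd = codebook.min_hd()
    decoded: list[DecodeResult] = []
    lost = np.array([mark_lost(row) for row in observed], dtype=bool)
    if (~lost).any():
        ident, tax_idx, corr = decode_barcodes(observed[~lost], codebook, min_hd=min_hd)
    pos = 0
    statuses, taxa_out = [], []
    for i, lab in enumerate(table.cell_ids):
        cid = f"seg{lab:05d}"
        if lost[i]:
            decoded.append(DecodeResult(cell_id=cid, status="lost"))
        elif ident[pos]:
            decoded.append(DecodeResult(cell_id=cid, status="identified",
                                        taxon=codebook.taxa[int(tax_idx[pos])],
                                        corrected_bits=int(corr[pos])))
        else:
            decoded.append(DecodeResult(cell_id=cid, status="unidentified"))
        if not lost[i]:
            pos += 1
        statuses.append(decoded[-1].status)
        taxa_out.append(decoded[-1].taxon or "")

    cells = table.regions.copy()
    cells["cell_id"] = [f"seg{lab:05d}" for lab in table.cell_ids]
    cells["taxon"] = taxa_out
    cells["status"] = statuses
    out_map = cm.CellMap(cells[["cell_id", "x_um", "y_um", "a_um", "b_um",
                                "theta", "taxon", "status"]],
                         mask=np.ones(stack.shape, dtype=bool),
                         pixel_size=stack.pixel_size)
    return PipelineResult(shifts=shifts, labels=labels, table=table,
                          observed=observed, decoded=decoded, cellmap=out_map)


def match_to_truth(result: PipelineResult, truth_map: cm.CellMap,
                   truth: pd.DataFrame) -> pd.DataFrame:
    """Match each planted cell to the segmented cell containing its centroid.

    Returns the truth table with ``called_taxon``/``status`` columns
    ("" / "missed" where no segment covers the planted centroid); the basis
    for end-to-end identification rates on synthetic stacks.
    """
    labels = result.labels
    px = truth_map.pixel_size
    by_label = {f"seg{lab:05d}": i for i, lab in enumerate(result.table.cell_ids)}
    called, status = [], []
    for _, row in truth_map.cells.iterrows():
        r = int(row["y_um"] / px)
        c = int(row["x_um"] / px)
        lab = labels[r, c] if (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]) else 0
        if lab == 0:
            called.append("")
            status.append("missed")
            continue
        res = result.decoded[by_label[f"seg{lab:05d}"]]
        called.append(res.taxon or "")
        status.append(res.status)
    out = truth.copy()
    out["called_taxon"] = called
    out["status"] = status
    return out
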