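"""Taxon-labeled cell maps: ellipse cells inside a region-of-interest mask.

A CellMap holds one field's segmented or planted cells — centroid (µm),
ellipse semi-axes (µm), orientation and taxon label — together with the
binary mask of the analyzed region (e.g. the root surface).  Synthetic
layout generators (uniform random and Thomas-process clustered) produce
the maps the spatial statistics are validated on.

Coordinates are 0-based with origin at the image top-left; x runs along
columns, y along rows; centroids are in µm via ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import draw

#: Default physical pixel size, µm per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.125

#: Default bacterial cell semi-axes, µm (a rod ~2 µm x 0.7 µm).
DEFAULT_A_UM = 1.0
DEFAULT_B_UM = 0.35

CELL_COLUMNS = ["cell_id", "x_um", "y_um", "a_um", "b_um", "theta", "taxon"]


@dataclass
class CellMap:
    """Cells (one row per cell) within a binary region-of-interest mask."""

    cells: pd.DataFrame
    mask: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table missing columns {missing}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def taxa(self) -> tuple[str, ...]:
        labeled = self.cells["taxon"].dropna()
        return tuple(sorted(set(labeled[labeled != ""])))

    def mask_area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2

    def cells_of(self, taxon: str) -> pd.DataFrame:
        return self.cells[self.cells["taxon"] == taxon]

    def cell_pixels(self, row: pd.Series, dilate_px: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Raster footprint (row indices, column indices) of one cell."""
        r = row["y_um"] / self.pixel_size
        c = row["x_um"] / self.pixel_size
        r_rad = row["b_um"] / self.pixel_size + dilate_px
        c_rad = row["a_um"] / self.pixel_size + dilate_px
        return draw.ellipse(r, c, max(r_rad, 0.5), max(c_rad, 0.5),
                            shape=self.shape, rotation=float(row["theta"]))

    def footprint(self, taxon: str | None = None, dilate_px: int = 0) -> np.ndarray:
        """Boolean raster of all cells (optionally one taxon), clipped to the
        frame; used for dipole hit-tests and coverage densities."""
        out = np.zeros(self.shape, dtype=bool)
        table = self.cells if taxon is None else self.cells_of(taxon)
        for _, row in table.iterrows():
            rr, cc = self.cell_pixels(row, dilate_px=dilate_px)
            out[rr, cc] = True
        return out


def full_frame_mask(shape: tuple[int, int]) -> np.ndarray:
    return np.ones(shape, dtype=bool)


def _make_cells_frame(xy_um: np.ndarray, taxa: Sequence[str], a_um: float,
                      b_um: float, thetas: np.ndarray) -> pd.DataFrame:
    n = len(xy_um)
    return pd.DataFrame({
        "cell_id": [f"cell{i:05d}" for i in range(n)],
        "x_um": xy_um[:, 0],
        "y_um": xy_um[:, 1],
        "a_um": a_um,
        "b_um": b_um,
        "theta": thetas,
        "taxon": list(taxa),
    })


def _sample_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator,
                    pixel_size: float, min_sep_um: float = 0.0,
                    max_tries: int = 200) -> np.ndarray:
    """Uniform points (µm) inside the mask, with optional minimal separation.

    Raises if the layout cannot be packed after bounded retries.
    """
    H, W = mask.shape
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        batch = rng.uniform(0, [W * pixel_size, H * pixel_size], size=(max(4 * n, 64), 2))
        cols = np.clip((batch[:, 0] / pixel_size).astype(int), 0, W - 1)
        rows = np.clip((batch[:, 1] / pixel_size).astype(int), 0, H - 1)
        batch = batch[mask[rows, cols]]
        for p in batch:
            if min_sep_um > 0 and pts:
                d2 = np.sum((np.asarray(pts) - p) ** 2, axis=1)
                if d2.min() < min_sep_um**2:
                    continue
            pts.append(p)
            if len(pts) == n:
                break
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} cells with min separation {min_sep_um} um "
                f"after {max_tries} sampling rounds (layout too crowded)")
    return np.asarray(pts).reshape(len(pts), 2)


def random_cellmap(
    n_cells: int,
    taxa: Sequence[str],
    shape: tuple[int, int] = (800, 800),
    pixel_size: float = 0.25,
    mask: np.ndarray | None = None,
    a_um: float = DEFAULT_A_UM,
    b_um: float = DEFAULT_B_UM,
    min_sep_um: float = 0.0,
    proportions: Sequence[float] | None = None,
    seed: int = 0,
) -> CellMap:
    """Complete-spatial-randomness layout: uniform positions and
    orientations, taxa drawn independently of position."""
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = full_frame_mask(shape)
    xy = _sample_in_mask(mask, n_cells, rng, pixel_size, min_sep_um=min_sep_um)
    p = None if proportions is None else np.asarray(proportions) / np.sum(proportions)
    labels = rng.choice(list(taxa), size=n_cells, p=p)
    thetas = rng.uniform(0, np.pi, size=n_cells)
    return CellMap(_make_cells_frame(xy, labels, a_um, b_um, thetas), mask, pixel_size)


def clustered_cellmap(
    n_parents: int,
    offspring_mean: float,
    cluster_sd_um: float,
    taxa: Sequence[str],
    shape: tuple[int, int] = (800, 800),
    pixel_size: float = 0.25,
    mask: np.ndarray | None = None,
    a_um: float = DEFAULT_A_UM,
    b_um: float = DEFAULT_B_UM,
    taxa_mixing: str = "per-parent",
    pair_fidelity: float = 1.0,
    seed: int = 0,
) -> CellMap:
    """Thomas-process layout: Poisson offspring scattered with Gaussian
    spread ``cluster_sd_um`` around uniformly placed parents.

    ``taxa_mixing`` controls how taxa relate to clusters:

    * ``"per-parent"`` — one taxon per cluster (segregated microcolonies);
    * ``"shared"`` — every cell's taxon drawn uniformly, independent of
      the cluster (clustered layout but no taxon association);
    * ``"paired"`` — consecutive taxa form pairs (taxa[0]+taxa[1], ...)
      and each cluster hosts one pair, planting positive association
      within pairs.  ``pair_fidelity`` is the probability a cell follows
      its cluster's pair rather than a uniform draw, so sweeping it tunes
      the planted association strength.
    """
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = full_frame_mask(shape)
    H, W = mask.shape
    parents = _sample_in_mask(mask, n_parents, rng, pixel_size)
    pts: list[np.ndarray] = []
    labels: list[str] = []
    taxa = list(taxa)
    if taxa_mixing == "paired" and len(taxa) % 2:
        raise ValueError("paired mixing needs an even number of taxa")
    pairs = [taxa[i:i + 2] for i in range(0, len(taxa), 2)]
    for parent in parents:
        k = rng.poisson(offspring_mean)
        parent_taxon = taxa[int(rng.integers(len(taxa)))]
        parent_pair = pairs[int(rng.integers(len(pairs)))]
        placed = 0
        guard = 0
        while placed < k and guard < 50 * max(k, 1):
            cand = parent + rng.normal(0, cluster_sd_um, size=2)
            guard += 1
            col = int(cand[0] / pixel_size)
            row = int(cand[1] / pixel_size)
            if not (0 <= row < H and 0 <= col < W and mask[row, col]):
                continue
            pts.append(cand)
            if taxa_mixing == "per-parent":
                labels.append(parent_taxon)
            elif taxa_mixing == "shared":
                labels.append(taxa[int(rng.integers(len(taxa)))])
            elif taxa_mixing == "paired":
                source = parent_pair if rng.random() < pair_fidelity else taxa
                labels.append(source[int(rng.integers(len(source)))])
            else:
                raise ValueError(f"unknown taxa_mixing {taxa_mixing!r}")
            placed += 1
    xy = np.asarray(pts) if pts else np.empty((0, 2))
    thetas = rng.uniform(0, np.pi, size=len(xy))
    return CellMap(_make_cells_frame(xy, labels, a_um, b_um, thetas), mask, pixel_size)


def write_cellmap_csv(cellmap: CellMap, path) -> None:
    cellmap.cells.to_csv(path, index=False)


def read_cellmap_csv(path, mask: np.ndarray, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> CellMap:
    return CellMap(pd.read_csv(path), mask, pixel_size)
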