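"""Seeded synthetic fixture bundles exercising the whole workflow.

Each scenario produces, bit-reproducibly from one seed, the artifacts a
real experiment would: a minimal-distance barcode pool, a 12-taxon
codebook, a probe-specificity (dG) matrix, and either a multi-round image
stack with planted ground truth or a taxon-labeled cell map.

Scenarios
---------
``syncom12-ideal``
    12 taxa, perfectly specific probes (diagonal dG), clean drift-free
    stack — the everything-works baseline.
``syncom12-nonspecific``
    Same community but a fraction of off-target probe-species pairs fall
    in the non-specific dG band (-13.0, -7.3) kcal/mol, producing symbol
    errors for the decoder to correct.
``root-clustered``
    An elongated root-like mask with Thomas-process microcolonies — input
    for the spatial statistics.
``drifted-stack``
    The ideal community imaged with planted per-round integer drifts up
    to 10 px, for registration checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from seerfish import cellmap as cm
from seerfish.codebook import (Codebook, CodebookPool, draw_codebook,
                               generate_pool, write_codebook_csv, write_pool_csv)
from seerfish.hybridization import SpecificityModel, write_dg_csv
from seerfish.imaging import ImageStack, SynthConfig, synthesize_stack

SCENARIOS = ("syncom12-ideal", "syncom12-nonspecific", "root-clustered",
             "drifted-stack")

TAXA12 = tuple(f"sp{i:02d}" for i in range(1, 13))

#: restarts for fixture pool construction (kept modest; capacity studies
#: use generate_pool directly with >= 100 restarts)
POOL_RESTARTS = 8


@dataclass
class FixtureBundle:
    scenario: str
    seed: int
    pool: CodebookPool
    codebook: Codebook
    dg: pd.DataFrame
    model: SpecificityModel
    stack: ImageStack | None = None
    cellmap: cm.CellMap | None = None
    truth: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pool_csv(self.pool, outdir / "pool.csv")
        write_codebook_csv(self.codebook, outdir / "codebook.csv")
        write_dg_csv(self.dg, outdir / "dg.csv")
        if self.stack is not None:
            self.stack.save(outdir / "stack")
        if self.cellmap is not None:
            cm.write_cellmap_csv(self.cellmap, outdir / "cellmap.csv")
            tifffile.imwrite(outdir / "mask.tif",
                             self.cellmap.mask.astype(np.uint8))
        if self.truth is not None:
            self.truth.to_csv(outdir / "truth.csv", index=False)


def _diagonal_dg(taxa) -> pd.DataFrame:
    dg = pd.DataFrame(-5.0, index=list(taxa), columns=list(taxa))
    np.fill_diagonal(dg.values, -14.0)
    return dg


def _nonspecific_dg(taxa, rng: np.random.Generator,
                    offdiag_fraction: float = 0.25) -> pd.DataFrame:
    """Diagonal specific; a fraction of off-diagonal pairs in the
    non-specific band (-13.0, -7.3) kcal/mol."""
    dg = _diagonal_dg(taxa)
    n = len(dg)
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    k = int(round(offdiag_fraction * len(off)))
    pick = rng.choice(len(off), size=k, replace=False)
    for p in pick:
        i, j = off[p]
        dg.iat[i, j] = rng.uniform(-12.9, -7.4)
    return dg


def _root_mask(shape: tuple[int, int]) -> np.ndarray:
    """Elongated band (a root lying along the image) as the ROI."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    top, bottom = int(0.15 * H), int(0.85 * H)
    mask[top:bottom, :] = True
    return mask


def make_fixtures(scenario: str, seed: int = 0) -> FixtureBundle:
    """Build one scenario's bundle in memory (see module docstring)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; known: {', '.join(SCENARIOS)}")
    rng = np.random.default_rng(seed)
    pool = generate_pool(3, 8, 4, seed=seed, restarts=POOL_RESTARTS)
    codebook = draw_codebook(pool, 12, seed=seed, taxa=TAXA12)

    if scenario == "syncom12-nonspecific":
        dg = _nonspecific_dg(TAXA12, rng)
    else:
        dg = _diagonal_dg(TAXA12)
    model = SpecificityModel.from_dg(dg)

    bundle = FixtureBundle(scenario=scenario, seed=seed, pool=pool,
                           codebook=codebook, dg=dg, model=model)

    if scenario in ("syncom12-ideal", "syncom12-nonspecific"):
        cfg = SynthConfig(model=model, shape=(256, 256), n_cells=48,
                          min_sep_um=3.0, drift=None, seed=seed)
        bundle.stack, bundle.cellmap, bundle.truth = synthesize_stack(cfg, codebook)
    elif scenario == "drifted-stack":
        drift = [(0, 0), (3, -2), (-5, 4), (10, 0), (0, -10),
                 (7, 7), (-8, -3), (2, 9)]
        cfg = SynthConfig(model=model, shape=(256, 256), n_cells=48,
                          min_sep_um=3.0, drift=drift, seed=seed)
        bundle.stack, bundle.cellmap, bundle.truth = synthesize_stack(cfg, codebook)
    elif scenario == "root-clustered":
        shape = (320, 1000)        # 80 x 250 µm at 0.25 µm/px
        mask = _root_mask(shape)
        bundle.cellmap = cm.clustered_cellmap(
            n_parents=40, offspring_mean=12, cluster_sd_um=3.0,
            taxa=TAXA12[:6], shape=shape, pixel_size=0.25, mask=mask,
            taxa_mixing="paired", seed=seed)
    return bundle
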