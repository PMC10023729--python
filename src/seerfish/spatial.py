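"""Micron-scale spatial statistics on taxon-labeled cell maps.

Three complementary views of community spatial structure:

* **Linear-dipole pair correlation** g(r): throw segments of length r with
  uniform anchor and orientation inside the region mask and score the
  probability P_r that the two ends hit cells of the two populations;
  g(r) = P_r / (2 D_i D_j) across taxa and P_r / D^2 within one taxon,
  where D is the areal coverage density.  g = 1 under spatial randomness,
  g > 1 for clustering at scale r.

* **Contact frequency**: touching cell pairs (1-pixel-dilated ellipse
  footprints intersecting) per µm^2 of mask, compared with random
  placements of the same ellipses at the same per-taxon densities.

* **Spatial association**: co-occurrence of two taxa within a fixed range
  (default 10 µm) relative to a taxon-label permutation null that keeps
  every cell position and all abundances fixed; differential association
  compares treatment and control groups of roots by log2 fold change with
  a t-test across roots and Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from scipy.spatial import cKDTree

from seerfish.cellmap import CellMap


def coverage_density(cellmap: CellMap, taxon: str | None = None) -> float:
    """Areal density: cell footprint area (clipped to the mask) / mask area."""
    if not cellmap.mask.any():
        raise ValueError("empty region mask")
    fp = cellmap.footprint(taxon) & cellmap.mask
    return float(fp.sum()) / float(cellmap.mask.sum())


@dataclass
class CorrelationCurve:
    taxon_i: str
    taxon_j: str
    radii: np.ndarray          # µm
    g: np.ndarray
    p_hit: np.ndarray          # raw both-end hit probabilities P_r
    n_dipoles: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None


def pair_correlation(
    cellmap: CellMap,
    taxon_i: str,
    taxon_j: str,
    radii: Sequence[float],
    n_dipoles: int = 100_000,
    seed: int = 0,
    ci: bool = False,
    n_boot: int = 200,
    n_blocks: int = 16,
) -> CorrelationCurve:
    """Linear-dipole pair (cross-)correlation between two populations.

    Dipoles are sampled with uniform anchors in the mask and uniform
    orientations; a dipole counts only if both ends fall inside the mask.
    For i != j a hit means the two ends fall on cells of the two
    populations in either order.  The optional confidence band resamples
    dipoles by spatial block (anchor-position grid) bootstrap.
    """
    rng = np.random.default_rng(seed)
    for t in (taxon_i, taxon_j):
        if len(cellmap.cells_of(t)) == 0:
            raise ValueError(f"taxon {t!r} has no cells in the map")
    D_i = coverage_density(cellmap, taxon_i)
    D_j = coverage_density(cellmap, taxon_j)
    if D_i == 0 or D_j == 0:
        raise ValueError("zero coverage density")
    fp_i = cellmap.footprint(taxon_i)
    fp_j = fp_i if taxon_j == taxon_i else cellmap.footprint(taxon_j)
    mask = cellmap.mask
    H, W = mask.shape
    px = cellmap.pixel_size
    same = taxon_i == taxon_j

    g = np.empty(len(radii))
    p_hit = np.empty(len(radii))
    n_used = np.empty(len(radii), dtype=int)
    ci_low = np.empty(len(radii)) if ci else None
    ci_high = np.empty(len(radii)) if ci else None

    for ri, r_um in enumerate(radii):
        hits = np.empty(n_dipoles, dtype=bool)
        blocks = np.empty(n_dipoles, dtype=np.int32)
        filled = 0
        while filled < n_dipoles:
            m = max(2 * (n_dipoles - filled), 4096)
            ax = rng.uniform(0, W * px, size=m)
            ay = rng.uniform(0, H * px, size=m)
            theta = rng.uniform(0, 2 * np.pi, size=m)
            bx = ax + r_um * np.cos(theta)
            by = ay + r_um * np.sin(theta)
            ac = (ax / px).astype(int)
            ar = (ay / px).astype(int)
            bc = (bx / px).astype(int)
            br = (by / px).astype(int)
            inside = (ar >= 0) & (ar < H) & (ac >= 0) & (ac < W) & \
                     (br >= 0) & (br < H) & (bc >= 0) & (bc < W)
            idx = np.flatnonzero(inside)
            both_in = mask[ar[idx], ac[idx]] & mask[br[idx], bc[idx]]
            idx = idx[both_in]
            take = idx[: n_dipoles - filled]
            a_on_i = fp_i[ar[take], ac[take]]
            b_on_j = fp_j[br[take], bc[take]]
            if same:
                hit = a_on_i & b_on_j
            else:
                a_on_j = fp_j[ar[take], ac[take]]
                b_on_i = fp_i[br[take], bc[take]]
                hit = (a_on_i & b_on_j) | (a_on_j & b_on_i)
            k = len(take)
            hits[filled:filled + k] = hit
            # spatial block of the anchor, for the bootstrap CI
            nb = int(np.sqrt(n_blocks))
            blocks[filled:filled + k] = (np.minimum(ar[take] * nb // H, nb - 1) * nb
                                         + np.minimum(ac[take] * nb // W, nb - 1))
            filled += k
        P = hits.mean()
        denom = (D_i * D_j) if same else (2 * D_i * D_j)
        p_hit[ri] = P
        g[ri] = P / denom
        n_used[ri] = n_dipoles
        if ci:
            nb2 = int(np.sqrt(n_blocks)) ** 2
            block_sums = np.bincount(blocks, weights=hits, minlength=nb2)
            block_counts = np.bincount(blocks, minlength=nb2)
            keep = block_counts > 0
            bs, bc_ = block_sums[keep], block_counts[keep]
            boots = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.integers(len(bs), size=len(bs))
                boots[b] = bs[pick].sum() / bc_[pick].sum() / denom
            ci_low[ri], ci_high[ri] = np.percentile(boots, [2.5, 97.5])
    return CorrelationCurve(taxon_i=taxon_i, taxon_j=taxon_j,
                            radii=np.asarray(radii, dtype=float), g=g,
                            p_hit=p_hit, n_dipoles=n_used,
                            ci_low=ci_low, ci_high=ci_high)


# ---------------------------------------------------------------------------
# Contact frequency

@dataclass
class ContactResult:
    taxon_a: str
    taxon_b: str
    events: int
    frequency: float            # events per µm^2 of mask
    null_mean: float
    null_sd: float
    fold: float
    p_value: float
    significant: bool = False


def _contact_pairs(cellmap: CellMap, dilate_px: int = 1) -> set[tuple[int, int]]:
    """Index pairs of cells whose dilated footprints intersect."""
    cells = cellmap.cells.reset_index(drop=True)
    n = len(cells)
    if n < 2:
        return set()
    xy = cells[["x_um", "y_um"]].to_numpy()
    reach = cells["a_um"].to_numpy() + dilate_px * cellmap.pixel_size
    tree = cKDTree(xy)
    candidates = tree.query_pairs(2 * reach.max(), output_type="ndarray")
    out: set[tuple[int, int]] = set()
    cache: dict[int, set[int]] = {}

    def pixset(i: int) -> set[int]:
        if i not in cache:
            rr, cc = cellmap.cell_pixels(cells.iloc[i], dilate_px=dilate_px)
            cache[i] = set(rr * cellmap.shape[1] + cc)
        return cache[i]

    for i, j in candidates:
        d = np.hypot(*(xy[i] - xy[j]))
        if d > reach[i] + reach[j]:
            continue
        if pixset(int(i)) & pixset(int(j)):
            out.add((int(min(i, j)), int(max(i, j))))
    return out


def _count_events(pairs: set[tuple[int, int]], labels: np.ndarray,
                  taxa: Sequence[str]) -> dict[tuple[str, str], int]:
    counts = {pair: 0 for pair in combinations(sorted(taxa), 2)}
    for t in sorted(taxa):
        counts[(t, t)] = 0
    for i, j in pairs:
        a, b = sorted((labels[i], labels[j]))
        if (a, b) in counts:
            counts[(a, b)] += 1
    return counts


def contact_analysis(
    cellmap: CellMap,
    n_sims: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    include_self: bool = False,
    method: str = "footprint",
    range_um: float = 1.0,
) -> list[ContactResult]:
    """Contact events per taxon pair against a random-ellipse null.

    Observed contacts are dilated-footprint intersections (or
    centroid-distance <= range_um with ``method="centroid"``).  The null
    redraws every cell's position and orientation uniformly in the mask,
    keeping per-taxon cell counts and axis lengths; the empirical
    upper-tail p-value is Bonferroni-corrected over the tested pairs.
    """
    rng = np.random.default_rng(seed)
    taxa = cellmap.taxa
    area = cellmap.mask_area_um2()
    cells = cellmap.cells.reset_index(drop=True)
    labels = cells["taxon"].to_numpy()

    def count_for(cmap: CellMap) -> dict[tuple[str, str], int]:
        if method == "footprint":
            pairs = _contact_pairs(cmap)
        elif method == "centroid":
            xy = cmap.cells[["x_um", "y_um"]].to_numpy()
            tree = cKDTree(xy)
            pairs = {tuple(sorted(p)) for p in tree.query_pairs(range_um)}
        else:
            raise ValueError(f"unknown contact method {method!r}")
        return _count_events(pairs, cmap.cells["taxon"].to_numpy(), taxa)

    observed = count_for(cellmap)
    null_counts = {pair: np.empty(n_sims) for pair in observed}
    H, W = cellmap.shape
    px = cellmap.pixel_size
    for s in range(n_sims):
        sim = cells.copy()
        # uniform placement inside the mask, orientations uniform
        m = len(sim)
        pts = []
        while len(pts) < m:
            cand = rng.uniform(0, [W * px, H * px], size=(2 * m, 2))
            cc = np.clip((cand[:, 0] / px).astype(int), 0, W - 1)
            rr = np.clip((cand[:, 1] / px).astype(int), 0, H - 1)
            pts.extend(cand[cellmap.mask[rr, cc]])
        pts = np.asarray(pts[:m])
        sim["x_um"], sim["y_um"] = pts[:, 0], pts[:, 1]
        sim["theta"] = rng.uniform(0, np.pi, size=m)
        sim_counts = count_for(CellMap(sim, cellmap.mask, px))
        for pair in null_counts:
            null_counts[pair][s] = sim_counts[pair]

    results = []
    tested_pairs = [p for p in observed if include_self or p[0] != p[1]]
    m_tests = max(len(tested_pairs), 1)
    for pair in tested_pairs:
        obs = observed[pair]
        null = null_counts[pair]
        null_mean = float(null.mean())
        p = (1 + int((null >= obs).sum())) / (1 + n_sims)
        fold = obs / null_mean if null_mean > 0 else np.inf if obs else np.nan
        results.append(ContactResult(
            taxon_a=pair[0], taxon_b=pair[1], events=int(obs),
            frequency=obs / area, null_mean=null_mean, null_sd=float(null.std()),
            fold=float(fold), p_value=float(p),
            significant=bool(p < alpha / m_tests)))
    return results


# ---------------------------------------------------------------------------
# Spatial association (permutation test)

@dataclass
class AssociationResult:
    taxon_a: str
    taxon_b: str
    observed: int               # co-occurrence events pooled over roots
    null_mean: float
    fold: float                 # mean of per-root folds
    per_root_folds: list[float] = field(default_factory=list)
    p_value: float = np.nan
    significant: bool = False
    dropped: bool = False
    drop_reason: str = ""


def _cooccurrence_counts(labels_int: np.ndarray, pair_idx: np.ndarray,
                         n_taxa: int) -> np.ndarray:
    """Count close cell pairs per unordered taxon pair; returns a flat
    (n_taxa * n_taxa) array indexed by min*n + max."""
    if len(pair_idx) == 0:
        return np.zeros(n_taxa * n_taxa, dtype=np.int64)
    a = labels_int[pair_idx[:, 0]]
    b = labels_int[pair_idx[:, 1]]
    key = np.minimum(a, b) * n_taxa + np.maximum(a, b)
    return np.bincount(key, minlength=n_taxa * n_taxa)


def association_analysis(
    maps: Sequence[CellMap],
    range_um: float = 10.0,
    n_perm: int = 100,
    min_events: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    include_self: bool = False,
) -> list[AssociationResult]:
    """Taxon-pair co-occurrence within ``range_um`` vs a label-permutation null.

    Co-occurrence counts cell pairs of the two taxa with centroid distance
    <= range_um.  For each root the null randomly reassigns taxa over the
    same cell positions (abundances fixed, ``n_perm`` permutations); the
    per-root fold is observed / mean(null).  The pooled empirical p-value
    compares the total observed count with the permutation totals and is
    Bonferroni-corrected over tested pairs; pairs with fewer than
    ``min_events`` pooled observed events are dropped.
    """
    if not maps:
        raise ValueError("need at least one root map")
    rng = np.random.default_rng(seed)
    all_taxa = sorted({t for m in maps for t in m.taxa})
    n_taxa = len(all_taxa)
    tax_index = {t: i for i, t in enumerate(all_taxa)}

    obs_total = np.zeros(n_taxa * n_taxa, dtype=np.int64)
    null_total = np.zeros((n_perm, n_taxa * n_taxa))
    per_root_obs = []
    per_root_null_mean = []
    for cmap in maps:
        cells = cmap.cells[cmap.cells["taxon"].isin(all_taxa)].reset_index(drop=True)
        xy = cells[["x_um", "y_um"]].to_numpy()
        labels_int = np.array([tax_index[t] for t in cells["taxon"]])
        tree = cKDTree(xy)
        pair_idx = tree.query_pairs(range_um, output_type="ndarray")
        obs = _cooccurrence_counts(labels_int, pair_idx, n_taxa)
        nulls = np.empty((n_perm, n_taxa * n_taxa))
        for s in range(n_perm):
            nulls[s] = _cooccurrence_counts(rng.permutation(labels_int),
                                            pair_idx, n_taxa)
        obs_total += obs
        null_total += nulls
        per_root_obs.append(obs)
        per_root_null_mean.append(nulls.mean(axis=0))

    results = []
    pairs = [(a, b) for a in range(n_taxa) for b in range(a, n_taxa)
             if include_self or a != b]
    kept = []
    for a, b in pairs:
        key = a * n_taxa + b
        if obs_total[key] >= min_events:
            kept.append((a, b))
    m_tests = max(len(kept), 1)
    for a, b in pairs:
        key = a * n_taxa + b
        obs = int(obs_total[key])
        null_mean = float(null_total[:, key].mean())
        folds = [float(o[key] / nm[key]) if nm[key] > 0 else np.nan
                 for o, nm in zip(per_root_obs, per_root_null_mean)]
        folds_ok = [f for f in folds if np.isfinite(f)]
        res = AssociationResult(
            taxon_a=all_taxa[a], taxon_b=all_taxa[b], observed=obs,
            null_mean=null_mean,
            fold=float(np.mean(folds_ok)) if folds_ok else np.nan,
            per_root_folds=folds)
        if (a, b) not in kept:
            res.dropped = True
            res.drop_reason = f"observed events {obs} < min_events {min_events}"
        else:
            p = (1 + int((null_total[:, key] >= obs).sum())) / (1 + n_perm)
            res.p_value = float(p)
            res.significant = bool(p < alpha / m_tests)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Differential association

@dataclass
class DifferentialResult:
    taxon_a: str
    taxon_b: str
    log2_fold_change: float
    p_value: float
    significant: bool
    applicable: bool
    note: str = ""


def differential_association(
    treated: Sequence[AssociationResult],
    control: Sequence[AssociationResult],
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Per-pair log2[(treated fold)/(control fold)] with a t-test across roots.

    Each group's fold is the per-root ratio of observed association
    frequency to the permutation-null frequency.  A pair must be detected
    (not dropped) in both groups to be applicable; the t-test is a
    two-sided Welch test on per-root log2 folds, Bonferroni-corrected by
    the number of unique pairs detected across all roots in either group.
    """
    def keyed(results):
        return {(r.taxon_a, r.taxon_b): r for r in results}

    t_map, c_map = keyed(treated), keyed(control)
    detected = {k for k, r in t_map.items() if not r.dropped} | \
               {k for k, r in c_map.items() if not r.dropped}
    m = max(len(detected), 1)
    out = []
    for key in sorted(set(t_map) | set(c_map)):
        a, b = key
        rt, rc = t_map.get(key), c_map.get(key)
        if rt is None or rc is None or rt.dropped or rc.dropped:
            out.append(DifferentialResult(a, b, np.nan, np.nan, False, False,
                                          note="pair not detected in both groups"))
            continue
        lt = np.log2([f for f in rt.per_root_folds if np.isfinite(f) and f > 0])
        lc = np.log2([f for f in rc.per_root_folds if np.isfinite(f) and f > 0])
        if len(lt) < 2 or len(lc) < 2:
            out.append(DifferentialResult(a, b, np.nan, np.nan, False, False,
                                          note="too few roots with finite folds"))
            continue
        lfc = float(lt.mean() - lc.mean())
        if np.allclose(lt, lt[0]) and np.allclose(lc, lc[0]) and np.isclose(lt[0], lc[0]):
            p = 1.0  # identical degenerate groups
        else:
            p = float(stats.ttest_ind(lt, lc, equal_var=False).pvalue)
            if not np.isfinite(p):
                p = 1.0
        out.append(DifferentialResult(a, b, lfc, p, bool(p < alpha / m), True))
    return out


def association_edges(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Edge list (taxon_a, taxon_b, fold, p, significant) for network views."""
    return pd.DataFrame({
        "taxon_a": [r.taxon_a for r in results],
        "taxon_b": [r.taxon_b for r in results],
        "fold": [r.fold for r in results],
        "p": [r.p_value for r in results],
        "significant": [r.significant for r in results],
    })
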