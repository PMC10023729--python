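"""Probe thermodynamics and the stochastic hybridization-intensity model.

Hybridization efficiency follows a two-state binding isotherm,
``E = e^(-dG/RT) Cp / (1 + e^(-dG/RT) Cp)``, with dG the probe-target free
energy (kcal/mol) and Cp the probe concentration.  Probe-species pairs are
classed by dG into specific, non-specific and background binding; the
fluorescence a cell shows in a channel is the sum over probes present in
that channel of lognormal intensity draws whose log10 mean depends on the
binding class (or on measured per-pair statistics).  Intensities are in
CCD-normalized units (1 = detector maximum), so a log10 mean of -2 means
1% of the detector range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from seerfish.codebook import Codebook

#: Molar gas constant, kcal mol^-1 K^-1.
GAS_CONSTANT = 1.98720425e-3
#: Default hybridization temperature (46 C) and probe concentration (250 nM).
DEFAULT_TEMPERATURE_K = 319.15
DEFAULT_PROBE_CONC_M = 2.5e-7

#: log10 intensity class means (CCD-normalized) and shared spread.
CLASS_LOG_MEANS = {"specific": -0.3, "nonspecific": -0.9, "background": -2.0}
CLASS_LOG_SIGMA = 0.3

#: dG class boundaries, kcal/mol: specific below, background above,
#: non-specific binding strictly between.
DG_SPECIFIC_CUTOFF = -13.0
DG_BACKGROUND_CUTOFF = -7.3


def hybridization_efficiency(
    dG: float | np.ndarray,
    Cp: float = DEFAULT_PROBE_CONC_M,
    T: float = DEFAULT_TEMPERATURE_K,
) -> float | np.ndarray:
    """Predicted fraction of target sites bound at equilibrium.

    Parameters
    ----------
    dG : free-energy change of probe-target binding, kcal/mol.
    Cp : probe concentration, molar.
    T : temperature, kelvin.
    """
    if np.any(np.asarray(Cp) <= 0) or np.any(np.asarray(T) <= 0):
        raise ValueError("Cp and T must be positive")
    # computed in log space so very negative dG cannot overflow
    log_kc = -np.asarray(dG, dtype=float) / (GAS_CONSTANT * T) + np.log(Cp)
    out = 1.0 / (1.0 + np.exp(-log_kc))
    return float(out) if np.isscalar(dG) else out


def classify_binding(dG: float) -> str:
    """Class a probe-species pair by binding free energy (kcal/mol)."""
    if dG <= DG_SPECIFIC_CUTOFF:
        return "specific"
    if dG < DG_BACKGROUND_CUTOFF:
        return "nonspecific"
    return "background"


@dataclass(frozen=True)
class ProbeCandidate:
    probe_id: str
    target_taxon: str
    length: int
    gc_fraction: float
    min_mismatches_to_nontarget: int
    dG_target: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("probe length must be positive")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")


def filter_candidates(
    candidates: Sequence[ProbeCandidate],
    min_length: int = 18,
    max_length: int = 21,
    min_gc: float = 0.45,
    max_gc: float = 0.60,
    min_mismatches: int = 3,
    dG_cutoff: float = DG_SPECIFIC_CUTOFF,
) -> tuple[list[ProbeCandidate], dict[str, list[str]]]:
    """Apply the standard probe-candidate filters.

    A probe is kept iff its length is 18-21 nt, GC fraction 45-60%, it has
    at least 3 mismatches to every non-target sequence, and its on-target
    dG is below -13.0 kcal/mol (specific binding).  Returns the kept list
    and, per rejected probe, the list of failed filters.
    """
    kept: list[ProbeCandidate] = []
    reasons: dict[str, list[str]] = {}
    for cand in candidates:
        why = []
        if not (min_length <= cand.length <= max_length):
            why.append("length")
        if not (min_gc <= cand.gc_fraction <= max_gc):
            why.append("gc")
        if cand.min_mismatches_to_nontarget < min_mismatches:
            why.append("mismatches")
        if not (cand.dG_target < dG_cutoff):
            why.append("dG")
        if why:
            reasons[cand.probe_id] = why
        else:
            kept.append(cand)
    return kept, reasons


@dataclass
class SpecificityModel:
    """Per probe x species description of hybridization strength.

    ``mu`` and ``sigma`` are (n_probes, n_species) matrices of log10
    intensity mean and spread.  In dG-classed mode they come from classing
    a dG matrix into specific/nonspecific/background; in measured mode
    they are supplied directly.  ``probe_targets`` names the taxon each
    probe was designed against, which determines the fluorescence channel
    the probe occupies in a given round (the channel the codebook assigns
    to its target in that round).
    """

    mu: pd.DataFrame            # rows: probes, columns: species
    sigma: pd.DataFrame
    probe_targets: tuple[str, ...]
    mode: str = "dG-classed"
    dG: pd.DataFrame | None = None
    class_means: dict[str, float] = field(default_factory=lambda: dict(CLASS_LOG_MEANS))
    class_sigma: float = CLASS_LOG_SIGMA

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have identical shape")
        if len(self.probe_targets) != len(self.mu.index):
            raise ValueError("one target taxon per probe row required")
        if (self.sigma.to_numpy() < 0).any():
            raise ValueError("sigma must be non-negative")

    @property
    def probes(self) -> tuple[str, ...]:
        return tuple(self.mu.index)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.mu.columns)

    @classmethod
    def from_dg(
        cls,
        dG: pd.DataFrame,
        probe_targets: Sequence[str] | None = None,
        class_means: dict[str, float] | None = None,
        class_sigma: float = CLASS_LOG_SIGMA,
    ) -> "SpecificityModel":
        """Build the class-based model from a probe x species dG matrix.

        When ``probe_targets`` is omitted the probe rows are taken to
        target the like-named species columns (one probe per taxon).
        """
        means = dict(CLASS_LOG_MEANS) if class_means is None else dict(class_means)
        mu = dG.map(lambda g: means[classify_binding(float(g))]).astype(float)
        sigma = pd.DataFrame(class_sigma, index=dG.index, columns=dG.columns, dtype=float)
        if probe_targets is None:
            probe_targets = tuple(str(p) for p in dG.index)
        return cls(mu=mu, sigma=sigma, probe_targets=tuple(probe_targets),
                   mode="dG-classed", dG=dG, class_means=means, class_sigma=class_sigma)

    @classmethod
    def from_measured(
        cls,
        mu: pd.DataFrame,
        sigma: pd.DataFrame,
        probe_targets: Sequence[str] | None = None,
    ) -> "SpecificityModel":
        """Model from measured per probe x species log10 intensity stats."""
        if probe_targets is None:
            probe_targets = tuple(str(p) for p in mu.index)
        return cls(mu=mu.astype(float), sigma=sigma.astype(float),
                   probe_targets=tuple(probe_targets), mode="measured")

    @classmethod
    def diagonal(cls, taxa: Sequence[str], class_sigma: float = CLASS_LOG_SIGMA,
                 dG_on: float = -14.0, dG_off: float = -5.0) -> "SpecificityModel":
        """Perfect-specificity model: each probe binds its own taxon
        specifically and every other taxon at background level."""
        taxa = [str(t) for t in taxa]
        dG = pd.DataFrame(dG_off, index=taxa, columns=taxa, dtype=float)
        np.fill_diagonal(dG.values, dG_on)
        return cls.from_dg(dG, probe_targets=taxa, class_sigma=class_sigma)

    def _matrices_for(self, codebook: Codebook) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu, sigma) restricted to probes targeting encoded taxa and to the
        codebook's species order, plus the per-probe target-taxon index."""
        taxa = list(codebook.taxa)
        missing = [t for t in taxa if t not in self.mu.columns]
        if missing:
            raise KeyError(f"taxa absent from specificity model: {missing}")
        keep = [i for i, tgt in enumerate(self.probe_targets) if tgt in taxa]
        if not keep:
            raise KeyError("no probe in the model targets an encoded taxon")
        mu = self.mu.iloc[keep][taxa].to_numpy(dtype=float)
        sigma = self.sigma.iloc[keep][taxa].to_numpy(dtype=float)
        tgt_idx = np.array([taxa.index(self.probe_targets[i]) for i in keep])
        return mu, sigma, tgt_idx


def _channel_matrix(codebook: Codebook, tgt_idx: np.ndarray, round_idx: int, F: int) -> np.ndarray:
    """C[p, k] = 1 iff probe p is carried in channel k during this round
    (the channel the codebook gives the probe's target taxon)."""
    codes = codebook.as_array()
    C = np.zeros((len(tgt_idx), F), dtype=float)
    C[np.arange(len(tgt_idx)), codes[tgt_idx, round_idx] - 1] = 1.0
    return C


def draw_cell_intensities(
    taxon: str,
    round_idx: int,
    codebook: Codebook,
    model: SpecificityModel,
    rng: np.random.Generator,
    F: int = 3,
) -> np.ndarray:
    """One cell's per-channel intensities for one round (length-F vector).

    Each probe contributes a lognormal draw ``10**N(mu, sigma)`` to the
    channel it occupies this round; channels carrying no probe receive a
    single background-class draw as a noise floor.
    """
    if taxon not in codebook.taxa:
        raise KeyError(f"taxon {taxon!r} not in codebook")
    mu, sigma, tgt_idx = model._matrices_for(codebook)
    i = list(codebook.taxa).index(taxon)
    C = _channel_matrix(codebook, tgt_idx, round_idx, F)
    draws = 10.0 ** rng.normal(mu[:, i], sigma[:, i])
    intensities = draws @ C
    empty = C.sum(axis=0) == 0
    if empty.any():
        bg_mu = model.class_means["background"]
        bg_sigma = model.class_sigma
        intensities[empty] += 10.0 ** rng.normal(bg_mu, bg_sigma, size=int(empty.sum()))
    return intensities


def simulate_intensity_stack(
    codebook: Codebook,
    model: SpecificityModel,
    taxon_of_cell: np.ndarray,
    rng: np.random.Generator,
    F: int = 3,
) -> np.ndarray:
    """Vectorized intensities for many cells: (n_cells, R, F) array.

    ``taxon_of_cell`` holds integer indices into ``codebook.taxa``.  Draws
    are independent per cell, per round and per probe.
    """
    mu, sigma, tgt_idx = model._matrices_for(codebook)
    n = len(taxon_of_cell)
    R = codebook.R
    mu_c = mu[:, taxon_of_cell].T        # (n, P)
    sg_c = sigma[:, taxon_of_cell].T
    out = np.empty((n, R, F), dtype=float)
    bg_mu = model.class_means["background"]
    bg_sigma = model.class_sigma
    for r in range(R):
        C = _channel_matrix(codebook, tgt_idx, r, F)
        draws = 10.0 ** rng.normal(mu_c, sg_c)
        I = draws @ C
        empty = C.sum(axis=0) == 0
        if empty.any():
            I[:, empty] += 10.0 ** rng.normal(bg_mu, bg_sigma, size=(n, int(empty.sum())))
        out[:, r, :] = I
    return out


def simulate_observed_barcodes(
    codebook: Codebook,
    model: SpecificityModel,
    n_cells_per_taxon: int = 1000,
    seed: int = 0,
    F: int = 3,
) -> pd.DataFrame:
    """Simulate cells and call each round's symbol as the brightest channel.

    Returns a table with columns ``cell_id``, ``true_taxon``,
    ``observed_barcode`` (digit string).  Simulated calling uses pure
    arg-max — codewords never contain 0, and dropout is negligible for
    high-copy rRNA targets — so observed symbols are always in 1..F.
    """
    rng = np.random.default_rng(seed)
    S = codebook.S
    taxon_of_cell = np.repeat(np.arange(S), n_cells_per_taxon)
    intensities = simulate_intensity_stack(codebook, model, taxon_of_cell, rng, F=F)
    symbols = intensities.argmax(axis=2) + 1      # (n, R)
    taxa = codebook.taxa
    return pd.DataFrame({
        "cell_id": [f"cell{i:06d}" for i in range(len(taxon_of_cell))],
        "true_taxon": [taxa[i] for i in taxon_of_cell],
        "observed_barcode": ["".join(map(str, row)) for row in symbols],
    })


def read_dg_csv(path) -> pd.DataFrame:
    """Probe x species dG matrix (kcal/mol), probes as the index column."""
    return pd.read_csv(path, index_col=0).astype(float)


def write_dg_csv(dG: pd.DataFrame, path) -> None:
    dG.to_csv(path)
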