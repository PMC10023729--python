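"""Error-robust F-color, R-round barcode codebooks.

A barcode assigns one fluorophore color (symbol in 1..F) to each of R
imaging rounds; a codebook assigns barcodes to taxa.  Keeping every pair of
codewords at Hamming distance >= 2k lets the decoder correct up to k
per-round detection errors.  This module constructs maximal
minimal-distance barcode pools by greedy elimination, counts ordered
codebook assignments exactly, draws random codebooks, and optimizes
codebooks against a user-supplied fitness (typically a simulated macro-F1)
with an elitist genetic algorithm.

Symbols are integers 1..F; 0 is reserved for "no channel detected" in
observed barcodes and never appears in a codeword.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Symbols = tuple[int, ...]


def parse_barcode(text: str) -> Symbols:
    """Parse a digit string like ``"12312312"`` into a symbol tuple."""
    if not text or not text.isdigit():
        raise ValueError(f"malformed barcode {text!r}: expected digits")
    return tuple(int(c) for c in text)


def format_barcode(symbols: Sequence[int]) -> str:
    return "".join(str(int(s)) for s in symbols)


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    """Hamming distance: number of rounds whose symbols differ.

    The dropout symbol 0 differs from every color 1..F.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


def enumerate_barcodes(F: int, R: int) -> np.ndarray:
    """All F**R codewords over {1..F}, lexicographic, as an (F**R, R) array."""
    grids = np.meshgrid(*[np.arange(1, F + 1)] * R, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1).astype(np.uint8)


@dataclass(frozen=True)
class CodebookPool:
    """A set of codewords with a guaranteed pairwise minimal Hamming distance.

    ``maximal`` means no codeword of {1..F}^R outside the pool is at
    distance >= min_hd from every member (true for greedy construction).
    """

    barcodes: tuple[Symbols, ...]
    F: int
    R: int
    min_hd: int
    maximal: bool = False

    def __post_init__(self) -> None:
        for bc in self.barcodes:
            if len(bc) != self.R:
                raise ValueError(f"barcode {bc} has length {len(bc)}, expected R={self.R}")
            if any(s < 1 or s > self.F for s in bc):
                raise ValueError(f"barcode {bc} has symbols outside 1..{self.F}")

    def __len__(self) -> int:
        return len(self.barcodes)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.barcodes, dtype=np.uint8).reshape(len(self.barcodes), self.R)


@dataclass(frozen=True)
class Codebook:
    """Ordered assignment of pool codewords to taxa."""

    assignment: tuple[tuple[str, Symbols], ...]

    def __post_init__(self) -> None:
        codes = [bc for _, bc in self.assignment]
        if len(set(codes)) != len(codes):
            raise ValueError("codebook barcodes must be pairwise distinct")
        lengths = {len(bc) for bc in codes}
        if len(lengths) > 1:
            raise ValueError("codebook barcodes must share one length")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[int] | str]) -> "Codebook":
        items = []
        for taxon, bc in mapping.items():
            symbols = parse_barcode(bc) if isinstance(bc, str) else tuple(int(s) for s in bc)
            items.append((str(taxon), symbols))
        return cls(tuple(items))

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.assignment)

    @property
    def S(self) -> int:
        return len(self.assignment)

    @property
    def R(self) -> int:
        return len(self.assignment[0][1]) if self.assignment else 0

    def barcode_of(self, taxon: str) -> Symbols:
        for t, bc in self.assignment:
            if t == taxon:
                return bc
        raise KeyError(taxon)

    def as_array(self) -> np.ndarray:
        return np.asarray([bc for _, bc in self.assignment], dtype=np.uint8)

    def min_hd(self) -> int:
        """Smallest pairwise Hamming distance among the codewords."""
        arr = self.as_array()
        if len(arr) < 2:
            return arr.shape[1]
        d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        iu = np.triu_indices(len(arr), k=1)
        return int(d[iu].min())

    def replace(self, taxon: str, barcode: Symbols) -> "Codebook":
        items = tuple((t, barcode if t == taxon else bc) for t, bc in self.assignment)
        return Codebook(items)


@dataclass
class ValidationReport:
    ok: bool
    violations: dict[tuple[Symbols, Symbols], int] = field(default_factory=dict)


@dataclass
class GAConfig:
    """Population structure of the elitist genetic algorithm.

    Each generation carries forward ``elites`` codebooks unchanged, adds
    ``mutants_per_elite`` single-taxon mutants of each elite, and injects
    ``random_injected`` fresh random codebooks; all are scored together.
    """

    population: int = 200
    elites: int = 15
    mutants_per_elite: int = 12
    random_injected: int = 5
    generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        expected = self.elites + self.elites * self.mutants_per_elite + self.random_injected
        if expected != self.population:
            raise ValueError(
                f"population structure inconsistent: {self.elites} + "
                f"{self.elites}x{self.mutants_per_elite} + {self.random_injected} "
                f"= {expected} != {self.population}"
            )


def _greedy_pool(candidates: np.ndarray, min_hd: int) -> np.ndarray:
    """Greedy elimination: scan candidates in order, keep each codeword at
    distance >= min_hd from everything kept so far.  The result is maximal:
    every rejected codeword is within min_hd of a kept one."""
    n, R = candidates.shape
    kept = np.empty_like(candidates)
    k = 0
    for i in range(n):
        cand = candidates[i]
        if k == 0:
            kept[0] = cand
            k = 1
            continue
        d = (kept[:k] != cand).sum(axis=1)
        if int(d.min()) >= min_hd:
            kept[k] = cand
            k += 1
    return kept[:k].copy()


def generate_pool(
    F: int,
    R: int,
    min_hd: int,
    seed: int = 0,
    restarts: int = 100,
) -> CodebookPool:
    """Build a maximal codeword pool at the given minimal Hamming distance.

    Runs greedy elimination over the full {1..F}^R enumeration once in
    lexicographic order and ``restarts - 1`` times over seeded random
    shufflings, returning the largest pool found.  Deterministic given
    (seed, restarts).
    """
    if F < 2:
        raise ValueError("F must be >= 2")
    if not (1 <= min_hd <= R):
        raise ValueError(f"min_hd must be in 1..{R}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    candidates = enumerate_barcodes(F, R)
    best = _greedy_pool(candidates, min_hd)
    rng = np.random.default_rng(seed)
    for _ in range(restarts - 1):
        order = rng.permutation(len(candidates))
        pool = _greedy_pool(candidates[order], min_hd)
        if len(pool) > len(best):
            best = pool
    barcodes = tuple(tuple(int(s) for s in row) for row in best)
    return CodebookPool(barcodes=barcodes, F=F, R=R, min_hd=min_hd, maximal=True)


def validate(pool_or_codebook: CodebookPool | Codebook, min_hd: int) -> ValidationReport:
    """List every codeword pair closer than min_hd; ok iff none."""
    if isinstance(pool_or_codebook, Codebook):
        codes = [bc for _, bc in pool_or_codebook.assignment]
    else:
        codes = list(pool_or_codebook.barcodes)
    violations: dict[tuple[Symbols, Symbols], int] = {}
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            d = hamming(codes[i], codes[j])
            if d < min_hd:
                violations[(codes[i], codes[j])] = d
    return ValidationReport(ok=not violations, violations=violations)


def assignment_count(M: int, S: int) -> int:
    """Number of ordered codebooks: the falling factorial M(M-1)...(M-S+1).

    Exact integer arithmetic; this is what makes exhaustive codebook
    evaluation infeasible and motivates the genetic algorithm.
    """
    if S > M:
        raise ValueError(f"cannot assign S={S} taxa from a pool of M={M}")
    return math.perm(M, S)


def draw_codebook(
    pool: CodebookPool,
    S: int,
    seed: int = 0,
    taxa: Sequence[str] | None = None,
) -> Codebook:
    """Uniform ordered sample of S distinct pool codewords, one per taxon."""
    if S > len(pool):
        raise ValueError(f"S={S} exceeds pool size {len(pool)}")
    if taxa is None:
        taxa = [f"sp{i + 1:02d}" for i in range(S)]
    elif len(taxa) != S:
        raise ValueError("len(taxa) must equal S")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=S, replace=False)
    return Codebook(tuple((str(t), pool.barcodes[i]) for t, i in zip(taxa, idx)))


def ga_optimize(
    S: int,
    pool: CodebookPool,
    scorer: Callable[[Codebook], float],
    cfg: GAConfig,
    taxa: Sequence[str] | None = None,
) -> tuple[Codebook, list[float]]:
    """Elitist genetic-algorithm search for a high-fitness codebook.

    Generation 0 scores ``cfg.population`` random codebooks.  Each later
    generation re-pools the elites, their single-taxon mutants (one taxon's
    codeword replaced by a random unused pool codeword) and a few fresh
    random codebooks, and scores them all together.  Because elites survive
    unchanged, the best-score trace is non-decreasing.

    Returns (best codebook, per-generation best score trace).
    """
    if S >= len(pool):
        raise ValueError("pool too small to mutate: need at least S+1 codewords")
    if taxa is None:
        taxa = [f"sp{i + 1:02d}" for i in range(S)]
    rng = np.random.default_rng(cfg.seed)

    def random_codebook() -> Codebook:
        idx = rng.choice(len(pool), size=S, replace=False)
        return Codebook(tuple((str(t), pool.barcodes[i]) for t, i in zip(taxa, idx)))

    def mutate(cb: Codebook) -> Codebook:
        taxon = taxa[int(rng.integers(S))]
        used = {bc for _, bc in cb.assignment}
        unused = [bc for bc in pool.barcodes if bc not in used]
        new_bc = unused[int(rng.integers(len(unused)))]
        return cb.replace(taxon, new_bc)

    cache: dict[tuple[Symbols, ...], float] = {}

    def score(cb: Codebook) -> float:
        key = tuple(bc for _, bc in cb.assignment)
        if key not in cache:
            cache[key] = float(scorer(cb))
        return cache[key]

    population = [random_codebook() for _ in range(cfg.population)]
    trace: list[float] = []
    best_cb: Codebook | None = None
    best_score = -np.inf
    for _ in range(cfg.generations):
        scored = sorted(((score(cb), i, cb) for i, cb in enumerate(population)),
                        key=lambda t: (-t[0], t[1]))
        gen_best_score, _, gen_best = scored[0]
        if gen_best_score > best_score:
            best_score, best_cb = gen_best_score, gen_best
        trace.append(best_score)
        elites = [cb for _, _, cb in scored[: cfg.elites]]
        population = list(elites)
        for elite in elites:
            population.extend(mutate(elite) for _ in range(cfg.mutants_per_elite))
        population.extend(random_codebook() for _ in range(cfg.random_injected))
    assert best_cb is not None
    return best_cb, trace


# ---------------------------------------------------------------------------
# CSV round-tripping (header `taxon,barcode`; pools are one barcode per line)

def write_codebook_csv(codebook: Codebook, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("taxon,barcode\n")
        for taxon, bc in codebook.assignment:
            fh.write(f"{taxon},{format_barcode(bc)}\n")


def read_codebook_csv(path) -> Codebook:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["taxon", "barcode"]:
        raise ValueError(f"expected header 'taxon,barcode', got {list(df.columns)}")
    items = []
    for row_num, (taxon, bc) in enumerate(zip(df["taxon"], df["barcode"]), start=2):
        try:
            symbols = parse_barcode(str(bc))
            if 0 in symbols:
                raise ValueError("codewords may not contain the dropout symbol 0")
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_num}: {exc}") from exc
        items.append((str(taxon), symbols))
    return Codebook(tuple(items))


def write_pool_csv(pool: CodebookPool, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for bc in pool.barcodes:
            fh.write(format_barcode(bc) + "\n")


def read_pool_csv(path, min_hd: int | None = None) -> CodebookPool:
    with open(path, encoding="utf-8") as fh:
        barcodes = tuple(parse_barcode(line.strip()) for line in fh if line.strip())
    if not barcodes:
        raise ValueError(f"{path}: empty pool")
    R = len(barcodes[0])
    F = max(max(bc) for bc in barcodes)
    if min_hd is None:
        arr = np.asarray(barcodes, dtype=np.uint8)
        d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        iu = np.triu_indices(len(arr), k=1)
        min_hd = int(d[iu].min()) if len(arr) > 1 else R
    return CodebookPool(barcodes=barcodes, F=F, R=R, min_hd=min_hd)


def random_codebooks(
    pool: CodebookPool, S: int, n: int, seed: int = 0,
    taxa: Sequence[str] | None = None,
) -> Iterable[Codebook]:
    """n independent random codebooks (a seeded stream, e.g. for Fig-style
    codebook-quality distributions)."""
    rng = np.random.default_rng(seed)
    if taxa is None:
        taxa = [f"sp{i + 1:02d}" for i in range(S)]
    for _ in range(n):
        idx = rng.choice(len(pool), size=S, replace=False)
        yield Codebook(tuple((str(t), pool.barcodes[i]) for t, i in zip(taxa, idx)))
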