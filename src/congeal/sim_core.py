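"""Forward-time, individual-based simulation of divergence with gene flow.

Two demes exchange migrants each generation; individuals are diploid,
hermaphroditic, obligate outcrossers with non-overlapping generations.
Divergently selected and neutral mutations arise de novo on a multi-chromosome
genetic map under an infinite-sites model.  The life cycle each generation is

    migration -> soft selection + reproduction (with recombination)
              -> mutation -> bookkeeping (loss/fixation pruning)

Fitness at a selected locus is additive within the locus (heterozygote exactly
intermediate) and multiplicative across loci; the derived allele is favored in
one deme and the ancestral allele in the other, so every selected locus is a
"two-allele" barrier locus.  Soft selection: each deme always contributes
exactly ``deme_size`` offspring regardless of mean fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


class EmptyDemeError(RuntimeError):
    """A deme has too few individuals to reproduce."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Parameters of the two-deme divergence simulation.

    ``s_mean`` is the mean of the exponential distribution from which
    selection coefficients of new divergently selected mutations are drawn;
    ``m`` is the per-individual, per-generation migration probability.
    Defaults reproduce the standard configuration: N = 5000 diploids split
    evenly across two demes, 10 new mutations per generation at a 10:1
    neutral:selected ratio, and a genome of four 50 cM chromosomes.
    """

    s_mean: float
    m: float
    N_total: int = 5000
    mutations_per_generation: int = 10
    p_neutral: float = 10.0 / 11.0
    n_chromosomes: int = 4
    chrom_length_morgans: float = 0.5
    max_mutations_introduced: int = 15_000_000
    nme_threshold: float = 1e-4
    nme_window: int = 100
    record_interval: int = 100
    seed: int = 0
    #: assign the favored deme of each new selected mutation at random instead
    #: of always favoring the derived allele in deme 2 (index 1)
    random_favored_deme: bool = False

    def __post_init__(self) -> None:
        if self.N_total < 4 or self.N_total % 2 != 0:
            raise ConfigurationError(
                f"N_total must be an even integer >= 4, got {self.N_total}")
        if not (0.0 <= self.m <= 1.0):
            raise ConfigurationError(f"m must be in [0, 1], got {self.m}")
        if self.s_mean <= 0:
            raise ConfigurationError(f"s_mean must be > 0, got {self.s_mean}")
        if not (0.0 <= self.p_neutral <= 1.0):
            raise ConfigurationError(
                f"p_neutral must be in [0, 1], got {self.p_neutral}")
        if self.chrom_length_morgans <= 0:
            raise ConfigurationError("chrom_length_morgans must be > 0")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.mutations_per_generation < 0:
            raise ConfigurationError("mutations_per_generation must be >= 0")
        if self.record_interval < 1:
            raise ConfigurationError("record_interval must be >= 1")

    @property
    def deme_size(self) -> int:
        return self.N_total // 2

    @property
    def genome_length(self) -> float:
        """Total map length in Morgans."""
        return self.n_chromosomes * self.chrom_length_morgans


# ---------------------------------------------------------------------------
# per-site metadata
# ---------------------------------------------------------------------------

@dataclass
class MutationRecord:
    """Metadata for one site under the infinite-sites model."""

    site_id: int
    chromosome: int
    position_morgans: float  # within-chromosome position
    kind: str  # "neutral" | "selected"
    s_i: float
    origin_generation: int
    origin_deme: int
    status: str = "segregating"  # "segregating" | "fixed" | "lost"
    favored_deme: int = 1  # deme index whose residents favor the derived allele
    resolved_generation: Optional[int] = None

    def __post_init__(self) -> None:
        assert self.s_i >= 0
        assert (self.s_i == 0) == (self.kind == "neutral")


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------

class PopulationState:
    """Haplotypes and site metadata for both demes at one point in time.

    Haplotypes are a ``(2 * N_total, S)`` binary matrix: rows ``2i`` and
    ``2i + 1`` are the two phased haplotypes of individual ``i``, columns are
    segregating sites ordered by genome position (0 = ancestral, 1 = derived).
    ``deme[i]`` gives individual ``i``'s current deme (0 or 1); migration
    changes only this assignment and the ``immigrant`` flags.
    """

    def __init__(self, params: SimulationParams):
        n = params.N_total
        self.params = params
        self.generation: int = 0
        self.haplotypes: np.ndarray = np.zeros((2 * n, 0), dtype=np.uint8)
        self.deme: np.ndarray = np.repeat(
            np.array([0, 1], dtype=np.int8), params.deme_size)
        self.immigrant: np.ndarray = np.zeros(n, dtype=bool)
        # structure-of-arrays site metadata, parallel to haplotype columns
        self.positions: np.ndarray = np.zeros(0)       # global map position
        self.s_coef: np.ndarray = np.zeros(0)
        self.neutral: np.ndarray = np.zeros(0, dtype=bool)
        self.favored: np.ndarray = np.zeros(0, dtype=np.int8)
        self.records: list[MutationRecord] = []
        self.resolved: list[MutationRecord] = []
        self.mutations_introduced_total: int = 0
        self.last_me: float = 0.0
        self._next_site_id: int = 0
        self._n_sorted: int = 0  # leading columns known to be map-sorted
        self._buffer: Optional[np.ndarray] = None  # spare capacity columns

    # -- derived views ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def chromosome(self) -> np.ndarray:
        L = self.params.chrom_length_morgans
        return np.minimum(
            (self.positions / L).astype(np.int64),
            self.params.n_chromosomes - 1)

    @property
    def position_within(self) -> np.ndarray:
        L = self.params.chrom_length_morgans
        return self.positions - self.chromosome * L

    def deme_indices(self, k: int) -> np.ndarray:
        return np.nonzero(self.deme == k)[0]

    def haplotypes_of(self, individuals: np.ndarray) -> np.ndarray:
        rows = np.empty(2 * len(individuals), dtype=np.int64)
        rows[0::2] = 2 * individuals
        rows[1::2] = 2 * individuals + 1
        return self.haplotypes[rows]

    def genotypes(self) -> np.ndarray:
        """(N, S) derived-allele dosage matrix."""
        return self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]


def init_population(params: SimulationParams) -> PopulationState:
    """Start from zero segregating variation (all mutations arise de novo)."""
    return PopulationState(params)


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def migrate(state: PopulationState, m: float,
            rng: np.random.Generator) -> PopulationState:
    """Each individual independently moves to the other deme with probability m.

    Movers are flagged as immigrants in their destination deme for this
    generation.  Total head count is conserved (demes may transiently differ
    in size; reproduction restores ``deme_size`` offspring per deme).
    """
    if not (0.0 <= m <= 1.0):
        raise ConfigurationError(f"m must be in [0, 1], got {m}")
    moves = rng.random(len(state.deme)) < m
    state.deme[moves] = 1 - state.deme[moves]
    state.immigrant = moves
    return state


# ---------------------------------------------------------------------------
# fitness and effective migration
# ---------------------------------------------------------------------------

def fitness_vector(state: PopulationState, deme: int,
                   individuals: Optional[np.ndarray] = None) -> np.ndarray:
    """Relative fitness W_j for every individual currently in ``deme``.

    W_j is the product over segregating selected loci of {1 + s_i, 1 + s_i/2,
    1}: in the favored deme the derived homozygote gets 1 + s_i, in the other
    deme the ancestral homozygote does, heterozygotes get 1 + s_i/2 in both.
    Neutral sites are ignored.  Every W_j >= 1.
    """
    if individuals is None:
        individuals = state.deme_indices(deme)
    sel = ~state.neutral
    if not sel.any() or len(individuals) == 0:
        return np.ones(len(individuals))
    H = state.haplotypes
    g = (H[2 * individuals][:, sel].astype(np.int16)
         + H[2 * individuals + 1][:, sel])
    # favored dosage: count of the locally favored allele's copies
    fav = state.favored[sel]
    d = np.where(fav[None, :] == deme, g, 2 - g)
    s = state.s_coef[sel]
    l_het = np.log1p(0.5 * s)
    l_hom = np.log1p(s)
    logw = (d == 1) @ l_het + (d == 2) @ l_hom
    return np.exp(logw)


def effective_migration_rate(
        fitness_by_deme: dict[int, np.ndarray],
        immigrant_by_deme: dict[int, np.ndarray]) -> float:
    """Expected proportion of reproduction attributable to immigrants.

    Per deme, m_e = sum(W of immigrants) / sum(W of everyone present); the
    mean over the two demes is returned.  Shrinks toward 0 as immigrants
    become less fit than residents.
    """
    vals = []
    for k, w in fitness_by_deme.items():
        if len(w) == 0:
            raise EmptyDemeError(f"deme {k} is empty; m_e undefined")
        imm = immigrant_by_deme[k]
        vals.append(float(w[imm].sum() / w.sum()))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# recombination / gamete formation
# ---------------------------------------------------------------------------

def _gamete_from_events(hap_a: np.ndarray, hap_b: np.ndarray,
                        positions: np.ndarray, events: np.ndarray,
                        start_parity: int) -> np.ndarray:
    """Assemble a gamete given sorted switch-point positions.

    The source haplotype starts at ``start_parity`` (0 = hap_a) and flips at
    every event position; a site exactly at an event position takes the
    post-switch source.
    """
    parity = (start_parity + np.searchsorted(events, positions, side="right")) % 2
    return np.where(parity == 0, hap_a, hap_b).astype(np.uint8)


def draw_recombination_events(params: SimulationParams,
                              rng: np.random.Generator
                              ) -> tuple[int, np.ndarray]:
    """Draw (start_parity, sorted switch positions) for one meiosis.

    Chromosomes assort independently: the starting parental haplotype of each
    chromosome is a fair coin, realised as a possible switch at each
    chromosome boundary.  Within the whole genome, crossover count is
    Poisson(total map length in Morgans) with uniform positions, so each
    chromosome receives Poisson(chrom_length) crossovers.
    """
    L = params.chrom_length_morgans
    G = params.genome_length
    start = int(rng.integers(0, 2))
    n_x = rng.poisson(G)
    xpos = rng.random(n_x) * G
    flips = rng.random(params.n_chromosomes - 1) < 0.5
    bpos = (np.nonzero(flips)[0] + 1) * L
    events = np.sort(np.concatenate([xpos, bpos]))
    return start, events


def make_gamete(parent_haplotypes: tuple[np.ndarray, np.ndarray],
                positions: np.ndarray, params: SimulationParams,
                rng: np.random.Generator) -> np.ndarray:
    """Form one gamete from a parent's phased haplotype pair.

    ``positions`` are the global map positions (Morgans) of the columns,
    ascending.
    """
    start, events = draw_recombination_events(params, rng)
    return _gamete_from_events(parent_haplotypes[0], parent_haplotypes[1],
                               positions, events, start)


def _assemble_gametes_py(H, het_indptr, het_cols, parents, starts, xpos,
                         xoff, flips, bound_pos, positions, out):
    """Pure-numpy reference for the gamete-assembly kernel.

    Per gamete: crossover positions plus flipped chromosome boundaries form
    the switch-point list; each site takes the source haplotype whose parity
    is the start parity plus the number of switch points at or before the
    site's map position.  (The heterozygous-column CSR arrays are a layout
    hint the compiled kernel exploits; the result does not depend on them.)
    """
    for g in range(out.shape[0]):
        ev = list(xpos[xoff[g]:xoff[g + 1]])
        ev += [bound_pos[k] for k in range(len(bound_pos)) if flips[g, k]]
        ev = np.sort(np.asarray(ev))
        parity = (starts[g]
                  + np.searchsorted(ev, positions, side="right")) % 2
        row = 2 * parents[g]
        out[g] = np.where(parity == 0, H[row], H[row + 1])


if _HAVE_NUMBA:

    @njit(cache=True)
    def _assemble_gametes_nb(H, het_indptr, het_cols, parents, starts, xpos,
                             xoff, flips, bound_pos, positions,
                             out):  # pragma: no cover - jitted
        # The gamete starts as a verbatim copy of one parental haplotype;
        # only columns where the parent is heterozygous can differ between
        # sources, so the switch-point parity is evaluated just at those
        # columns (their CSR index is precomputed per parent).  Events are
        # kept sorted, allowing early exit in the parity scan.
        n_gam = out.shape[0]
        S = positions.shape[0]
        n_b = bound_pos.shape[0]
        ev_pos = np.empty(64, dtype=np.float64)
        for g in range(n_gam):
            k0 = xoff[g]
            n_x = xoff[g + 1] - k0
            if n_x + n_b > ev_pos.shape[0]:
                ev_pos = np.empty(n_x + n_b + 8, dtype=np.float64)
            n_ev = 0
            for t in range(n_x):
                ev_pos[n_ev] = xpos[k0 + t]
                n_ev += 1
            for k in range(n_b):
                if flips[g, k]:
                    ev_pos[n_ev] = bound_pos[k]
                    n_ev += 1
            for a in range(1, n_ev):  # insertion sort; n_ev is tiny
                v = ev_pos[a]
                b = a - 1
                while b >= 0 and ev_pos[b] > v:
                    ev_pos[b + 1] = ev_pos[b]
                    b -= 1
                ev_pos[b + 1] = v
            p = parents[g]
            row = 2 * p
            srcA = row + starts[g]
            srcB = row + (1 - starts[g])
            for j in range(S):
                out[g, j] = H[srcA, j]
            for t in range(het_indptr[p], het_indptr[p + 1]):
                c = het_cols[t]
                x = positions[c]
                par = 0
                for e in range(n_ev):
                    if ev_pos[e] <= x:
                        par ^= 1
                    else:
                        break
                if par == 1:
                    out[g, c] = H[srcB, c]

    @njit(cache=True)
    def _het_csr_nb(out, new_indptr, new_cols):  # pragma: no cover - jitted
        # heterozygous-column CSR of the freshly written offspring matrix
        n = out.shape[0] // 2
        S = out.shape[1]
        k = 0
        for i in range(n):
            new_indptr[i] = k
            r = 2 * i
            for j in range(S):
                if out[r, j] != out[r + 1, j]:
                    new_cols[k] = j
                    k += 1
        new_indptr[n] = k
        return k

    _assemble_gametes = _assemble_gametes_nb
else:  # pragma: no cover
    _assemble_gametes = _assemble_gametes_py
    _het_csr_nb = None


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

def _sample_parent_pairs(idx: np.ndarray, w: np.ndarray, n_off: int,
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Fitness-proportional parent pairs; the two parents of one offspring
    are distinct (obligate outcrossing, selfing excluded by rejection)."""
    cdf = np.cumsum(w)
    tot = cdf[-1]

    def draw(n):
        j = np.searchsorted(cdf, rng.random(n) * tot, side="right")
        return idx[np.minimum(j, len(idx) - 1)]

    p1 = draw(n_off)
    p2 = draw(n_off)
    bad = p1 == p2
    while bad.any():
        p2[bad] = draw(int(bad.sum()))
        bad = p1 == p2
    return p1, p2


def reproduce(state: PopulationState, params: SimulationParams,
              rng: np.random.Generator,
              fitness_by_deme: Optional[dict[int, np.ndarray]] = None
              ) -> PopulationState:
    """Soft selection: each deme produces exactly ``deme_size`` offspring.

    Parents are drawn within the deme with probability proportional to
    fitness (with replacement across offspring); each parent contributes one
    recombinant gamete.  Offspring replace parents (non-overlapping
    generations) and immigrant flags are cleared.
    """
    n_off = params.deme_size
    n = params.N_total
    parents = np.empty(2 * n, dtype=np.int64)  # one entry per gamete
    for k in (0, 1):
        idx = state.deme_indices(k)
        if len(idx) < 2:
            raise EmptyDemeError(
                f"deme {k} has {len(idx)} individuals; need >= 2 to reproduce")
        if fitness_by_deme is not None and k in fitness_by_deme:
            w = fitness_by_deme[k]
        else:
            w = fitness_vector(state, k, idx)
        p1, p2 = _sample_parent_pairs(idx, w, n_off, rng)
        base = 2 * k * n_off
        parents[base + 0:base + 2 * n_off:2] = p1
        parents[base + 1:base + 2 * n_off:2] = p2

    S = state.n_sites
    # allocate slack columns so this generation's new mutations can be
    # written in place instead of reallocating the matrix
    slack = params.mutations_per_generation
    buf = np.empty((2 * n, S + slack), dtype=np.uint8)
    H_new = buf[:, :S]
    if S > 0:
        starts = rng.integers(0, 2, size=2 * n).astype(np.int64)
        n_x = rng.poisson(params.genome_length, size=2 * n)
        L = params.chrom_length_morgans
        flips = (rng.random((2 * n, params.n_chromosomes - 1)) < 0.5
                 ).astype(np.uint8)
        xoff = np.zeros(2 * n + 1, dtype=np.int64)
        np.cumsum(n_x, out=xoff[1:])
        xpos = rng.random(int(xoff[-1])) * params.genome_length
        bound_pos = np.arange(1, params.n_chromosomes) * L
        H = state.haplotypes
        het_indptr = np.empty(n + 1, dtype=np.int64)
        if _het_csr_nb is not None:
            het_cols = np.empty(n * S, dtype=np.int64)
            _het_csr_nb(H, het_indptr, het_cols)
        else:  # pragma: no cover - numba unavailable
            rows, het_cols = np.nonzero(H[0::2] != H[1::2])
            het_indptr[0] = 0
            np.cumsum(np.bincount(rows, minlength=n), out=het_indptr[1:])
        _assemble_gametes(H, het_indptr, het_cols, parents,
                          starts, xpos, xoff, flips, bound_pos,
                          state.positions, H_new)
    state._buffer = buf
    state.haplotypes = H_new
    state.deme = np.repeat(np.array([0, 1], dtype=np.int8), n_off)
    state.immigrant = np.zeros(n, dtype=bool)
    return state


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def introduce_mutations(state: PopulationState, params: SimulationParams,
                        rng: np.random.Generator) -> list[MutationRecord]:
    """Add exactly ``mutations_per_generation`` new sites.

    Each mutation lands on one haplotype of a uniformly chosen offspring at a
    uniform genome position (infinite sites: positions are continuous and
    almost surely unique).  A mutation is neutral with probability
    ``p_neutral``; otherwise its selection coefficient is drawn from an
    exponential distribution with mean ``s_mean``.  The derived allele is
    favored in deme 2 (index 1) by default; a mutation may arise in either
    deme, including the one where it is disadvantageous.
    """
    k = params.mutations_per_generation
    if k == 0:
        return []
    n = params.N_total
    inds = rng.integers(0, n, size=k)
    haps = rng.integers(0, 2, size=k)
    pos = rng.random(k) * params.genome_length
    is_neutral = rng.random(k) < params.p_neutral
    s_draws = rng.exponential(params.s_mean, size=k)
    s_i = np.where(is_neutral, 0.0, s_draws)
    if params.random_favored_deme:
        fav = rng.integers(0, 2, size=k).astype(np.int8)
    else:
        fav = np.ones(k, dtype=np.int8)

    L = params.chrom_length_morgans
    new_records = []
    for j in range(k):
        chrom = min(int(pos[j] / L), params.n_chromosomes - 1)
        rec = MutationRecord(
            site_id=state._next_site_id,
            chromosome=chrom,
            position_morgans=float(pos[j] - chrom * L),
            kind="neutral" if is_neutral[j] else "selected",
            s_i=float(s_i[j]),
            origin_generation=state.generation,
            origin_deme=int(state.deme[inds[j]]),
            favored_deme=int(fav[j]),
        )
        state._next_site_id += 1
        new_records.append(rec)

    # new columns are appended; pruning restores map order when it compacts
    S = state.n_sites
    buf = state._buffer
    if buf is not None and state.haplotypes.base is buf \
            and buf.shape[1] >= S + k \
            and state.haplotypes.ctypes.data == buf.ctypes.data:
        buf[:, S:S + k] = 0
        buf[2 * inds + haps, S + np.arange(k)] = 1
        state.haplotypes = buf[:, :S + k]
    else:
        cols = np.zeros((2 * n, k), dtype=np.uint8)
        cols[2 * inds + haps, np.arange(k)] = 1
        state.haplotypes = np.concatenate([state.haplotypes, cols], axis=1)
        state._buffer = None
    state.positions = np.concatenate([state.positions, pos])
    state.s_coef = np.concatenate([state.s_coef, s_i])
    state.neutral = np.concatenate([state.neutral, is_neutral])
    state.favored = np.concatenate([state.favored, fav])
    state.records = state.records + new_records
    state.mutations_introduced_total += k
    return new_records


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def prune_sites(state: PopulationState) -> list[MutationRecord]:
    """Remove columns at global derived frequency 0 (lost) or 1 (fixed) and
    restore map order of the remaining columns.

    Fixed selected sites can be dropped from fitness: within a deme they
    multiply every individual's W by the same constant, which cancels under
    soft selection.  Resolved records keep their status and resolution time.
    Pruning may be applied every generation or deferred and amortized: a
    lost column can never regain copies (no back mutation) and a fixed one
    never lose them, so resolution is idempotent and order-insensitive.
    """
    if state.n_sites == 0:
        return []
    freq = state.haplotypes.sum(axis=0, dtype=np.int64)
    lost = freq == 0
    fixed = freq == state.haplotypes.shape[0]
    gone = lost | fixed
    unsorted = bool(np.any(state.positions[1:] < state.positions[:-1]))
    if not gone.any() and not unsorted:
        state._n_sorted = state.n_sites
        return []
    resolved = []
    for i in np.nonzero(gone)[0]:
        rec = state.records[i]
        rec.status = "fixed" if fixed[i] else "lost"
        rec.resolved_generation = state.generation
        resolved.append(rec)
    keep_idx = np.nonzero(~gone)[0]
    order = keep_idx[np.argsort(state.positions[keep_idx], kind="stable")]
    state.haplotypes = np.ascontiguousarray(state.haplotypes[:, order])
    state.positions = state.positions[order]
    state.s_coef = state.s_coef[order]
    state.neutral = state.neutral[order]
    state.favored = state.favored[order]
    state.records = [state.records[i] for i in order]
    state.resolved.extend(resolved)
    state._n_sorted = state.n_sites
    state._buffer = None
    return resolved


# ---------------------------------------------------------------------------
# one generation, full run
# ---------------------------------------------------------------------------

def _relative_fitness_by_deme(state: PopulationState) -> dict[int, np.ndarray]:
    """Per-deme relative fitness, numerically normalized within each deme.

    Equivalent to :func:`fitness_vector` up to a positive per-deme constant
    (which cancels under soft selection, in parent sampling and in m_e).
    log W is evaluated as a quadratic in the derived-allele dosage so the
    per-site loop becomes two matrix-vector products.
    """
    sel = np.nonzero(~state.neutral)[0] if state.n_sites else np.empty(0, int)
    if len(sel) == 0:
        return {k: np.ones(len(state.deme_indices(k))) for k in (0, 1)}
    H = state.haplotypes
    G8 = H[0::2][:, sel] + H[1::2][:, sel]
    Gf = G8.astype(np.float32)
    Qf = Gf * (Gf - np.float32(1.0))
    s = state.s_coef[sel].astype(np.float32)
    l1 = np.log1p(np.float32(0.5) * s)
    l2 = np.log1p(s)
    fav = state.favored[sel]
    beta = np.empty((len(sel), 2), dtype=np.float32)
    gamma = np.empty((len(sel), 2), dtype=np.float32)
    for k in (0, 1):
        l0_k = np.where(fav == k, np.float32(0.0), l2)
        l2_k = np.where(fav == k, l2, np.float32(0.0))
        beta[:, k] = l1 - l0_k
        gamma[:, k] = np.float32(0.5) * (l2_k - 2.0 * l1 + l0_k)
    V = Gf @ beta + Qf @ gamma  # (N, 2); per-deme constant term dropped
    logw = np.where(state.deme == 0, V[:, 0], V[:, 1]).astype(np.float64)
    out = {}
    for k in (0, 1):
        lw = logw[state.deme == k]
        out[k] = np.exp(lw - lw.max()) if len(lw) else lw
    return out


def step_generation(state: PopulationState, params: SimulationParams,
                    rng: np.random.Generator,
                    compact: bool = True) -> PopulationState:
    """Apply one full life cycle and advance the generation counter.

    With ``compact=False`` the loss/fixation sweep is deferred (resolved
    columns are inert: they scale every fitness in a deme uniformly and are
    excluded from statistics once pruned), which amortizes the column
    compaction cost across generations.
    """
    migrate(state, params.m, rng)
    fit = _relative_fitness_by_deme(state)
    imm = {k: state.immigrant[state.deme_indices(k)] for k in (0, 1)}
    state.last_me = effective_migration_rate(fit, imm)
    reproduce(state, params, rng, fitness_by_deme=fit)
    introduce_mutations(state, params, rng)
    if compact:
        prune_sites(state)
    state.generation += 1
    return state


@dataclass
class SimulationResult:
    params: SimulationParams
    records: list  # of popgen_stats.TimeSeriesRecord
    stop_reason: str
    final_state: PopulationState
    seed: int
    snapshots: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        from .popgen_stats import TSV_COLUMNS
        rows = [[getattr(r, c) for c in TSV_COLUMNS] for r in self.records]
        return pd.DataFrame(rows, columns=TSV_COLUMNS)


def run_simulation(params: SimulationParams,
                   rng: Optional[np.random.Generator] = None,
                   max_generations: Optional[int] = None,
                   stop_afd_selected: Optional[float] = None,
                   stop_afd_neutral: Optional[float] = None,
                   record_ld: bool = True,
                   ld_pair_cap: int = 20_000,
                   snapshot_gens: Optional[list[int]] = None,
                   progress: Optional[Callable[[int], None]] = None
                   ) -> SimulationResult:
    """Run the simulation until a stopping rule triggers.

    Stopping rules: the mutation cap (``max_mutations_introduced``), or the
    reproductive-isolation criterion N * m_e < ``nme_threshold`` evaluated on
    a trailing mean of m_e over ``nme_window`` generations.  Optional extras:
    a generation cap and early stops on mean selected / neutral AFD crossing
    a threshold (checked at record points).

    A summary row is recorded at generation 0 and every ``record_interval``
    generations thereafter.
    """
    from .popgen_stats import summarize_timepoint

    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_population(params)
    records = []
    snapshots = {}
    snap_set = set(snapshot_gens or [])
    me_hist = np.zeros(params.nme_window)
    me_n = 0

    def record_now():
        prune_sites(state)  # idempotent; ensures statistics see a clean state
        records.append(summarize_timepoint(
            state, me=state.last_me, record_ld=record_ld,
            ld_pair_cap=ld_pair_cap, rng=rng))

    record_now()
    stop_reason = "max_generations"
    compact_every = 16
    while True:
        if max_generations is not None and state.generation >= max_generations:
            stop_reason = "max_generations"
            break
        if state.mutations_introduced_total >= params.max_mutations_introduced:
            stop_reason = "mutation_cap"
            break
        nxt = state.generation + 1
        compact = (nxt % compact_every == 0
                   or nxt % params.record_interval == 0
                   or nxt in snap_set)
        step_generation(state, params, rng, compact=compact)
        me_hist[me_n % params.nme_window] = state.last_me
        me_n += 1
        if (params.nme_threshold > 0 and me_n >= params.nme_window
                and params.N_total * me_hist.mean() < params.nme_threshold):
            stop_reason = "nme_threshold"
            record_now()
            break
        if state.generation in snap_set:
            snapshots[state.generation] = take_snapshot(state)
        if state.generation % params.record_interval == 0:
            record_now()
            if progress is not None:
                progress(state.generation)
            last = records[-1]
            if (stop_afd_selected is not None
                    and not math.isnan(last.afd_selected)
                    and last.afd_selected > stop_afd_selected):
                stop_reason = "afd_selected_stop"
                break
            if (stop_afd_neutral is not None
                    and not math.isnan(last.afd_neutral)
                    and last.afd_neutral > stop_afd_neutral):
                stop_reason = "afd_neutral_stop"
                break
    return SimulationResult(params=params, records=records,
                            stop_reason=stop_reason, final_state=state,
                            seed=params.seed, snapshots=snapshots)


def take_snapshot(state: PopulationState) -> dict:
    """Plain-dict copy of the haplotype matrix and site metadata."""
    return {
        "generation": state.generation,
        "haplotypes": state.haplotypes.copy(),
        "positions": state.positions.copy(),
        "s_coef": state.s_coef.copy(),
        "neutral": state.neutral.copy(),
        "favored": state.favored.copy(),
        "deme": state.deme.copy(),
    }
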