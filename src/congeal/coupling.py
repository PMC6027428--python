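"""Coupling statistics: s-bar, r-bar, the coupling coefficient theta, the
single-locus migration-selection equilibrium, s*, and the effective number
of loci Le.

theta = s-bar / r-bar quantifies the *potential* for coupling: total
selection against total recombination.  The *realised* amount of coupling is
Le = s*/s-bar, where s* is the selection coefficient a single locus would
need to hold the observed mean favored-deme frequency of barrier alleles at
migration-selection balance.  Independent loci sit at their own single-locus
balance, so s* ~ s-bar and Le ~ 1; coupled loci reach higher frequencies
than any single locus could, pushing s* and Le up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sim_core import PopulationState


class BeyondSingleLocusBalance(Exception):
    """p-bar is at or above a level no finite single-locus s can sustain."""


@dataclass
class CouplingSummary:
    s_bar: float
    r_bar: float
    theta: float
    p_bar: float
    s_star: float
    Le: float
    beyond_balance: bool = False


def mean_selection_coefficient(s_coefs: np.ndarray) -> float:
    """Arithmetic mean s_i of segregating selected sites."""
    s_coefs = np.asarray(s_coefs, dtype=float)
    if len(s_coefs) == 0:
        return math.nan
    return float(s_coefs.mean())


def mean_map_distance(chromosome: np.ndarray, position: np.ndarray,
                      cross_chromosome_distance: float = 0.5,
                      haldane: bool = False) -> float:
    """Mean map distance (Morgans) between consecutive selected sites.

    Sites are ordered by (chromosome, position); within-chromosome gaps are
    map distances, and adjacent pairs spanning a chromosome boundary
    contribute ``cross_chromosome_distance`` (0.5 M: free recombination).
    With ``haldane=True``, gaps are first converted to recombination
    fractions via Haldane's map function r = (1 - exp(-2d))/2.
    """
    chromosome = np.asarray(chromosome)
    position = np.asarray(position, dtype=float)
    if len(position) < 2:
        return math.nan
    order = np.lexsort((position, chromosome))
    c = chromosome[order]
    p = position[order]
    same = c[1:] == c[:-1]
    gaps = np.where(same, np.diff(p), cross_chromosome_distance)
    if haldane:
        gaps = 0.5 * (1.0 - np.exp(-2.0 * gaps))
    return float(gaps.mean())


def coupling_coefficient(s_bar: float, r_bar: float) -> float:
    """Barton's coupling coefficient theta = s_bar / r_bar."""
    if not r_bar > 0:
        return math.nan
    return s_bar / r_bar


# ---------------------------------------------------------------------------
# single-locus migration-selection balance
# ---------------------------------------------------------------------------

def equilibrium_recursion(s_i: float, m: float, tol: float = 1e-13,
                          max_iter: int = 5_000_000) -> float:
    """Deterministic two-deme recursion iterated to its fixed point.

    Tracks one locus with the additive-within-locus fitness scheme in an
    infinite symmetric population: adults are Hardy-Weinberg within their
    natal deme, migration mixes the two genotype pools in proportions
    (1 - m) : m, and selection weights genotypes during reproduction.  By
    symmetry the favored-deme frequency p is the same in both demes.  Serves
    as the independent oracle for the closed-form equilibrium.
    """
    if s_i <= 0:
        raise ValueError("s_i must be > 0")
    if not (0.0 <= m < 0.5):
        raise ValueError("requires 0 <= m < 0.5")
    p = 0.9
    for _ in range(max_iter):
        pres, pimm = p, 1.0 - p
        f_bb = (1 - m) * pres ** 2 + m * pimm ** 2
        f_ab = (1 - m) * 2 * pres * (1 - pres) + m * 2 * pimm * (1 - pimm)
        p_mix = f_bb + 0.5 * f_ab
        num = (1 + s_i) * f_bb + (1 + 0.5 * s_i) * 0.5 * f_ab
        p_new = num / (1.0 + s_i * p_mix)
        if abs(p_new - p) < tol:
            return p_new
        p = p_new
    return p


def single_locus_equilibrium(s_i: float, m: float,
                             method: str = "closed_form") -> float:
    """Equilibrium favored-deme frequency under migration-selection balance.

    ``method="closed_form"`` solves the quadratic obtained by equating the
    implied single-locus coefficient of a frequency p to s_i and takes the
    root in (0.5, 1]; ``method="recursion"`` iterates the deterministic
    recursion (the two agree to ~1e-10).  In the swamping regime (no
    interior equilibrium above 0.5) the closed form has no admissible root
    and the recursion's boundary behaviour (p -> 0.5) is returned.
    """
    if method == "recursion":
        return equilibrium_recursion(s_i, m)
    if method != "closed_form":
        raise ValueError(f"unknown method {method!r}")
    if s_i <= 0:
        raise ValueError("s_i must be > 0")
    if m == 0:
        return 1.0
    # invert s_star(p, m) = s_i:  quadratic a p^2 + b p + c = 0
    a = s_i * (m - 0.25)
    b = s_i * (0.25 - 1.5 * m) - m
    c = 0.5 * m * (s_i + 1.0)
    disc = b * b - 4 * a * c
    if disc < 0:
        return equilibrium_recursion(s_i, m)
    roots = [(-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)]
    admissible = [r for r in roots if 0.5 < r <= 1.0 + 1e-12]
    if not admissible:
        # swamping: defer to the recursion's boundary behaviour
        return equilibrium_recursion(s_i, m)
    return float(min(min(admissible), 1.0))


def s_star(p_bar: float, m: float) -> float:
    """Implied single-locus selection coefficient for mean frequency p_bar.

    s* = m (p - 1/2) / [ (1/4)(1 - p) p + m (1/2 + p (p - 3/2)) ].  It is 0
    at p = 1/2 and diverges as p -> 1 (no finite single-locus s sustains
    near-fixation against migration).  A non-positive denominator means
    p_bar is beyond any single-locus balance and raises
    :class:`BeyondSingleLocusBalance`.
    """
    if not (0.0 <= p_bar <= 1.0):
        raise ValueError("p_bar must be in [0, 1]")
    if m <= 0:
        raise ValueError("m must be > 0")
    num = m * (p_bar - 0.5)
    den = (0.25 - 0.25 * p_bar) * p_bar + m * (0.5 + p_bar * (p_bar - 1.5))
    if den <= 0:
        raise BeyondSingleLocusBalance(
            f"p_bar={p_bar} is beyond single-locus balance at m={m}")
    return num / den


def effective_loci(s_star_value: float, s_bar: float) -> float:
    """Le = s*/s_bar: the number of maximally coupled barrier loci that
    would produce the observed divergence.  ~1 under uncoupled single-locus
    balance; > 1 indicates coupling (LD among selected loci)."""
    if not s_bar > 0:
        return math.nan
    return s_star_value / s_bar


def coupling_summary(state: PopulationState, m: float) -> CouplingSummary:
    """Compute (s-bar, r-bar, theta, p-bar, s*, Le) from the current state.

    p-bar is the mean frequency of segregating selected (barrier) alleles in
    their favored deme; fixed sites are excluded, matching the s-bar
    convention.  When p-bar lies beyond single-locus balance, s* and Le are
    reported as +inf with ``beyond_balance`` set.
    """
    sel = ~state.neutral
    nan = math.nan
    if not sel.any():
        return CouplingSummary(nan, nan, nan, nan, nan, nan)
    s_bar = mean_selection_coefficient(state.s_coef[sel])
    r_bar = mean_map_distance(state.chromosome[sel],
                              state.position_within[sel])
    theta = coupling_coefficient(s_bar, r_bar) if not math.isnan(r_bar) else nan

    # mean favored-deme frequency of barrier alleles
    from .popgen_stats import deme_allele_frequencies
    p0, p1 = deme_allele_frequencies(state)
    p_fav = np.where(state.favored == 0, p0, p1)[sel]
    p_bar = float(p_fav.mean())

    beyond = False
    if m > 0 and p_bar > 0.5:
        try:
            ss = s_star(p_bar, m)
        except BeyondSingleLocusBalance:
            ss = math.inf
            beyond = True
    elif m > 0:
        # below 1/2 the implied coefficient is <= 0; report it anyway
        den = (0.25 - 0.25 * p_bar) * p_bar + m * (0.5 + p_bar * (p_bar - 1.5))
        ss = m * (p_bar - 0.5) / den if den > 0 else math.nan
    else:
        ss = nan
    le = effective_loci(ss, s_bar) if not math.isnan(ss) else nan
    return CouplingSummary(s_bar=s_bar, r_bar=r_bar, theta=theta,
                           p_bar=p_bar, s_star=ss, Le=le,
                           beyond_balance=beyond)
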