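"""Within-species LD analysis of two-taxon genotype data.

Pipeline stages: posterior-mean genotype dosages from genotype likelihoods
under empirical Hardy-Weinberg priors (EM allele-frequency estimates),
per-locus FST / AFD between the two taxa, per-chromosome 99th-quantile
outlier designation, and sampling of pairwise within-taxon r^2 values for
six comparison groups (outlier/non-outlier x same/other chromosome).  A
synthetic two-taxon fixture generator emulates the key structure of real
resequencing data: high-AFD, mutually correlated barrier loci against an
undifferentiated background.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

GROUPS = {
    1: "outlier x outlier, same chromosome",
    2: "non-outlier x non-outlier, same chromosome",
    3: "outlier x non-outlier, same chromosome",
    4: "outlier x outlier, other chromosomes",
    5: "non-outlier x non-outlier, other chromosomes",
    6: "outlier x non-outlier, other chromosomes",
}


# ---------------------------------------------------------------------------
# genotype posteriors
# ---------------------------------------------------------------------------

def _hw_prior(p: float) -> np.ndarray:
    # clip so boundary frequencies keep all genotypes barely possible
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def em_allele_frequency(likelihoods: np.ndarray, tol: float = 1e-6,
                        max_iter: int = 200) -> float:
    """EM estimate of the alternate-allele frequency from genotype
    likelihoods of one locus.

    ``likelihoods`` is (n_individuals, 3) for genotypes 0/1/2 alternate
    copies.  Each iteration sets the Hardy-Weinberg prior from the current
    p-hat, forms posteriors proportional to likelihood x prior, and updates
    p-hat to half the mean posterior dosage.  Rows that carry no information
    (all zero) are ignored; an all-missing locus raises ValueError.
    """
    L = np.asarray(likelihoods, dtype=float)
    informative = L.sum(axis=1) > 0
    if not informative.any():
        raise ValueError("all individuals missing at this locus")
    L = L[informative]
    p = 0.5
    dosage = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        post = L * _hw_prior(p)
        post /= post.sum(axis=1, keepdims=True)
        p_new = float((post @ dosage).mean() / 2.0)
        if abs(p_new - p) < tol:
            return p_new
        p = p_new
    return p


def genotype_posterior_mean(likelihood: np.ndarray, p_hat: float) -> float:
    """Posterior-mean dosage of one genotype under the HW prior at p_hat.

    sum_g g L(g) HW(g) / sum_g L(g) HW(g), a real number in [0, 2].
    """
    L = np.asarray(likelihood, dtype=float)
    w = L * _hw_prior(p_hat)
    tot = w.sum()
    if tot == 0:
        raise ValueError("zero posterior mass")
    return float((w @ np.array([0.0, 1.0, 2.0])) / tot)


def dosage_matrix(likelihoods: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean dosages and EM allele frequencies for all loci.

    ``likelihoods`` is (loci, individuals, 3).  Returns (dosages (loci,
    individuals), p_hat (loci,)).  Loci where every individual is missing
    get NaN dosages and NaN p-hat.
    """
    GL = np.asarray(likelihoods, dtype=float)
    n_loci, n_ind, _ = GL.shape
    dosages = np.full((n_loci, n_ind), np.nan)
    p_hats = np.full(n_loci, np.nan)
    g = np.array([0.0, 1.0, 2.0])
    for i in range(n_loci):
        L = GL[i]
        informative = L.sum(axis=1) > 0
        if not informative.any():
            continue
        p = em_allele_frequency(L[informative])
        p_hats[i] = p
        w = L[informative] * _hw_prior(p)
        dosages[i, informative] = (w @ g) / w.sum(axis=1)
    return dosages, p_hats


# ---------------------------------------------------------------------------
# per-locus differentiation between taxa
# ---------------------------------------------------------------------------

def per_locus_fst(dosages_a: np.ndarray, dosages_b: np.ndarray,
                  estimator: str = "hudson") -> np.ndarray:
    """Per-locus FST between two taxa from dosage matrices (loci x ind).

    Default is Hudson's two-population estimator on estimated allele
    frequencies with a sample-size correction; values can be negative and
    are *not* truncated at 0 (quantiles are taken on raw values).  The
    Nei/GST form (HT - HS)/HT is available as ``estimator="nei"``.
    Loci with fewer than 2 non-missing individuals in either taxon get NaN.
    """
    def freq_and_n(d):
        n = np.sum(~np.isnan(d), axis=1)
        p = np.nanmean(d, axis=1) / 2.0
        return p, n

    pa, na = freq_and_n(np.asarray(dosages_a, dtype=float))
    pb, nb = freq_and_n(np.asarray(dosages_b, dtype=float))
    valid = (na >= 2) & (nb >= 2)
    out = np.full(len(pa), np.nan)
    if estimator == "hudson":
        ca, cb = 2.0 * na, 2.0 * nb  # allele counts
        num = ((pa - pb) ** 2
               - pa * (1 - pa) / (ca - 1)
               - pb * (1 - pb) / (cb - 1))
        den = pa * (1 - pb) + pb * (1 - pa)
        ok = valid & (den > 0)
        out[ok] = num[ok] / den[ok]
    elif estimator == "nei":
        pbar = 0.5 * (pa + pb)
        ht = 2 * pbar * (1 - pbar)
        hs = pa * (1 - pa) + pb * (1 - pb)
        ok = valid & (ht > 0)
        out[ok] = (ht[ok] - hs[ok]) / ht[ok]
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return out


def per_locus_afd(dosages_a: np.ndarray, dosages_b: np.ndarray) -> np.ndarray:
    """Absolute allele-frequency difference per locus."""
    pa = np.nanmean(np.asarray(dosages_a, dtype=float), axis=1) / 2.0
    pb = np.nanmean(np.asarray(dosages_b, dtype=float), axis=1) / 2.0
    return np.abs(pa - pb)


# ---------------------------------------------------------------------------
# outlier designation
# ---------------------------------------------------------------------------

@dataclass
class OutlierDesignation:
    is_outlier: np.ndarray            # per-locus bool
    thresholds: dict                  # chromosome -> quantile threshold
    lo_per_chromosome: dict           # chromosome -> outlier count
    quantile: float
    warnings: list = field(default_factory=list)

    @property
    def lo_total(self) -> int:
        return int(self.is_outlier.sum())


def designate_outliers(statistic: np.ndarray, chromosomes: np.ndarray,
                       q: float = 0.99) -> OutlierDesignation:
    """Flag loci whose statistic lies strictly above the per-chromosome
    q-quantile (numpy's linear-interpolation quantile definition, so
    thresholds are bit-reproducible).  NaN statistics are never outliers
    and are excluded from the quantile."""
    statistic = np.asarray(statistic, dtype=float)
    chromosomes = np.asarray(chromosomes)
    is_out = np.zeros(len(statistic), dtype=bool)
    thresholds: dict = {}
    lo: dict = {}
    warns = []
    for c in pd.unique(chromosomes):
        on = chromosomes == c
        vals = statistic[on]
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            thresholds[c] = math.nan
            lo[c] = 0
            continue
        if len(finite) < 100:
            warns.append(f"chromosome {c}: only {len(finite)} loci; "
                         "quantile threshold is noisy")
        thr = float(np.quantile(finite, q))
        thresholds[c] = thr
        flag = on & (statistic > thr)
        is_out |= flag
        lo[c] = int(flag.sum())
    return OutlierDesignation(is_outlier=is_out, thresholds=thresholds,
                              lo_per_chromosome=lo, quantile=q,
                              warnings=warns)


# ---------------------------------------------------------------------------
# r^2 between dosage columns
# ---------------------------------------------------------------------------

def _r2_matrix(A: np.ndarray, B: Optional[np.ndarray] = None,
               min_pairs: int = 4) -> np.ndarray:
    """Squared Pearson correlations between rows of A and rows of B (loci x
    individuals), pairwise-complete over individuals.  Pairs with fewer than
    ``min_pairs`` complete observations, or zero variance, are NaN."""
    A = np.asarray(A, dtype=float)
    B = A if B is None else np.asarray(B, dtype=float)
    if not (np.isnan(A).any() or np.isnan(B).any()):
        za = _standardize_rows(A)
        zb = _standardize_rows(B)
        r = (za @ zb.T) / A.shape[1]
        return r * r
    out = np.full((A.shape[0], B.shape[0]), np.nan)
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            ok = ~(np.isnan(A[i]) | np.isnan(B[j]))
            if ok.sum() < min_pairs:
                continue
            x, y = A[i, ok], B[j, ok]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out[i, j] = r * r
    return out


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (X - mu) / sd


@dataclass
class R2GroupSample:
    group: int
    chromosome: object
    r2: np.ndarray
    lo: int
    seed: Optional[int] = None
    flags: list = field(default_factory=list)


def sample_group_r2(dosages: np.ndarray, is_outlier: np.ndarray,
                    chromosomes: np.ndarray, chromosome, group: int,
                    max_snps: int = 5000,
                    rng: Optional[np.random.Generator] = None
                    ) -> R2GroupSample:
    """Within-taxon pairwise r^2 values for one comparison group.

    ``dosages`` is (loci x individuals) for *one* taxon; outlier flags come
    from the between-taxon comparison.  Groups 1-2 return the full upper
    triangle of the correlation matrix of the (capped) same-chromosome
    outlier / non-outlier set.  Groups 3-6 sample Lo partner loci (from the
    complementary set on the same chromosome, or from all other
    chromosomes), compute the cross r^2 matrix, and keep every second value
    in row-major order until (Lo^2 - Lo)/2 values are collected, Lo being
    the (capped) outlier count of the chromosome.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if group not in GROUPS:
        raise ValueError(f"group must be 1..6, got {group}")
    dosages = np.asarray(dosages, dtype=float)
    chromosomes = np.asarray(chromosomes)
    on = chromosomes == chromosome
    flags: list[str] = []

    def cap(idx: np.ndarray) -> np.ndarray:
        if len(idx) > max_snps:
            return np.sort(rng.choice(idx, size=max_snps, replace=False))
        return idx

    out_here = cap(np.nonzero(on & is_outlier)[0])
    non_here = cap(np.nonzero(on & ~is_outlier)[0])
    out_other = cap(np.nonzero(~on & is_outlier)[0])
    non_other = cap(np.nonzero(~on & ~is_outlier)[0])
    lo = len(out_here)

    if group in (1, 2):
        idx = out_here if group == 1 else non_here
        if len(idx) < 2:
            flags.append("fewer than 2 loci; group empty")
            return R2GroupSample(group, chromosome, np.empty(0), lo,
                                 flags=flags)
        M = _r2_matrix(dosages[idx])
        iu, ju = np.triu_indices(len(idx), 1)
        vals = M[iu, ju]
        return R2GroupSample(group, chromosome, vals[np.isfinite(vals)], lo,
                             flags=flags)

    targets, partners = {
        3: (out_here, non_here),
        4: (out_here, out_other),
        5: (non_here, non_other),
        6: (out_here, non_other),
    }[group]
    want = (lo * lo - lo) // 2
    if want <= 0:
        flags.append("Lo < 2; nothing to sample")
        return R2GroupSample(group, chromosome, np.empty(0), lo, flags=flags)
    if len(targets) == 0 or len(partners) == 0:
        flags.append("empty target or partner set")
        return R2GroupSample(group, chromosome, np.empty(0), lo, flags=flags)
    n_t = min(len(targets), lo)
    t_idx = (np.sort(rng.choice(targets, size=n_t, replace=False))
             if len(targets) > n_t else targets)
    n_p = min(len(partners), max(lo, math.ceil(2 * want / max(n_t, 1)) + 1))
    p_idx = (np.sort(rng.choice(partners, size=n_p, replace=False))
             if len(partners) > n_p else partners)
    M = _r2_matrix(dosages[t_idx], dosages[p_idx])
    vals = M.ravel()[::2]
    vals = vals[np.isfinite(vals)]
    if len(vals) < want:
        flags.append(f"only {len(vals)} of {want} target values available")
    return R2GroupSample(group, chromosome, vals[:want], lo, flags=flags)


# ---------------------------------------------------------------------------
# density summaries of log(r^2)
# ---------------------------------------------------------------------------

@dataclass
class DensitySummary:
    grid: np.ndarray          # log r^2 evaluation grid
    density: np.ndarray
    modes: list               # [(location, mass)] sorted by location
    upper_mode_present: bool
    n_values: int
    n_floored: int

    def to_json(self) -> str:
        return json.dumps({
            "modes": [{"log_r2": loc, "mass": mass}
                      for loc, mass in self.modes],
            "upper_mode_present": self.upper_mode_present,
            "n_values": self.n_values,
            "n_floored": self.n_floored,
        })


def density_summary(r2_values: np.ndarray, floor: float = 1e-8,
                    grid_size: int = 512,
                    upper_mode_r2: float = 0.5,
                    upper_mode_mass: float = 0.01) -> DensitySummary:
    """Kernel density of log(r^2) with mode detection.

    Exact zeros are floored at ``floor`` before taking natural logs (the
    count is reported).  Local density maxima are located on a fixed grid;
    the mass of each mode is the integral between the flanking minima.  The
    "upper mode present" heuristic asks for a local maximum above
    r^2 = ``upper_mode_r2`` carrying at least ``upper_mode_mass`` of the
    sample - a tool-defined operationalization of visual bimodality.
    """
    vals = np.asarray(r2_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 10:
        raise ValueError("need at least 10 r^2 values")
    n_floored = int((vals < floor).sum())
    logv = np.log(np.maximum(vals, floor))
    grid = np.linspace(math.log(floor) - 0.5, 0.5, grid_size)
    if np.ptp(logv) < 1e-12:
        dens = np.zeros(grid_size)
        loc = float(logv[0])
        return DensitySummary(grid, dens, [(loc, 1.0)],
                              upper_mode_present=loc > math.log(upper_mode_r2),
                              n_values=len(vals), n_floored=n_floored)
    kde = gaussian_kde(logv)
    # Scott's rule over-smooths small samples on the log(r^2) scale, where
    # distinct modes sit several log-units apart; cap the bandwidth.
    bw_cap = 0.75
    sigma = float(np.std(logv, ddof=1))
    if sigma > 0 and kde.factor * sigma > bw_cap:
        kde.set_bandwidth(bw_cap / sigma)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = np.nonzero((np.hstack([d, -1]) < 0)
                        & (np.hstack([1, d]) > 0))[0]
    minima = np.nonzero((np.hstack([d, 1]) > 0)
                        & (np.hstack([-1, d]) < 0))[0]
    total = np.trapezoid(dens, grid)
    modes = []
    for mx in maxima:
        left = minima[minima < mx]
        right = minima[minima > mx]
        lo_i = int(left[-1]) if len(left) else 0
        hi_i = int(right[0]) if len(right) else grid_size - 1
        mass = float(np.trapezoid(dens[lo_i:hi_i + 1], grid[lo_i:hi_i + 1])
                     / total)
        modes.append((float(grid[mx]), mass))
    upper = any(loc > math.log(upper_mode_r2) and mass >= upper_mode_mass
                for loc, mass in modes)
    return DensitySummary(grid, dens, modes, upper, len(vals), n_floored)


# ---------------------------------------------------------------------------
# synthetic two-taxon fixture
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalFixture:
    likelihoods: dict            # taxon -> (loci, individuals, 3)
    chromosomes: np.ndarray
    positions: np.ndarray
    truth: pd.DataFrame          # per-locus: is_barrier, p_a, p_b
    taxa: tuple


def make_empirical_fixture(n_individuals: int = 10,
                           loci_per_chromosome: int = 300,
                           n_chromosomes: int = 5,
                           barrier_fraction: float = 0.005,
                           barrier_afd: float = 0.9,
                           coupling_strength: float = 0.9,
                           error_rate: float = 0.01,
                           mean_depth: float = 8.0,
                           rng: Optional[np.random.Generator] = None,
                           taxa: tuple = ("taxonA", "taxonB")
                           ) -> EmpiricalFixture:
    """Generate a synthetic two-taxon genotype-likelihood dataset.

    Background loci share Uniform(0.05, 0.95) allele frequencies across
    taxa and are independent Hardy-Weinberg draws.  Each chromosome carries
    a fixed number round(barrier_fraction * loci_per_chromosome) of barrier
    loci (at least one), which differ in frequency between taxa by
    ``barrier_afd`` (p = 0.5 +/- afd/2) and are mutually correlated within
    taxa through a latent haplotype factor: each barrier allele copies the
    individual's latent haplotype ancestry state with probability
    coupling_strength**(1/4), which makes the pairwise dosage r^2 among
    barrier loci approach ``coupling_strength``.  The latent ancestry pool
    is conditioned to hold at least 3 minor-ancestry haplotypes (a few
    admixed individuals), so the correlations are well defined at small n.
    Genotype likelihoods come from Poisson-depth reads with a symmetric
    per-read error rate.  Defaults mirror a 10-individual-per-taxon
    resequencing design; barrier_fraction stays below 1 - quantile so a
    99th-quantile outlier scan can recover the planted barriers.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_loci = loci_per_chromosome * n_chromosomes
    chroms = np.repeat(np.arange(1, n_chromosomes + 1), loci_per_chromosome)
    positions = np.concatenate(
        [np.sort(rng.integers(1, 10_000_000, size=loci_per_chromosome))
         for _ in range(n_chromosomes)])
    n_barrier = max(1, round(barrier_fraction * loci_per_chromosome))
    is_barrier = np.zeros(n_loci, dtype=bool)
    for c in range(n_chromosomes):
        picks = rng.choice(loci_per_chromosome, size=n_barrier, replace=False)
        is_barrier[c * loci_per_chromosome + picks] = True
    p_shared = rng.uniform(0.05, 0.95, size=n_loci)
    p_a = p_shared.copy()
    p_b = p_shared.copy()
    p_a[is_barrier] = 0.5 + barrier_afd / 2.0
    p_b[is_barrier] = 0.5 - barrier_afd / 2.0
    gamma = max(coupling_strength, 0.0) ** 0.25

    likelihoods = {}
    for taxon, p_t in zip(taxa, (p_a, p_b)):
        pb = p_t[is_barrier][0] if is_barrier.any() else 0.5
        # A latent per-haplotype ancestry state drives the barrier-locus
        # correlation within the taxon.  The pool is conditioned to carry a
        # minimum of minor-ancestry haplotypes (a few admixed individuals),
        # otherwise the within-taxon correlations are degenerate at small n.
        n_hap = 2 * n_individuals
        k = int(rng.binomial(n_hap, pb))
        floor_minor = min(3, n_hap // 2)
        k = int(np.clip(k, floor_minor, n_hap - floor_minor))
        flat = np.zeros(n_hap, dtype=bool)
        flat[rng.permutation(n_hap)[:k]] = True
        latent = flat.reshape(2, n_individuals)
        G = np.zeros((n_loci, n_individuals), dtype=np.int64)
        for h in range(2):
            alleles = rng.random((n_loci, n_individuals)) < p_t[:, None]
            use_latent = (is_barrier[:, None]
                          & (rng.random((n_loci, n_individuals)) < gamma))
            alleles = np.where(use_latent, latent[h][None, :], alleles)
            G += alleles.astype(np.int64)
        depth = rng.poisson(mean_depth, size=(n_loci, n_individuals))
        p_read = np.choose(G, [error_rate, 0.5, 1.0 - error_rate])
        alt_reads = rng.binomial(depth, p_read)
        ref_reads = depth - alt_reads
        GL = np.empty((n_loci, n_individuals, 3))
        for g, pr in enumerate([error_rate, 0.5, 1.0 - error_rate]):
            GL[:, :, g] = pr ** alt_reads * (1.0 - pr) ** ref_reads
        GL[depth == 0] = 1.0 / 3.0  # no reads: flat likelihood
        likelihoods[taxon] = GL
    truth = pd.DataFrame({
        "chromosome": chroms, "position": positions,
        "is_barrier": is_barrier, "p_a": p_a, "p_b": p_b,
    })
    return EmpiricalFixture(likelihoods=likelihoods, chromosomes=chroms,
                            positions=positions, truth=truth, taxa=taxa)
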