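"""Per-generation population-genetic summaries.

Allele frequencies per deme, allele-frequency differences (AFD), per-site
FST as (HT - HS)/HT, and pairwise linkage disequilibrium measured as the
squared correlation of allelic states on haplotypes.  LD "between demes"
pools haplotypes from both demes; "within-deme" LD uses one deme's
haplotypes only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .sim_core import PopulationState

#: exact column order of the time-series TSV
TSV_COLUMNS = [
    "generation", "n_seg_selected", "n_seg_neutral",
    "afd_selected", "afd_neutral", "fst_selected", "fst_neutral",
    "ld_between_selected", "ld_between_neutral",
    "ld_within_selected", "ld_within_neutral",
    "s_bar", "r_bar", "theta", "s_star", "Le", "me", "N_me",
]


@dataclass
class TimeSeriesRecord:
    generation: int
    n_seg_selected: int
    n_seg_neutral: int
    afd_selected: float
    afd_neutral: float
    fst_selected: float
    fst_neutral: float
    ld_between_selected: float
    ld_between_neutral: float
    ld_within_selected: float
    ld_within_neutral: float
    s_bar: float
    r_bar: float
    theta: float
    s_star: float
    Le: float
    me: float
    N_me: float


def deme_allele_frequencies(state: PopulationState
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency in deme 0 and deme 1."""
    freqs = []
    for k in (0, 1):
        idx = state.deme_indices(k)
        H = state.haplotypes_of(idx)
        denom = 2 * len(idx)
        freqs.append(H.sum(axis=0) / denom if denom else
                     np.full(state.n_sites, np.nan))
    return freqs[0], freqs[1]


def afd(p0: np.ndarray, p1: np.ndarray, neutral: np.ndarray,
        favored: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-site AFD and class means.

    For a selected site, AFD is signed: frequency in the favored deme minus
    frequency in the other deme (negative early on is possible).  For
    neutral sites AFD is |p0 - p1|.
    """
    p_by_deme = np.stack([p0, p1])
    p_fav = np.where(favored == 0, p0, p1)
    p_oth = np.where(favored == 0, p1, p0)
    per_site = np.where(neutral, np.abs(p0 - p1), p_fav - p_oth)
    sel = ~neutral
    mean_sel = float(per_site[sel].mean()) if sel.any() else math.nan
    mean_neu = float(per_site[neutral].mean()) if neutral.any() else math.nan
    return per_site, mean_sel, mean_neu


def fst_gst(p0: np.ndarray, p1: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site FST = (HT - HS)/HT with HT from the pooled frequency.

    HT = 2 p-bar (1 - p-bar); HS is the mean of the within-deme expected
    heterozygosities.  Sites monomorphic in the pooled sample (HT = 0) are
    undefined; the second return value flags the sites where FST is valid.
    """
    pbar = 0.5 * (p0 + p1)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = 0.5 * (2.0 * p0 * (1.0 - p0) + 2.0 * p1 * (1.0 - p1))
    valid = ht > 0
    fst = np.full(len(pbar), np.nan)
    fst[valid] = (ht[valid] - hs[valid]) / ht[valid]
    return fst, valid


def pairwise_r2(X: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of 0/1 allelic states of two columns.

    Rows of ``X`` are haplotypes in the evaluated sample.  Undefined (raises)
    if either column has zero variance.
    """
    x = X[:, i].astype(float)
    y = X[:, j].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        raise ValueError("r^2 undefined: a locus is monomorphic in the sample")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pair_from_linear(t: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode linear upper-triangle indices (row-major, i < j) of a k x k grid."""
    # row i starts at offset i*k - i*(i+1)/2 - i ... solve quadratically
    i = (2 * k - 1 - np.sqrt((2 * k - 1) ** 2 - 8 * t.astype(np.float64))) // 2
    i = i.astype(np.int64)
    # guard against floating point at row edges
    start = i * (2 * k - i - 1) // 2
    i[start > t] -= 1
    start = i * (2 * k - i - 1) // 2
    nxt = (i + 1) * (2 * k - i - 2) // 2
    bump = nxt <= t
    i[bump] += 1
    start = i * (2 * k - i - 1) // 2
    j = t - start + i + 1
    return i, j


def sampled_pair_r2(X: np.ndarray, pair_cap: int,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """r^2 for all (or a seeded subsample of) column pairs of ``X``.

    Columns monomorphic in the sample are excluded up front.  If the number
    of pairs exceeds ``pair_cap``, pairs are subsampled uniformly without
    replacement.
    """
    Xf = X.astype(np.float64)
    sd = Xf.std(axis=0)
    poly = sd > 0
    Xf = Xf[:, poly]
    k = Xf.shape[1]
    if k < 2:
        return np.empty(0)
    n_pairs = k * (k - 1) // 2
    if n_pairs > pair_cap:
        if rng is None:
            rng = np.random.default_rng(0)
        t = rng.choice(n_pairs, size=pair_cap, replace=False)
        ii, jj = _pair_from_linear(t, k)
    else:
        ii, jj = np.triu_indices(k, 1)
    Z = (Xf - Xf.mean(axis=0)) / Xf.std(axis=0)
    r = np.einsum("ni,ni->i", Z[:, ii], Z[:, jj]) / Xf.shape[0]
    return r * r


def mean_pairwise_ld(state: PopulationState, cls: str, scope: str,
                     pair_cap: int = 125_000,
                     rng: Optional[np.random.Generator] = None,
                     use_abs_r: bool = False
                     ) -> tuple[float, np.ndarray, int]:
    """Mean pairwise LD among same-class segregating sites.

    ``cls`` in {"selected", "neutral"}; ``scope`` in {"pooled", "deme0",
    "deme1"} ("pooled" is the between-deme LD: haplotypes of both demes).
    Returns (mean, full r^2 sample, number of sites excluded as monomorphic
    within the scope).  The mean is NaN when fewer than two polymorphic
    sites exist in scope.
    """
    if cls == "selected":
        cols = ~state.neutral
    elif cls == "neutral":
        cols = state.neutral
    else:
        raise ValueError(f"unknown class {cls!r}")
    if scope == "pooled":
        H = state.haplotypes
    elif scope in ("deme0", "deme1"):
        H = state.haplotypes_of(state.deme_indices(int(scope[-1])))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    X = H[:, cols]
    n_mono = int((X.std(axis=0) == 0).sum())
    r2 = sampled_pair_r2(X, pair_cap, rng)
    if use_abs_r:
        r2 = np.sqrt(r2)
    mean = float(r2.mean()) if len(r2) else math.nan
    return mean, r2, n_mono


def summarize_timepoint(state: PopulationState, me: float,
                        record_ld: bool = True, ld_pair_cap: int = 20_000,
                        rng: Optional[np.random.Generator] = None
                        ) -> TimeSeriesRecord:
    """Assemble one time-series row (statistics plus coupling summary)."""
    from .coupling import coupling_summary

    n = state.n_sites
    sel = ~state.neutral
    nan = math.nan
    if n > 0:
        p0, p1 = deme_allele_frequencies(state)
        _, afd_sel, afd_neu = afd(p0, p1, state.neutral, state.favored)
        fst, valid = fst_gst(p0, p1)
        fst_sel = (float(np.nanmean(fst[sel & valid]))
                   if (sel & valid).any() else nan)
        fst_neu = (float(np.nanmean(fst[state.neutral & valid]))
                   if (state.neutral & valid).any() else nan)
    else:
        afd_sel = afd_neu = fst_sel = fst_neu = nan
    if record_ld and n > 0:
        ld_b_sel, _, _ = mean_pairwise_ld(state, "selected", "pooled",
                                          ld_pair_cap, rng)
        ld_b_neu, _, _ = mean_pairwise_ld(state, "neutral", "pooled",
                                          ld_pair_cap, rng)
        w_sel = [mean_pairwise_ld(state, "selected", f"deme{k}",
                                  ld_pair_cap, rng)[0] for k in (0, 1)]
        w_neu = [mean_pairwise_ld(state, "neutral", f"deme{k}",
                                  ld_pair_cap, rng)[0] for k in (0, 1)]
        ld_w_sel = float(np.nanmean(w_sel)) if not all(
            math.isnan(v) for v in w_sel) else nan
        ld_w_neu = float(np.nanmean(w_neu)) if not all(
            math.isnan(v) for v in w_neu) else nan
    else:
        ld_b_sel = ld_b_neu = ld_w_sel = ld_w_neu = nan
    cs = coupling_summary(state, state.params.m)
    return TimeSeriesRecord(
        generation=state.generation,
        n_seg_selected=int(sel.sum()),
        n_seg_neutral=int(state.neutral.sum()),
        afd_selected=afd_sel, afd_neutral=afd_neu,
        fst_selected=fst_sel, fst_neutral=fst_neu,
        ld_between_selected=ld_b_sel, ld_between_neutral=ld_b_neu,
        ld_within_selected=ld_w_sel, ld_within_neutral=ld_w_neu,
        s_bar=cs.s_bar, r_bar=cs.r_bar, theta=cs.theta,
        s_star=cs.s_star, Le=cs.Le, me=me,
        N_me=state.params.N_total * me,
    )
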