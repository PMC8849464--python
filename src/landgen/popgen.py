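"""Population-genetic summary and differentiation statistics.

Implements, for biallelic SNP matrices with missing data handled
pairwise-complete per locus:

* per-group diversity (observed heterozygosity H_O, Nei's unbiased gene
  diversity H_E, inbreeding coefficient F_IS),
* rarefied allelic richness A_r with a permutation two-sample test,
* composite (Burrows) linkage-disequilibrium r-squared,
* pairwise differentiation: Nei (1973) F_ST with individual-permutation
  significance and Benjamini-Hochberg FDR, Hedrick/Meirmans double-corrected
  G''_ST, and Meirmans' maximum-standardised F'_ST,
* Pearson correlation between labelled distance matrices with a Mantel-style
  permutation p-value,
* hierarchical F-statistics from nested moment (ANOVA) variance components at
  the allele level, with locus-bootstrap CIs and permutation tests.

Estimator conventions follow Nei & Chesser (1983) corrections where a
finite-sample correction is called for; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    MISSING,
    AnalysisError,
    ConfigurationError,
    DistanceMatrix,
    GenotypeMatrix,
)
from .rng import substream

__all__ = [
    "diversity_stats",
    "rarefied_allelic_richness",
    "richness_permutation_test",
    "ld_r2",
    "pairwise_fst_nei",
    "gst_hedrick",
    "fst_meirmans",
    "matrix_correlation",
    "hierarchical_f",
    "HierarchicalFResult",
]


# ------------------------------------------------------------------ helpers


def _group_rows(gm: GenotypeMatrix, grouping: str) -> dict[str, np.ndarray]:
    groups = gm.groups(grouping)
    for lab, rows in groups.items():
        if len(rows) < 2:
            raise AnalysisError(f"group '{lab}' has fewer than 2 samples")
    return groups


def _locus_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n_called, alt_count, het_count) for a genotype sub-matrix."""
    called = g != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    het = np.logical_and(called, g == 1).sum(axis=0)
    return n, alt, het


# ------------------------------------------------------------------ diversity


def diversity_stats(gm: GenotypeMatrix, grouping: str = "site_id") -> pd.DataFrame:
    """Per-group H_O, H_E (unbiased), F_IS and sample size.

    Per-locus values are averaged over loci with >= 2 called genotypes in the
    group; H_E carries the 2n/(2n-1) small-sample correction; F_IS is computed
    from the multilocus averages, with the convention F_IS = 0 when H_E = 0.
    """
    rows = []
    for lab, idx in _group_rows(gm, grouping).items():
        n, alt, het = _locus_counts(gm.genotypes[idx])
        use = n >= 2
        if not use.any():
            raise AnalysisError(f"group '{lab}' has no locus with 2+ called genotypes")
        nn, aa, hh = n[use], alt[use], het[use]
        p = aa / (2.0 * nn)
        ho = hh / nn
        he = 2.0 * p * (1.0 - p) * (2.0 * nn) / (2.0 * nn - 1.0)
        mean_ho = float(ho.mean())
        mean_he = float(he.mean())
        fis = 0.0 if mean_he == 0 else 1.0 - mean_ho / mean_he
        rows.append(
            {
                "group": lab,
                "n": int(len(idx)),
                "n_loci": int(use.sum()),
                "H_O": mean_ho,
                "H_E": mean_he,
                "F_IS": fis,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _per_locus_richness(n: np.ndarray, alt: np.ndarray, g: int) -> np.ndarray:
    """Rarefied allele count per locus; NaN where gene copies < g."""
    N = 2.0 * n
    out = np.full(n.shape, np.nan)
    ok = N >= g
    if not ok.any():
        return out
    Nk, altk = N[ok], alt[ok].astype(float)
    vals = np.zeros(Nk.shape)
    for counts in (altk, Nk - altk):  # alt and ref allele copy counts
        # P(allele absent from a subsample of g copies) = C(N-Ni, g)/C(N, g)
        absent = np.zeros(Nk.shape)
        feasible = (Nk - counts) >= g
        if feasible.any():
            absent[feasible] = np.exp(
                _log_comb(Nk[feasible] - counts[feasible], g) - _log_comb(Nk[feasible], g)
            )
        present = counts > 0
        vals += np.where(present, 1.0 - np.where(feasible, absent, 0.0), 0.0)
    out[ok] = vals
    return out


def rarefied_allelic_richness(
    gm: GenotypeMatrix, grouping: str = "site_id", g: int | None = None
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Per-group rarefied allelic richness A_r at `g` gene copies.

    Returns (per-group mean A_r, per-locus A_r table groups x loci, g used).
    Default g is the smallest per-locus gene-copy count observed in any group
    (so every locus with data is rarefiable in every group).
    """
    groups = _group_rows(gm, grouping)
    counts = {lab: _locus_counts(gm.genotypes[idx])[:2] for lab, idx in groups.items()}
    if g is None:
        g_candidates = [
            2 * int(n[n > 0].min()) for (n, _) in counts.values() if (n > 0).any()
        ]
        g = min(g_candidates)
    if g < 2:
        raise ConfigurationError("rarefaction size g must be >= 2 gene copies")
    per_locus = pd.DataFrame(
        {lab: _per_locus_richness(n, alt, g) for lab, (n, alt) in counts.items()},
        index=gm.locus_ids,
    ).T
    return per_locus.mean(axis=1, skipna=True), per_locus, int(g)


def richness_permutation_test(
    gm: GenotypeMatrix,
    group_a: str,
    group_b: str,
    grouping: str = "site_ecotope",
    n_perm: int = 10_000,
    seed: int = 0,
    g: int | None = None,
) -> dict:
    """Two-sided permutation two-sample test on per-locus A_r values.

    The statistic is the difference of per-locus means; the null is built by
    reassigning the pooled per-locus values to the two groups at random.
    p = (b + 1) / (n_perm + 1).
    """
    _, per_locus, g_used = rarefied_allelic_richness(gm, grouping, g)
    va = per_locus.loc[group_a].dropna().to_numpy()
    vb = per_locus.loc[group_b].dropna().to_numpy()
    if len(va) == 0 or len(vb) == 0:
        raise AnalysisError("a group has no rarefiable loci")
    obs = va.mean() - vb.mean()
    pooled = np.concatenate([va, vb])
    rng = substream(seed, f"richness:{group_a}:{group_b}")
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = perm[: len(va)].mean() - perm[len(va):].mean()
        if abs(t) >= abs(obs) - 1e-15:
            b += 1
    return {
        "statistic": float(obs),
        "p": (b + 1) / (n_perm + 1),
        "g": g_used,
        "mean_a": float(va.mean()),
        "mean_b": float(vb.mean()),
    }


# ------------------------------------------------------------------ LD


def ld_r2(
    gm: GenotypeMatrix, rows: np.ndarray | None = None, threshold: float = 0.2
) -> dict:
    """Composite (Burrows) LD r^2: squared Pearson correlation of genotype
    codes per locus pair over pairwise-complete samples.

    Monomorphic (or fully missing-overlap) pairs are excluded and counted.
    Returns the full r^2 matrix, the fraction of evaluable pairs above
    `threshold`, and the exclusion count.
    """
    g = gm.genotypes if rows is None else gm.genotypes[rows]
    if g.shape[1] < 2:
        raise AnalysisError("need at least 2 loci for LD")
    x = np.ma.masked_equal(g.astype(float), float(MISSING))
    corr = np.ma.corrcoef(x, rowvar=False)
    r2 = np.asarray(np.ma.filled(corr, np.nan), dtype=float) ** 2
    np.fill_diagonal(r2, np.nan)
    iu = np.triu_indices(r2.shape[0], k=1)
    vals = r2[iu]
    n_excluded = int(np.isnan(vals).sum())
    ok = vals[~np.isnan(vals)]
    frac = float((ok > threshold).mean()) if len(ok) else float("nan")
    return {
        "r2_matrix": r2,
        "fraction_above": frac,
        "threshold": threshold,
        "n_pairs": int(len(vals)),
        "n_excluded": n_excluded,
    }


# ------------------------------------------------------------------ pairwise F_ST


def _nei_fst_pair(
    ga: np.ndarray, gb: np.ndarray, min_called: int = 2
) -> tuple[float, bool]:
    """Multilocus Nei (1973) F_ST = (H_T - H_S)/H_T for two groups.

    H_S per locus is the mean of the two groups' unbiased gene diversities;
    H_T comes from the unweighted mean allele frequency. Multilocus values are
    averages over loci called in both groups. Returns (fst, ht_zero_flag);
    F_ST = 0 by convention when the multilocus H_T is 0.
    """
    na, alta, _ = _locus_counts(ga)
    nb, altb, _ = _locus_counts(gb)
    use = (na >= min_called) & (nb >= min_called)
    if not use.any():
        return float("nan"), True
    pa = alta[use] / (2.0 * na[use])
    pb = altb[use] / (2.0 * nb[use])
    hs = 0.5 * (
        2 * pa * (1 - pa) * (2 * na[use]) / (2 * na[use] - 1)
        + 2 * pb * (1 - pb) * (2 * nb[use]) / (2 * nb[use] - 1)
    )
    pbar = 0.5 * (pa + pb)
    ht = 2 * pbar * (1 - pbar)
    sum_ht = ht.sum()
    if sum_ht <= 0:
        return 0.0, True
    return float((sum_ht - hs.sum()) / sum_ht), False


def pairwise_fst_nei(
    gm: GenotypeMatrix,
    grouping: str = "site_ecotope",
    n_perm: int = 999,
    seed: int = 0,
    test_pairs: str | list[tuple[str, str]] = "all",
) -> tuple[DistanceMatrix, pd.DataFrame, pd.DataFrame]:
    """Pairwise Nei F_ST matrix with permutation p-values and BH-FDR q-values.

    The permutation null reshuffles individuals between the two groups of a
    pair (999 by default); p = (b+1)/(B+1); q from Benjamini-Hochberg across
    all tested pairs. `test_pairs` limits the (costly) permutation test to a
    subset of pairs ("within_site" tests only domestic-wild pairs that share a
    site); untested pairs get NaN p.
    """
    groups = _group_rows(gm, grouping)
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise AnalysisError("need at least 2 groups")
    fst = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)

    if test_pairs == "all":
        tested = set(frozenset(p) for p in combinations(labels, 2))
    elif test_pairs == "within_site":
        tested = set()
        for a, b in combinations(labels, 2):
            sa, sb = a.split(":")[0], b.split(":")[0]
            if sa == sb:
                tested.add(frozenset((a, b)))
    else:
        tested = set(frozenset(p) for p in test_pairs)

    rng = substream(seed, "pairwise_fst")
    for i, j in combinations(range(k), 2):
        ra, rb = groups[labels[i]], groups[labels[j]]
        obs, _ = _nei_fst_pair(gm.genotypes[ra], gm.genotypes[rb])
        fst[i, j] = fst[j, i] = obs if np.isfinite(obs) else 0.0
        if frozenset((labels[i], labels[j])) in tested and np.isfinite(obs):
            pooled = np.concatenate([ra, rb])
            b = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                f_perm, _ = _nei_fst_pair(
                    gm.genotypes[perm[: len(ra)]], gm.genotypes[perm[len(ra):]]
                )
                if np.isfinite(f_perm) and f_perm >= obs - 1e-15:
                    b += 1
            pmat[i, j] = pmat[j, i] = (b + 1) / (n_perm + 1)

    qmat = np.full((k, k), np.nan)
    iu = np.triu_indices(k, 1)
    pvals = pmat[iu]
    ok = ~np.isnan(pvals)
    if ok.any():
        q = np.full(pvals.shape, np.nan)
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        qmat[iu] = q
        qmat[(iu[1], iu[0])] = q
    dm = DistanceMatrix(labels, fst, kind="fst_nei")
    return (
        dm,
        pd.DataFrame(pmat, index=labels, columns=labels),
        pd.DataFrame(qmat, index=labels, columns=labels),
    )


# ----------------------------------------------- corrected differentiation


def _nei_chesser_pair(ga: np.ndarray, gb: np.ndarray) -> dict | None:
    """Per-pair multilocus Nei & Chesser (1983) quantities for 2 groups.

    Returns mean (over usable loci) of Ho, Hs_est, Ht_est and the
    maximal-differentiation Ht (pops recoded to private alleles), or None if
    no locus is usable.
    """
    na, alta, heta = _locus_counts(ga)
    nb, altb, hetb = _locus_counts(gb)
    use = (na >= 2) & (nb >= 2)
    if not use.any():
        return None
    na, alta, heta = na[use], alta[use], heta[use]
    nb, altb, hetb = nb[use], altb[use], hetb[use]
    pa, pb = alta / (2.0 * na), altb / (2.0 * nb)
    npops = 2
    n_harm = npops / (1.0 / na + 1.0 / nb)
    ho = 0.5 * (heta / na + hetb / nb)
    hs0 = 0.5 * (2 * pa * (1 - pa) + 2 * pb * (1 - pb))
    hs = n_harm / (n_harm - 1.0) * (hs0 - ho / (2.0 * n_harm))
    pbar = 0.5 * (pa + pb)
    ht0 = 2 * pbar * (1 - pbar)
    ht = ht0 + hs / (n_harm * npops) - ho / (2.0 * n_harm * npops)
    # recoded maximal differentiation: every allele private to its population
    sum_sq = (pa**2 + (1 - pa) ** 2 + pb**2 + (1 - pb) ** 2) / npops**2
    ht_max = (1.0 - sum_sq) + hs / (n_harm * npops) - ho / (2.0 * n_harm * npops)
    return {
        "ho": float(ho.mean()),
        "hs": float(hs.mean()),
        "ht": float(ht.mean()),
        "ht_max": float(ht_max.mean()),
    }


def _pairwise_corrected(gm: GenotypeMatrix, grouping: str, which: str) -> DistanceMatrix:
    groups = _group_rows(gm, grouping)
    labels = list(groups)
    k = len(labels)
    out = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        q = _nei_chesser_pair(gm.genotypes[groups[labels[i]]], gm.genotypes[groups[labels[j]]])
        if q is None or q["ht"] <= 0:
            val = 0.0
        elif which == "gst_hedrick":
            # double-corrected G''_ST (Meirmans & Hedrick 2011)
            denom = (2 * q["ht"] - q["hs"]) * (1.0 - q["hs"])
            val = 0.0 if denom <= 0 else 2 * (q["ht"] - q["hs"]) / denom
        else:  # Meirmans' maximum-standardised F'_ST
            gst = (q["ht"] - q["hs"]) / q["ht"]
            gst_max = (q["ht_max"] - q["hs"]) / q["ht_max"] if q["ht_max"] > 0 else 0.0
            val = 0.0 if gst_max <= 0 else gst / gst_max
        out[i, j] = out[j, i] = val
    return DistanceMatrix(labels, out, kind=which)


def gst_hedrick(gm: GenotypeMatrix, grouping: str = "site_id") -> DistanceMatrix:
    """Pairwise double-corrected G''_ST (Meirmans & Hedrick 2011)."""
    return _pairwise_corrected(gm, grouping, "gst_hedrick")


def fst_meirmans(gm: GenotypeMatrix, grouping: str = "site_id") -> DistanceMatrix:
    """Pairwise Meirmans maximum-standardised F'_ST = F_ST / F_ST(max)."""
    return _pairwise_corrected(gm, grouping, "fst_meirmans")


# ------------------------------------------------------------------ matrix r


def matrix_correlation(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Pearson r / r^2 over off-diagonal elements of two aligned matrices,
    with a Mantel-style permutation p (two-sided on r)."""
    if set(dm_a.labels) != set(dm_b.labels):
        raise ConfigurationError("distance matrices have different labels")
    dm_b = dm_a.align(dm_b)
    x, y = dm_a.condensed(), dm_b.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "r2": float("nan"), "p": float("nan"),
                "note": "constant matrix: correlation undefined"}
    r = float(np.corrcoef(x, y)[0, 1])
    rng = substream(seed, "matrix_correlation")
    n = dm_a.n
    b = 0
    vals = dm_b.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = vals[np.ix_(perm, perm)][np.tril_indices(n, -1)]
        if abs(np.corrcoef(x, yp)[0, 1]) >= abs(r) - 1e-15:
            b += 1
    return {"r": r, "r2": r * r, "p": (b + 1) / (n_perm + 1)}


# ------------------------------------------------------------------ hierarchical F


@dataclass
class HierarchicalFResult:
    """Nested variance components (summed over loci) and hierarchical F's.

    components: per-stratum variance components, ordered top level first,
    ending with 'individual' and 'error' (within-individual).
    f_stats: F for each level; the top level is measured against the total
    variance, deeper levels against the variance remaining within their
    parent stratum. ci: 95% locus-bootstrap intervals. p: permutation
    p-values (units at the level immediately below the tested one are
    permuted across cells within their parent).
    """

    levels: list[str]
    components: dict[str, float]
    f_stats: dict[str, float]
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]


def _nested_components(
    dosage: np.ndarray, called: np.ndarray, level_codes: list[np.ndarray]
) -> np.ndarray:
    """Method-of-moments variance components of an unbalanced nested design.

    Allele-level nested ANOVA: strata are `level_codes` (per-individual
    integer labels, top level first), then individuals, then alleles within
    individuals (error). Returns array (n_levels + 2, n_loci) of components
    [level_1, ..., level_L, individual, error] per locus. Components can be
    negative (moment estimators).
    """
    n_ind, n_loci = dosage.shape
    # assignment arrays, top to bottom; last = individuals
    assigns = [np.zeros(n_ind, dtype=int)] + list(level_codes) + [np.arange(n_ind)]
    # make codes hierarchical: child cell ids unique within the whole design
    for li in range(1, len(assigns)):
        combo = assigns[li - 1].astype(np.int64) * (assigns[li].max() + 1) + assigns[li]
        _, assigns[li] = np.unique(combo, return_inverse=True)

    L = len(level_codes)  # user levels (excluding grand/individual)
    d = np.where(called, dosage, 0).astype(float)
    c2 = 2.0 * called  # allele counts per individual per locus

    ind_code = np.arange(n_ind)

    def cell_sums(code: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ncells = code.max() + 1
        if ncells == n_ind and np.array_equal(code, ind_code):
            return d, c2.astype(float)
        onehot = np.zeros((ncells, n_ind))
        onehot[code, ind_code] = 1.0
        return onehot @ d, onehot @ c2

    sums_l, cnts_l = zip(*(cell_sums(a) for a in assigns))
    n_strata = L + 2  # user levels + individual + error

    # sums of squares and df per stratum (grand level is assigns[0])
    SS = np.zeros((n_strata, n_loci))
    df = np.zeros((n_strata, n_loci))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = [np.where(cnts_l[i] > 0, sums_l[i] / cnts_l[i], np.nan) for i in range(len(assigns))]
    # map each cell of level i to its parent cell id
    for i in range(1, len(assigns)):
        code, pcode = assigns[i], assigns[i - 1]
        # representative parent per cell
        ncells = code.max() + 1
        rep = np.zeros(ncells, dtype=int)
        rep[code] = pcode
        diff = means[i] - means[i - 1][rep]
        SS[i - 1] = np.nansum(cnts_l[i] * np.where(np.isnan(diff), 0.0, diff) ** 2, axis=0)
        occupied_i = (cnts_l[i] > 0).sum(axis=0)
        occupied_p = (cnts_l[i - 1] > 0).sum(axis=0)
        df[i - 1] = occupied_i - occupied_p
    # error: alleles within individuals; SS = 0.5 per called heterozygote
    SS[n_strata - 1] = 0.5 * np.logical_and(called, dosage == 1).sum(axis=0)
    n_called_tot = called.sum(axis=0)
    df[n_strata - 1] = n_called_tot  # 2C - C

    # expected-mean-square coefficients k[l, m]: coefficient of component m
    # (m indexed over strata 0..L+? excluding error) in E[MS of stratum l]
    # S_m(a) = sum over level-(m+1) cells within a of n_cell^2
    def S_over(level_idx: int, agg_code_level: int) -> np.ndarray:
        """Sum of squared counts of cells at `level_idx`, aggregated to cells
        of `agg_code_level`, divided by aggregate counts, summed: returns
        per-locus Sum_{cells c at agg} S(c)/n_c."""
        n2 = cnts_l[level_idx] ** 2
        code_fine = assigns[level_idx]
        code_coarse = assigns[agg_code_level]
        ncoarse = code_coarse.max() + 1
        nfine = code_fine.max() + 1
        rep = np.zeros(nfine, dtype=int)
        rep[code_fine] = code_coarse
        onehot = np.zeros((ncoarse, nfine))
        onehot[rep, np.arange(nfine)] = 1.0
        agg = onehot @ n2
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(cnts_l[agg_code_level] > 0, agg / cnts_l[agg_code_level], 0.0)
        return ratio.sum(axis=0)

    n_random = L + 1  # strata with k-coefficients (user levels + individuals)
    K = np.zeros((n_random, n_random, n_loci))
    for l in range(n_random):  # MS row, stratum l <-> assigns level l+1
        for m in range(l, n_random):
            term_l = S_over(m + 1, l + 1)
            term_p = S_over(m + 1, l)
            with np.errstate(invalid="ignore", divide="ignore"):
                K[l, m] = np.where(df[l] > 0, (term_l - term_p) / df[l], 0.0)

    comps = np.zeros((n_strata, n_loci))
    with np.errstate(invalid="ignore", divide="ignore"):
        MS = np.where(df > 0, SS / df, 0.0)
    comps[n_strata - 1] = MS[n_strata - 1]  # error
    for l in range(n_random - 1, -1, -1):
        acc = MS[l] - comps[n_strata - 1]
        for m in range(l + 1, n_random):
            acc = acc - K[l, m] * comps[m]
        with np.errstate(invalid="ignore", divide="ignore"):
            comps[l] = np.where(K[l, l] != 0, acc / K[l, l], 0.0)
        comps[l][df[l] <= 0] = 0.0
    return comps


def _f_from_components(total_comps: np.ndarray, levels: list[str]) -> dict[str, float]:
    tot = total_comps.sum()
    out: dict[str, float] = {}
    L = len(levels)
    for i, lev in enumerate(levels):
        denom = tot if i == 0 else total_comps[i:].sum()
        out[f"{lev}/{'total' if i == 0 else levels[i - 1]}"] = (
            float(total_comps[i] / denom) if denom != 0 else float("nan")
        )
    within = total_comps[L:].sum()
    out["individual/within"] = float(total_comps[L] / within) if within != 0 else float("nan")
    return out


def hierarchical_f(
    gm: GenotypeMatrix,
    levels: list[str] | None = None,
    n_perm: int = 999,
    n_boot: int = 200,
    seed: int = 0,
) -> HierarchicalFResult:
    """Hierarchical F-statistics from nested allele-level variance components.

    `levels` is an ordered list of metadata columns, outermost first (e.g.
    ["site_id", "ecotope"] for ecotope nested within collection site). Each
    inner level must nest cleanly in its parent. Per-locus components are
    summed over loci before taking F ratios; 95% CIs bootstrap loci;
    permutation p-values shuffle the units one level below the tested level
    across cells within their parent stratum (999 permutations by default).
    A level realised by a single cell is reported as NaN.
    """
    if levels is None:
        levels = ["site_id"]
    codes = []
    for i, lev in enumerate(levels):
        lab = gm.meta[lev].astype(str)
        if i > 0:  # verify nesting: composite label
            lab = gm.meta[levels[i - 1]].astype(str) + "|" + lab
        codes.append(pd.factorize(lab)[0])
    dosage = gm.genotypes.astype(float)
    called = gm.genotypes != MISSING

    comps = _nested_components(dosage, called, codes)
    total = comps.sum(axis=1)
    names = levels + ["individual", "error"]
    f_stats = _f_from_components(total, levels)
    # a level realised by a single cell (or no more cells than its parent)
    # has no degrees of freedom: its F is undefined
    n_cells_above = 1
    for i, lev in enumerate(levels):
        n_cells = len(np.unique(codes[i]))
        if n_cells <= n_cells_above:
            f_stats[list(f_stats)[i]] = float("nan")
        n_cells_above = n_cells

    rng = substream(seed, "hierarchical_f")
    # locus bootstrap CIs
    ci: dict[str, tuple[float, float]] = {}
    n_loci = comps.shape[1]
    boots = {k: [] for k in f_stats}
    for _ in range(n_boot):
        idx = rng.integers(0, n_loci, n_loci)
        fb = _f_from_components(comps[:, idx].sum(axis=1), levels)
        for k2, v in fb.items():
            boots[k2].append(v)
    for k2, vals in boots.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        ci[k2] = (
            (float(np.quantile(arr, 0.025)), float(np.quantile(arr, 0.975)))
            if len(arr)
            else (float("nan"), float("nan"))
        )

    # permutation tests: level i tested by permuting level-(i+1) units
    # (or individuals for the innermost level) across level-i cells within
    # the parent stratum
    p: dict[str, float] = {}
    keys = list(f_stats)
    for i, lev in enumerate(levels):
        key = keys[i]
        obs = f_stats[key]
        if not np.isfinite(obs):
            p[key] = float("nan")
            continue
        parent = codes[i - 1] if i > 0 else np.zeros(gm.n_samples, dtype=int)
        b = 0
        for _ in range(n_perm):
            perm_codes = [c.copy() for c in codes]
            new_i = perm_codes[i].copy()
            for pc in np.unique(parent):
                sel = np.flatnonzero(parent == pc)
                new_i[sel] = perm_codes[i][rng.permutation(sel)]
            perm_codes[i] = new_i
            # deeper levels keep their own labels but re-nest under the permuted level
            fp = _f_from_components(
                _nested_components(dosage, called, perm_codes).sum(axis=1), levels
            )[key]
            if np.isfinite(fp) and fp >= obs - 1e-15:
                b += 1
        p[key] = (b + 1) / (n_perm + 1)

    return HierarchicalFResult(
        levels=levels,
        components=dict(zip(names, total.tolist())),
        f_stats=f_stats,
        ci=ci,
        p=p,
    )
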