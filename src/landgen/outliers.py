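"""Domestic/wild outlier-locus scans and their consensus.

Four complementary scans for loci associated with the domestic ecotope:

* Random-forest ranking by scaled per-tree out-of-bag permutation importance
  with backwards purging to the subset minimising the out-of-bag error rate
  (OOB-ER),
* partial redundancy analysis (RDA): genotypes regressed on the ecotope
  indicator conditioned on spatial principal coordinates; per-locus loadings
  on the single constrained axis are z-scored and thresholded at +/-2 and
  +/-3 SD,
* an OutFlank-style scan: per-locus uncorrected F_ST fitted by a trimmed
  maximum-likelihood scaled chi-square null, right-tail p and BH q-values,
* an fsthet-style scan: smoothed empirical quantile envelopes of the
  F_ST-heterozygosity cloud, distribution-free.

The consensus report intersects the per-method flag sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .datatypes import MISSING, AnalysisError, GenotypeMatrix
from .rng import child_seed, substream

__all__ = [
    "spatial_covariates",
    "rf_rank",
    "rf_backwards_purge",
    "rda_scan",
    "outflank_scan",
    "fsthet_scan",
    "consensus",
    "RFRankResult",
    "RFPurgeResult",
    "RDAResult",
    "FstHetResult",
    "OutlierReport",
]


# ------------------------------------------------------------- spatial PCoA


def spatial_covariates(gm: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """First `k` axes of a principal-coordinates analysis (classical MDS) of
    the inter-sample geographic distance matrix."""
    xy = gm.meta[["x", "y"]].to_numpy(dtype=float)
    if np.allclose(xy, xy[0]):
        raise AnalysisError("all samples share one coordinate; PCoA undefined")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    n = len(xy)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    axes = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    return pd.DataFrame(
        axes, index=gm.sample_ids, columns=[f"PCo{i + 1}" for i in range(k)]
    )


# ------------------------------------------------------------- RF helpers


def _impute_and_correct(
    gm: GenotypeMatrix, spatial_covs: pd.DataFrame | None, mode: str
) -> np.ndarray:
    """Genotypes as floats with per-locus mean imputation, optionally
    residualised on the spatial covariates."""
    X = gm.genotypes.astype(float)
    miss = gm.genotypes == MISSING
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(miss, col_mean[None, :], X)
    if spatial_covs is not None and mode == "residualise":
        Q = np.column_stack([np.ones(len(X)), spatial_covs.loc[gm.sample_ids].to_numpy()])
        X = X - Q @ np.linalg.lstsq(Q, X, rcond=None)[0]
    elif spatial_covs is not None and mode == "covariates":
        X = np.column_stack([X, spatial_covs.loc[gm.sample_ids].to_numpy()])
    return X


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> BaggingClassifier:
    base = DecisionTreeClassifier(max_features="sqrt", class_weight="balanced")
    bag = BaggingClassifier(
        estimator=base,
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    bag.fit(X, y)
    return bag


def _oob_error(bag: BaggingClassifier, X: np.ndarray, y: np.ndarray) -> float:
    """Majority-vote out-of-bag error rate."""
    n = len(y)
    votes = np.zeros((n, len(bag.classes_)))
    for tree, inbag in zip(bag.estimators_, bag.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[inbag] = False
        if not oob.any():
            continue
        pred = tree.predict(X[oob])
        votes[np.flatnonzero(oob), pred.astype(int)] += 1
    has = votes.sum(axis=1) > 0
    pred_class = bag.classes_[np.argmax(votes[has], axis=1)]
    return float(np.mean(pred_class != y[has]))


def _scaled_importance(
    bag: BaggingClassifier, X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    n_features: int,
) -> np.ndarray:
    """Scaled permutation importance: mean per-tree OOB accuracy decrease
    divided by its standard error over trees (the classic randomForest
    scale=TRUE convention). Features beyond `n_features` (appended
    covariates) are permuted but not reported."""
    n, p = X.shape
    X = np.ascontiguousarray(X, dtype=np.float32)
    deltas = np.zeros((len(bag.estimators_), p))
    used = np.zeros(len(bag.estimators_), dtype=bool)
    max_elems = 8_000_000
    for t, (tree, inbag) in enumerate(zip(bag.estimators_, bag.estimators_samples_)):
        oob = np.ones(n, dtype=bool)
        oob[inbag] = False
        idx = np.flatnonzero(oob)
        if len(idx) < 2:
            continue
        used[t] = True
        Xo, yo = X[idx], y[idx]
        m = len(idx)
        acc0 = float(np.mean(tree.predict(Xo) == yo))
        block = max(1, max_elems // (m * p))
        for start in range(0, p, block):
            feats = np.arange(start, min(start + block, p))
            nf = len(feats)
            rep = np.broadcast_to(Xo, (nf, m, p)).copy()
            perms = rng.permuted(
                np.broadcast_to(np.arange(m), (nf, m)).copy(), axis=1
            )
            rep[np.arange(nf)[:, None], np.arange(m)[None, :], feats[:, None]] = (
                Xo[perms, feats[:, None]]
            )
            pred = tree.predict(rep.reshape(-1, p)).reshape(nf, m)
            acc = (pred == yo[None, :]).mean(axis=1)
            deltas[t, feats] = acc0 - acc
    d = deltas[used][:, :n_features]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    se = sd / np.sqrt(used.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(se > 0, mean / se, 0.0)
    return scaled


@dataclass
class RFRankResult:
    importance: pd.Series  # mean scaled importance per locus, over runs
    ranked_loci: list[str]  # importance > threshold, descending
    run_correlations: list[float]
    mean_correlation: float
    oob_error: list[float]
    threshold: float


def rf_rank(
    gm: GenotypeMatrix,
    spatial_covs: pd.DataFrame | None = None,
    n_trees: int = 5000,
    n_runs: int = 3,
    threshold: float = 3.0,
    seed: int = 0,
    spatial_correction: str = "residualise",
) -> RFRankResult:
    """Rank loci by scaled RF permutation importance for the ecotope label.

    Runs `n_runs` independent forests; reports the per-run pairwise Pearson
    correlation of importances as a convergence check (warning below mean
    r = 0.5) and returns loci whose mean scaled importance exceeds
    `threshold`, ranked. The spatial correction residualises genotypes on the
    PCoA axes by default (alternatives: "covariates" appends them as extra
    predictors; "off").
    """
    eco = gm.meta["ecotope"].to_numpy()
    classes = np.unique(eco)
    if len(classes) < 2:
        raise AnalysisError("both ecotopes must be present")
    if gm.n_loci < 10:
        raise AnalysisError("need at least 10 loci for RF ranking")
    y = (eco == classes[-1]).astype(int)
    X = _impute_and_correct(gm, spatial_covs, spatial_correction)
    rng = substream(seed, "rf_rank")
    imps, oob = [], []
    for run in range(n_runs):
        bag = _fit_forest(X, y, n_trees, child_seed(seed, f"rf_run{run}"))
        imps.append(_scaled_importance(bag, X, y, rng, gm.n_loci))
        oob.append(_oob_error(bag, X, y))
    imps = np.asarray(imps)
    cors = []
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            cors.append(float(np.corrcoef(imps[i], imps[j])[0, 1]))
    mean_r = float(np.mean(cors)) if cors else 1.0
    if cors and mean_r < 0.5:
        warnings.warn(
            f"RF importance runs poorly converged (mean r={mean_r:.2f}); "
            "increase n_trees",
            stacklevel=2,
        )
    mean_imp = pd.Series(imps.mean(axis=0), index=gm.locus_ids)
    ranked = list(mean_imp[mean_imp > threshold].sort_values(ascending=False).index)
    return RFRankResult(mean_imp, ranked, cors, mean_r, oob, threshold)


@dataclass
class RFPurgeResult:
    trajectory: pd.DataFrame  # columns: n_loci, oob_error
    subsets: list[list[str]]
    best_subset: list[str]
    best_oob_error: float


def rf_backwards_purge(
    gm: GenotypeMatrix,
    ranked_loci: list[str],
    spatial_covs: pd.DataFrame | None = None,
    n_trees: int = 2000,
    seed: int = 0,
    spatial_correction: str = "residualise",
) -> RFPurgeResult:
    """Backwards purging: refit the forest on the ranked subset, drop the
    least-important locus, repeat until two remain; return the subset with
    the lowest OOB-ER (ties broken toward the smaller subset)."""
    if len(ranked_loci) < 3:
        raise AnalysisError("backwards purging needs at least 3 ranked loci")
    eco = gm.meta["ecotope"].to_numpy()
    classes = np.unique(eco)
    if len(classes) < 2:
        raise AnalysisError("both ecotopes must be present")
    y = (eco == classes[-1]).astype(int)
    locus_index = {l: i for i, l in enumerate(gm.locus_ids)}
    current = list(ranked_loci)
    rng = substream(seed, "rf_purge")
    records, subsets = [], []
    step = 0
    while len(current) >= 2:
        sub = gm.subset(loci=[locus_index[l] for l in current])
        X = _impute_and_correct(sub, spatial_covs, spatial_correction)
        bag = _fit_forest(X, y, n_trees, child_seed(seed, f"purge{step}"))
        err = _oob_error(bag, X, y)
        records.append({"n_loci": len(current), "oob_error": err})
        subsets.append(list(current))
        if len(current) == 2:
            break
        imp = _scaled_importance(bag, X, y, rng, len(current))
        current.pop(int(np.argmin(imp)))
        step += 1
    traj = pd.DataFrame(records)
    errs = traj["oob_error"].to_numpy()
    sizes = traj["n_loci"].to_numpy()
    # argmin with ties toward the smaller subset
    best = min(range(len(errs)), key=lambda i: (errs[i], sizes[i]))
    return RFPurgeResult(traj, subsets, subsets[best], float(errs[best]))


# ------------------------------------------------------------- RDA


@dataclass
class RDAResult:
    loadings: pd.Series
    z_loadings: pd.Series
    flags_2sd: pd.Series
    flags_3sd: pd.Series
    variance_explained: float
    pseudo_f: float
    p_axis: float
    sample_scores: pd.Series


def rda_scan(
    gm: GenotypeMatrix,
    spatial_covs: pd.DataFrame | None = None,
    sd_thresholds: tuple[float, float] = (2.0, 3.0),
    n_perm: int = 999,
    seed: int = 0,
) -> RDAResult:
    """Partial RDA of centred genotypes on the ecotope indicator, conditioned
    on spatial principal coordinates.

    With a single binary predictor the constrained ordination has one axis;
    per-locus loadings are the regression coefficients of the residualised
    genotypes on the residualised indicator, z-scored across loci and flagged
    at the +/-2 and +/-3 SD thresholds. Significance permutes the
    residualised predictor (999 permutations, pseudo-F statistic)."""
    eco = gm.meta["ecotope"].to_numpy()
    classes = np.unique(eco)
    if len(classes) < 2:
        raise AnalysisError("both ecotopes must be present")
    h = (eco == classes[-1]).astype(float)
    X = _impute_and_correct(gm, None, "off")
    X = X - X.mean(axis=0, keepdims=True)
    n = len(h)
    if spatial_covs is not None:
        Q = np.column_stack([np.ones(n), spatial_covs.loc[gm.sample_ids].to_numpy()])
    else:
        Q = np.ones((n, 1))
    proj = lambda M: M - Q @ np.linalg.lstsq(Q, M, rcond=None)[0]
    Gr = proj(X)
    hr = proj(h[:, None]).ravel()
    ss_h = float(hr @ hr)
    if ss_h < 1e-12:
        raise AnalysisError("ecotope is constant after conditioning on space")
    b = (hr @ Gr) / ss_h
    ss_fit = ss_h * float(b @ b)
    ss_tot = float((Gr**2).sum())
    q = Q.shape[1]
    df_resid = n - q - 1
    pseudo_f = (ss_fit / 1.0) / ((ss_tot - ss_fit) / df_resid)
    rng = substream(seed, "rda_perm")
    hits = 0
    for _ in range(n_perm):
        hp = hr[rng.permutation(n)]
        bp = (hp @ Gr) / float(hp @ hp)
        ssf = float(hp @ hp) * float(bp @ bp)
        fp = ssf / ((ss_tot - ssf) / df_resid)
        hits += int(fp >= pseudo_f - 1e-15)
    z = (b - b.mean()) / b.std(ddof=0)
    lo, hi = sd_thresholds
    loadings = pd.Series(b, index=gm.locus_ids)
    zs = pd.Series(z, index=gm.locus_ids)
    return RDAResult(
        loadings=loadings,
        z_loadings=zs,
        flags_2sd=zs.abs() > lo,
        flags_3sd=zs.abs() > hi,
        variance_explained=ss_fit / ss_tot,
        pseudo_f=float(pseudo_f),
        p_axis=(hits + 1) / (n_perm + 1),
        sample_scores=pd.Series(hr, index=gm.sample_ids),
    )


# ------------------------------------------------------------- F_ST-het


@dataclass
class FstHetResult:
    table: pd.DataFrame  # locus, fst, het, (p, q | envelope), flag
    flags: pd.Series
    extras: dict = field(default_factory=dict)


def _per_locus_fst_het(gm: GenotypeMatrix, grouping: str) -> pd.DataFrame:
    """Uncorrected per-locus F_ST (weighted variance of group allele
    frequencies over pbar qbar) and pooled expected heterozygosity."""
    groups = gm.groups(grouping)
    ps, ws = [], []
    for lab, rows in groups.items():
        n_called, alt = gm.allele_stats(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps.append(np.where(n_called > 0, alt / (2.0 * n_called), np.nan))
        ws.append(2.0 * n_called)
    P = np.asarray(ps)  # groups x loci
    W = np.asarray(ws, dtype=float)
    W = np.where(np.isnan(P), 0.0, W)
    P0 = np.where(np.isnan(P), 0.0, P)
    wsum = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (W * P0).sum(axis=0) / wsum
        var_p = (W * (P0 - pbar[None, :]) ** 2).sum(axis=0) / wsum
        het = 2.0 * pbar * (1.0 - pbar)
        fst = np.where(het > 0, var_p / (pbar * (1.0 - pbar)), np.nan)
    return pd.DataFrame({"fst": fst, "het": het}, index=gm.locus_ids)


def outflank_scan(
    gm: GenotypeMatrix,
    grouping: str = "ecotope",
    trim_low: float = 0.06,
    trim_high: float = 0.35,
    he_min: float = 0.1,
    q_cut: float = 0.05,
) -> FstHetResult:
    """OutFlank-style scan: trimmed-likelihood scaled chi-square null.

    The lowest `trim_low` and highest `trim_high` fractions of per-locus
    uncorrected F_ST values are trimmed; a scaled chi-square (degrees of
    freedom and mean) is fitted by maximum likelihood to the retained,
    truncated distribution (Brent search on df in (1, 200), mean profiled);
    every locus with pooled heterozygosity >= `he_min` gets a right-tail p
    and a BH q; flags at q < `q_cut`. Low-heterozygosity loci are never
    flagged."""
    tab = _per_locus_fst_het(gm, grouping)
    usable = tab.dropna()
    if len(usable) < 50:
        warnings.warn(f"only {len(usable)} usable loci; null fit may be unstable",
                      stacklevel=2)
    fit_vals = usable.loc[usable["het"] >= he_min, "fst"].to_numpy()
    fit_vals = fit_vals[fit_vals > 0]
    if len(fit_vals) < 10:
        raise AnalysisError("too few positive F_ST values to fit a null")
    lo_q = np.quantile(fit_vals, trim_low)
    hi_q = np.quantile(fit_vals, 1.0 - trim_high)
    kept = fit_vals[(fit_vals >= lo_q) & (fit_vals <= hi_q)]

    def negll_df(df: float) -> tuple[float, float]:
        def negll_mean(log_mean: float) -> float:
            scale = np.exp(log_mean) / df
            logpdf = chi2.logpdf(kept / scale, df) - np.log(scale)
            trunc = chi2.cdf(hi_q / scale, df) - chi2.cdf(lo_q / scale, df)
            if trunc <= 0:
                return 1e12
            return float(-(logpdf - np.log(trunc)).sum())

        res = minimize_scalar(
            negll_mean,
            bounds=(np.log(kept.mean()) - 3, np.log(kept.mean()) + 3),
            method="bounded",
        )
        return float(res.fun), float(np.exp(res.x))

    res_df = minimize_scalar(lambda d: negll_df(d)[0], bounds=(1.0, 200.0), method="bounded")
    if not res_df.success:
        raise AnalysisError("trimmed chi-square null fit failed to converge")
    df_hat = float(res_df.x)
    _, mean_hat = negll_df(df_hat)
    scale = mean_hat / df_hat

    fst = tab["fst"].to_numpy()
    het = tab["het"].to_numpy()
    eligible = np.isfinite(fst) & (het >= he_min)
    p = np.full(len(tab), np.nan)
    p[eligible] = chi2.sf(fst[eligible] / scale, df_hat)
    q = np.full(len(tab), np.nan)
    if eligible.any():
        q[eligible] = multipletests(p[eligible], method="fdr_bh")[1]
    flags = pd.Series(np.where(eligible, q < q_cut, False).astype(bool), index=tab.index)
    out = tab.copy()
    out["p"] = p
    out["q"] = q
    out["flag"] = flags
    return FstHetResult(
        out, flags, extras={"df": df_hat, "mean_fst": mean_hat, "n_trimmed_fit": len(kept)}
    )


def fsthet_scan(
    gm: GenotypeMatrix,
    grouping: str = "ecotope",
    alpha: float = 0.05,
    n_bins: int = 10,
    smooth: int = 3,
) -> FstHetResult:
    """fsthet-style scan: smoothed empirical quantile envelope.

    Loci are binned by heterozygosity into `n_bins` equal-count bins; per-bin
    alpha/2 and 1-alpha/2 F_ST quantiles are smoothed by a `smooth`-bin
    moving average and interpolated at each locus's heterozygosity; loci
    outside the envelope are flagged. Distribution-free."""
    tab = _per_locus_fst_het(gm, grouping)
    usable = tab.dropna().sort_values("het")
    n = len(usable)
    if n < 2 * n_bins:
        n_bins = max(2, n // 4)
        warnings.warn(f"few loci; widened to {n_bins} bins", stacklevel=2)
    edges = np.array_split(np.arange(n), n_bins)
    centers, lows, highs = [], [], []
    for idx in edges:
        h = usable["het"].to_numpy()[idx]
        f = usable["fst"].to_numpy()[idx]
        centers.append(h.mean())
        lows.append(np.quantile(f, alpha / 2.0))
        highs.append(np.quantile(f, 1.0 - alpha / 2.0))

    def movavg(v):
        v = np.asarray(v, dtype=float)
        k = min(smooth, len(v))
        kernel = np.ones(k) / k
        pad = k // 2
        vp = np.pad(v, pad, mode="edge")
        out = np.convolve(vp, kernel, mode="valid")
        return out[: len(v)]

    low_s, high_s = movavg(lows), movavg(highs)
    high_s = np.maximum(high_s, low_s)  # envelope never crosses
    lo_i = np.interp(tab["het"], centers, low_s)
    hi_i = np.interp(tab["het"], centers, high_s)
    fst = tab["fst"].to_numpy()
    flags = pd.Series(
        np.isfinite(fst) & ((fst > hi_i) | (fst < lo_i)), index=tab.index
    )
    out = tab.copy()
    out["env_low"] = lo_i
    out["env_high"] = hi_i
    out["flag"] = flags
    return FstHetResult(out, flags, extras={"alpha": alpha, "n_bins": n_bins})


# ------------------------------------------------------------- consensus


@dataclass
class OutlierReport:
    per_locus: pd.DataFrame  # bool flags per method + consensus_count
    method_sets: dict[str, set[str]]
    at_least: dict[int, set[str]]
    all_methods: set[str]


def consensus(flags: dict[str, pd.Series]) -> OutlierReport:
    """Combine per-method boolean flag Series over a common locus universe."""
    methods = list(flags)
    universe = None
    for m in methods:
        idx = set(flags[m].index)
        if universe is None:
            universe = idx
        elif idx != universe:
            raise AnalysisError("outlier reports cover different locus sets")
    df = pd.DataFrame({m: flags[m].astype(bool) for m in methods})
    df["consensus_count"] = df[methods].sum(axis=1)
    sets = {m: set(df.index[df[m]]) for m in methods}
    at_least = {
        k: set(df.index[df["consensus_count"] >= k]) for k in range(1, len(methods) + 1)
    }
    return OutlierReport(df, sets, at_least, at_least[len(methods)])
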