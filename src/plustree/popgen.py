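"""Population-genetic characterization: diversity, LD, kinship, PCA, ancestry.

Expected/observed heterozygosity, pairwise linkage disequilibrium (r^2) with
an EM maximum-likelihood haplotype-frequency estimator for unphased diploid
data, map-distance LD decay profiles, a VanRaden realized relationship
matrix, genotype PCA, ancestry estimation by simplex-constrained matrix
factorization with a masked cross-entropy criterion for choosing the number
of clusters, and the per-genotype effective number of clusters N_Q (inverse
Simpson index of the admixture row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .io import GeneticMap, GenotypeMatrix

__all__ = [
    "DiversityStats",
    "LDResult",
    "AncestryResult",
    "heterozygosities",
    "ld_r2",
    "ld_profiles",
    "kinship",
    "pca",
    "PCAResult",
    "estimate_ancestry",
    "effective_clusters",
    "genomic_inflation",
]


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    per_snp: pd.DataFrame     # columns: population, snp_id, He, Ho, n
    summary: pd.DataFrame     # columns: population, He, Ho, n


def heterozygosities(
    gm: GenotypeMatrix,
    by_population: bool = True,
    bias_corrected: bool = True,
) -> DiversityStats:
    """Per-SNP and population-averaged expected / observed heterozygosity.

    H_E = 2 p (1 - p), by default with the small-sample correction n/(n-1)
    (n = number of genotypes with a call); H_O = fraction of heterozygous
    (score 0) calls.
    """
    if by_population and gm.populations is not None:
        groups = gm.by_population()
    else:
        groups = {"all": gm}
    per_snp_rows, summary_rows = [], []
    for pop, sub in groups.items():
        if sub.n_genotypes < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 genotypes")
        X = sub.scores
        n_obs = (~np.isnan(X)).sum(axis=0).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(X + 1.0, axis=0) / 2.0
            n_het = np.nansum(np.where(np.isnan(X), np.nan, X == 0), axis=0)
            ho = np.where(n_obs > 0, n_het / n_obs, np.nan)
        he = 2.0 * p * (1.0 - p)
        if bias_corrected:
            with np.errstate(divide="ignore", invalid="ignore"):
                he = he * np.where(n_obs > 1, n_obs / (n_obs - 1.0), np.nan)
        per_snp_rows.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "snp_id": sub.snp_ids,
                    "He": he,
                    "Ho": ho,
                    "n": n_obs.astype(int),
                }
            )
        )
        summary_rows.append(
            {
                "population": pop,
                "He": float(np.nanmean(he)),
                "Ho": float(np.nanmean(ho)),
                "n": sub.n_genotypes,
            }
        )
    return DiversityStats(
        per_snp=pd.concat(per_snp_rows, ignore_index=True),
        summary=pd.DataFrame(summary_rows),
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@njit(cache=True)
def _em_r2_from_counts(n33: np.ndarray, max_iter: int, tol: float) -> float:
    """EM haplotype-frequency r^2 for two biallelic loci from the 3x3 table of
    unphased genotype counts (rows/cols = copies of the A/B allele: 0, 1, 2).
    Returns -1.0 when either locus is monomorphic."""
    n = n33.sum()
    if n == 0:
        return -1.0
    nA = 0.0
    nB = 0.0
    for i in range(3):
        for j in range(3):
            nA += i * n33[i, j]
            nB += j * n33[i, j]
    pA = nA / (2.0 * n)
    pB = nB / (2.0 * n)
    if pA <= 0.0 or pA >= 1.0 or pB <= 0.0 or pB >= 1.0:
        return -1.0
    # haplotype freqs: f[0]=AB, f[1]=Ab, f[2]=aB, f[3]=ab (A = allele coded 1)
    f = np.empty(4)
    f[0] = pA * pB
    f[1] = pA * (1.0 - pB)
    f[2] = (1.0 - pA) * pB
    f[3] = (1.0 - pA) * (1.0 - pB)
    for _ in range(max_iter):
        # expected haplotype counts; only the double heterozygote is ambiguous
        c = np.zeros(4)
        for i in range(3):
            for j in range(3):
                cnt = n33[i, j]
                if cnt == 0:
                    continue
                if i == 1 and j == 1:
                    cis = f[0] * f[3]
                    trans = f[1] * f[2]
                    tot = cis + trans
                    w = 0.5 if tot <= 0 else cis / tot
                    c[0] += cnt * w
                    c[3] += cnt * w
                    c[1] += cnt * (1.0 - w)
                    c[2] += cnt * (1.0 - w)
                else:
                    # haplotypes are determined: i copies of A split over two
                    # haplotypes; for i or j != 1 at most one phase possible
                    # put the single copy at a heterozygous locus on
                    # haplotype 1; phase is unambiguous outside the double het
                    a1 = 1 if i >= 1 else 0
                    a2 = 1 if i == 2 else 0
                    b1 = 1 if j >= 1 else 0
                    b2 = 1 if j == 2 else 0
                    # haplotype index: 0=AB, 1=Ab, 2=aB, 3=ab
                    idx1 = (0 if a1 == 1 else 2) + (0 if b1 == 1 else 1)
                    idx2 = (0 if a2 == 1 else 2) + (0 if b2 == 1 else 1)
                    c[idx1] += cnt
                    c[idx2] += cnt
        newf = c / (2.0 * n)
        diff = 0.0
        for k in range(4):
            d = abs(newf[k] - f[k])
            if d > diff:
                diff = d
            f[k] = newf[k]
        if diff < tol:
            break
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    denom = pA * (1.0 - pA) * pB * (1.0 - pB)
    if denom <= 0.0:
        return -1.0
    r2 = D * D / denom
    if r2 > 1.0:
        r2 = 1.0
    return r2


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    ok = ~(np.isnan(a) | np.isnan(b))
    ai = (a[ok] + 1).astype(np.int64)
    bi = (b[ok] + 1).astype(np.int64)
    n33 = np.zeros((3, 3), dtype=np.int64)
    np.add.at(n33, (ai, bi), 1)
    return n33, int(ok.sum())


def ld_r2(
    snp_a: np.ndarray,
    snp_b: np.ndarray,
    estimator: str = "em",
    min_pairs: int = 10,
) -> tuple[float, float]:
    """Pairwise LD between two score vectors.

    Default estimator: EM maximum-likelihood haplotype frequencies for
    unphased diploids under random mating, r^2 = D^2 / (p_A p_a p_B p_b),
    with significance from the chi-square statistic n_hap * r^2 (1 df,
    n_hap = 2 x complete genotype pairs).  ``estimator="composite"`` uses the
    squared Pearson correlation of the genotype scores instead.

    Returns (r2, p_value); (nan, nan) when either locus is monomorphic.
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    n = int(ok.sum())
    if n < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {n}")
    if estimator == "em":
        n33, n = _pair_counts(a, b)
        r2 = _em_r2_from_counts(n33, 200, 1e-10)
        if r2 < 0:
            return float("nan"), float("nan")
        chi2 = 2.0 * n * r2
    elif estimator == "composite":
        av, bv = a[ok], b[ok]
        if av.std() == 0 or bv.std() == 0:
            return float("nan"), float("nan")
        r = np.corrcoef(av, bv)[0, 1]
        r2 = float(r * r)
        chi2 = n * r2
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    p = float(stats.chi2.sf(chi2, df=1))
    return float(r2), p


@dataclass
class LDResult:
    pairs: pd.DataFrame      # population, snp_a, snp_b, distance, r2, p
    summary: pd.DataFrame    # population, n_pairs, mean_r2, pct_significant
    decay: pd.DataFrame      # population, bin_left, bin_right, mean_r2, n_pairs


def ld_profiles(
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    mode: str = "within_LG",
    by_population: bool = True,
    estimator: str = "em",
    bin_width: float | None = None,
    sig_level: float = 0.01,
    max_pairs_per_group: int | None = None,
    seed: int = 0,
    min_pairs: int = 10,
) -> LDResult:
    """All within-linkage-group (or within-isotig) LD pairs per population.

    Reports the pair table, per-population mean r^2 and the percentage of
    pairs significant at ``sig_level``, plus a binned distance-decay curve
    (default bin width 1 cM for map mode, 500 bp for isotig mode).
    ``max_pairs_per_group`` subsamples pairs within each LG/isotig for large
    inputs.
    """
    t = gmap.table
    if mode == "within_LG":
        sub = t[t["cM"].notna()]
        group_col, dist_col = "linkage_group", "cM"
        bin_width = 1.0 if bin_width is None else bin_width
    elif mode == "within_isotig":
        if not gmap.has_isotigs:
            raise ValueError("map has no isotig placements")
        sub = t[t["isotig"].notna()]
        group_col, dist_col = "isotig", "bp"
        bin_width = 500.0 if bin_width is None else bin_width
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sub = sub[sub.index.isin(gm.snp_ids)]
    rng = np.random.default_rng(seed)
    pair_list: list[tuple[str, str, float]] = []
    for _, grp in sub.groupby(group_col, observed=True):
        ids = grp.index.to_numpy(object)
        d = grp[dist_col].to_numpy(float)
        k = len(ids)
        if k < 2:
            continue
        iu, ju = np.triu_indices(k, 1)
        if max_pairs_per_group is not None and iu.size > max_pairs_per_group:
            pick = rng.choice(iu.size, size=max_pairs_per_group, replace=False)
            iu, ju = iu[pick], ju[pick]
        for a, b in zip(iu, ju):
            pair_list.append((ids[a], ids[b], abs(d[a] - d[b])))
    if not pair_list:
        empty = pd.DataFrame(
            columns=["population", "snp_a", "snp_b", "distance", "r2", "p"]
        )
        return LDResult(
            pairs=empty,
            summary=pd.DataFrame(columns=["population", "n_pairs", "mean_r2", "pct_significant"]),
            decay=pd.DataFrame(columns=["population", "bin_left", "bin_right", "mean_r2", "n_pairs"]),
        )

    groups = gm.by_population() if (by_population and gm.populations is not None) else {"all": gm}
    col_of = {s: i for i, s in enumerate(gm.snp_ids)}
    rows, summary_rows, decay_rows = [], [], []
    for pop, sub_gm in groups.items():
        X = sub_gm.scores
        r2s = np.empty(len(pair_list))
        ps = np.empty(len(pair_list))
        for idx, (sa, sb, dist) in enumerate(pair_list):
            a, b = X[:, col_of[sa]], X[:, col_of[sb]]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < min_pairs:
                r2s[idx], ps[idx] = np.nan, np.nan
                continue
            try:
                r2s[idx], ps[idx] = ld_r2(a, b, estimator=estimator, min_pairs=min_pairs)
            except ValueError:
                r2s[idx], ps[idx] = np.nan, np.nan
        dists = np.array([p[2] for p in pair_list])
        df = pd.DataFrame(
            {
                "population": pop,
                "snp_a": [p[0] for p in pair_list],
                "snp_b": [p[1] for p in pair_list],
                "distance": dists,
                "r2": r2s,
                "p": ps,
            }
        )
        rows.append(df)
        valid = df["r2"].notna()
        summary_rows.append(
            {
                "population": pop,
                "n_pairs": int(valid.sum()),
                "mean_r2": float(df.loc[valid, "r2"].mean()) if valid.any() else np.nan,
                "pct_significant": float(100.0 * (df.loc[valid, "p"] < sig_level).mean())
                if valid.any()
                else np.nan,
            }
        )
        if valid.any():
            bins = np.arange(0.0, dists.max() + bin_width, bin_width)
            which = np.digitize(dists, bins) - 1
            for b_i in np.unique(which[valid]):
                sel = valid & (which == b_i)
                decay_rows.append(
                    {
                        "population": pop,
                        "bin_left": bins[b_i],
                        "bin_right": bins[b_i] + bin_width,
                        "mean_r2": float(df.loc[sel, "r2"].mean()),
                        "n_pairs": int(sel.sum()),
                    }
                )
    return LDResult(
        pairs=pd.concat(rows, ignore_index=True),
        summary=pd.DataFrame(summary_rows),
        decay=pd.DataFrame(decay_rows),
    )


# ---------------------------------------------------------------------------
# kinship and PCA
# ---------------------------------------------------------------------------

def kinship(scores: np.ndarray) -> np.ndarray:
    """VanRaden realized additive relationship matrix from a complete
    genotype score matrix on the -1/0/1 scale:
    K = W W' / (2 sum p(1-p)) with W the column-centered scores."""
    X = np.asarray(scores, dtype=float)
    if np.isnan(X).any():
        raise ValueError("kinship requires a complete (imputed) matrix")
    p = X.mean(axis=0) / 2.0 + 0.5
    W = X - (2.0 * p - 1.0)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    return W @ W.T / denom


@dataclass
class PCAResult:
    scores: np.ndarray                 # genotypes x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray               # components x SNPs


def pca(scores: np.ndarray, n_components: int | None = None, scale: bool = False) -> PCAResult:
    """PCA of the column-centered (optionally unit-scaled) genotype matrix.

    Sign convention: within each component the loading of largest magnitude
    is made positive.
    """
    X = np.asarray(scores, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genotypes")
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :Vt.shape[0]]
    var = s**2
    total = (Xc**2).sum()
    return PCAResult(
        scores=U * s,
        explained_variance_ratio=var / total,
        loadings=Vt,
    )


# ---------------------------------------------------------------------------
# ancestry estimation
# ---------------------------------------------------------------------------

@dataclass
class AncestryResult:
    K: int
    Q: np.ndarray              # genotypes x K, rows on the simplex
    G: np.ndarray              # K x SNPs ancestral allele-frequency parameters
    cross_entropy: float       # masked-prediction score (lower is better)
    N_Q: np.ndarray            # per-genotype effective cluster number


def _simplex_nnls_rows(GGt: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Solve min ||f_i - q G||^2 per row subject to q >= 0, then normalize to
    the simplex.  GGt = G G' (K x K); C rows are G f_i' (n x K)."""
    from scipy.optimize import nnls

    K = GGt.shape[0]
    # Cholesky of GGt for the least-squares reformulation
    R = np.linalg.cholesky(GGt + 1e-10 * np.eye(K)).T
    Q = np.empty_like(C)
    Rinv_T = np.linalg.inv(R).T
    for i in range(C.shape[0]):
        b = Rinv_T @ C[i]
        q, _ = nnls(R, b)
        s = q.sum()
        Q[i] = q / s if s > 0 else np.full(K, 1.0 / K)
    return Q


def _fit_factorization(
    F: np.ndarray,
    obs: np.ndarray,
    K: int,
    rng: np.random.Generator,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating projected least squares for F ~ Q G with simplex rows of Q
    and G entries in [0, 1].  Missing entries of F are refilled with the
    current model prediction each sweep."""
    n, m = F.shape
    col_mean = np.where(obs, F, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    Fw = np.where(obs, F, col_mean)
    Q = rng.dirichlet(np.ones(K), size=n)
    G = np.clip(col_mean + 0.1 * rng.standard_normal((K, m)), 0.02, 0.98)
    for _ in range(n_iter):
        # G update: ridge-stabilised least squares, clipped to [0, 1]
        QtQ = Q.T @ Q + 1e-8 * np.eye(K)
        G = np.clip(np.linalg.solve(QtQ, Q.T @ Fw), 0.0, 1.0)
        # Q update: per-row NNLS + simplex normalization
        GGt = G @ G.T
        C = Fw @ G.T
        Q = _simplex_nnls_rows(GGt, C)
        if not obs.all():
            pred = Q @ G
            Fw = np.where(obs, F, pred)
    return Q, G


def _masked_cross_entropy(
    F: np.ndarray, counts: np.ndarray, mask: np.ndarray, Q: np.ndarray, G: np.ndarray
) -> float:
    """Mean negative binomial log-likelihood per masked allele call, scoring
    the masked genotype counts (0/1/2 copies) under allele probability QG."""
    eps = 1e-6
    P = np.clip(Q @ G, eps, 1.0 - eps)
    x = counts[mask]
    p = P[mask]
    ll = x * np.log(p) + (2.0 - x) * np.log(1.0 - p)
    return float(-ll.mean() / 2.0)


def estimate_ancestry(
    gm: GenotypeMatrix | np.ndarray,
    K: int,
    n_runs: int = 3,
    mask_fraction: float = 0.05,
    seed: int = 0,
    n_iter: int = 60,
) -> AncestryResult:
    """Admixture estimation by simplex-constrained matrix factorization.

    Scores are rescaled to allele dosages in [0, 1] and factorized as
    F ~ Q G with Q rows on the simplex (admixture proportions) and G in
    [0, 1] (ancestral allele frequencies).  Model fit is scored by masking a
    random subset of observed entries, fitting on the remainder and computing
    the cross-entropy (negative binomial log-likelihood) of the masked calls;
    the best of ``n_runs`` random restarts is returned.  N_Q is the inverse
    Simpson index of each Q row.
    """
    X = gm.scores if isinstance(gm, GenotypeMatrix) else np.asarray(gm, float)
    n, m = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} genotypes")
    if not (0.0 < mask_fraction < 0.5):
        raise ValueError("mask_fraction must lie in (0, 0.5)")
    obs = ~np.isnan(X)
    counts = np.where(obs, X + 1.0, 0.0)  # allele dosage 0/1/2
    F = counts / 2.0

    rng_master = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_runs)):
        rng = np.random.default_rng(rng_master.integers(2**31))
        mask = obs & (rng.random(X.shape) < mask_fraction)
        fit_obs = obs & ~mask
        if K == 1:
            Q = np.ones((n, 1))
            col_mean = np.where(fit_obs, F, 0.0).sum(axis=0) / np.maximum(
                fit_obs.sum(axis=0), 1
            )
            G = col_mean[None, :]
        else:
            Q, G = _fit_factorization(F, fit_obs, K, rng, n_iter=n_iter)
        ce = _masked_cross_entropy(F, counts, mask, Q, G)
        if best is None or ce < best[0]:
            best = (ce, Q, G)
    ce, Q, G = best
    nq = np.array([effective_clusters(q, K) for q in Q])
    return AncestryResult(K=K, Q=Q, G=G, cross_entropy=ce, N_Q=nq)


def effective_clusters(q_row: np.ndarray, K: int | None = None, tol: float = 1e-6) -> float:
    """Effective number of ancestral clusters for one genotype.

    Inverse Simpson index of the admixture proportion row:
    N_Q = 1 / sum_i Q_i^2.  Equals 1 for a one-hot row, K for the uniform
    row, and never decreases when probability mass moves from a larger to a
    smaller component (Schur-concavity) -- i.e., stronger admixture gives a
    higher value.
    """
    q = np.asarray(q_row, dtype=float)
    if K is None:
        K = q.size
    if abs(q.sum() - 1.0) > tol:
        raise ValueError(f"Q row sums to {q.sum():.6f}, not 1")
    if (q < -tol).any():
        raise ValueError("Q row has negative entries")
    nq = 1.0 / float(np.sum(q**2))
    return float(min(max(nq, 1.0), K))


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor lambda: median association chi-square over
    the null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
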