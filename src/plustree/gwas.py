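"""Mixed-model single-marker association with kinship and PC covariates.

Per-population GWAS on clonal values: the trait is regressed on each marker
with a polygenic random effect whose covariance is the realized relationship
matrix, plus optional genotype-PC fixed covariates.  Variance components are
estimated once on the marker-free null model (the P3D/EMMAX approximation)
through a spectral decomposition of the kinship matrix; every marker is then
tested on the rotated generalized-least-squares scale.  Downstream utilities
cover Benjamini-Hochberg q-values, LD-based placement of unmapped hits
(assign the position of the most correlated mapped SNP when r^2 > 0.6) and
detection of genome regions significant across populations within a
centimorgan window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GeneticMap, GenotypeMatrix
from .popgen import ld_r2, pca

__all__ = [
    "GWASResult",
    "CommonRegion",
    "mixed_model_scan",
    "bh_qvalues",
    "place_unmapped",
    "find_common_regions",
]

#: floor applied to p-values before taking -log10
P_FLOOR = 1e-300


@dataclass
class GWASResult:
    table: pd.DataFrame          # snp_id-indexed: effect, p, minus_log10_p, q, flags
    delta: float                 # null-model variance ratio sigma_e^2 / sigma_g^2
    heritability_null: float     # sigma_g^2 / (sigma_g^2 + sigma_e^2)
    n_pc: int


def _null_delta(yt: np.ndarray, Wt: np.ndarray, S: np.ndarray) -> float:
    """REML estimate of delta = sigma_e^2/sigma_g^2 on the marker-free model,
    on the eigenbasis of K (S = eigenvalues)."""
    n, p = Wt.shape

    def neg_restricted(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = S + delta
        Ww = Wt / w[:, None]
        A = Wt.T @ Ww
        b = Ww.T @ yt
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return 1e12
        r = yt - Wt @ beta
        rss = float(r @ (r / w))
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        return (
            (n - p) * np.log(rss)
            + np.sum(np.log(w))
            + logdetA
        )

    grid = np.linspace(-10.0, 10.0, 41)
    vals = [neg_restricted(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        neg_restricted, bounds=(g0 - 1.0, g0 + 1.0), method="bounded"
    )
    return float(np.exp(res.x))


def mixed_model_scan(
    scores: np.ndarray,
    trait: np.ndarray | pd.Series,
    K: np.ndarray,
    n_pc: int = 0,
    snp_ids: np.ndarray | None = None,
    fdr_level: float = 0.1,
    logp_threshold: float = 3.0,
) -> GWASResult:
    """Single-marker mixed-model scan with P3D variance components.

    Parameters
    ----------
    scores : complete (imputed) genotype matrix, genotypes x SNPs
    trait : clonal values aligned with the matrix rows
    K : realized relationship matrix over the same genotypes
    n_pc : number of genotype principal components used as fixed covariates

    The marker test is a two-sided t test of the marker coefficient in the
    rotated (GLS) regression; markers collinear with the covariates are
    flagged untestable (NaN p).
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(trait, dtype=float)
    n, m = X.shape
    if y.shape != (n,) or K.shape != (n, n):
        raise ValueError("trait / kinship dimensions do not match genotypes")
    if n_pc < 0:
        raise ValueError("n_pc must be >= 0")
    if snp_ids is None:
        snp_ids = np.array([f"SNP{j}" for j in range(m)], dtype=object)

    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    W = np.ones((n, 1))
    if n_pc > 0:
        W = np.column_stack([W, pca(X, n_components=n_pc).scores])
    yt = U.T @ y
    Wt = U.T @ W
    Xt = U.T @ X

    delta = _null_delta(yt, Wt, S)
    w = S + delta
    sw = np.sqrt(w)
    A = Wt / sw[:, None]
    yv = yt / sw
    Xv = Xt / sw[:, None]

    # residualize trait and markers on the covariates (GLS scale)
    Qc, _ = np.linalg.qr(A)
    ey = yv - Qc @ (Qc.T @ yv)
    EX = Xv - Qc @ (Qc.T @ Xv)
    xx = np.einsum("ij,ij->j", EX, EX)
    xy = EX.T @ ey
    dof = n - W.shape[1] - 1
    testable = xx > 1e-10 * n
    beta = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    beta[testable] = xy[testable] / xx[testable]
    rss = float(ey @ ey) - beta[testable] ** 2 * xx[testable]
    sigma2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / xx[testable])
        tstat[testable] = beta[testable] / se
    p = np.full(m, np.nan)
    p[testable] = 2.0 * stats.t.sf(np.abs(tstat[testable]), df=dof)
    q = np.full(m, np.nan)
    q[testable] = bh_qvalues(p[testable])
    mlog = -np.log10(np.clip(p, P_FLOOR, 1.0))

    h2 = 1.0 / (1.0 + delta)
    table = pd.DataFrame(
        {
            "effect": beta,
            "p": p,
            "minus_log10_p": mlog,
            "q_value": q,
            "sig_fdr": q < fdr_level,
            "sig_logp": mlog > logp_threshold,
            "testable": testable,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GWASResult(table=table, delta=delta, heritability_null=h2, n_pc=n_pc)


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with enforced
    monotonicity: q_(i) = min_{j >= i} (m p_(j) / j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class Placement:
    placed: bool
    linkage_group: int | None = None
    cM: float | None = None
    paired_snp: str | None = None
    r2: float | None = None


def place_unmapped(
    snp_id: str,
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    r2_threshold: float = 0.6,
    estimator: str = "em",
    min_pairs: int = 10,
) -> Placement:
    """Assign an unmapped SNP the map position of its highest-r^2 mapped
    partner when that r^2 exceeds the threshold; otherwise leave unplaced.

    Ties at the maximum r^2 break to the smallest cM, then lexicographic
    SNP id, for determinism.
    """
    if gmap.is_mapped(snp_id):
        raise ValueError(f"{snp_id} is already mapped")
    mapped = [s for s in gmap.mapped_ids if s in set(gm.snp_ids)]
    if not mapped:
        raise ValueError("no mapped SNPs available")
    a = gm.scores[:, gm.snp_index(snp_id)]
    best: tuple[float, float, str, int] | None = None  # (-r2, cM, id, lg)
    for sid in mapped:
        b = gm.scores[:, gm.snp_index(sid)]
        try:
            r2, _ = ld_r2(a, b, estimator=estimator, min_pairs=min_pairs)
        except ValueError:
            continue
        if np.isnan(r2):
            continue
        lg, cm = gmap.position(sid)
        key = (-r2, cm, str(sid), lg)
        if best is None or key < best:
            best = key
    if best is None or -best[0] <= r2_threshold:
        return Placement(placed=False)
    return Placement(
        placed=True,
        linkage_group=best[3],
        cM=best[1],
        paired_snp=best[2],
        r2=-best[0],
    )


@dataclass
class CommonRegion:
    linkage_group: int
    cM_min: float
    cM_max: float
    members: pd.DataFrame     # population, snp_id, cM, minus_log10_p

    @property
    def span(self) -> float:
        return self.cM_max - self.cM_min


def find_common_regions(
    results: dict[str, pd.DataFrame],
    window_cM: float = 10.0,
    min_populations: int | None = None,
    logp_threshold: float = 3.0,
) -> list[CommonRegion]:
    """Cross-population significant regions.

    ``results`` maps population name to a table with columns
    ``linkage_group``, ``cM`` and ``minus_log10_p`` (placed SNPs only; rows
    with missing positions are ignored).  A region is a maximal group of
    significant SNPs on one linkage group whose cM span is < ``window_cM``
    and that includes at least one SNP from every required population
    (default: all populations supplied).
    """
    if len(results) < 2:
        raise ValueError("need results from >= 2 populations")
    need = len(results) if min_populations is None else min_populations
    rows = []
    for pop, df in results.items():
        sig = df[
            (df["minus_log10_p"] > logp_threshold)
            & df["cM"].notna()
            & df["linkage_group"].notna()
        ]
        for sid, r in sig.iterrows():
            rows.append(
                {
                    "population": pop,
                    "snp_id": sid,
                    "linkage_group": int(r["linkage_group"]),
                    "cM": float(r["cM"]),
                    "minus_log10_p": float(r["minus_log10_p"]),
                }
            )
    if not rows:
        return []
    hits = pd.DataFrame(rows).sort_values(["linkage_group", "cM", "snp_id"])
    regions: list[CommonRegion] = []
    for lg, grp in hits.groupby("linkage_group"):
        grp = grp.reset_index(drop=True)
        cm = grp["cM"].to_numpy()
        k = len(grp)
        prev_j = -1
        for i in range(k):
            j = i
            while j + 1 < k and cm[j + 1] - cm[i] < window_cM:
                j += 1
            if j <= prev_j:   # contained in the previous maximal window
                continue
            prev_j = j
            members = grp.iloc[i : j + 1]
            if members["population"].nunique() >= need:
                regions.append(
                    CommonRegion(
                        linkage_group=int(lg),
                        cM_min=float(members["cM"].min()),
                        cM_max=float(members["cM"].max()),
                        members=members[
                            ["population", "snp_id", "cM", "minus_log10_p"]
                        ].reset_index(drop=True),
                    )
                )
    # drop regions whose member set is a subset of another region's
    keep = []
    sets = [set(r.members["snp_id"]) for r in regions]
    for idx, r in enumerate(regions):
        if any(
            idx != other and sets[idx] < sets[other] for other in range(len(regions))
        ):
            continue
        keep.append(r)
    keep.sort(key=lambda r: (r.linkage_group, r.cM_min))
    return keep
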