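"""Genotype containers, tabular/VCF I/O, SNP quality control and imputation.

Genotypes are held as a dense genotypes x SNPs matrix of scores in {-1, 0, 1}
(minor/major homozygote coded -1/1, heterozygote 0) with NaN marking missing
calls.  The genetic map places SNPs on linkage groups at centimorgan positions;
SNPs may additionally carry an isotig (EST contig) id and a base-pair position
within that isotig, and map-less SNPs are simply unmapped.

Quality control applies three filters in a fixed order -- monomorphic removal,
missing-rate, then minor-allele-frequency -- and reports how many SNPs survive
each stage.  Missing calls are filled either by per-SNP mean imputation or by
an iterative relationship-based scheme that re-predicts each missing entry
from the genotypes of related individuals until the imputed values stabilise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneticMap",
    "SNPQCReport",
    "ImputationResult",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_map",
    "write_map",
    "qc_filter",
    "impute_em",
    "impute_mean",
]

MISSING = np.nan


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Dense genotype score matrix with missing mask.

    Parameters
    ----------
    genotype_ids : sequence of str
        Row labels, unique.
    snp_ids : sequence of str
        Column labels, unique.
    scores : ndarray, shape (n_genotypes, n_snps)
        Float array with values in {-1, 0, 1} or NaN for missing.
    populations : sequence of str, optional
        Per-genotype population label.
    """

    genotype_ids: np.ndarray
    snp_ids: np.ndarray
    scores: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
        if self.scores.shape != (len(self.genotype_ids), len(self.snp_ids)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise ValueError("duplicate genotype ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and not np.isin(obs, (-1.0, 0.0, 1.0)).all():
            raise ValueError("non-missing scores must be in {-1, 0, 1}")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.scores)

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(snp_id)
        return int(idx[0])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to SNPs selected by `keep`
        (boolean mask or index array over columns)."""
        return replace(
            self, snp_ids=self.snp_ids[keep], scores=self.scores[:, keep]
        )

    def subset_genotypes(self, keep: np.ndarray) -> "GenotypeMatrix":
        pops = self.populations[keep] if self.populations is not None else None
        return GenotypeMatrix(
            self.genotype_ids[keep], self.snp_ids, self.scores[keep], pops
        )

    def by_population(self) -> dict[str, "GenotypeMatrix"]:
        if self.populations is None:
            raise ValueError("no population labels attached")
        out = {}
        for pop in pd.unique(self.populations):
            out[pop] = self.subset_genotypes(self.populations == pop)
        return out

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the +1-coded allele from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.scores + 1.0, axis=0) / 2.0


@dataclass
class GeneticMap:
    """SNP placement on linkage groups, with optional isotig placement.

    Backed by a DataFrame indexed by snp_id with columns
    ``linkage_group`` (nullable int), ``cM`` (float, NaN when unmapped) and
    optionally ``isotig`` (str) and ``bp`` (within-isotig position).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "linkage_group" not in t.columns or "cM" not in t.columns:
            raise ValueError("map table needs linkage_group and cM columns")
        if t.index.duplicated().any():
            raise ValueError("duplicate SNP ids in map")
        mapped = t["cM"].notna()
        if (t.loc[mapped, "cM"] < 0).any():
            raise ValueError("cM positions must be >= 0")

    @property
    def mapped_ids(self) -> np.ndarray:
        return self.table.index[self.table["cM"].notna()].to_numpy(object)

    @property
    def unmapped_ids(self) -> np.ndarray:
        return self.table.index[self.table["cM"].isna()].to_numpy(object)

    @property
    def has_isotigs(self) -> bool:
        return "isotig" in self.table.columns and self.table["isotig"].notna().any()

    def is_mapped(self, snp_id: str) -> bool:
        return bool(pd.notna(self.table.at[snp_id, "cM"]))

    def position(self, snp_id: str) -> tuple[int, float]:
        row = self.table.loc[snp_id]
        if pd.isna(row["cM"]):
            raise KeyError(f"{snp_id} is unmapped")
        return int(row["linkage_group"]), float(row["cM"])


@dataclass
class SNPQCReport:
    """Per-SNP QC metrics and the SNP counts surviving each filter stage."""

    per_snp: pd.DataFrame   # maf, missing_rate, monomorphic, pass
    stage_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "n_snps": list(self.stage_counts.values())}
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Rows = genotypes, columns = SNP ids, values -1/0/1 or NA."""
    df = pd.DataFrame(gm.scores, index=gm.genotype_ids, columns=gm.snp_ids)
    if gm.populations is not None:
        df.insert(0, "population", gm.populations)
    df.index.name = "genotype"
    with pd.option_context("display.float_format", None):
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    pops = None
    if "population" in df.columns:
        pops = df.pop("population").to_numpy(object)
    scores = df.to_numpy(float)
    bad = np.flatnonzero(
        ~(np.isnan(scores) | np.isin(scores, (-1.0, 0.0, 1.0))).all(axis=1)
    )
    if bad.size:
        raise ValueError(
            f"malformed genotype row {bad[0] + 2} in {path}: "
            "scores must be -1/0/1/NA"
        )
    return GenotypeMatrix(
        df.index.to_numpy(object), df.columns.to_numpy(object), scores, pops
    )


def _read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} not supported"
            )
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS} sample {samples[i]}"
                )
            if -1 in alleles:
                continue
            col[i] = alleles[0] + alleles[1] - 1  # 0/0 -> -1, 0/1 -> 0, 1/1 -> 1
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        cols.append(col)
    scores = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, np.asarray(snp_ids, dtype=object), scores)


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF.

    VCF GT fields are coded 0/0 -> -1, 0/1 -> 0, 1/1 -> 1, ./. -> missing;
    records must be biallelic and diploid.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown format {format!r}")


#: cM positions are stored in VCF POS as round(cM * 1e4) to stay integral.
_VCF_CM_SCALE = 10_000


def write_genotypes_vcf(
    gm: GenotypeMatrix, gmap: GeneticMap, path: str | Path
) -> None:
    """Write mapped SNPs as a VCF v4.2 with contig = linkage group and
    POS = round(cM x 10^4). Unmapped SNPs go on contig 'UN' at running POS."""
    lines = ["##fileformat=VCFv4.2"]
    lgs = sorted(
        int(v) for v in gmap.table["linkage_group"].dropna().unique()
    )
    for lg in lgs:
        lines.append(f"##contig=<ID=LG{lg}>")
    lines.append("##contig=<ID=UN>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(g) for g in gm.genotype_ids)
    )
    gt_code = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
    unmapped_pos = 0
    rows = []
    for j, sid in enumerate(gm.snp_ids):
        try:
            lg, cm = gmap.position(sid)
            chrom, pos = f"LG{lg}", int(round(cm * _VCF_CM_SCALE)) + 1
        except KeyError:
            unmapped_pos += 1
            chrom, pos = "UN", unmapped_pos
        gts = "\t".join(
            gt_code.get(v, "./.") if not np.isnan(v) else "./."
            for v in gm.scores[:, j]
        )
        rows.append((chrom, pos, f"{chrom}\t{pos}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}"))
    # VCF requires position-sorted records within contig
    rows.sort(key=lambda r: (r[0] != "UN", r[0], r[1]))
    lines.extend(r[2] for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.rename_axis("snp_id").to_csv(path, sep="\t", na_rep="NA")


def read_map(path: str | Path) -> GeneticMap:
    t = pd.read_csv(path, sep="\t", index_col="snp_id", na_values=["NA"])
    t["linkage_group"] = t["linkage_group"].astype("Int64")
    return GeneticMap(t)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter(
    gm: GenotypeMatrix,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, SNPQCReport]:
    """Apply the three SNP filters in order and report stage counts.

    Order is fixed: (1) drop monomorphic SNPs (all non-missing calls equal,
    or no calls at all); (2) drop SNPs with missing rate > ``max_missing``;
    (3) drop SNPs with pooled-cohort MAF < ``min_maf``.  MAF is computed on
    non-missing calls over all genotypes together.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    X = gm.scores
    n_obs = (~np.isnan(X)).sum(axis=0)
    missing_rate = 1.0 - n_obs / gm.n_genotypes
    freq = gm.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        monomorphic = (np.nanmax(X, axis=0) == np.nanmin(X, axis=0)) | (n_obs == 0)

    keep = ~monomorphic
    n_after_mono = int(keep.sum())
    keep &= missing_rate <= max_missing
    n_after_miss = int(keep.sum())
    keep &= maf >= min_maf
    n_after_maf = int(keep.sum())

    report = SNPQCReport(
        per_snp=pd.DataFrame(
            {
                "maf": maf,
                "missing_rate": missing_rate,
                "monomorphic": monomorphic,
                "pass": keep,
            },
            index=pd.Index(gm.snp_ids, name="snp_id"),
        ),
        stage_counts={
            "input": gm.n_snps,
            "monomorphic_removed": n_after_mono,
            "missing_filtered": n_after_miss,
            "maf_filtered": n_after_maf,
        },
    )
    if n_after_maf == 0:
        raise ValueError("no SNPs survive QC filtering")
    return gm.subset_snps(keep), report


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    scores: np.ndarray          # complete, real-valued; observed entries intact
    n_iter: int
    converged: bool
    method: str = "em"


def impute_mean(gm: GenotypeMatrix) -> ImputationResult:
    """Fill each missing call with the per-SNP mean of observed calls."""
    X = gm.scores.copy()
    mask = np.isnan(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("some SNPs have no observed calls")
    X[mask] = np.broadcast_to(col_mean, X.shape)[mask]
    return ImputationResult(X, n_iter=0, converged=True, method="mean")


def impute_em(
    gm: GenotypeMatrix,
    max_iter: int = 50,
    tol: float = 1e-4,
    method: str = "em",
) -> ImputationResult:
    """Iterative relationship-based imputation of missing genotype scores.

    Missing entries start at the per-SNP mean.  Each iteration recomputes the
    realized additive relationship matrix from the current complete matrix and
    re-predicts every missing entry as the relationship-weighted combination
    of the observed genotypes at that SNP (weights = positive part of the
    relationship to each observed individual), shrunk toward the SNP mean when
    no informative relatives exist.  Iteration stops when the largest change
    of any imputed entry falls below ``tol``.  Observed entries are never
    altered and imputed values are clipped to [-1, 1].

    ``method="mean"`` short-circuits to plain mean imputation.
    """
    if method == "mean":
        return impute_mean(gm)
    if method != "em":
        raise ValueError(f"unknown imputation method {method!r}")

    mask = np.isnan(gm.scores)
    res = impute_mean(gm)
    if not mask.any():
        return ImputationResult(res.scores, n_iter=0, converged=True)
    X = res.scores
    n = gm.n_genotypes
    # prior weight pulling an entry toward the SNP mean; dominates only when
    # the individual has no positively-related observed peers at that SNP
    prior = 0.05
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = X.mean(axis=0) / 2.0 + 0.5
        W = X - (2.0 * p - 1.0)
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise ValueError("all SNPs monomorphic; relationships undefined")
        K = W @ W.T / denom
        # soft-threshold at the sampling noise of a zero relationship
        # (sd ~ 1/sqrt(m)), then square so strong relatives dominate; with no
        # informative relatives the prior pulls to the SNP mean
        tau = 3.0 / np.sqrt(gm.n_snps)
        Kpos = np.clip(K - tau, 0.0, None) ** 2
        np.fill_diagonal(Kpos, 0.0)
        obs = ~mask
        col_mean = np.where(obs, X, 0.0).sum(axis=0) / obs.sum(axis=0)
        # weighted average of observed scores per (individual, SNP)
        num = Kpos @ np.where(obs, X, 0.0) + prior * col_mean
        den = Kpos @ obs.astype(float) + prior
        pred = np.clip(num / den, -1.0, 1.0)
        delta = np.abs(pred[mask] - X[mask]).max()
        X = np.where(mask, pred, gm.scores)
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"relationship-based imputation did not converge in {max_iter} "
            f"iterations (last max change {delta:.2e})",
            RuntimeWarning,
        )
    return ImputationResult(X, n_iter=it, converged=converged)
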