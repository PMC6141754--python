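"""Synthetic admixed plus-tree cohorts with mapped genotypes, traits and trials.

The generator emulates the data structure of a multi-population conifer
breeding cohort: several populations of unrelated clonally-archived genotypes,
each genotype an admixture of a few ancestral clusters, genotyped at SNPs laid
out on a centimorgan linkage map.  Linkage disequilibrium arises from an
ancestry-mosaic mechanism: each haplotype is a mosaic of ancestral segments
with exponentially distributed lengths, so nearby SNPs tend to descend from
the same cluster and r^2 decays with map distance at a rate set by the mean
segment length.  Ancestral allele frequencies follow a Balding-Nichols
construction around a common base frequency, with between-cluster divergence
acting like an F_ST dial.

Quantitative traits are additive (optionally with dominance) over a chosen
number of QTL SNPs; clonal field trials replicate each genotype over sites and
blocks with the usual site / block-in-site / genotype-by-site / residual
variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, GeneticMap

__all__ = [
    "CohortSpec",
    "TraitSpec",
    "TrialDesignSpec",
    "CohortData",
    "TraitData",
    "simulate_ancestral_frequencies",
    "simulate_admixed_genotypes",
    "simulate_cohort",
    "simulate_trait",
    "simulate_clonal_phenotypes",
    "simulate_trial_records",
]


def _per_pop(value, n_pop: int) -> list:
    """Broadcast a scalar / single sequence to one entry per population."""
    if np.isscalar(value):
        return [value] * n_pop
    value = list(value)
    if len(value) == n_pop:
        return value
    raise ValueError(f"expected scalar or length-{n_pop} sequence, got {value!r}")


@dataclass
class CohortSpec:
    """Configuration of a synthetic multi-population cohort.

    Defaults mirror a three-population plus-tree study: populations of
    181/159/136 unrelated genotypes, K = 4 ancestral clusters mixed in
    population-specific proportions (two similar, broadly admixed populations
    and one more single-ancestry population with longer LD blocks), ~6,455
    mapped SNPs over 11 linkage groups plus a set of unmapped SNPs tied to
    mapped ones by high r^2.
    """

    n_populations: int = 3
    n_genotypes_per_pop: Sequence[int] | int | None = None
    n_ancestral_clusters: int = 4
    n_snps_mapped: int = 6455
    n_snps_unmapped: int = 200
    n_linkage_groups: int = 11
    map_length_cM: float | Sequence[float] = 120.0
    divergence: float = 0.1
    admixture_concentration: Sequence[Sequence[float]] | None = None
    recombination_block_cM: float | Sequence[float] | None = None
    unmapped_noise: float = 0.02
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_ancestral_clusters < 1:
            raise ValueError("counts must be >= 1")
        if self.n_genotypes_per_pop is None:
            # study-sized populations; extra populations default to 150
            sizes = [181, 159, 136]
            self.n_genotypes_per_pop = (
                sizes[: self.n_populations]
                + [150] * max(0, self.n_populations - 3)
            )
        if self.recombination_block_cM is None:
            # the third (Kyushu-like) population carries longer ancestry
            # blocks, hence slower LD decay
            blocks = [5.0] * self.n_populations
            if self.n_populations >= 3:
                blocks[2] = 8.0
            self.recombination_block_cM = blocks
        if np.isscalar(self.n_genotypes_per_pop):
            self.n_genotypes_per_pop = [int(self.n_genotypes_per_pop)] * self.n_populations
        else:
            self.n_genotypes_per_pop = [
                int(v) for v in _per_pop(self.n_genotypes_per_pop, self.n_populations)
            ]
        if min(self.n_genotypes_per_pop) < 1 or self.n_snps_mapped < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.admixture_concentration is None:
            self.admixture_concentration = _default_admixture(
                self.n_populations, self.n_ancestral_clusters
            )
        self.admixture_concentration = [
            np.asarray(a, dtype=float) for a in self.admixture_concentration
        ]
        if len(self.admixture_concentration) != self.n_populations:
            raise ValueError("one Dirichlet parameter vector per population")
        for a in self.admixture_concentration:
            if len(a) != self.n_ancestral_clusters or (a <= 0).any():
                raise ValueError("Dirichlet parameters must be positive, length K")
        self.map_length_cM = [
            float(v) for v in _per_pop(self.map_length_cM, self.n_linkage_groups)
        ]
        if min(self.map_length_cM) <= 0:
            raise ValueError("map lengths must be positive")
        self.recombination_block_cM = [
            float(v) for v in _per_pop(self.recombination_block_cM, self.n_populations)
        ]
        if min(self.recombination_block_cM) <= 0:
            raise ValueError("block length must be positive")


def _default_admixture(n_pop: int, K: int) -> list[np.ndarray]:
    """Two broadly admixed populations sharing the same cluster palette and a
    third, less admixed population leaning on a different cluster."""
    base = []
    for p in range(n_pop):
        a = np.full(K, 0.2)
        if p < 2 or n_pop < 3:
            a[: max(K - 1, 1)] = 1.2  # broad mixture over K-1 clusters
        else:
            a[:] = 0.35               # low concentration -> near one-hot
            a[K - 1] = 0.6            # with a population-specific cluster
        base.append(a)
    return base


@dataclass
class TraitSpec:
    """Genetic architecture of a simulated quantitative trait."""

    architecture: str = "polygenic"          # or "oligogenic"
    n_qtl: int = 1000
    heritability_broad: float = 0.6
    dominance_fraction: float = 0.0
    qtl_effect_distribution: str = "gaussian"  # or "geometric"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("polygenic", "oligogenic"):
            raise ValueError("architecture must be 'polygenic' or 'oligogenic'")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if not (0.0 <= self.heritability_broad <= 1.0):
            raise ValueError("heritability_broad must lie in [0, 1]")
        if not (0.0 <= self.dominance_fraction < 1.0):
            raise ValueError("dominance_fraction must lie in [0, 1)")


@dataclass
class TrialDesignSpec:
    """Clonal field-trial layout and its non-genetic variance components."""

    n_sites: int = 5
    n_blocks_per_site: int = 3
    site_variance: float = 1.0
    site_block_variance: float = 0.25
    gxe_variance: float = 0.25
    residual_variance: float = 1.0
    genotype_site_incidence: float | str = "all"  # or fraction of sites per genotype

    def __post_init__(self) -> None:
        for v in (
            self.site_variance,
            self.site_block_variance,
            self.gxe_variance,
            self.residual_variance,
        ):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        if self.n_sites < 1 or self.n_blocks_per_site < 1:
            raise ValueError("counts must be >= 1")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Everything a simulated cohort knows about itself."""

    gm: GenotypeMatrix                  # scores with missing calls applied
    gmap: GeneticMap                    # mapped + unmapped SNPs
    Q_true: np.ndarray                  # genotypes x K sampled admixture rows
    realized_ancestry: np.ndarray       # genotypes x K mosaic fractions
    ancestral_freqs: np.ndarray         # K x mapped SNPs
    scores_complete: np.ndarray         # pre-missingness scores, genotypes x SNPs
    unmapped_source: dict[str, str]     # unmapped SNP id -> mapped source id


@dataclass
class TraitData:
    genetic_values: pd.Series           # standardized, indexed by genotype id
    qtl_table: pd.DataFrame             # snp_id, additive/dominance effect, position


# ---------------------------------------------------------------------------
# ancestral frequencies
# ---------------------------------------------------------------------------

def simulate_ancestral_frequencies(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Balding-Nichols draws of K cluster allele-frequency rows.

    A base frequency per SNP is drawn Uniform(0.1, 0.9); each cluster then
    draws Beta(p(1-F)/F, (1-p)(1-F)/F) around it, where F is the divergence
    parameter (expected pairwise F_ST scale).  Frequencies are clipped to
    (0.02, 0.98) so no cluster is ever fixed.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    K, m, F = spec.n_ancestral_clusters, spec.n_snps_mapped, spec.divergence
    base = rng.uniform(0.1, 0.9, size=m)
    ratio = (1.0 - F) / F
    freqs = rng.beta(base * ratio, (1.0 - base) * ratio, size=(K, m))
    return np.clip(freqs, 0.02, 0.98)


# ---------------------------------------------------------------------------
# genotype mosaics
# ---------------------------------------------------------------------------

def _mapped_positions(spec: CohortSpec, rng: np.random.Generator):
    """Assign mapped SNPs to linkage groups (near-equal counts) at sorted
    uniform cM positions."""
    n_lg = spec.n_linkage_groups
    counts = np.full(n_lg, spec.n_snps_mapped // n_lg)
    counts[: spec.n_snps_mapped % n_lg] += 1
    lg_ids, positions = [], []
    for lg in range(n_lg):
        pos = np.sort(rng.uniform(0.0, spec.map_length_cM[lg], size=counts[lg]))
        positions.append(pos)
        lg_ids.append(np.full(counts[lg], lg + 1))
    return np.concatenate(lg_ids), np.concatenate(positions)


def _mosaic_haplotype(
    freqs: np.ndarray,
    q: np.ndarray,
    lg_of_snp: np.ndarray,
    pos: np.ndarray,
    lg_lengths: Sequence[float],
    block_cM: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One haplotype: exponential-length ancestral segments per LG, alleles
    drawn from the segment cluster's frequencies.  Returns (alleles, cluster
    label per SNP)."""
    m = pos.size
    cluster_of_snp = np.empty(m, dtype=np.int64)
    K = q.size
    for lg in np.unique(lg_of_snp):
        sel = lg_of_snp == lg
        length = lg_lengths[lg - 1]
        # segment breakpoints: cumulative exponential lengths
        n_seg_guess = max(4, int(3 * length / block_cM) + 4)
        seg_len = rng.exponential(block_cM, size=n_seg_guess)
        while seg_len.sum() < length:
            seg_len = np.concatenate([seg_len, rng.exponential(block_cM, size=n_seg_guess)])
        bounds = np.cumsum(seg_len)
        n_seg = int(np.searchsorted(bounds, length)) + 1
        seg_cluster = rng.choice(K, size=n_seg, p=q)
        idx = np.searchsorted(bounds[:n_seg], pos[sel], side="right")
        cluster_of_snp[sel] = seg_cluster[np.minimum(idx, n_seg - 1)]
    p_here = freqs[cluster_of_snp, np.arange(m)]
    alleles = (rng.random(m) < p_here).astype(np.int8)
    return alleles, cluster_of_snp


def simulate_admixed_genotypes(
    freqs: np.ndarray, spec: CohortSpec
) -> CohortData:
    """Generate the full cohort: mosaic diploid genotypes, map, admixture truth.

    Each genotype samples an admixture row Q from its population's Dirichlet;
    its two haplotypes are independent ancestral mosaics given Q.  Scores are
    the sum of the two alleles minus 1 (so -1/0/1).  Unmapped SNPs are noisy
    copies of random mapped SNPs (each genotype's score re-drawn with
    probability ``unmapped_noise``), guaranteeing a high-r^2 mapped partner.
    Missing calls are then applied completely at random.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_ancestral_clusters
    if freqs.shape[0] != K or freqs.shape[1] != spec.n_snps_mapped:
        raise ValueError("frequency matrix does not match spec dimensions")
    if spec.n_snps_mapped < 1:
        raise ValueError("map has zero mapped SNPs")

    lg_of_snp, pos = _mapped_positions(spec, rng)
    m = spec.n_snps_mapped
    n_total = int(sum(spec.n_genotypes_per_pop))

    scores = np.empty((n_total, m), dtype=float)
    Q_true = np.empty((n_total, K))
    realized = np.zeros((n_total, K))
    pops = np.empty(n_total, dtype=object)
    gids = np.array([f"G{i:04d}" for i in range(n_total)], dtype=object)

    i = 0
    for p_idx in range(spec.n_populations):
        alpha = spec.admixture_concentration[p_idx]
        block = spec.recombination_block_cM[p_idx]
        for _ in range(spec.n_genotypes_per_pop[p_idx]):
            q = rng.dirichlet(alpha)
            h1, c1 = _mosaic_haplotype(
                freqs, q, lg_of_snp, pos, spec.map_length_cM, block, rng
            )
            h2, c2 = _mosaic_haplotype(
                freqs, q, lg_of_snp, pos, spec.map_length_cM, block, rng
            )
            scores[i] = h1 + h2 - 1.0
            Q_true[i] = q
            counts = np.bincount(c1, minlength=K) + np.bincount(c2, minlength=K)
            realized[i] = counts / counts.sum()
            pops[i] = f"pop{p_idx + 1}"
            i += 1

    # unmapped SNPs: noisy duplicates of random mapped SNPs
    unmapped_source: dict[str, str] = {}
    mapped_ids = np.array([f"SNP{j:05d}" for j in range(m)], dtype=object)
    u = spec.n_snps_unmapped
    if u > 0:
        src = rng.integers(0, m, size=u)
        unmapped = scores[:, src].copy()
        flip = rng.random(unmapped.shape) < spec.unmapped_noise
        # re-draw flipped entries uniformly among the other two score values
        shift = rng.integers(1, 3, size=unmapped.shape)
        unmapped = np.where(flip, ((unmapped + 1 + shift) % 3) - 1, unmapped)
        unmapped_ids = np.array([f"USNP{j:05d}" for j in range(u)], dtype=object)
        for j in range(u):
            unmapped_source[unmapped_ids[j]] = mapped_ids[src[j]]
        all_scores = np.concatenate([scores, unmapped], axis=1)
        all_ids = np.concatenate([mapped_ids, unmapped_ids])
    else:
        all_scores, all_ids = scores, mapped_ids

    # genetic map with isotig placement for mapped SNPs: runs of 1-3
    # consecutive same-LG SNPs share an isotig, bp positions within 6 kb
    isotig = np.empty(m, dtype=object)
    bp = np.empty(m, dtype=float)
    iso_counter = 0
    j = 0
    while j < m:
        size = int(rng.integers(1, 4))
        members = [k for k in range(j, min(j + size, m)) if lg_of_snp[k] == lg_of_snp[j]]
        bps = np.sort(rng.integers(1, 6000, size=len(members)))
        for rank, k in enumerate(members):
            isotig[k] = f"iso{iso_counter:05d}"
            bp[k] = bps[rank]
        iso_counter += 1
        j = members[-1] + 1
    map_table = pd.DataFrame(
        {
            "linkage_group": pd.array(
                np.concatenate([lg_of_snp, np.full(u, -1)]), dtype="Int64"
            ),
            "cM": np.concatenate([pos, np.full(u, np.nan)]),
            "isotig": np.concatenate([isotig, np.full(u, None)]),
            "bp": np.concatenate([bp, np.full(u, np.nan)]),
        },
        index=pd.Index(all_ids, name="snp_id"),
    )
    map_table.loc[map_table["cM"].isna(), "linkage_group"] = pd.NA

    complete = all_scores.copy()
    if spec.missing_rate > 0:
        miss = rng.random(all_scores.shape) < spec.missing_rate
        all_scores = np.where(miss, np.nan, all_scores)

    gm = GenotypeMatrix(gids, all_ids, all_scores, pops)
    return CohortData(
        gm=gm,
        gmap=GeneticMap(map_table),
        Q_true=Q_true,
        realized_ancestry=realized,
        ancestral_freqs=freqs,
        scores_complete=complete,
        unmapped_source=unmapped_source,
    )


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Convenience wrapper: ancestral frequencies + admixed genotypes."""
    rng = np.random.default_rng(spec.seed)
    freqs = simulate_ancestral_frequencies(spec, rng)
    return simulate_admixed_genotypes(freqs, spec)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait(
    cohort: CohortData,
    trait: TraitSpec,
    candidate_snps: np.ndarray | None = None,
) -> TraitData:
    """Sample QTLs and build standardized clonal genetic values.

    Additive values are the score-weighted sum of QTL effects; an optional
    dominance term adds a heterozygote-specific deviation per QTL, scaled so
    that the requested fraction of genetic variance is non-additive.  The
    returned genetic values are standardized to zero mean, unit variance; the
    truth table records each QTL's id, map position and effects.
    """
    rng = np.random.default_rng(trait.seed)
    gm = cohort.gm
    X = cohort.scores_complete
    if candidate_snps is None:
        candidate_snps = cohort.gmap.mapped_ids
    cand_idx = np.flatnonzero(np.isin(gm.snp_ids, candidate_snps))
    if trait.n_qtl > cand_idx.size:
        raise ValueError(
            f"n_qtl={trait.n_qtl} exceeds {cand_idx.size} candidate SNPs"
        )
    qtl_idx = np.sort(rng.choice(cand_idx, size=trait.n_qtl, replace=False))
    if trait.qtl_effect_distribution == "gaussian":
        effects = rng.standard_normal(trait.n_qtl)
    elif trait.qtl_effect_distribution == "geometric":
        mag = 0.9 ** np.arange(trait.n_qtl)
        effects = rng.permutation(mag) * rng.choice((-1.0, 1.0), size=trait.n_qtl)
    else:
        raise ValueError(
            f"unknown effect distribution {trait.qtl_effect_distribution!r}"
        )

    add = X[:, qtl_idx] @ effects
    dom_effects = np.zeros(trait.n_qtl)
    g = add.copy()
    if trait.dominance_fraction > 0:
        dom_raw = rng.standard_normal(trait.n_qtl)
        het = (X[:, qtl_idx] == 0).astype(float)
        dom = (het - het.mean(axis=0)) @ dom_raw
        va, vd = add.var(), dom.var()
        if vd > 0:
            f = trait.dominance_fraction
            scale = np.sqrt((f / (1.0 - f)) * va / vd)
            dom_effects = dom_raw * scale
            g = add + dom * scale
    sd = g.std()
    if sd == 0:
        raise ValueError("degenerate trait: zero genetic variance")
    g_std = (g - g.mean()) / sd

    qtl_ids = gm.snp_ids[qtl_idx]
    table = cohort.gmap.table.reindex(qtl_ids)[["linkage_group", "cM"]].copy()
    table["additive_effect"] = effects
    table["dominance_effect"] = dom_effects
    return TraitData(
        genetic_values=pd.Series(g_std, index=gm.genotype_ids, name="genetic_value"),
        qtl_table=table,
    )


def simulate_clonal_phenotypes(
    genetic_values: pd.Series, heritability_broad: float, seed: int = 0
) -> pd.Series:
    """Add environmental noise so the broad-sense heritability of the clonal
    score equals ``heritability_broad`` (genetic values assumed unit-variance)."""
    if not (0.0 < heritability_broad <= 1.0):
        raise ValueError("heritability must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    var_e = (1.0 - heritability_broad) / heritability_broad
    noise = rng.normal(0.0, np.sqrt(var_e), size=len(genetic_values))
    return genetic_values + noise


# ---------------------------------------------------------------------------
# field trials
# ---------------------------------------------------------------------------

def simulate_trial_records(
    genetic_values: pd.Series,
    design: TrialDesignSpec,
    mu: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot-mean trial records: y = mu + site + block(site) + genotype +
    genotype-by-site + residual, one record per genotype x block at each site
    the genotype is planted."""
    rng = np.random.default_rng(seed)
    genos = genetic_values.index.to_numpy(object)
    n_g, n_s, n_b = len(genos), design.n_sites, design.n_blocks_per_site

    if design.genotype_site_incidence == "all":
        incidence = np.ones((n_g, n_s), dtype=bool)
    else:
        frac = float(design.genotype_site_incidence)
        incidence = rng.random((n_g, n_s)) < frac
        empty = ~incidence.any(axis=1)
        incidence[empty, rng.integers(0, n_s, size=empty.sum())] = True
    if not incidence.any(axis=1).all():
        raise ValueError("every genotype must appear at >= 1 site")

    site_eff = rng.normal(0.0, np.sqrt(design.site_variance), size=n_s)
    block_eff = rng.normal(
        0.0, np.sqrt(design.site_block_variance), size=(n_s, n_b)
    )
    gxe = rng.normal(0.0, np.sqrt(design.gxe_variance), size=(n_g, n_s))

    g_idx, s_idx = np.nonzero(incidence)
    g_rep = np.repeat(g_idx, n_b)
    s_rep = np.repeat(s_idx, n_b)
    b_rep = np.tile(np.arange(n_b), g_idx.size)
    resid = rng.normal(0.0, np.sqrt(design.residual_variance), size=g_rep.size)
    y = (
        mu
        + site_eff[s_rep]
        + block_eff[s_rep, b_rep]
        + genetic_values.to_numpy()[g_rep]
        + gxe[g_rep, s_rep]
        + resid
    )
    return pd.DataFrame(
        {
            "site": [f"S{s + 1}" for s in s_rep],
            "block": [f"B{b + 1}" for b in b_rep],
            "genotype": genos[g_rep],
            "value": y,
        }
    )
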