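"""Low-density SNP panel selection and the accuracy-vs-panel-size experiment.

Two selection procedures over the mapped SNPs:

* GWAS-based: greedily pick the SNP with the highest association score
  (-log10 P), excluding all SNPs within +/- d centimorgans on the same
  linkage group (initial d = 10 cM); when no admissible SNP remains, halve d
  and re-admit SNPs at distinct map positions satisfying the relaxed radius
  around the already-selected SNPs; once every distinct position is taken,
  fill the remaining slots purely in descending score order.
* Semi-random: assign a uniformly random permutation of ranks 1..m as the
  scores and run the same greedy procedure, which spreads picks along the
  map without reference to the trait.

Because selection is a deterministic ranking, panels are nested across
sizes.  The accuracy-curve experiment cross-validates a prediction model on
each panel size for both procedures; by default the association scores that
drive GWAS-based selection are recomputed inside each training fold so panel
choice never sees the validation genotypes (the single whole-cohort scan the
simpler protocol uses is available as ``whole_cohort_scores``).  Each size's replicate
accuracies are compared with the best size's by a two-sample t test; sizes
with p >= 0.05 are flagged as statistically indistinguishable from the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import mixed_model_scan
from .io import GeneticMap
from .popgen import kinship
from .predict import CVResult, PredictionModelSpec, _fit_predict, _safe_corr

__all__ = [
    "SelectionConfig",
    "SelectedPanel",
    "gwas_based_select",
    "semi_random_select",
    "accuracy_curve",
]

DEFAULT_PANEL_SIZES = (10, 25, 50, 100, 250, 500, 1000, 2500, 5000)


@dataclass
class SelectionConfig:
    procedure: str = "gwas_based"          # or "semi_random"
    initial_exclusion_d: float = 10.0      # cM
    panel_sizes: tuple[int, ...] = DEFAULT_PANEL_SIZES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.procedure not in ("gwas_based", "semi_random"):
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.initial_exclusion_d <= 0:
            raise ValueError("exclusion radius must be positive")
        sizes = tuple(self.panel_sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("panel sizes must be strictly increasing")
        self.panel_sizes = sizes


@dataclass
class SelectedPanel:
    table: pd.DataFrame   # rank, snp_id, linkage_group, cM, score, d_in_force

    @property
    def ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy(object)

    def head(self, k: int) -> "SelectedPanel":
        return SelectedPanel(self.table.iloc[:k].reset_index(drop=True))


def gwas_based_select(
    scores: pd.Series,
    gmap: GeneticMap,
    target_n: int,
    config: SelectionConfig | None = None,
) -> SelectedPanel:
    """Greedy highest-score selection with same-LG exclusion; see module
    docstring.  ``scores`` is indexed by SNP id; every scored SNP must be
    mapped.  Ties break to higher score, lower LG, lower cM, then
    lexicographic SNP id.
    """
    config = config or SelectionConfig()
    t = gmap.table.reindex(scores.index)
    if t["cM"].isna().any():
        bad = t.index[t["cM"].isna()][0]
        raise ValueError(f"SNP {bad} is unmapped; selection needs mapped SNPs")
    m = len(scores)
    if target_n > m:
        raise ValueError(f"target_n={target_n} exceeds {m} SNPs")

    ids = scores.index.to_numpy(object)
    lg = t["linkage_group"].to_numpy(int)
    cm = t["cM"].to_numpy(float)
    sc = scores.to_numpy(float)
    # deterministic priority: higher score, lower LG, lower cM, lex id
    order = sorted(range(m), key=lambda j: (-sc[j], lg[j], cm[j], str(ids[j])))
    prio = np.empty(m)
    prio[order] = np.arange(m)

    selected: list[int] = []
    d_in_force: list[float] = []
    taken = np.zeros(m, dtype=bool)
    d = float(config.initial_exclusion_d)
    # min distance to any already-selected SNP on the same LG (inf = none)
    mindist = np.full(m, np.inf)

    while len(selected) < target_n:
        admissible = ~taken & (mindist > d)
        if admissible.any():
            pick = int(np.argmin(np.where(admissible, prio, np.inf)))
            selected.append(pick)
            d_in_force.append(d)
            taken[pick] = True
            same_lg = lg == lg[pick]
            np.minimum(mindist, np.where(same_lg, np.abs(cm - cm[pick]), np.inf),
                       out=mindist)
            continue
        # no admissible SNP at this radius: halve and retry while a SNP at a
        # distinct position could still qualify at some smaller radius
        if d > 1e-9 and (~taken & (mindist > 0.0)).any():
            d /= 2.0
            continue
        # fill phase: remaining slots purely in descending score order
        remaining = [j for j in order if not taken[j]]
        for j in remaining[: target_n - len(selected)]:
            selected.append(j)
            d_in_force.append(0.0)
            taken[j] = True
        break

    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(selected) + 1),
            "snp_id": ids[selected],
            "linkage_group": lg[selected],
            "cM": cm[selected],
            "score": sc[selected],
            "d_in_force": d_in_force,
        }
    )
    return SelectedPanel(table)


def semi_random_select(
    gmap: GeneticMap,
    target_n: int,
    seed: int = 0,
    config: SelectionConfig | None = None,
) -> SelectedPanel:
    """Assign a random unique rank 1..m to every mapped SNP and run the
    GWAS-based procedure on those ranks as scores."""
    config = config or SelectionConfig(procedure="semi_random", seed=seed)
    mapped = gmap.mapped_ids
    rng = np.random.default_rng(seed)
    ranks = rng.permutation(len(mapped)) + 1
    scores = pd.Series(ranks.astype(float), index=pd.Index(mapped, name="snp_id"))
    return gwas_based_select(scores, gmap, target_n, config)


# ---------------------------------------------------------------------------
# accuracy vs panel size
# ---------------------------------------------------------------------------

def accuracy_curve(
    scores_matrix: np.ndarray,
    snp_ids: np.ndarray,
    trait: np.ndarray | pd.Series,
    gmap: GeneticMap,
    model_spec: PredictionModelSpec,
    config: SelectionConfig | None = None,
    procedures: tuple[str, ...] = ("gwas_based", "semi_random"),
    folds: int = 10,
    replicates: int = 10,
    seed: int = 0,
    n_pc: int = 0,
    whole_cohort_scores: bool = False,
) -> pd.DataFrame:
    """Cross-validated accuracy per (procedure, panel size) with t-test flags.

    For the GWAS-based procedure the association scores feeding selection are
    recomputed from each training fold's genotypes (mixed-model scan with
    training kinship), unless ``whole_cohort_scores`` is set, in which case one scan
    on the full cohort supplies the scores for every fold.  Semi-random
    panels depend only on the seed.  Returns a table with columns procedure,
    size, mean, se, t_stat, p_vs_best and not_different_from_best.
    """
    config = config or SelectionConfig()
    X = np.asarray(scores_matrix, dtype=float)
    y = np.asarray(trait, dtype=float)
    snp_ids = np.asarray(snp_ids, dtype=object)
    mapped = [s for s in gmap.mapped_ids if s in set(snp_ids)]
    col_of = {s: j for j, s in enumerate(snp_ids)}
    mapped_cols = np.array([col_of[s] for s in mapped])
    sizes = [s for s in config.panel_sizes if s <= len(mapped)]
    if not sizes:
        raise ValueError("no panel size fits the available mapped SNPs")
    max_size = max(sizes)
    n = len(y)
    rng = np.random.default_rng(seed)

    full_scan_scores = None
    if whole_cohort_scores and "gwas_based" in procedures:
        Kfull = kinship(X[:, mapped_cols])
        res = mixed_model_scan(
            X[:, mapped_cols], y, Kfull, n_pc=n_pc, snp_ids=np.asarray(mapped, object)
        )
        full_scan_scores = res.table["minus_log10_p"]

    acc: dict[tuple[str, int], list[float]] = {
        (proc, s): [] for proc in procedures for s in sizes
    }
    for rep in range(replicates):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        rep_seed = int(rng.integers(2**31))
        semi_panel = (
            semi_random_select(
                GeneticMap(gmap.table.loc[mapped]), max_size, seed=rep_seed, config=None
            )
            if "semi_random" in procedures
            else None
        )
        preds: dict[tuple[str, int], np.ndarray] = {
            key: np.empty(n) for key in acc
        }
        for f in range(folds):
            test = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            panels: dict[str, SelectedPanel] = {}
            if "gwas_based" in procedures:
                if whole_cohort_scores:
                    sel_scores = full_scan_scores
                else:
                    Ktr = kinship(X[np.ix_(train, mapped_cols)])
                    scan = mixed_model_scan(
                        X[np.ix_(train, mapped_cols)],
                        y[train],
                        Ktr,
                        n_pc=n_pc,
                        snp_ids=np.asarray(mapped, object),
                    )
                    sel_scores = scan.table["minus_log10_p"].fillna(0.0)
                panels["gwas_based"] = gwas_based_select(
                    sel_scores, gmap, max_size, config
                )
            if semi_panel is not None:
                panels["semi_random"] = semi_panel
            fold_seed = int(rng.integers(2**31))
            for proc, panel in panels.items():
                for s in sizes:
                    cols = np.array([col_of[i] for i in panel.head(s).ids])
                    Xp = X[:, cols]
                    Kp = kinship(Xp) if model_spec.model == "GBLUP" else None
                    preds[(proc, s)][test] = _fit_predict(
                        model_spec, Xp, y, Kp, train, test, fold_seed
                    )
        for key in acc:
            acc[key].append(_safe_corr(y, preds[key]))

    rows = []
    for proc in procedures:
        means = {s: float(np.mean(acc[(proc, s)])) for s in sizes}
        best_size = max(sizes, key=lambda s: means[s])
        best_acc = np.asarray(acc[(proc, best_size)])
        for s in sizes:
            a = np.asarray(acc[(proc, s)])
            if s == best_size:
                t_stat, p = 0.0, 1.0
            else:
                with np.errstate(invalid="ignore"):
                    t_stat, p = stats.ttest_ind(a, best_acc)
                if np.isnan(p):  # zero variance in both groups
                    t_stat, p = 0.0, (1.0 if np.allclose(a, best_acc) else 0.0)
            rows.append(
                {
                    "procedure": proc,
                    "size": s,
                    "mean": means[s],
                    "se": float(np.std(a, ddof=1) / np.sqrt(len(a)))
                    if len(a) > 1
                    else 0.0,
                    "best_size": best_size,
                    "t_stat": float(t_stat),
                    "p_vs_best": float(p),
                    "not_different_from_best": bool(p >= 0.05),
                }
            )
    return pd.DataFrame(rows)
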