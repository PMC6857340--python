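"""Locating the phylotypic period from cross-species transcriptomes.

The most conserved (phylotypic) developmental period is identified from
whole-embryo expression tables of several species: for every combination of
one stage per species, the expression distance ``expDist`` is the average,
over a configured selection of species pairs, of 1 - Spearman rho computed on
1:1 orthologue FPKM values.  The lowest 1% of combinations are the most
similar stage combinations, and ``P_top`` is the percentage of those kept
combinations that include a given stage of a given species.  The whole
procedure is repeated over resamplings that draw one biological replicate per
species-stage, yielding a mean and SD per stage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COMBINATION_GUARD = 1_000_000


@dataclass
class ExpressionMatrix:
    """Long FPKM table of one species: gene_id, stage, replicate, fpkm."""

    species: str
    data: pd.DataFrame
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.data["fpkm"] < 0).any():
            raise ValueError(f"{self.species}: negative FPKM values")
        missing = set(self.stage_order) - set(self.data["stage"])
        if missing:
            raise ValueError(f"{self.species}: stages without data: {sorted(missing)}")

    def replicates(self, stage: str) -> list[str]:
        return sorted(self.data.loc[self.data["stage"] == stage, "replicate"].unique())

    def stage_vector(self, stage: str, replicate: str) -> pd.Series:
        sub = self.data[(self.data["stage"] == stage) & (self.data["replicate"] == replicate)]
        return pd.Series(sub["fpkm"].to_numpy(), index=sub["gene_id"].to_numpy())

    @classmethod
    def from_tsv(cls, species: str, path: str, stage_order: Sequence[str]) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"stage": str, "replicate": str})
        return cls(species, df, tuple(stage_order))


class OrthologyMap:
    """1:1 orthologue correspondences per species pair.

    Gene pairs must be bijective within each pair of species; genes lacking a
    counterpart are simply absent from the pair's table and are ignored in
    comparisons involving that pair.
    """

    def __init__(self, pair_tables: Mapping[tuple[str, str], pd.DataFrame]) -> None:
        self._tables: dict[frozenset, pd.DataFrame] = {}
        for (sp_a, sp_b), df in pair_tables.items():
            if sp_a == sp_b:
                raise ValueError("orthology pair must involve two distinct species")
            if df[sp_a].duplicated().any() or df[sp_b].duplicated().any():
                raise ValueError(f"orthology for ({sp_a}, {sp_b}) is not 1:1")
            self._tables[frozenset((sp_a, sp_b))] = df[[sp_a, sp_b]].reset_index(drop=True)

    def pairs(self, sp_a: str, sp_b: str) -> pd.DataFrame:
        key = frozenset((sp_a, sp_b))
        if key not in self._tables:
            raise KeyError(f"no orthology table for ({sp_a}, {sp_b})")
        return self._tables[key]

    def species_pairs(self) -> list[tuple[str, str]]:
        return [tuple(sorted(k)) for k in self._tables]


def expdist_pair(
    expr_a: pd.Series, expr_b: pd.Series, orthology: pd.DataFrame | None = None
) -> float:
    """1 - Spearman rho over paired 1:1 orthologue expression values.

    ``orthology`` is a two-column gene-id mapping (columns in the order of the
    two expression vectors); with None, the series are matched on their index.
    Requires >= 3 shared orthologues; a constant vector makes rho undefined
    and raises.
    """
    if orthology is not None:
        cols = list(orthology.columns)
        a = expr_a.reindex(orthology[cols[0]]).to_numpy()
        b = expr_b.reindex(orthology[cols[1]]).to_numpy()
    else:
        shared = expr_a.index.intersection(expr_b.index)
        a = expr_a.loc[shared].to_numpy()
        b = expr_b.loc[shared].to_numpy()
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need at least three shared orthologues")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("constant expression vector: Spearman rho undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(1.0 - rho)


def expdist_combination(
    stage_exprs: Mapping[str, pd.Series],
    pair_selection: Sequence[tuple[str, str]],
    orthology: OrthologyMap,
) -> float:
    """Mean pairwise expression distance for one stage-per-species combination.

    ``stage_exprs`` maps species to the expression vector at its chosen
    stage; ``pair_selection`` lists the species pairs reflecting the
    phylogenetic scale of interest.
    """
    if not pair_selection:
        raise ValueError("pair selection must be non-empty")
    dists = []
    for sp_a, sp_b in pair_selection:
        table = orthology.pairs(sp_a, sp_b)
        cols = [c for c in table.columns]
        ordered = table[[sp_a, sp_b]]
        dists.append(expdist_pair(stage_exprs[sp_a], stage_exprs[sp_b], ordered))
    return float(np.mean(dists))


def _rank_columns(mat: np.ndarray) -> np.ndarray:
    """Column-wise tie-corrected ranks, z-scored for fast correlation."""
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    ranks -= ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    sd[sd == 0] = np.nan
    return ranks / sd


@dataclass
class PTopResult:
    """Per-species, per-stage P_top summary over replicate resamplings."""

    summary: pd.DataFrame  # species, stage, stage_index, mean, sd
    per_resample: pd.DataFrame  # species, stage, resample, p_top
    kept_count: int
    n_combinations: int


def p_top(
    matrices: Mapping[str, ExpressionMatrix],
    orthology: OrthologyMap,
    pair_selection: Sequence[tuple[str, str]],
    top_frac: float = 0.01,
    n_resamples: int = 100,
    seed: int = 0,
) -> PTopResult:
    """Share of most-similar stage combinations containing each stage.

    All one-stage-per-species combinations are scored by expDist; the lowest
    ``ceil(top_frac * N)`` are kept (ties resolved by combination order, i.e.
    deterministically); P_top is the percentage of kept combinations that
    include each stage.  Each of ``n_resamples`` rounds draws one whole
    biological replicate per species-stage (no within-gene mixing),
    reproducibly from ``seed``.
    """
    species = sorted(matrices)
    stage_lists = {sp: list(matrices[sp].stage_order) for sp in species}
    n_comb = math.prod(len(stage_lists[sp]) for sp in species)
    if n_comb > COMBINATION_GUARD:
        raise ValueError(
            f"{n_comb} stage combinations exceed the guard ({COMBINATION_GUARD}); "
            "subset the stages"
        )
    kept_count = math.ceil(top_frac * n_comb)
    rng = np.random.default_rng(seed)

    # pre-align orthologue row indices per selected pair
    pair_index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    gene_index = {
        sp: {g: i for i, g in enumerate(sorted(matrices[sp].data["gene_id"].unique()))}
        for sp in species
    }
    for sp_a, sp_b in pair_selection:
        tab = orthology.pairs(sp_a, sp_b)
        ia = tab[sp_a].map(gene_index[sp_a])
        ib = tab[sp_b].map(gene_index[sp_b])
        ok = ia.notna() & ib.notna()
        pair_index[(sp_a, sp_b)] = (
            ia[ok].to_numpy(dtype=int), ib[ok].to_numpy(dtype=int)
        )

    combos = list(itertools.product(*(range(len(stage_lists[sp])) for sp in species)))
    combos_arr = np.array(combos)
    records = []
    for resample in range(n_resamples):
        # one replicate per species-stage
        value_mats = {}
        for sp in species:
            genes = sorted(gene_index[sp], key=gene_index[sp].get)
            mat = np.empty((len(genes), len(stage_lists[sp])))
            for j, stage in enumerate(stage_lists[sp]):
                reps = matrices[sp].replicates(stage)
                rep = reps[int(rng.integers(len(reps)))]
                vec = matrices[sp].stage_vector(stage, rep)
                mat[:, j] = vec.reindex(genes).to_numpy()
            value_mats[sp] = mat
        # pairwise distance matrices (stages_a x stages_b) per selected pair
        dist = {}
        for (sp_a, sp_b), (ia, ib) in pair_index.items():
            za = _rank_columns(value_mats[sp_a][ia])
            zb = _rank_columns(value_mats[sp_b][ib])
            rho = za.T @ zb / za.shape[0]
            dist[(sp_a, sp_b)] = 1.0 - rho
        scores = np.zeros(n_comb)
        for (sp_a, sp_b), d in dist.items():
            a_idx = combos_arr[:, species.index(sp_a)]
            b_idx = combos_arr[:, species.index(sp_b)]
            scores += d[a_idx, b_idx]
        scores /= len(pair_index)
        kept = np.argsort(scores, kind="stable")[:kept_count]
        kept_combos = combos_arr[kept]
        for si, sp in enumerate(species):
            counts = np.bincount(kept_combos[:, si], minlength=len(stage_lists[sp]))
            for j, stage in enumerate(stage_lists[sp]):
                records.append(
                    (sp, stage, j, resample, 100.0 * counts[j] / kept_count)
                )
    per_resample = pd.DataFrame(
        records, columns=["species", "stage", "stage_index", "resample", "p_top"]
    )
    summary = (
        per_resample.groupby(["species", "stage", "stage_index"], sort=True)["p_top"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"std": "sd"})
        .sort_values(["species", "stage_index"], ignore_index=True)
    )
    return PTopResult(summary=summary, per_resample=per_resample,
                      kept_count=kept_count, n_combinations=n_comb)
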