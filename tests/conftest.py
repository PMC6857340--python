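"""Shared fixtures: small trees, synthetic datasets, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acrage import (
    SimulationConfig,
    build_sharing_profile,
    parse_tree,
    read_coverage_beds,
    run_method,
    simulate,
)
from acrage.coverage import CoverageSet
from acrage.io import read_chrom_sizes
from acrage.phylotypic import ExpressionMatrix, OrthologyMap

TREE3 = "((R:90,A:90):70,B:160);"  # reference R; categories: R, (R,A), root


@pytest.fixture(scope="session")
def tree3():
    return parse_tree(TREE3, "R")


@pytest.fixture(scope="session")
def tree5():
    # 5-leaf ladder, reference R
    return parse_tree("((((R:30,A:30):30,B:60):40,C:100):50,D:150);", "R")


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory):
    """Default study conditions (loss rate 0.12, monotone schedule)."""
    return simulate(SimulationConfig(), tmp_path_factory.mktemp("sim_default"), seed=1)


@pytest.fixture(scope="session")
def sim_noloss(tmp_path_factory):
    return simulate(
        SimulationConfig(loss_rate=0.0), tmp_path_factory.mktemp("sim_noloss"), seed=2
    )


@pytest.fixture(scope="session")
def sim_loss02(tmp_path_factory):
    return simulate(
        SimulationConfig(loss_rate=0.2), tmp_path_factory.mktemp("sim_loss02"), seed=3
    )


def load_tree_profile(sim):
    """Tree, sharing profile and planted ACR tuples from an emitted dataset."""
    cfg = sim.config
    tree = parse_tree(sim.manifest.tree_newick, cfg.reference)
    covs = read_coverage_beds(
        {sp: sim.paths[f"coverage/{sp}.bed"] for sp in cfg.species}
    )
    profile = build_sharing_profile(covs, sim.manifest.chrom_sizes)
    acr_tuples = [(a.chrom, a.start, a.end, a.acr_id) for a in sim.manifest.acrs]
    return tree, profile, acr_tuples


@pytest.fixture(scope="session")
def profiled_default(sim_default):
    return load_tree_profile(sim_default)


@pytest.fixture(scope="session")
def profiled_noloss(sim_noloss):
    return load_tree_profile(sim_noloss)


@pytest.fixture(scope="session")
def profiled_loss02(sim_loss02):
    return load_tree_profile(sim_loss02)


def make_config(sim, out_dir, **overrides):
    """RunConfig pointed at an emitted synthetic dataset."""
    from acrage import RunConfig

    cfg = sim.config
    base = dict(
        data_dir=str(sim.outdir),
        out_dir=str(out_dir),
        reference=cfg.reference,
        stages=tuple(cfg.stages),
        replicates=tuple(f"rep{i+1}" for i in range(cfg.n_replicates)),
        method="I",
        window_start_stage=1,
        seed=sim.seed,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def pipeline_default(sim_default, tmp_path_factory):
    """Full pipeline run (with the gene-age branch) on the default fixture."""
    from acrage import run_pipeline

    out = tmp_path_factory.mktemp("pipe_default")
    cfg = make_config(
        sim_default, out, run_gene_age=True,
        expression_stages=tuple(sim_default.config.expression_stages),
    )
    return run_pipeline(cfg)


# ----------------------------------------------------------------------
# brute-force oracles


def brute_force_profile(cov_by_species, length):
    """Per-base labelling oracle: list of (start, end, frozenset) segments."""
    species = sorted(cov_by_species)
    arr = np.zeros(length, dtype=np.uint32)
    for bit, sp in enumerate(species):
        for s, e in cov_by_species[sp]:
            arr[s:e] |= np.uint32(1 << bit)
    segs = []
    start = 0
    for i in range(1, length + 1):
        if i == length or arr[i] != arr[start]:
            mask = int(arr[start])
            members = frozenset(sp for b, sp in enumerate(species) if mask & (1 << b))
            segs.append((start, i, members))
            start = i
    return segs


def random_coverage_instance(rng, max_species=5, max_len=10_000):
    """One random coverage scenario for oracle comparisons."""
    length = int(rng.integers(50, max_len + 1))
    n_sp = int(rng.integers(1, max_species + 1))
    cov = {}
    for i in range(n_sp):
        n_iv = int(rng.integers(0, 8))
        ivs = []
        for _ in range(n_iv):
            s = int(rng.integers(0, length))
            e = int(rng.integers(s + 1, length + 1))
            ivs.append((s, e))
        cov[f"sp{i}"] = ivs
    return length, cov


def profile_from_instance(length, cov):
    coverages = [
        CoverageSet.from_records(sp, [("chr", s, e) for s, e in ivs])
        for sp, ivs in cov.items()
    ]
    return build_sharing_profile(coverages, {"chr": length})


def run_recovery(sim, tree, profile, acr_tuples, method):
    """Fraction of ACRs whose aged output matches the manifest expectation."""
    segs = run_method(acr_tuples, profile, tree, method)
    by_acr: dict[str, list] = {}
    for g in segs:
        by_acr.setdefault(g.acr_id, []).append(g)
    n_ok = 0
    acrs = sim.manifest.acrs
    for a in acrs:
        exp = sim.manifest.expected_methods[a.acr_id][method]
        got = sorted(by_acr.get(a.acr_id, []), key=lambda g: g.start)
        if method in ("I", "II"):
            pred = [(g.start, g.end, g.category.rank, g.status) for g in got]
            want = [(p["start"], p["end"], p["rank"], p["status"]) for p in exp]
            n_ok += pred == want
        else:
            if exp is None:
                n_ok += len(got) == 0
            else:
                n_ok += (
                    len(got) == 1
                    and got[0].category.rank == exp["rank"]
                    and got[0].status == exp["status"]
                )
    return n_ok / len(acrs)


# ----------------------------------------------------------------------
# expression helpers


def expression_inputs(tables, orthology, stage_order):
    """Wrap generator output into p_top inputs."""
    matrices = {
        sp: ExpressionMatrix(sp, tab, tuple(stage_order)) for sp, tab in tables.items()
    }
    orth = OrthologyMap(orthology)
    species = sorted(tables)
    pair_selection = [(a, b) for i, a in enumerate(species) for b in species[i + 1:]]
    return matrices, orth, pair_selection
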