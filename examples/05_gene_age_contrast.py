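"""Gene-level negative control: reuse of old genes hides recapitulation.

On the same simulated dataset, the ACR-level analysis recovers the planted
recapitulative ordering (tau = 1), while the gene-level analysis - ages from
a homolog presence/absence matrix, percentages of summed FPKM per category -
does not, because a configurable share of evolutionarily old genes is
re-deployed at late stages.
"""

import tempfile

import pandas as pd

from acrage import (
    RunConfig,
    SimulationConfig,
    gene_ages,
    parse_tree,
    recap_concordance,
    relative_expression_table,
    run_pipeline,
    simulate,
)

with tempfile.TemporaryDirectory() as tmp:
    config = SimulationConfig()  # reuse_rate = 0.5 by default
    sim = simulate(config, f"{tmp}/data", seed=3)
    tree = parse_tree(sim.manifest.tree_newick, config.reference)

    # ACR level
    run = RunConfig(
        data_dir=f"{tmp}/data", out_dir=f"{tmp}/out",
        reference=config.reference, stages=config.stages,
        replicates=tuple(f"rep{i+1}" for i in range(config.n_replicates)),
        method="I", window_start_stage=1, seed=3,
    )
    acr_tau = run_pipeline(run).concordance.tau

    # gene level: ages from homolog presence, excluding secondary losses
    presence = pd.read_csv(sim.paths["presence.tsv"], sep="\t", index_col=0)
    ages = gene_ages(presence, tree, exclude_secondary_loss=True)
    expr = pd.read_csv(sim.paths["expression/ref.tsv"], sep="\t",
                       dtype={"stage": str, "replicate": str})
    table = relative_expression_table(expr, ages, config.expression_stages)
    gene_tau = recap_concordance(table, window_start_stage=0, seed=3).tau

    print(f"ACR-level Kendall tau : {acr_tau:.3f}")
    print(f"gene-level Kendall tau: {gene_tau:.3f}")
    print(f"\n{int((~ages['excluded']).sum())} genes aged "
          f"({int(ages['excluded'].sum())} excluded as secondarily lost); "
          f"reuse rate {config.reuse_rate}")

# The gap between the two taus is the point: regulatory elements carry a
# cleaner evolutionary signal of activation order than protein-coding genes,
# which are recruited repeatedly in different developmental contexts.
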