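"""End-to-end run: simulate a planted dataset, run the pipeline, print stats.

The generator plants a monotone age-to-stage schedule (younger age
categories peak at later developmental stages).  The pipeline rebuilds
everything from the emitted files - coverage BEDs, peak sets, raw read ends -
and should recover the planted order exactly: Kendall tau = 1 between
category youngness and peak stage, with significant stage effects
(Kruskal-Wallis, BH-adjusted) for every category.
"""

import tempfile

from acrage import RunConfig, SimulationConfig, run_pipeline, simulate

with tempfile.TemporaryDirectory() as tmp:
    config = SimulationConfig()  # default study conditions
    sim = simulate(config, f"{tmp}/data", seed=1)
    print(f"simulated {len(sim.manifest.segments)} genomic segments, "
          f"{len(sim.manifest.acrs)} ACRs, "
          f"{len(config.stages)} stages x {config.n_replicates} replicates")

    run = RunConfig(
        data_dir=f"{tmp}/data",
        out_dir=f"{tmp}/out",
        reference=config.reference,
        stages=config.stages,
        replicates=tuple(f"rep{i+1}" for i in range(config.n_replicates)),
        method="I",            # subdivide by origin, strict conservation only
        window_start_stage=1,  # phylotypic stage: the recapitulation window
        seed=1,
    )
    result = run_pipeline(run)

    print("\nper-category peak stages (rank 0 = youngest):")
    print(result.peaks.to_string(index=False))
    print(f"\nKendall tau (youngness vs peak stage): {result.concordance.tau:.3f} "
          f"(p = {result.concordance.p_value:.2e}, {result.concordance.method})")
    print(f"categories with BH-adjusted stage effect p < 0.05: "
          f"{int(result.kw['significant'].sum())}/{len(result.kw)}")
    frips = list(result.frip_by_sample.values())
    print(f"FRiP range across samples: {min(frips):.3f}-{max(frips):.3f} "
          "(> 0.2 is acceptable)")

# tau = 1 means the planted recapitulative ordering was recovered perfectly:
# each younger category attains its maximum relative signal at a strictly
# later stage.
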