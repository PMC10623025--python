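"""Bayesian track: bivariate animal-model Gibbs sampler and posterior summary.

Runs a short AFC/FSP chain on a synthetic herd (pedigree A-inverse, period +
season fixed effects), then prints the Table-style posterior summary of the
derived genetic parameters: heritabilities and the genetic/phenotypic
correlations, each with mean/mode/median/SD/HPD/ESS/MCE/Geweke.
"""

import numpy as np

from herdvar import (
    ChainConfig,
    ModelSpec,
    SimulationParams,
    build_A_inverse,
    build_design,
    derive_parameters,
    renumber_pedigree,
    run_chain,
    simulate_herd,
)
from herdvar.io import summaries_to_frame

params = SimulationParams(traits=("AFC", "FSP"), seed=1)
pedigree, phenotypes = simulate_herd(params)
ped = renumber_pedigree(pedigree)
codes_map = {a: i for i, a in enumerate(ped.original_id)}
phenotypes["animal_code"] = phenotypes["animal"].map(codes_map)

design = build_design(ModelSpec(responses=("AFC", "FSP"), covariate=None), phenotypes)
codes = phenotypes["animal_code"].to_numpy(np.int64)[design.rows]

samples = run_chain(
    design.y, design.X, codes, build_A_inverse(ped),
    config=ChainConfig(total_iterations=4_000, burn_in=500, thinning=5, seed=2),
    traits=("AFC", "FSP"),
)
print(f"stored draws: {samples.n_stored} (=(4000-500)/5)")

derived = derive_parameters(samples)
table = summaries_to_frame(derived["summaries"])
keep = table.parameter.str.startswith(("h2", "r_"))
print(table[keep].round(3).to_string(index=False))
print(
    "\nh2 near 0.5-0.6 and a positive r_g reflect the simulated architecture; "
    "ESS below the stored count shows chain autocorrelation, and MCE = "
    "SD/sqrt(ESS) is the Monte-Carlo error of each posterior mean."
)
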