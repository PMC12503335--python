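"""Mean expression per gene type across a continuum of supercoiling shifts.

Sweeps the environmental supercoiling perturbation from -0.02 to +0.02 for an
evolved genome and prints the per-type response next to the neighbor-less
baseline, exposing genes whose expression *rises* under DNA relaxation.
"""

import warnings

import numpy as np

import tscevo as tv

warnings.simplefilter("ignore", tv.ConvergenceWarning)

params = tv.SimulationParams()
log, pop = tv.run_replicate(seed=12, params=params, n_generations=600)
reports = [tv.evaluate(g, params) for g in pop.individuals]
best = pop.individuals[int(np.argmax([r.fitness for r in reports]))]

grid = np.arange(-0.02, 0.0201, 0.005)
df = tv.environment_sweep(best, params, grid, n_random_baseline=5)

wide = df.pivot(index="delta_sigma_env", columns="series", values="mean_expression")
print(wide[["A", "B", "AB", "isolated", "random"]].round(3).to_string())

# The isolated-gene baseline decreases monotonically as DNA relaxes (shift
# increasing). A-type genes must be ON in the relaxed environment (+0.01) yet
# OFF in the negatively supercoiled one (-0.01): when that pattern evolves,
# their mean response becomes non-monotonic — activation by DNA relaxation,
# produced purely by gene arrangement.
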