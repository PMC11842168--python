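"""Model migration success over the simulation grid with a binomial GLM.

Fits per-path success against basin shape, step length and turning-angle
sigma (logit link), tests the sigma term by likelihood ratio, reports odds
ratios, and compares passage-time distributions between basins with
Kruskal-Wallis + Dunn (Holm-adjusted).

Run:  python examples/05_success_glm.py
"""

import numpy as np

from lakewalk import (
    fit_success_glm,
    hypothetical_design,
    kruskal_dunn,
    lrt,
    paths_frame,
    run_grid,
)

design = hypothetical_design(seed=5, n_per_cell=30)
cells, paths = run_grid(design, return_paths=True)
records = paths_frame(paths)

full = fit_success_glm(records, "success ~ basin + step_length_m + turn_sd_deg")
nested = fit_success_glm(records, "success ~ basin + step_length_m")
test = lrt(nested, full)

print(f"binomial GLM on {full.n_obs} simulated paths: {full.formula}\n")
print(full.odds_ratios.round(4).to_string())
print(f"\nLRT for the turning-angle term: 2dLL = {test.statistic:.1f}, "
      f"df = {test.df}, p = {test.p_value:.2g}")
or_sigma = full.odds_ratios.loc["turn_sd_deg", "odds_ratio"]
print(f"Each extra degree of turning-angle sigma multiplies the odds of a")
print(f"successful crossing by {or_sigma:.3f} — wider turning hurts.\n")

samples = {
    b: np.concatenate(
        [c.passage_times for c in cells if c.basin == b and c.passage_times.size]
    )
    for b in ("circular", "elliptical", "rectangular")
}
omnibus, pairs = kruskal_dunn(samples)
print(f"passage times, Kruskal-Wallis: H = {omnibus.statistic:.1f}, "
      f"p = {omnibus.p_value:.2g}")
for p in pairs:
    print(f"  Dunn {p.groups[0]}-{p.groups[1]}: Z = {p.statistic:+.2f}, "
          f"Holm-adjusted p = {p.adjusted_p:.2g}")
print("\nSuccessful crossings of the rectangular basin take longer — the")
print("same random search covers more water before finding a lateral outlet.")
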