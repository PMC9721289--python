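"""Forward-prediction validation of the metafounder models.

Removes the last four years of records, predicts with the reduced data,
and regresses full-data daughter yield deviations (bulls) on the
reduced-data [G]EBV.  A doubled slope (b1) near 1 means no
over/under-prediction; the adjusted reliability is the weighted R^2
divided by the mean regression weight.
"""

from metablup.gamma import GammaMatrix, bend_gamma
from metablup.mme import ModelSpec
from metablup.simulate import SimulationConfig, simulate_all
from metablup.validation import forward_validation

cfg = SimulationConfig(seed=3, sires_per_cell=25, offspring_per_generation=400)
data = simulate_all(cfg)
gamma = bend_gamma(GammaMatrix(data.truth.gamma_true,
                               list(range(1, 5)), provenance="extrapolated"))
print(f"{data.pedigree.n} animals, {len(data.phenotypes)} records, "
      f"cutoff = last 4 record years\n")
print(f"{'model':<6} {'role':<5} {'n':>4} {'b1':>6} {'R2':>6} {'adj.rel':>8}")
for mt in ("ssmf", "pmf"):
    spec = ModelSpec(traits=["trait1"], fixed_factors=["herd", "year", "season"],
                     model_type=mt, G0=cfg.G0(), R0=data.truth.R0_used)
    for role in ("bull", "cow"):
        r = forward_validation(spec, data.pedigree, data.groups,
                               data.phenotypes, panel=data.panel, gamma=gamma,
                               cutoff_years=4, role=role, min_daughters=3)[0]
        print(f"{mt:<6} {role:<5} {r.n:>4} {r.b1:>6.2f} {r.r2:>6.3f} "
              f"{r.adjusted_reliability:>8.3f}")
# b1 fluctuates around 1 on unselected data; the single-step model's
# adjusted reliability exceeds the pedigree model's because marker data
# sharpen the predictions of young validation animals.
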