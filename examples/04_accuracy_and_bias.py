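"""Empirical accuracy and bias of genomic predictions on a masked test set.

Breeding values are predicted for test individuals whose phenotypes were
withheld from the REML fit.  Accuracy is the residual correlation between
EBV and phenotype (both adjusted for sex and hatch week within the test
set) divided by sqrt(h2); bias is the regression of phenotype on EBV,
with 1 meaning EBV differences predict phenotypic differences without
over- or under-dispersion.  The deterministic predictor lambda = m/(m+k)
is printed for comparison with the empirical profile peak.
"""

import gblend as gb

config = gb.SimulationConfig(
    n_founders=100, n_generations=4, n_sires_per_gen=12, n_dams_per_gen=40,
    offspring_per_dam=4, n_chromosomes=3, markers_per_chromosome=200,
    n_qtl=120, hatch_week_levels=4, seed=1,
)
pop = gb.simulate_population(config)
subset = gb.split_trn_tst(pop.pedigree, 0.6, seed=2)
phen = pop.phenotypes.copy()
phen["subset"] = subset.loc[phen["id"]].to_numpy()
trn = phen.loc[phen["subset"] == "TRN"]

A = gb.build_A(pop.pedigree)
GLD = gb.build_GLD(pop.marker_genotypes())

h2_ped = gb.reml_fit(trn, A).h2
print(f"pedigree REML h2 on TRN (used to scale accuracy): {h2_ped:.3f}")

for lam in (0.0, 0.5, 1.0):
    M = gb.blend(GLD, A, lam)
    fit = gb.reml_fit(trn, M)
    ebv = gb.predict_ebv(fit, M)
    res = gb.evaluate_predictions(ebv, phen, h2_ped)
    print(f"lambda = {lam:.1f}: accuracy = {res.empirical_accuracy:.3f}, "
          f"bias = {res.bias_coefficient:.2f} (SE {res.bias_se:.2f}), "
          f"n_tst = {res.n_tst}")

m = GLD.provenance["m"]
for k, label in ((50, "k = 50 (VanRaden)"), (7800, "k = M_e = 7,800 (Goddard)")):
    lam = gb.predict_lambda_theory(gb.TheoryParams(m=m, k=k))
    print(f"theory lambda with m = {m}, {label}: {lam:.3f}")
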