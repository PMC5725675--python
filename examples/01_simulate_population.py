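"""Simulate a pedigreed broiler-like population and inspect its structure.

A six-generation pedigree is grown from a founder base; genomes recombine
down the pedigree under the Haldane model and a polygenic trait with
h2 ~ 0.34 (V_A = 54.94, V_E = 104.54) is laid on top, with sex and
hatch-week fixed effects.  The defaults mirror a commercial female-parent
broiler line: ~16 offspring per sire, ~5 per dam.
"""

import numpy as np

import gblend as gb

# a reduced edition of the default design, for a fast demonstration
config = gb.SimulationConfig(
    n_founders=120, n_generations=4, n_sires_per_gen=14, n_dams_per_gen=48,
    offspring_per_dam=4, n_chromosomes=3, markers_per_chromosome=200,
    n_qtl=100, hatch_week_levels=6, seed=42,
)
pop = gb.simulate_population(config)
ped = pop.pedigree

counts = ped.offspring_counts()
sires = counts.loc[counts["as_sire"] > 0, "as_sire"]
dams = counts.loc[counts["as_dam"] > 0, "as_dam"]
print(f"individuals: {ped.n} over {config.n_generations} generations "
      f"({int(ped.is_founder.sum())} founders)")
print(f"mean offspring per sire: {sires.mean():.1f}, per dam: {dams.mean():.1f}")

founders = np.flatnonzero(ped.is_founder)
print(f"founder breeding-value variance: {np.var(pop.true_bv[founders], ddof=1):.2f} "
      f"(target V_A = {config.V_A})")

# realized heritability: BV variance over phenotypic variance net of fixed effects
resid = pop.phenotypes["bwt"] - pop.phenotypes["bwt"].mean()
h2 = np.var(pop.true_bv, ddof=1) / (np.var(pop.true_bv, ddof=1) + config.V_E)
print(f"realized h2 (BV variance / (BV variance + V_E)): {h2:.3f}")

subset = gb.split_trn_tst(ped, fraction_trn=0.6, seed=43)
n = subset.value_counts()
print(f"training/testing split: {n['TRN']} TRN, {n['TST']} TST "
      "(no TST individual has offspring in TRN)")
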