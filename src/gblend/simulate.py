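"""Synthetic pedigreed populations with recombining genomes.

The generator emulates the data structure of a closed broiler breeding
line: a base population of ~288 founders, six discrete generations with a
limited number of sires and dams per generation, a dense biallelic SNP map
on multiple chromosomes, and a largely polygenic body-weight-like trait
(h2 ~ 0.35) with fixed effects of sex and hatch week.  Founder alleles
carry unique origin labels, so realized identity-by-descent is known
exactly and downstream relationship-matrix estimators can be tested
against the simulation truth.

Meiosis follows the Haldane model: crossovers form a Poisson process along
the genetic map (no interference), and the starting parental haplotype of
each gamete is chosen uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_pedigree",
    "drop_genomes",
    "simulate_trait",
    "simulate_population",
    "true_ibd_matrix",
    "split_trn_tst",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic population.

    Defaults mirror the structure of the source dataset: 288 founders,
    6 generations, ~16 offspring per sire and ~5 per dam (64 sires and
    205 dams bred per generation), giving ~5,400 individuals in total.
    Trait variances default to the pedigree-model estimates V_A = 54.94,
    V_E = 104.54 (h2 ~ 0.34) in arbitrary body-weight units.
    """

    n_founders: int = 288
    n_generations: int = 6
    n_sires_per_gen: int = 64
    n_dams_per_gen: int = 205
    offspring_per_dam: int = 5
    n_chromosomes: int = 10
    markers_per_chromosome: int = 500
    map_length_cM: float = 100.0
    founder_maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 500
    qtl_on_panel: bool = False
    female_fraction: float = 0.75
    V_A: float = 54.94
    V_E: float = 104.54
    sex_effect: float = 10.0
    hatch_week_levels: int = 32
    hatch_week_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_founders=self.n_founders,
            n_generations=self.n_generations,
            n_sires_per_gen=self.n_sires_per_gen,
            n_dams_per_gen=self.n_dams_per_gen,
            offspring_per_dam=self.offspring_per_dam,
            n_chromosomes=self.n_chromosomes,
            markers_per_chromosome=self.markers_per_chromosome,
            hatch_week_levels=self.hatch_week_levels,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.map_length_cM <= 0:
            raise ValueError("map_length_cM must be > 0")
        if self.V_A < 0:
            raise ValueError("V_A must be >= 0")
        if self.V_E <= 0:
            raise ValueError("V_E must be > 0")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 < self.female_fraction < 1.0):
            raise ValueError("female_fraction must be in (0, 1)")
        if self.n_qtl > self.n_chromosomes * self.markers_per_chromosome:
            raise ValueError("n_qtl exceeds total locus count")

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass
class SimulatedPopulation:
    """Truth store for one simulated population.

    ``haplotypes`` has shape (n, 2, L): axis 1 is (paternal, maternal).
    ``founder_origin`` has the same shape and holds the founder-gamete
    label (2*founder_index + haplotype) each allele descends from.
    """

    pedigree: Pedigree
    config: SimulationConfig
    haplotypes: np.ndarray
    founder_origin: np.ndarray
    loci: pd.DataFrame  # marker, chrom, cM, bp, founder_freq, is_qtl
    true_bv: np.ndarray | None = None
    phenotypes: pd.DataFrame | None = None
    qtl_effects: np.ndarray | None = None

    def marker_genotypes(self, include_qtl: bool | None = None) -> GenotypeMatrix:
        """Allele-count matrix over the marker panel loci.

        QTL loci are excluded unless ``config.qtl_on_panel`` (or the
        explicit override) says otherwise, so LD-based matrices must work
        through linkage disequilibrium rather than causal genotypes.
        """
        if include_qtl is None:
            include_qtl = self.config.qtl_on_panel
        keep = np.ones(len(self.loci), dtype=bool)
        if not include_qtl and "is_qtl" in self.loci.columns:
            keep = ~self.loci["is_qtl"].to_numpy()
        counts = self.haplotypes[:, :, keep].sum(axis=1).astype(np.int8)
        markers = self.loci.loc[keep, ["marker", "chrom", "cM", "bp"]]
        return GenotypeMatrix(self.pedigree.ids, counts, markers)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_pedigree(config: SimulationConfig, seed: int | None = None) -> Pedigree:
    """Random-mating multi-generation pedigree.

    Each generation's sires and dams are sampled without replacement from
    the previous generation; every dam is mated to one randomly chosen
    sire and produces ``offspring_per_dam`` offspring.  Hatch weeks are
    contemporary groups nested within generation.
    """
    rng = _rng(config.seed if seed is None else seed)
    rows = []
    next_id = 1
    prev_ids: np.ndarray = np.array([], dtype=np.int64)
    prev_sex: np.ndarray = np.array([], dtype="U1")
    L = config.hatch_week_levels
    for g in range(config.n_generations):
        if g == 0:
            n_off = config.n_founders
            sire_of = np.zeros(n_off, dtype=np.int64)
            dam_of = np.zeros(n_off, dtype=np.int64)
        else:
            males = prev_ids[prev_sex == "M"]
            females = prev_ids[prev_sex == "F"]
            if len(males) < config.n_sires_per_gen:
                raise ValueError(
                    f"generation {g}: only {len(males)} candidate sires, "
                    f"need {config.n_sires_per_gen}"
                )
            if len(females) < config.n_dams_per_gen:
                raise ValueError(
                    f"generation {g}: only {len(females)} candidate dams, "
                    f"need {config.n_dams_per_gen}"
                )
            sires = rng.choice(males, size=config.n_sires_per_gen, replace=False)
            dams = rng.choice(females, size=config.n_dams_per_gen, replace=False)
            # balanced allocation: every sire serves ~equal numbers of dams
            mate = rng.permutation(np.resize(np.arange(len(sires)), len(dams)))
            dam_of = np.repeat(dams, config.offspring_per_dam)
            sire_of = np.repeat(sires[mate], config.offspring_per_dam)
            n_off = len(dam_of)
        ids = np.arange(next_id, next_id + n_off, dtype=np.int64)
        next_id += n_off
        # deterministic sex counts (female-parent line: mostly females),
        # clamped so the next generation can always draw its parents
        n_female = int(round(config.female_fraction * n_off))
        if g < config.n_generations - 1:
            if n_off < config.n_sires_per_gen + config.n_dams_per_gen:
                raise ValueError(
                    f"generation {g} has {n_off} individuals, fewer than "
                    f"{config.n_sires_per_gen} sires + "
                    f"{config.n_dams_per_gen} dams needed next"
                )
            n_female = min(
                max(n_female, config.n_dams_per_gen),
                n_off - config.n_sires_per_gen,
            )
        sex = np.full(n_off, "M", dtype="U1")
        sex[rng.permutation(n_off)[:n_female]] = "F"
        hw = g * L + rng.integers(0, L, size=n_off)
        for k in range(n_off):
            rows.append((ids[k], sire_of[k], dam_of[k], sex[k], g, hw[k]))
        prev_ids, prev_sex = ids, sex
    table = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "generation", "hatch_week"]
    )
    return Pedigree(table)


def _marker_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Irregularly spaced marker map: uniform positions on each chromosome."""
    frames = []
    for c in range(config.n_chromosomes):
        m = config.markers_per_chromosome
        cm = np.sort(rng.uniform(0.0, config.map_length_cM, size=m))
        bp = np.maximum(1, np.round(cm * 1e6).astype(np.int64))
        bp = np.maximum.accumulate(bp) + np.arange(m)  # strictly increasing
        frames.append(
            pd.DataFrame(
                {
                    "marker": [f"snp{c + 1}_{j + 1}" for j in range(m)],
                    "chrom": c + 1,
                    "cM": cm,
                    "bp": bp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _meiosis_parity(
    rng: np.random.Generator, n_gametes: int, d_morgan: np.ndarray
) -> np.ndarray:
    """Which parental haplotype (0/1) each gamete carries at each locus.

    ``d_morgan`` holds adjacent-locus map distances within one chromosome;
    crossover counts per interval are independent Poisson (Haldane).
    """
    L = len(d_morgan) + 1
    start = rng.integers(0, 2, size=(n_gametes, 1))
    if L == 1:
        return start.astype(np.int8)
    crossings = rng.poisson(d_morgan[None, :], size=(n_gametes, L - 1))
    cum = np.concatenate(
        [np.zeros((n_gametes, 1), dtype=np.int64), np.cumsum(crossings, axis=1)],
        axis=1,
    )
    return ((start + cum) % 2).astype(np.int8)


def drop_genomes(
    pedigree: Pedigree, config: SimulationConfig, seed: int | None = None
) -> SimulatedPopulation:
    """Gene-drop haplotypes and founder-origin labels down the pedigree."""
    rng = _rng(config.seed if seed is None else seed)
    loci = _marker_map(config, rng)
    n, L = pedigree.n, len(loci)
    hap = np.zeros((n, 2, L), dtype=np.int8)
    origin = np.zeros((n, 2, L), dtype=np.int32)

    p = rng.uniform(*config.founder_maf_range, size=L)
    flip = rng.random(L) < 0.5  # A1 is not systematically the minor allele
    p = np.where(flip, 1.0 - p, p)
    loci = loci.assign(founder_freq=p)

    founders = np.flatnonzero(pedigree.is_founder)
    hap[founders] = (
        rng.random((len(founders), 2, L)) < p[None, None, :]
    ).astype(np.int8)
    for h in (0, 1):
        origin[founders, h, :] = (2 * founders + h)[:, None]

    chrom_slices = [
        np.flatnonzero(loci["chrom"].to_numpy() == c)
        for c in sorted(loci["chrom"].unique())
    ]
    d_morgans = [
        np.diff(loci["cM"].to_numpy()[sl]) / 100.0 for sl in chrom_slices
    ]

    gens = pedigree.table["generation"].to_numpy()
    for g in sorted(np.unique(gens)):
        off = np.flatnonzero((gens == g) & ~pedigree.is_founder)
        if len(off) == 0:
            continue
        for side, parents in ((0, pedigree.sire_idx[off]), (1, pedigree.dam_idx[off])):
            for sl, dm in zip(chrom_slices, d_morgans):
                parity = _meiosis_parity(rng, len(off), dm)
                ph = hap[parents][:, :, sl]
                po = origin[parents][:, :, sl]
                sel = parity[:, None, :].astype(np.int64)
                hap[off[:, None], side, sl[None, :]] = np.take_along_axis(
                    ph, sel, axis=1
                )[:, 0, :]
                origin[off[:, None], side, sl[None, :]] = np.take_along_axis(
                    po, sel, axis=1
                )[:, 0, :]
    return SimulatedPopulation(pedigree, config, hap, origin, loci)


def simulate_trait(
    population: SimulatedPopulation,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Polygenic trait: QTL effects rescaled to hit V_A exactly in founders.

    Phenotype = sex effect + hatch-week effect + true BV + N(0, V_E)
    residual.  QTL are a random subset of simulated loci; with the default
    ``qtl_on_panel=False`` they are excluded from the marker panel.
    Updates ``population`` in place and returns the phenotype table.
    """
    config = population.config if config is None else config
    rng = _rng(config.seed + 1 if seed is None else seed)
    ped = population.pedigree
    n, L = ped.n, len(population.loci)

    if config.V_A > 0 and config.n_qtl == 0:
        raise ValueError("V_A > 0 requires n_qtl >= 1")

    qtl = np.sort(rng.choice(L, size=config.n_qtl, replace=False))
    is_qtl = np.zeros(L, dtype=bool)
    is_qtl[qtl] = True
    population.loci = population.loci.assign(is_qtl=is_qtl)

    if config.V_A == 0:
        effects = np.zeros(config.n_qtl)
        bv = np.zeros(n)
    else:
        effects = rng.normal(0.0, 1.0, size=config.n_qtl)
        counts = population.haplotypes[:, :, qtl].sum(axis=1)
        raw = counts @ effects
        founders = np.flatnonzero(ped.is_founder)
        sd = np.std(raw[founders], ddof=1)
        if sd == 0:
            raise ValueError("founder breeding values degenerate; add QTL or founders")
        scale = np.sqrt(config.V_A) / sd
        effects *= scale
        bv = raw * scale
        bv -= bv[founders].mean()

    hw_codes, hw_levels = pd.factorize(ped.table["hatch_week"])
    hw_effects = rng.normal(0.0, config.hatch_week_sd, size=len(hw_levels))
    sex = ped.table["sex"].to_numpy()
    y = (
        np.where(sex == "M", config.sex_effect, 0.0)
        + hw_effects[hw_codes]
        + bv
        + rng.normal(0.0, np.sqrt(config.V_E), size=n)
    )
    phen = pd.DataFrame(
        {
            "id": ped.ids,
            "bwt": y,
            "sex": sex,
            "hatch_week": ped.table["hatch_week"].to_numpy(),
            "subset": "",
        }
    )
    population.true_bv = bv
    population.qtl_effects = effects
    population.phenotypes = phen
    return phen


def simulate_population(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedPopulation:
    """Pedigree + gene drop + trait in one call (single seed stream)."""
    base = config.seed if seed is None else seed
    ped = simulate_pedigree(config, seed=base)
    pop = drop_genomes(ped, config, seed=base + 1)
    simulate_trait(pop, config, seed=base + 2)
    return pop


def true_ibd_matrix(
    population: SimulatedPopulation, loci: np.ndarray | None = None
) -> RelationshipMatrix:
    """Realized IBD relationships from founder-origin labels.

    Entry (i, j) is the mean over loci of half the number of ordered
    allele pairs sharing a founder-gamete label, so the diagonal is
    1 + realized inbreeding and a non-inbred parent-offspring pair is
    exactly 0.5 at every locus.
    """
    org = population.founder_origin
    if loci is not None:
        org = org[:, :, loci]
    n, _, L = org.shape
    G = np.zeros((n, n))
    chunk = max(1, int(2e8 // max(1, n * n)))
    for a in (0, 1):
        for b in (0, 1):
            for s in range(0, L, chunk):
                sl = slice(s, min(L, s + chunk))
                eq = org[:, a, sl][:, None, :] == org[:, b, sl][None, :, :]
                G += eq.sum(axis=2)
    G /= 2.0 * L
    return RelationshipMatrix(population.pedigree.ids, G, "trueIBD")


def split_trn_tst(
    pedigree: Pedigree, fraction_trn: float = 3146 / 5416, seed: int = 0
) -> pd.Series:
    """Training/testing partition honouring the validation design.

    Test individuals are drawn from the youngest generations upward and
    never have an offspring in the training set: an individual can enter
    TST only if all of its offspring are already in TST.  Returns a Series
    of ``"TRN"``/``"TST"`` indexed by individual id.
    """
    if not (0.0 < fraction_trn <= 1.0):
        raise ValueError("fraction_trn must be in (0, 1]")
    n = pedigree.n
    n_tst = int(round((1.0 - fraction_trn) * n))
    labels = np.full(n, "TRN", dtype="U3")
    if n_tst == 0:
        return pd.Series(labels, index=pedigree.ids, name="subset")
    gens = pedigree.table["generation"].to_numpy()
    if len(np.unique(gens)) < 2:
        raise ValueError("need >= 2 generations to form a TST set")
    has_trn_offspring = np.zeros(n, dtype=bool)
    # offspring are always younger; scanning generations downward means a
    # child's label is fixed before its parents are considered
    rng = _rng(seed)
    remaining = n_tst
    for g in sorted(np.unique(gens), reverse=True):
        members = np.flatnonzero(gens == g)
        rng.shuffle(members)
        for i in members:
            if remaining == 0:
                break
            if has_trn_offspring[i]:
                continue
            labels[i] = "TST"
            remaining -= 1
        # propagate: anyone in this generation labelled TRN blocks parents
        for i in members:
            if labels[i] == "TRN":
                for p in (pedigree.sire_idx[i], pedigree.dam_idx[i]):
                    if p >= 0:
                        has_trn_offspring[p] = True
        if remaining == 0:
            break
    if remaining > 0:
        raise ValueError(
            f"cannot place {n_tst} individuals in TST without giving a TST "
            f"individual a TRN offspring ({remaining} short)"
        )
    return pd.Series(labels, index=pedigree.ids, name="subset")
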