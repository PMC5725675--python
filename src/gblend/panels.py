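"""Marker quality control and in-silico chip construction.

Two chips of equal density per chromosome are built from the post-QC
markers: an evenly spaced chip (ESM) chosen on genetic-map spacing with a
preference for high minor allele frequency, and a GWA chip (GWAM) made of
the top single-marker association hits per chromosome, ranked on P value
irrespective of genome-wide significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "ChipPanel",
    "hwe_test",
    "qc_filter",
    "run_gwa",
    "select_esm_panel",
    "select_gwam_panel",
]


@dataclass
class QcThresholds:
    """Per-marker rejection rules: HWE P <= hwe_p_max, call rate <=
    completeness_min, MAF < maf_min."""

    hwe_p_max: float = 0.001
    completeness_min: float = 0.95
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("hwe_p_max", "completeness_min", "maf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QcReport:
    """Overlapping per-criterion failure counts, as in a rejection table."""

    n_input: int
    n_fail_hwe: int
    n_fail_completeness: int
    n_fail_maf: int
    n_removed: int
    n_remaining: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ChipPanel:
    """Ordered marker list of one in-silico chip."""

    markers: list
    design: str  # "ESM" or "GWAM"
    per_chromosome: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("panel markers must be unique")

    @property
    def size(self) -> int:
        return len(self.markers)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square goodness-of-fit P value against HWE proportions.

    Expectations use the sample allele frequency; monomorphic samples
    return P = 1 (no departure is testable).
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(counts: np.ndarray) -> np.ndarray:
    """Vectorized HWE chi-square P per marker (missing calls ignored)."""
    nAA = (counts == 2).sum(axis=0).astype(float)
    nAa = (counts == 1).sum(axis=0).astype(float)
    naa = (counts == 0).sum(axis=0).astype(float)
    n = nAA + nAa + naa
    n = np.maximum(n, 1)
    p = (2 * nAA + nAa) / (2 * n)
    q = 1 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            (nAA - n * p * p) ** 2 / (n * p * p)
            + (nAa - 2 * n * p * q) ** 2 / (2 * n * p * q)
            + (naa - n * q * q) ** 2 / (n * q * q)
        )
    pv = stats.chi2.sf(chi2, df=1)
    return np.where((p == 0) | (p == 1), 1.0, pv)


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers failing any criterion; individuals are never removed.

    The report tallies failures per criterion with overlap (a marker
    failing two rules is counted in both tallies but removed once).
    """
    thresholds = thresholds or QcThresholds()
    pv = _hwe_pvalues(genotypes.counts)
    fail_hwe = (pv <= thresholds.hwe_p_max) if thresholds.hwe_p_max > 0 else np.zeros(
        genotypes.n_markers, dtype=bool
    )
    fail_call = genotypes.call_rate() <= thresholds.completeness_min
    if thresholds.completeness_min == 0:
        fail_call &= False
    fail_maf = genotypes.maf() < thresholds.maf_min
    removed = fail_hwe | fail_call | fail_maf
    report = QcReport(
        n_input=genotypes.n_markers,
        n_fail_hwe=int(fail_hwe.sum()),
        n_fail_completeness=int(fail_call.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_removed=int(removed.sum()),
        n_remaining=int((~removed).sum()),
    )
    if report.n_remaining == 0:
        warnings.warn("QC removed every marker", stacklevel=2)
    out = GenotypeMatrix(
        genotypes.ids,
        genotypes.counts[:, ~removed],
        genotypes.markers.loc[~removed],
    )
    return out, report


def run_gwa(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    fixed: tuple[str, ...] = ("sex", "hatch_week"),
    response: str = "bwt",
) -> pd.DataFrame:
    """Single-marker fixed linear model per marker, training set only.

    Phenotype is regressed on allele count with sex and hatch-week
    covariates; by Frisch-Waugh the marker coefficient equals the slope
    between covariate-residualized phenotype and covariate-residualized
    allele count, which is computed vectorized across markers.  Returns a
    DataFrame (marker, chrom, cM, bp, maf, beta, t, p).
    """
    from .mixedmodel import design_matrix

    if "subset" in phenotypes.columns and (phenotypes["subset"] == "TST").any():
        phenotypes = phenotypes.loc[phenotypes["subset"] != "TST"]
    phen = phenotypes.reset_index(drop=True)
    idx = pd.Index(genotypes.ids).get_indexer(pd.Index(phen["id"]))
    if (idx < 0).any():
        raise KeyError("phenotyped ids missing from genotype matrix")
    counts = genotypes.counts[idx].astype(float)
    miss = counts < 0
    if miss.any():
        colmean = np.where(
            miss, 0.0, counts
        ).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
        counts = np.where(miss, colmean[None, :], counts)
    y = phen[response].to_numpy(dtype=float)
    X, _ = design_matrix(phen, fixed)
    n, p = X.shape
    dof = n - p - 1
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom for GWA")
    # project out the covariates
    Q, _ = np.linalg.qr(X)
    ry = y - Q @ (Q.T @ y)
    rg = counts - Q @ (Q.T @ counts)
    sxx = (rg**2).sum(axis=0)
    sxy = rg.T @ ry
    poly = sxx > 1e-12
    beta = np.zeros(genotypes.n_markers)
    tstat = np.zeros(genotypes.n_markers)
    pval = np.ones(genotypes.n_markers)
    beta[poly] = sxy[poly] / sxx[poly]
    rss = (ry**2).sum() - beta[poly] ** 2 * sxx[poly]
    rss = np.maximum(rss, 1e-300)
    se = np.sqrt(rss / dof / sxx[poly])
    tstat[poly] = beta[poly] / se
    pval[poly] = 2.0 * stats.t.sf(np.abs(tstat[poly]), df=dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    out = genotypes.markers[["marker", "chrom", "cM", "bp"]].copy()
    out["maf"] = genotypes.maf()
    out["beta"] = beta
    out["t"] = tstat
    out["p"] = pval
    return out


def select_esm_panel(
    markers: pd.DataFrame, n_per_chromosome: int
) -> ChipPanel:
    """Evenly spaced chip on the genetic map, preferring high MAF.

    On each chromosome, targets sit at (j - 0.5) * L / n for j = 1..n over
    the occupied map range; for each target, candidates within half the
    inter-target spacing are ranked by MAF (then proximity, then marker
    id) and the winner is taken; with no candidate in the window the
    nearest unselected marker is used.  Chromosomes with <= n markers
    contribute all of them.

    ``markers`` needs columns marker, chrom, cM, maf.
    """
    chosen: list = []
    per_chrom: dict = {}
    for chrom, grp in markers.groupby("chrom", sort=True):
        grp = grp.sort_values(["cM", "marker"]).reset_index(drop=True)
        if len(grp) == 0:
            per_chrom[chrom] = 0
            continue
        if len(grp) <= n_per_chromosome:
            sel = grp["marker"].tolist()
            chosen.extend(sel)
            per_chrom[chrom] = len(sel)
            continue
        lo, hi = grp["cM"].min(), grp["cM"].max()
        span = max(hi - lo, 1e-9)
        spacing = span / n_per_chromosome
        targets = lo + (np.arange(n_per_chromosome) + 0.5) * spacing
        pos = grp["cM"].to_numpy()
        maf = grp["maf"].to_numpy()
        ids = grp["marker"].to_numpy()
        taken = np.zeros(len(grp), dtype=bool)
        sel = []
        for t in targets:
            dist = np.abs(pos - t)
            cand = np.flatnonzero((dist <= spacing / 2.0) & ~taken)
            if len(cand) == 0:
                cand = np.flatnonzero(~taken)
            # prefer max MAF, then nearest, then lowest marker id
            order = sorted(
                cand, key=lambda k: (-maf[k], dist[k], str(ids[k]))
            )
            k = order[0]
            taken[k] = True
            sel.append(ids[k])
        chosen.extend(sel)
        per_chrom[chrom] = len(sel)
    return ChipPanel(chosen, "ESM", per_chrom)


def select_gwam_panel(gwa: pd.DataFrame, n_per_chromosome: int) -> ChipPanel:
    """Top associations per chromosome, ranked by P value.

    Ties break on smaller P, then larger |t|, then lowest marker id, so
    the panel is invariant to the input row order.  Chromosomes with
    fewer markers than requested contribute all of them (with a warning).
    """
    chosen: list = []
    per_chrom: dict = {}
    for chrom, grp in gwa.groupby("chrom", sort=True):
        grp = grp.assign(_abs_t=grp["t"].abs(), _mid=grp["marker"].astype(str))
        grp = grp.sort_values(
            ["p", "_abs_t", "_mid"], ascending=[True, False, True]
        )
        if len(grp) < n_per_chromosome:
            warnings.warn(
                f"chromosome {chrom}: only {len(grp)} markers available "
                f"(requested {n_per_chromosome})",
                stacklevel=2,
            )
        sel = grp["marker"].head(n_per_chromosome).tolist()
        chosen.extend(sel)
        per_chrom[chrom] = len(sel)
    return ChipPanel(chosen, "GWAM", per_chrom)
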