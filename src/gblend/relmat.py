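"""Relationship matrices: pedigree A, linkage-analysis G_LA, LD-based G_LD.

Three sources of information about additive relationships:

* ``build_A`` — expected relationships from the pedigree alone (tabular
  method / Wright's numerator relationship matrix).
* ``build_GLD`` — realized identity-by-state relationships from allele
  counts, VanRaden's Method 2 (each marker standardized by 2p(1-p)).
* ``build_GLA`` — realized identity-by-descent relationships anchored to
  the pedigree base: a per-meiosis transmission HMM infers which parental
  haplotype each offspring received at each locus, an allele-level
  kinship recursion converts the posteriors into per-locus relationship
  matrices, and G_LA is their unweighted mean.  Base-population alleles
  are assumed distinct, as in the pedigree model.

``blend`` forms the composite M = lambda*M1 + (1-lambda)*M2.

The transmission HMM is a deliberate simplification of full multi-locus
iterative peeling: parental phase is only resolved where the parent's own
parents force it Mendelianly, and unresolved heterozygous loci are
treated as uninformative.  Two exact limits anchor it: with uninformative
markers G_LA collapses to A entrywise, and with fully informative markers
it recovers the realized gene-drop IBD matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .datatypes import GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "build_A",
    "build_GLD",
    "infer_transmissions",
    "build_GLA",
    "blend",
    "TransmissionPosteriors",
    "mendelian_phase",
    "haldane_r",
]


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_jj = 1 + 0.5 * a(sire_j, dam_j); a_ij = 0.5 * (a_i,sire_j + a_i,dam_j)
    with unknown parents contributing zero.
    """
    n = pedigree.n
    s, d = pedigree.sire_idx, pedigree.dam_idx
    A = np.zeros((n, n))
    for j in range(n):
        sj, dj = s[j], d[j]
        if sj >= 0 and dj >= 0:
            row = 0.5 * (A[sj, :j] + A[dj, :j])
            diag = 1.0 + 0.5 * A[sj, dj]
        elif sj >= 0:
            row = 0.5 * A[sj, :j]
            diag = 1.0
        elif dj >= 0:
            row = 0.5 * A[dj, :j]
            diag = 1.0
        else:
            row = np.zeros(j)
            diag = 1.0
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = diag
    return RelationshipMatrix(pedigree.ids, A, "A")


def build_GLD(
    genotypes: GenotypeMatrix, panel=None, min_freq: float = 0.0
) -> RelationshipMatrix:
    """VanRaden Method 2 genomic relationship matrix.

    G_ij = (1/m) sum_k z_ik z_jk / (2 p_k (1 - p_k)) with z = count - 2p
    and p the observed allele frequency over all genotyped individuals.
    Missing genotypes are mean-imputed (contribute 0).  Monomorphic
    markers are dropped with a warning.
    """
    g = genotypes if panel is None else genotypes.subset_markers(panel)
    p = g.allele_freq()
    poly = (p > min_freq) & (p < 1.0 - min_freq)
    if not poly.any():
        raise ValueError("every marker is monomorphic; cannot build G_LD")
    if (~poly).sum():
        warnings.warn(
            f"dropping {(~poly).sum()} monomorphic markers from G_LD",
            stacklevel=2,
        )
    p = p[poly]
    counts = g.counts[:, poly].astype(np.float64)
    z = np.where(counts < 0, 0.0, counts - 2.0 * p[None, :])
    s = z / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    G = (s @ s.T) / s.shape[1]
    return RelationshipMatrix(
        g.ids, G, "GLD", {"m": int(poly.sum()), "freq_source": "all genotyped"}
    )


# ---------------------------------------------------------------------------
# transmission HMM
# ---------------------------------------------------------------------------


def haldane_r(d_morgan: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for a map distance."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgan)))


@dataclass
class TransmissionPosteriors:
    """Per-meiosis, per-locus posterior of transmitting parental haplotype 1.

    ``t_sire[i, l]``/``t_dam[i, l]`` refer to the meiosis producing
    individual ``i``'s paternal/maternal allele; founders (and meioses
    with no informative locus) sit at the uninformative value 0.5.
    """

    ids: np.ndarray
    t_sire: np.ndarray
    t_dam: np.ndarray
    uninformative_meioses: int = 0


def mendelian_phase(pedigree: Pedigree, genotypes: GenotypeMatrix) -> np.ndarray:
    """Phase parental genotypes where the grandparents force it.

    Returns (n, 2, L) int8 haplotypes, axis 1 = (from-sire, from-dam);
    -1 marks loci that cannot be resolved (unphased heterozygotes,
    missing calls, Mendelian conflicts).
    """
    n, L = genotypes.counts.shape
    g = genotypes.counts
    ph = np.full((n, 2, L), -1, dtype=np.int8)
    hom = (g == 0) | (g == 2)
    for h in (0, 1):
        ph[:, h, :] = np.where(hom, (g // 2).astype(np.int8), -1)
    het = g == 1
    for i in range(n):
        if not het[i].any():
            continue
        si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
        gs = g[si] if si >= 0 else np.full(L, -1, dtype=g.dtype)
        gd = g[di] if di >= 0 else np.full(L, -1, dtype=g.dtype)
        m = het[i]
        # grandsire homozygous fixes the paternal allele
        pat = np.where(gs == 0, 0, np.where(gs == 2, 1, -1))
        mat = np.where(gd == 0, 0, np.where(gd == 2, 1, -1))
        # consistency: if both resolved they must sum to 1 at a het locus
        conflict = (pat >= 0) & (mat >= 0) & (pat + mat != 1)
        pat = np.where(conflict, -1, pat)
        mat = np.where(conflict, -1, mat)
        pat = np.where((pat < 0) & (mat >= 0), 1 - mat, pat)
        mat = np.where((mat < 0) & (pat >= 0), 1 - pat, mat)
        ph[i, 0, m] = pat[m].astype(np.int8)
        ph[i, 1, m] = mat[m].astype(np.int8)
    return ph


def _emissions(
    parent_phase: np.ndarray,
    child: np.ndarray,
    other_geno: np.ndarray,
    freq: np.ndarray,
    eps: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus emission likelihoods for the two transmission states.

    The allele contributed by the other parent is integrated out using
    that parent's genotype (probability g/2 of transmitting A1), falling
    back on the population allele frequency when it is unknown.
    """
    n_meio, L = child.shape
    h1 = parent_phase[:, 0, :]
    h2 = parent_phase[:, 1, :]
    informative = (h1 >= 0) & (h2 >= 0) & (h1 != h2) & (child >= 0)
    pb1 = np.where(other_geno >= 0, other_geno / 2.0, freq[None, :])

    def like(a):
        # P(child genotype | transmitted allele a), small error rate eps
        out = np.zeros_like(pb1)
        for b, pb in ((0, 1.0 - pb1), (1, pb1)):
            x = a + b
            match = x == child
            out += pb * np.where(match, 1.0 - eps, eps / 2.0)
        return out

    e1 = np.where(informative, like(h1), 1.0)
    e2 = np.where(informative, like(h2), 1.0)
    return e1, e2


def _forward_backward(
    e1: np.ndarray, e2: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Two-state scaled forward-backward; returns P(state 1) per locus.

    ``r`` holds recombination fractions between adjacent loci (length
    L-1; 0.5 across chromosome boundaries).
    """
    n, L = e1.shape
    f1 = np.empty((n, L))
    f2 = np.empty((n, L))
    f1[:, 0] = 0.5 * e1[:, 0]
    f2[:, 0] = 0.5 * e2[:, 0]
    scale = f1[:, 0] + f2[:, 0]
    f1[:, 0] /= scale
    f2[:, 0] /= scale
    for k in range(1, L):
        rk = r[k - 1]
        a1 = (1.0 - rk) * f1[:, k - 1] + rk * f2[:, k - 1]
        a2 = rk * f1[:, k - 1] + (1.0 - rk) * f2[:, k - 1]
        f1[:, k] = a1 * e1[:, k]
        f2[:, k] = a2 * e2[:, k]
        scale = f1[:, k] + f2[:, k]
        f1[:, k] /= scale
        f2[:, k] /= scale
    b1 = np.ones(n)
    b2 = np.ones(n)
    post = np.empty((n, L))
    post[:, L - 1] = f1[:, L - 1] * b1 / (
        f1[:, L - 1] * b1 + f2[:, L - 1] * b2
    )
    for k in range(L - 2, -1, -1):
        rk = r[k]
        nb1 = (1.0 - rk) * e1[:, k + 1] * b1 + rk * e2[:, k + 1] * b2
        nb2 = rk * e1[:, k + 1] * b1 + (1.0 - rk) * e2[:, k + 1] * b2
        s = np.maximum(nb1 + nb2, 1e-300)
        b1, b2 = nb1 / s, nb2 / s
        num = f1[:, k] * b1
        post[:, k] = num / (num + f2[:, k] * b2)
    return post


def infer_transmissions(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    eps: float = 1e-3,
    phase: np.ndarray | None = None,
) -> TransmissionPosteriors:
    """Posterior transmitted-haplotype probabilities for every meiosis.

    ``phase`` may supply externally known parental haplotypes (n, 2, L),
    e.g. simulation truth; by default phase is resolved from grandparental
    genotypes where Mendelianly forced.
    """
    if not np.array_equal(pedigree.ids, genotypes.ids):
        raise ValueError("pedigree and genotype ids differ")
    n, L = genotypes.counts.shape
    if phase is None:
        phase = mendelian_phase(pedigree, genotypes)
    freq = genotypes.allele_freq()
    chrom = genotypes.markers["chrom"].to_numpy()
    d = np.diff(genotypes.markers["cM"].to_numpy()) / 100.0
    r = haldane_r(np.maximum(d, 0.0))
    r = np.where(chrom[1:] != chrom[:-1], 0.5, r)
    r = np.clip(r, 1e-12, 0.5)

    t_sire = np.full((n, L), 0.5)
    t_dam = np.full((n, L), 0.5)
    uninf = 0
    nonf = np.flatnonzero(~pedigree.is_founder)
    if len(nonf) == 0:
        return TransmissionPosteriors(pedigree.ids, t_sire, t_dam, 0)
    for side, parent_idx, other_idx, out in (
        (0, pedigree.sire_idx, pedigree.dam_idx, t_sire),
        (1, pedigree.dam_idx, pedigree.sire_idx, t_dam),
    ):
        kids = nonf[parent_idx[nonf] >= 0]
        if len(kids) == 0:
            continue
        par = parent_idx[kids]
        oth = other_idx[kids]
        other_geno = np.where(
            (oth >= 0)[:, None],
            genotypes.counts[np.maximum(oth, 0)],
            -1,
        )
        e1, e2 = _emissions(
            phase[par], genotypes.counts[kids], other_geno, freq, eps
        )
        flat = np.isclose(e1, e2).all(axis=1)
        uninf += int(flat.sum())
        out[kids] = _forward_backward(e1, e2, r)
        out[kids[flat]] = 0.5
    return TransmissionPosteriors(pedigree.ids, t_sire, t_dam, uninf)


@njit(cache=True)
def _gla_kernel(sire, dam, ts, td):  # pragma: no cover - exercised via wrapper
    n, L = ts.shape
    G = np.zeros((n, n))
    K = np.zeros((2 * n, 2 * n), dtype=np.float32)
    for l in range(L):
        for i in range(n):
            p1 = 2 * i
            m1 = 2 * i + 1
            f = sire[i]
            m = dam[i]
            tp = ts[i, l]
            tm = td[i, l]
            if f >= 0:
                for c in range(2 * i):
                    v = tp * K[2 * f, c] + (1.0 - tp) * K[2 * f + 1, c]
                    K[p1, c] = v
                    K[c, p1] = v
            else:
                for c in range(2 * i):
                    K[p1, c] = 0.0
                    K[c, p1] = 0.0
            if m >= 0:
                for c in range(2 * i):
                    v = tm * K[2 * m, c] + (1.0 - tm) * K[2 * m + 1, c]
                    K[m1, c] = v
                    K[c, m1] = v
            else:
                for c in range(2 * i):
                    K[m1, c] = 0.0
                    K[c, m1] = 0.0
            if f >= 0 and m >= 0:
                x = tp * K[m1, 2 * f] + (1.0 - tp) * K[m1, 2 * f + 1]
            else:
                x = 0.0
            K[p1, m1] = x
            K[m1, p1] = x
            K[p1, p1] = 1.0
            K[m1, m1] = 1.0
        for i in range(n):
            for j in range(i + 1):
                g = 0.5 * (
                    K[2 * i, 2 * j]
                    + K[2 * i, 2 * j + 1]
                    + K[2 * i + 1, 2 * j]
                    + K[2 * i + 1, 2 * j + 1]
                )
                G[i, j] += g
    G /= L
    for i in range(n):
        for j in range(i):
            G[j, i] = G[i, j]
    return G


def build_GLA(
    pedigree: Pedigree,
    transmissions: TransmissionPosteriors,
    loci: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Linkage-analysis relationship matrix, averaged over loci.

    Per locus, founder alleles are taken as distinct (self-kinship 1) and
    a child allele's kinship with any allele is the transmission-posterior
    mixture of its parent's two allele kinships; the individual-level
    relationship is half the sum of the four cross-allele kinships.
    """
    if not np.array_equal(pedigree.ids, transmissions.ids):
        raise ValueError("pedigree and transmission ids differ")
    ts = transmissions.t_sire
    td = transmissions.t_dam
    if loci is not None:
        ts = ts[:, loci]
        td = td[:, loci]
    G = _gla_kernel(
        pedigree.sire_idx,
        pedigree.dam_idx,
        np.ascontiguousarray(ts, dtype=np.float64),
        np.ascontiguousarray(td, dtype=np.float64),
    )
    return RelationshipMatrix(pedigree.ids, G, "GLA", {"n_loci": ts.shape[1]})


def blend(
    M1: RelationshipMatrix, M2: RelationshipMatrix, lam: float
) -> RelationshipMatrix:
    """Composite matrix M = lambda*M1 + (1-lambda)*M2 (entrywise)."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    if not np.array_equal(M1.ids, M2.ids):
        raise ValueError("cannot blend matrices over different id lists")
    vals = lam * M1.values + (1.0 - lam) * M2.values
    return RelationshipMatrix(
        M1.ids,
        vals,
        "composite",
        {"lambda": lam, "kind1": M1.kind, "kind2": M2.kind},
    )
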