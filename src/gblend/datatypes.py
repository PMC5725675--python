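"""Core in-memory containers shared across the package.

Conventions
-----------
* Individuals are identified by positive integer ids; ``0`` (or empty) in
  files means "unknown parent".  Internally parents are stored as row
  indices into the pedigree, with ``-1`` for unknown.
* Genotypes are counts of the A1 allele in ``{0, 1, 2}`` with ``-1`` for
  missing.
* Relationship matrices are dense, symmetric, and ordered identically to
  the pedigree they were built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "RelationshipMatrix",
    "PedigreeError",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents)."""


@dataclass
class Pedigree:
    """A multi-generation pedigree sorted parents-before-offspring.

    Parameters
    ----------
    table:
        DataFrame with columns ``id, sire, dam, sex, generation,
        hatch_week``.  ``sire``/``dam`` are ids, 0 = unknown.  ``sex`` is
        ``"M"`` or ``"F"``.
    """

    table: pd.DataFrame
    sire_idx: np.ndarray = field(init=False, repr=False)
    dam_idx: np.ndarray = field(init=False, repr=False)

    REQUIRED = ("id", "sire", "dam", "sex", "generation", "hatch_week")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids")
        pos = {int(i): k for k, i in enumerate(ids)}
        n = len(ids)
        sire_idx = np.full(n, -1, dtype=np.int64)
        dam_idx = np.full(n, -1, dtype=np.int64)
        offenders = []
        for k in range(n):
            for col, out in (("sire", sire_idx), ("dam", dam_idx)):
                p = int(self.table[col].iat[k])
                if p == 0:
                    continue
                if p not in pos:
                    offenders.append((int(ids[k]), col, p))
                    continue
                out[k] = pos[p]
        if offenders:
            raise PedigreeError(
                "parents referenced but never defined: "
                + ", ".join(f"id {i} {c}={p}" for i, c, p in offenders)
            )
        bad = [
            int(ids[k])
            for k in range(n)
            if (sire_idx[k] >= k) or (dam_idx[k] >= k)
        ]
        if bad:
            raise PedigreeError(
                f"individuals listed before a parent (or self-parenting): {bad}"
            )
        self.sire_idx = sire_idx
        self.dam_idx = dam_idx

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def positions(self, ids) -> np.ndarray:
        """Row indices of the given ids (raises on unknown id)."""
        pos = pd.Index(self.table["id"])
        loc = pos.get_indexer(np.asarray(ids))
        if (loc < 0).any():
            unknown = np.asarray(ids)[loc < 0]
            raise PedigreeError(f"ids not in pedigree: {unknown.tolist()}")
        return loc

    def offspring_counts(self) -> pd.DataFrame:
        """Number of offspring per individual (as sire and as dam)."""
        n = self.n
        as_sire = np.bincount(self.sire_idx[self.sire_idx >= 0], minlength=n)
        as_dam = np.bincount(self.dam_idx[self.dam_idx >= 0], minlength=n)
        return pd.DataFrame(
            {"id": self.ids, "as_sire": as_sire, "as_dam": as_dam}
        )


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers, allele counts 0/1/2, -1 missing.

    ``markers`` carries the map: columns ``marker, chrom, cM, bp`` (and
    optionally ``a1, a2`` recording the counted allele).
    """

    ids: np.ndarray
    counts: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Observed A1 allele frequency per marker, ignoring missing calls."""
        c = np.ma.masked_equal(self.counts, -1)
        return np.asarray(c.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.counts >= 0).mean(axis=0)

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = pd.Index(self.markers["marker"])
        loc = idx.get_indexer(pd.Index(marker_ids))
        if (loc < 0).any():
            raise KeyError("marker ids absent from genotype matrix")
        return GenotypeMatrix(
            self.ids, self.counts[:, loc], self.markers.iloc[loc]
        )


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered id list.

    ``kind`` is one of ``"A"``, ``"GLA"``, ``"GLD"``, ``"composite"``;
    composites record ``(lambda, kind1, kind2)`` in ``provenance``.
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = pd.Index(self.ids)
        loc = idx.get_indexer(pd.Index(ids))
        if (loc < 0).any():
            raise KeyError("ids absent from relationship matrix")
        return RelationshipMatrix(
            np.asarray(ids), self.values[np.ix_(loc, loc)], self.kind,
            dict(self.provenance),
        )
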