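"""Readers and writers for the pipeline boundary formats.

Formats: pedigree CSV (id,sire,dam,sex,generation,hatch_week; 0 = unknown
parent), PLINK text .ped/.map genotypes, a genotype TSV (rows =
individuals, columns = markers, values 0/1/2, NA = missing), phenotype
CSV (id,bwt,sex,hatch_week,subset), and relationship matrices as either a
square TSV with id headers or a sparse lower-triangle (i, j, value) text
file with a companion id list.

Counts are of the A1 allele per marker (the first-listed allele in the
.ped file), recorded in the marker table so 0/1/2 codings are
reproducible across tools.  Coordinates: bp are 1-based, genetic
positions in cM in the .map third column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "read_matrix",
    "write_matrix",
]

log = logging.getLogger(__name__)


# -- pedigree ---------------------------------------------------------------


def read_pedigree_csv(path) -> Pedigree:
    """Read and validate a pedigree CSV, reordering parents first if needed."""
    df = pd.read_csv(path)
    missing = [c for c in Pedigree.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pedigree columns {missing}")
    for col in ("sire", "dam"):
        df[col] = df[col].fillna(0).astype(np.int64)
    df["id"] = df["id"].astype(np.int64)
    order = _topological_order(df)
    if not np.array_equal(order, np.arange(len(df))):
        log.info("%s: rows reordered parents-before-offspring", path)
        df = df.iloc[order].reset_index(drop=True)
    return Pedigree(df)


def _topological_order(df: pd.DataFrame) -> np.ndarray:
    ids = df["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    state = np.zeros(len(df), dtype=np.int8)  # 0 new, 1 visiting, 2 done
    order: list[int] = []
    sire = df["sire"].to_numpy()
    dam = df["dam"].to_numpy()

    def visit(k: int) -> None:
        stack = [(k, 0)]
        while stack:
            node, phase = stack.pop()
            if phase == 0:
                if state[node] == 2:
                    continue
                if state[node] == 1:
                    raise ValueError("pedigree contains a cycle")
                state[node] = 1
                stack.append((node, 1))
                for p in (sire[node], dam[node]):
                    if p != 0:
                        if int(p) not in pos:
                            raise ValueError(
                                f"parent id {int(p)} referenced but never defined"
                            )
                        if state[pos[int(p)]] != 2:
                            stack.append((pos[int(p)], 0))
            else:
                if state[node] != 2:
                    state[node] = 2
                    order.append(node)

    for k in range(len(df)):
        if state[k] == 0:
            visit(k)
    return np.asarray(order)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, index=False)


# -- phenotypes -------------------------------------------------------------


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "bwt", "sex", "hatch_week"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    if "subset" not in df.columns:
        df["subset"] = ""
    df["subset"] = df["subset"].fillna("")
    return df


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


# -- genotypes --------------------------------------------------------------


def write_genotypes(
    genotypes: GenotypeMatrix, prefix, fmt: str = "plink_text"
) -> list[Path]:
    """Write PLINK text (.ped/.map) or genotype TSV (+ .markers.tsv map)."""
    prefix = Path(prefix)
    if fmt == "plink_text":
        mp = genotypes.markers
        map_df = pd.DataFrame(
            {
                "chrom": mp["chrom"],
                "marker": mp["marker"],
                "cM": mp["cM"],
                "bp": mp["bp"],
            }
        )
        map_path = prefix.with_suffix(".map")
        map_df.to_csv(map_path, sep="\t", header=False, index=False)
        ped_path = prefix.with_suffix(".ped")
        allele_pairs = {-1: "0 0", 0: "2 2", 1: "1 2", 2: "1 1"}
        with open(ped_path, "w") as fh:
            for i, iid in enumerate(genotypes.ids):
                head = f"0 {iid} 0 0 0 -9"
                body = " ".join(
                    allele_pairs[int(c)] for c in genotypes.counts[i]
                )
                fh.write(f"{head} {body}\n")
        return [ped_path, map_path]
    if fmt == "tsv":
        tsv_path = prefix.with_suffix(".tsv")
        df = pd.DataFrame(
            np.where(genotypes.counts < 0, np.nan, genotypes.counts),
            index=pd.Index(genotypes.ids, name="id"),
            columns=genotypes.markers["marker"],
        )
        df.to_csv(tsv_path, sep="\t", na_rep="NA", float_format="%.0f")
        marker_path = Path(str(prefix) + ".markers.tsv")
        genotypes.markers.to_csv(marker_path, sep="\t", index=False)
        return [tsv_path, marker_path]
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read PLINK text (.ped + .map) or a genotype TSV.

    For PLINK input ``path`` may be either file of the pair; counts are
    of the A1 allele, defined as the lexicographically smallest allele
    name per marker (recorded in the marker table), so the coding does
    not depend on the order of individuals in the file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "plink_text" if path.suffix in (".ped", ".map") else "tsv"
    if fmt == "plink_text":
        ped_path = path.with_suffix(".ped")
        map_path = path.with_suffix(".map")
        mp = pd.read_csv(
            map_path, sep=r"\s+", header=None,
            names=["chrom", "marker", "cM", "bp"],
        )
        m = len(mp)
        ids = []
        rows = []
        a1 = np.array([""] * m, dtype=object)
        a2 = np.array([""] * m, dtype=object)
        with open(ped_path) as fh:
            for ln, line in enumerate(fh, 1):
                tok = line.split()
                if not tok:
                    continue
                if len(tok) != 6 + 2 * m:
                    raise ValueError(
                        f"{ped_path}: line {ln} has {len(tok)} fields, "
                        f"expected {6 + 2 * m} for {m} markers"
                    )
                ids.append(int(tok[1]))
                alleles = tok[6:]
                counts = np.full(m, -1, dtype=np.int8)
                for k in range(m):
                    x, y = alleles[2 * k], alleles[2 * k + 1]
                    if x == "0" or y == "0":
                        continue
                    for al in (x, y):
                        if a1[k] == "":
                            a1[k] = al
                        elif al != a1[k] and a2[k] == "":
                            a2[k] = al
                        elif al not in (a1[k], a2[k]):
                            raise ValueError(
                                f"{ped_path}: marker {mp['marker'].iat[k]} has "
                                f"more than two alleles"
                            )
                    counts[k] = int(x == a1[k]) + int(y == a1[k])
                rows.append(counts)
        counts = np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
        # monomorphic markers show a single allele name; with numeric 1/2
        # coding the unseen partner is known, keeping round trips exact
        only_two = (a2 == "") & (a1 == "2")
        a2[only_two] = "2"
        a1[only_two] = "1"
        if only_two.any() and len(rows):
            cols = np.flatnonzero(only_two)
            miss = counts[:, cols] < 0
            counts[:, cols] = np.where(miss, -1, 2 - counts[:, cols])
        only_one = (a2 == "") & (a1 == "1")
        a2[only_one] = "2"
        # orient counts to the lexicographically smallest allele so the
        # 0/1/2 coding is independent of individual order
        flip = (a2 != "") & (a1 > a2)
        if flip.any() and len(counts):
            cols = np.flatnonzero(flip)
            miss = counts[:, cols] < 0
            counts[:, cols] = np.where(miss, -1, 2 - counts[:, cols])
        a1f = np.where(flip, a2, a1)
        a2f = np.where(flip, a1, a2)
        markers = mp.assign(a1=a1f, a2=a2f)
        return GenotypeMatrix(np.asarray(ids), counts, markers)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy(dtype=float)
        counts = np.where(np.isnan(counts), -1, counts).astype(np.int8)
        marker_path = Path(str(path.with_suffix("")) + ".markers.tsv")
        if marker_path.exists():
            markers = pd.read_csv(marker_path, sep="\t")
        else:
            markers = pd.DataFrame(
                {
                    "marker": df.columns,
                    "chrom": 1,
                    "cM": np.arange(len(df.columns), dtype=float),
                    "bp": np.arange(1, len(df.columns) + 1),
                }
            )
        return GenotypeMatrix(df.index.to_numpy(), counts, markers)
    raise ValueError(f"unknown genotype format {fmt!r}")


# -- relationship matrices --------------------------------------------------


def write_matrix(
    matrix: RelationshipMatrix, path, fmt: str = "square"
) -> list[Path]:
    """Square TSV with id headers, or sparse lower triangle + id file."""
    path = Path(path)
    if fmt == "square":
        df = pd.DataFrame(
            matrix.values,
            index=pd.Index(matrix.ids, name="id"),
            columns=matrix.ids,
        )
        df.to_csv(path, sep="\t", float_format="%.6g")
        return [path]
    if fmt == "sparse":
        id_path = Path(str(path) + ".ids")
        pd.Series(matrix.ids).to_csv(id_path, index=False, header=False)
        with open(path, "w") as fh:
            n = matrix.n
            for i in range(n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{matrix.values[i, j]:.6g}\n")
        return [path, id_path]
    raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path, kind: str = "unknown") -> RelationshipMatrix:
    """Auto-detecting matrix reader (square TSV vs sparse triplets)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tok = first.rstrip("\n").split("\t")
    if len(tok) == 3 and _is_number(tok[0]) and _is_number(tok[2]):
        ids = pd.read_csv(
            Path(str(path) + ".ids"), header=None
        )[0].to_numpy()
        n = len(ids)
        vals = np.zeros((n, n))
        trip = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "v"])
        i = trip["i"].to_numpy(dtype=int) - 1
        j = trip["j"].to_numpy(dtype=int) - 1
        vals[i, j] = trip["v"]
        vals[j, i] = trip["v"]
        return RelationshipMatrix(ids, vals, kind)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.index.to_numpy(), df.to_numpy(dtype=float), kind)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
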