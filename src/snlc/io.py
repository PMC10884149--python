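"""Text readers and writers for contact matrices, partitions and structures.

All formats are plain text and diffable.  Loci are 1-based in every file
(the Hi-C bin-label convention) and 0-based in memory.

* contact matrices: dense TSV with a header row of locus labels, or
  triplet lines ``i j count`` (auto-detected on read);
* partitions: JSON ``{"n": ..., "U": [...], "A": [...]}`` with 1-based loci;
* structures: ``tsv_xyz`` tables (locus, homolog, x, y, z, flag) or a
  PDB-like pseudo-atom export with one chain per homolog for molecular
  viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import ContactData, LociPartition, Structure3D, _availability_masks

__all__ = [
    "write_matrix", "read_matrix", "write_contacts", "read_contacts",
    "write_partition", "read_partition", "write_structure", "read_structure",
]


def write_matrix(M: np.ndarray, path, layout: str = "dense") -> None:
    M = np.asarray(M)
    path = Path(path)
    if layout == "dense":
        header = "\t".join(str(j + 1) for j in range(M.shape[1]))
        lines = [header]
        for row in M:
            lines.append("\t".join(repr(float(v)) for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif layout == "triplet":
        lines = []
        for i in range(M.shape[0]):
            for j in range(M.shape[1]):
                if M[i, j] != 0:
                    lines.append(f"{i + 1} {j + 1} {float(M[i, j])!r}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("layout must be 'dense' or 'triplet'")


def read_matrix(path, shape: tuple[int, int]) -> np.ndarray:
    """Read a dense-TSV or triplet matrix file (layout auto-detected)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return np.zeros(shape)
    first = lines[0].split()
    dense = "\t" in lines[0] and len(lines) == shape[0] + 1
    if not dense and len(first) != 3:
        dense = True
    if dense:
        M = np.zeros(shape)
        for r, ln in enumerate(lines[1:]):
            vals = ln.split("\t")
            if len(vals) != shape[1]:
                raise ValueError(f"{path}:{r + 2}: expected {shape[1]} columns")
            M[r] = [float(v) for v in vals]
        return M
    M = np.zeros(shape)
    for k, ln in enumerate(lines, start=1):
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{k}: malformed triplet line")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        v = float(parts[2])
        if v < 0:
            raise ValueError(f"{path}:{k}: negative count")
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise ValueError(f"{path}:{k}: index out of range")
        M[i, j] = v
    return M


def write_contacts(contacts: ContactData, directory, layout: str = "dense") -> dict:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / f"c{k}.tsv" for k in ("U", "P", "A")}
    write_matrix(contacts.cU, paths["U"], layout)
    write_matrix(contacts.cP, paths["P"], layout)
    write_matrix(contacts.cA, paths["A"], layout)
    return paths


def read_contacts(path_cU, path_cP, path_cA, n: int,
                  partition: LociPartition | None = None) -> ContactData:
    """Read the three matrices; cU and cA are symmetrized by max-of-pair.

    When a partition is given the availability masks follow its semantics;
    otherwise every off-self entry is treated as available.
    """
    cU = read_matrix(path_cU, (2 * n, 2 * n))
    cP = read_matrix(path_cP, (2 * n, n))
    cA = read_matrix(path_cA, (n, n))
    for M, name in ((cU, "cU"), (cA, "cA")):
        asym = np.abs(M - M.T).max()
        if asym > 1e-9:
            import warnings

            warnings.warn(f"{name} asymmetric by {asym:.2e}; symmetrizing by max")
        np.maximum(M, M.T, out=M)
    if partition is not None:
        mU, mP, mA = _availability_masks(partition)
    else:
        mU = ~np.eye(2 * n, dtype=bool)
        locus = np.concatenate([np.arange(n), np.arange(n)])
        mU &= locus[:, None] != locus[None, :]
        mP = np.ones((2 * n, n), dtype=bool)
        mP[np.arange(n), np.arange(n)] = False
        mP[np.arange(n) + n, np.arange(n)] = False
        mA = ~np.eye(n, dtype=bool)
    return ContactData(n, cU * mU, cP * mP, cA * mA, mU, mP, mA)


def write_partition(partition: LociPartition, path) -> None:
    doc = {"n": partition.n,
           "U": [int(i) + 1 for i in partition.U],
           "A": [int(i) + 1 for i in partition.A]}
    Path(path).write_text(json.dumps(doc) + "\n")


def read_partition(path) -> LociPartition:
    doc = json.loads(Path(path).read_text())
    return LociPartition(int(doc["n"]),
                         np.asarray(doc["U"], dtype=int) - 1,
                         np.asarray(doc["A"], dtype=int) - 1)


def write_structure(structure: Structure3D, partition: LociPartition | None,
                    path, format: str = "tsv_xyz",
                    flags: dict[int, str] | None = None) -> None:
    path = Path(path)
    n = structure.n
    amb = set(partition.A.tolist()) if partition is not None else set()
    flags = flags or {}

    def flag(i):
        return flags.get(i, "ambiguous" if i in amb else "unambiguous")

    if format == "tsv_xyz":
        lines = ["locus\thomolog\tx\ty\tz\tflag"]
        for hom, coords in ((1, structure.x), (2, structure.y)):
            for i in range(n):
                cx, cy, cz = coords[i]
                lines.append(f"{i + 1}\t{hom}\t{float(cx)!r}\t{float(cy)!r}"
                             f"\t{float(cz)!r}\t{flag(i)}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "pdb_like":
        lines = []
        serial = 1
        for chain, coords in (("A", structure.x), ("B", structure.y)):
            for i in range(n):
                cx, cy, cz = coords[i]
                lines.append(
                    f"ATOM  {serial:5d}  CA  BED {chain}{i + 1:4d}    "
                    f"{cx:8.3f}{cy:8.3f}{cz:8.3f}  1.00  0.00           C"
                )
                serial += 1
            lines.append("TER")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("format must be 'tsv_xyz' or 'pdb_like'")


def read_structure(path) -> Structure3D:
    lines = Path(path).read_text().splitlines()
    rows = [ln.split("\t") for ln in lines[1:] if ln.strip()]
    n = max(int(r[0]) for r in rows)
    x = np.zeros((n, 3))
    y = np.zeros((n, 3))
    for r in rows:
        i, hom = int(r[0]) - 1, int(r[1])
        (x if hom == 1 else y)[i] = [float(r[2]), float(r[3]), float(r[4])]
    return Structure3D(x, y)
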