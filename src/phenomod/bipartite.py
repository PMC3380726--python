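"""COG-pair x organism bipartite network in binary matrix form.

Organisms are the row headers and COG pairs the column headers; a cell is 1
iff that pair is functionally associated in that organism.  The matrix is
typically very sparse and is stored as ``scipy.sparse`` CSR internally; the
public contract is representation-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .io import CogNetwork, CogPair


@dataclass
class BipartiteMatrix:
    """Binary organisms x COG-pairs incidence matrix.

    Row order follows the order the networks were supplied in (manifest
    order); columns are sorted lexicographically on the pair, and every
    column has at least one 1 (the column set is the union of edge sets).
    """

    organisms: list[str]
    cog_pairs: list[CogPair]
    cells: sparse.csr_matrix
    col_index: dict[CogPair, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.col_index:
            self.col_index = {p: j for j, p in enumerate(self.cog_pairs)}

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.organisms), len(self.cog_pairs)

    def row_pairs(self, i: int) -> frozenset[CogPair]:
        """The COG pairs present in organism row ``i``."""
        row = self.cells.getrow(i)
        return frozenset(self.cog_pairs[j] for j in row.indices)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.cells.todense(), dtype=np.int8)

    def to_tsv(self, path) -> None:
        """Debug dump: organism rows, ``COGa--COGb`` columns."""
        dense = self.to_dense()
        with open(path, "w", encoding="utf-8") as fh:
            header = ["organism_id"] + [f"{u}--{v}" for u, v in self.cog_pairs]
            fh.write("\t".join(header) + "\n")
            for i, org in enumerate(self.organisms):
                fh.write("\t".join([org] + [str(int(x)) for x in dense[i]]) + "\n")


def build_matrix(nets: list[CogNetwork]) -> BipartiteMatrix:
    """Assemble the incidence matrix for a panel of COG-level networks.

    Raises ``ValueError`` on duplicate organism ids or an empty panel.
    """
    if not nets:
        raise ValueError("build_matrix requires at least one network")
    organisms = [n.organism_id for n in nets]
    if len(set(organisms)) != len(organisms):
        dupes = sorted({o for o in organisms if organisms.count(o) > 1})
        raise ValueError(f"duplicate organism_id(s): {dupes}")
    cog_pairs = sorted(set().union(*(n.edges for n in nets)))
    col_index = {p: j for j, p in enumerate(cog_pairs)}
    rows, cols = [], []
    for i, net in enumerate(nets):
        for pair in net.edges:
            rows.append(i)
            cols.append(col_index[pair])
    cells = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(organisms), len(cog_pairs)),
    )
    return BipartiteMatrix(
        organisms=organisms, cog_pairs=cog_pairs, cells=cells, col_index=col_index
    )


def presence_count(cog_pairs: set[CogPair] | frozenset[CogPair], matrix: BipartiteMatrix) -> int:
    """Number of organisms (rows) that contain EVERY pair in ``cog_pairs``.

    A pair absent from the matrix's column set is present in no organism, so
    any query containing one returns 0.  The empty query is undefined.
    """
    if not cog_pairs:
        raise ValueError("presence_count is undefined for an empty COG-pair set")
    cols = []
    for pair in cog_pairs:
        j = matrix.col_index.get(pair)
        if j is None:
            return 0
        cols.append(j)
    if matrix.cells.shape[0] == 0:
        return 0
    per_row = np.asarray(matrix.cells[:, cols].sum(axis=1)).ravel()
    return int(np.count_nonzero(per_row == len(cols)))
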