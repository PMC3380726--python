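"""Enumeration of all inclusion-maximal biclusters (maximal bicliques).

A bicluster is an all-ones submatrix of the organisms x COG-pairs incidence
matrix: a set of COG associations conserved in every organism of a set.  The
inclusion-maximal ones are exactly the formal concepts of the binary
relation, so we enumerate closed organism sets (extents) by closing the set
of per-column supports under intersection — the organism side is small, so
this is fast and provably complete.  ``brute_force_biclusters`` is the
exponential column-subset oracle used to certify the enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .bipartite import BipartiteMatrix
from .io import CogPair


class BiclusterOverflowError(RuntimeError):
    """Raised when the number of maximal biclusters exceeds ``max_output``."""


@dataclass(frozen=True)
class Bicluster:
    """A maximal all-ones submatrix: organisms O' x COG pairs C'.

    Every pair in ``cog_pairs`` is conserved in every organism of
    ``organisms``; no organism or pair can be added without breaking that.
    """

    organisms: frozenset[str]
    cog_pairs: frozenset[CogPair]

    def sort_key(self):
        return (
            -len(self.organisms),
            -len(self.cog_pairs),
            sorted(self.cog_pairs),
            sorted(self.organisms),
        )


def _row_masks(matrix: BipartiteMatrix) -> list[int]:
    """Per-organism bitmask over column indices."""
    masks = []
    csr = matrix.cells.tocsr()
    for i in range(len(matrix.organisms)):
        m = 0
        for j in csr.getrow(i).indices:
            m |= 1 << int(j)
        masks.append(m)
    return masks


def _col_extents(matrix: BipartiteMatrix) -> list[int]:
    """Per-column bitmask over row indices (distinct patterns only)."""
    csc = matrix.cells.tocsc()
    seen: set[int] = set()
    for j in range(len(matrix.cog_pairs)):
        e = 0
        for i in csc.getcol(j).indices:
            e |= 1 << int(i)
        seen.add(e)
    return sorted(seen)


def _materialize(extent: int, intent: int, matrix: BipartiteMatrix) -> Bicluster:
    orgs = frozenset(
        matrix.organisms[i] for i in range(len(matrix.organisms)) if extent >> i & 1
    )
    pairs = frozenset(
        matrix.cog_pairs[j] for j in range(len(matrix.cog_pairs)) if intent >> j & 1
    )
    return Bicluster(organisms=orgs, cog_pairs=pairs)


def enumerate_maximal_biclusters(
    matrix: BipartiteMatrix,
    min_orgs: int = 2,
    min_pairs: int = 1,
    max_output: int = 100_000,
) -> list[Bicluster]:
    """All inclusion-maximal biclusters with >= ``min_orgs`` organisms and
    >= ``min_pairs`` pairs, in deterministic order (descending organism
    count, then descending pair count, then lexicographic pair list).

    Raises :class:`BiclusterOverflowError` rather than truncating when more
    than ``max_output`` biclusters exist — truncation would silently bias
    downstream statistics; tighten the size floors instead.
    """
    if min_orgs < 2:
        raise ValueError("min_orgs must be >= 2 (conservation needs two organisms)")
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    row_masks = _row_masks(matrix)
    generators = _col_extents(matrix)
    n_rows = len(matrix.organisms)

    # Closed extents = intersections of column supports; prune below the
    # organism floor (intersections only shrink).
    closed: set[int] = set()
    full = (1 << n_rows) - 1
    stack = [e for e in generators + [full] if e.bit_count() >= min_orgs]
    while stack:
        e = stack.pop()
        if e in closed:
            continue
        closed.add(e)
        for g in generators:
            x = e & g
            if x != e and x not in closed and x.bit_count() >= min_orgs:
                stack.append(x)

    results: list[Bicluster] = []
    for extent in closed:
        intent = -1
        for i in range(n_rows):
            if extent >> i & 1:
                intent &= row_masks[i]
        if intent.bit_count() < min_pairs:
            continue
        # Re-close on the organism side: the extent of the intent may be
        # wider than the generating intersection; keep each concept once.
        true_extent = 0
        for i in range(n_rows):
            if row_masks[i] & intent == intent:
                true_extent |= 1 << i
        if true_extent != extent:
            continue  # this concept is reached from its own closed extent
        results.append(_materialize(extent, intent, matrix))
        if len(results) > max_output:
            raise BiclusterOverflowError(
                f"more than {max_output} maximal biclusters; raise min_orgs/"
                f"min_pairs or max_output"
            )
    results.sort(key=Bicluster.sort_key)
    return results


def brute_force_biclusters(
    matrix: BipartiteMatrix, min_orgs: int = 2, min_pairs: int = 1
) -> list[Bicluster]:
    """Exponential oracle: closes every column subset. Refuses wide matrices."""
    n_cols = len(matrix.cog_pairs)
    if n_cols > 20:
        raise ValueError(f"brute force limited to 20 columns, got {n_cols}")
    row_masks = _row_masks(matrix)
    n_rows = len(matrix.organisms)
    csc = matrix.cells.tocsc()
    col_ext = []
    for j in range(n_cols):
        e = 0
        for i in csc.getcol(j).indices:
            e |= 1 << int(i)
        col_ext.append(e)
    full = (1 << n_rows) - 1
    concepts: set[tuple[int, int]] = set()
    for size in range(0, n_cols + 1):
        for subset in combinations(range(n_cols), size):
            extent = full
            for j in subset:
                extent &= col_ext[j]
            if extent.bit_count() < min_orgs:
                continue
            intent = -1
            for i in range(n_rows):
                if extent >> i & 1:
                    intent &= row_masks[i]
            if intent.bit_count() < min_pairs:
                continue
            concepts.add((extent, intent))
    results = [_materialize(e, c, matrix) for e, c in concepts]
    results.sort(key=Bicluster.sort_key)
    return results
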