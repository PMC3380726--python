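"""Hypergeometric phenotype-bias statistic and bicluster filtering.

For a bicluster B the bias is the hypergeometric probability of seeing its
conservation pattern split across the two phenotype classes by chance:

    P  total organisms in the panel (both classes)
    S  phenotype-expressing organisms
    X  organisms of either class in which B is conserved
    Y  expressing organisms in which B is conserved

    bias(B) = C(S, Y) * C(P - S, X - Y) / C(P, X)

The default is this point probability; an upper-tail sum (the conventional
enrichment p-value, Y' >= Y) is available via ``mode="tail"``.  Biclusters
with bias <= alpha (default 0.05) are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .biclusters import Bicluster
from .bipartite import BipartiteMatrix, presence_count

logger = logging.getLogger(__name__)

POINT = "point"
TAIL = "tail"
MODES = (POINT, TAIL)


@dataclass(frozen=True)
class BiasResult:
    """Conservation counts and hypergeometric bias for one bicluster."""

    P: int
    S: int
    X: int
    Y: int
    p_value: float
    mode: str


def _validate_counts(P: int, S: int, X: int, Y: int) -> None:
    checks = [
        (0 <= S <= P, "0 <= S <= P"),
        (0 <= X <= P, "0 <= X <= P"),
        (0 <= Y <= S, "0 <= Y <= S"),
        (Y <= X, "Y <= X"),
        (X - Y <= P - S, "X - Y <= P - S"),
    ]
    for ok, name in checks:
        if not ok:
            raise ValueError(
                f"hypergeometric counts violate {name}: P={P}, S={S}, X={X}, Y={Y}"
            )


def hypergeom_bias(P: int, S: int, X: int, Y: int, mode: str = POINT) -> float:
    """Hypergeometric bias; point mass by default, upper tail via ``mode``.

    Evaluated in log space (scipy's hypergeometric distribution) and clamped
    to [0, 1].
    """
    _validate_counts(P, S, X, Y)
    if mode == POINT:
        p = float(stats.hypergeom.pmf(Y, P, S, X))
    elif mode == TAIL:
        # sum_{k >= Y} of the point mass = survival function at Y - 1
        p = float(stats.hypergeom.sf(Y - 1, P, S, X))
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if p < -1e-12 or p > 1 + 1e-12:
        raise AssertionError(f"hypergeometric p-value {p} outside [0, 1]")
    return min(max(p, 0.0), 1.0)


def bias_results(
    biclusters: list[Bicluster],
    neg_matrix: BipartiteMatrix | None,
    panel: dict[str, str],
    mode: str = POINT,
) -> list[BiasResult]:
    """Score every bicluster against the non-expressing matrix (no filter).

    ``panel`` maps organism_id -> "expressing"/"non_expressing".  By
    bicluster maximality Y is exactly |O'| (no re-scan of the expressing
    matrix), and X = Y plus the number of non-expressing organisms that
    contain every pair of the bicluster.
    """
    P = len(panel)
    expressing = {o for o, lab in panel.items() if lab == "expressing"}
    S = len(expressing)
    results = []
    for bc in biclusters:
        stray = bc.organisms - expressing
        if stray:
            raise ValueError(
                f"bicluster organisms not in the expressing set: {sorted(stray)}"
            )
        Y = len(bc.organisms)
        X = Y
        if neg_matrix is not None and len(neg_matrix.organisms):
            X += presence_count(bc.cog_pairs, neg_matrix)
        results.append(
            BiasResult(P=P, S=S, X=X, Y=Y, p_value=hypergeom_bias(P, S, X, Y, mode), mode=mode)
        )
    return results


def score_biclusters(
    biclusters: list[Bicluster],
    neg_matrix: BipartiteMatrix | None,
    panel: dict[str, str],
    alpha: float = 0.05,
    mode: str = POINT,
    correction: str = "none",
) -> list[tuple[Bicluster, BiasResult]]:
    """Score biclusters and keep the phenotype-biased ones (bias <= alpha).

    ``correction="bh"`` applies Benjamini-Hochberg across the batch and
    retains on the adjusted values (reported p_values stay raw); default is
    the raw cutoff.  Input order is preserved.
    """
    results = bias_results(biclusters, neg_matrix, panel, mode=mode)
    if not results:
        return []
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        keep = list(reject)
    elif correction == "none":
        keep = [r.p_value <= alpha for r in results]
    else:
        raise ValueError(f"correction must be 'none' or 'bh', got {correction!r}")
    retained = [
        (bc, res) for bc, res, k in zip(biclusters, results, keep) if k
    ]
    logger.info(
        "score_biclusters: %d/%d biclusters phenotype-biased at alpha=%g (%s mode)",
        len(retained), len(biclusters), alpha, results[0].mode,
    )
    return retained
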