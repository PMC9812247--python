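"""Rank-rank hypergeometric overlap (RRHO) between two ranked gene lists.

Two analyses that rank the same gene universe (here: by Spearman rho with
an activation map) are compared by sliding a pair of rank cutoffs down both
lists: for each cutoff pair the overlap of the two top-prefixes is scored
with an upper-tail hypergeometric p-value, signed positive when the overlap
exceeds its expectation and negative when it falls below it. The full map
of signed -log10 p-values visualizes where in the rankings the lists agree;
a single scalar, rho_rrho, summarizes agreement as the Spearman correlation
between the two lists' per-gene ranking metrics, with a gene-label
permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .correlate import CorrelationTable, spearman
from .errors import AlignmentError, ParameterError

__all__ = ["RRHOResult", "hypergeom_overlap_p", "rrho_map"]

#: floor for p-values before log-transform (avoids -log10(0))
_P_FLOOR = 5e-324


@dataclass
class RRHOResult:
    step: int
    thresholds_1: np.ndarray
    thresholds_2: np.ndarray
    signed_logp: np.ndarray  # (len(thresholds_1), len(thresholds_2))
    rho_rrho: float
    p_rrho: float


def hypergeom_overlap_p(N: int, t1: int, t2: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, t1, t2).

    The chance that two random subsets of sizes t1 and t2 drawn from a
    universe of N genes share at least k members.
    """
    if not (0 <= k <= min(t1, t2) <= max(t1, t2) <= N):
        raise ParameterError(
            f"infeasible counts: N={N}, t1={t1}, t2={t2}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, t1, t2))


def rrho_map(
    list1: CorrelationTable,
    list2: CorrelationTable,
    step: int | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> RRHOResult:
    """RRHO map and scalar rank-agreement between two correlation tables.

    ``step`` sets the cutoff spacing (default ~N/100 so small and full-size
    lists both give a map of about 100 x 100 cells). Entry (i, j) is the
    signed -log10 upper-tail hypergeometric p for the overlap of the top
    i*step genes of list 1 with the top j*step genes of list 2.
    """
    g1 = set(list1.gene_ids.tolist())
    g2 = set(list2.gene_ids.tolist())
    if g1 != g2:
        raise AlignmentError(
            f"gene universes differ: {len(g1 - g2)} only in list 1, "
            f"{len(g2 - g1)} only in list 2"
        )
    N = len(g1)
    if step is None:
        step = max(1, N // 100)
    if step < 1:
        raise ParameterError("step must be >= 1")

    rank1 = list1.data.set_index("gene_id")["rank"]
    rank2 = list2.data.set_index("gene_id")["rank"]
    genes = rank1.index.to_numpy()
    r1 = rank1.to_numpy()
    r2 = rank2.loc[genes].to_numpy()

    thresholds = np.arange(step, N + 1, step)
    nt = len(thresholds)
    # joint histogram of (cutoff bin of rank1, cutoff bin of rank2);
    # cumulative sum gives prefix-overlap counts for every cutoff pair
    # genes ranked beyond the last full threshold on either axis can never
    # fall inside a prefix pair, so they contribute to no cell
    inside = (r1 <= thresholds[-1]) & (r2 <= thresholds[-1])
    b1 = (r1[inside] - 1) // step
    b2 = (r2[inside] - 1) // step
    hist = np.zeros((nt, nt))
    np.add.at(hist, (b1, b2), 1.0)
    k = hist.cumsum(axis=0).cumsum(axis=1)
    counted1 = thresholds[:, None].astype(float)
    counted2 = thresholds[None, :].astype(float)
    expected = counted1 * counted2 / N
    sign = np.where(k >= expected, 1.0, -1.0)
    p = hypergeom.sf(
        k - 1,
        N,
        np.broadcast_to(counted1, k.shape),
        np.broadcast_to(counted2, k.shape),
    )
    logp = sign * (-np.log10(np.maximum(p, _P_FLOOR)))

    rho1 = list1.rho_series().loc[genes].to_numpy()
    rho2 = list2.rho_series().loc[genes].to_numpy()
    rho_rrho = spearman(rho1, rho2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = spearman(rho1, rng.permutation(rho2))
    p_rrho = float(np.mean(np.abs(null) >= abs(rho_rrho)))

    return RRHOResult(
        step=int(step),
        thresholds_1=thresholds,
        thresholds_2=thresholds,
        signed_logp=logp,
        rho_rrho=rho_rrho,
        p_rrho=p_rrho,
    )
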