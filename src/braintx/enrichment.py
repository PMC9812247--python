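"""Category and gene-set enrichment of correlation profiles.

Two complementary analyses of a ranked correlation table:

* **GCEA** (gene-category enrichment analysis): each category's statistic is
  the mean gene score (one-sided positive/negative or absolute transform of
  rho) over its annotated genes, tested against an ensemble null in which
  the *activation map* is replaced by variogram-matched surrogates and all
  gene correlations are recomputed per null map. Surrogating the phenotype
  map, rather than the gene maps, keeps the gene-gene correlation structure
  intact under the null and makes the cost linear in the number of nulls.
  Benjamini-Hochberg adjustment across tested categories.

* **GSEA** (gene-set enrichment analysis): a weighted Kolmogorov-Smirnov
  running sum walked down the rho-ranked list; hits add |rho|^w normalized
  by the set total, misses subtract 1/(N - m). The enrichment score is the
  signed maximum deviation from zero, tested against gene-label
  permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .correlate import CorrelationTable, spearman_matrix
from .errors import DegenerateSetError, ParameterError
from .io import SpatialProfile
from .surrogates import generate_surrogates

__all__ = [
    "GSEAResult",
    "gene_scores",
    "gcea",
    "gsea_es",
    "gsea_pvalue",
    "bh_adjust",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("positive", "negative", "absolute")


@dataclass
class GSEAResult:
    es: float
    es_curve: np.ndarray  # running sum, one value per rank position
    p: float | None
    max_position: int  # 1-based rank index of the maximal |deviation|


def gene_scores(table: CorrelationTable, direction: str = "positive") -> pd.Series:
    """Nonnegative per-gene scores from a correlation table.

    positive: max(rho, 0); negative: max(-rho, 0); absolute: |rho|. Genes
    that correlate strongly in the requested direction get high scores.
    """
    if direction not in DIRECTIONS:
        raise ParameterError(f"direction must be one of {DIRECTIONS}")
    rho = table.rho_series()
    if direction == "positive":
        return rho.clip(lower=0.0)
    if direction == "negative":
        return (-rho).clip(lower=0.0)
    return rho.abs()


def _direction_transform(rho: np.ndarray, direction: str) -> np.ndarray:
    if direction == "positive":
        return np.maximum(rho, 0.0)
    if direction == "negative":
        return np.maximum(-rho, 0.0)
    return np.abs(rho)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def gcea(
    scores: pd.Series,
    annotations: dict[str, list[str]],
    activation: SpatialProfile,
    expression: pd.DataFrame,
    n_nulls: int = 1000,
    seed: int = 0,
    direction: str = "positive",
    size_range: tuple[int, int] = (5, 200),
    k_neighbors: int = 20,
    ensemble=None,
) -> pd.DataFrame:
    """Gene-category enrichment with a spatial ensemble null.

    Categories are tested if their annotation count within the scored gene
    universe lies in ``size_range`` (default 5-200). p_raw is the literal
    proportion of null category means >= the observed mean; for BH
    adjustment a zero proportion is replaced by 1 / (2 n_nulls) so the
    adjustment stays well-defined. Result sorted by p_cor, then by
    descending mean gene score.

    ``ensemble`` allows passing a precomputed surrogate ensemble of the
    activation profile (it is the expensive stage and can be shared).
    """
    if n_nulls < 100:
        raise ParameterError("n_nulls must be >= 100")
    universe = set(scores.index)
    tested = {}
    for cat, members in annotations.items():
        known = sorted(set(members) & universe)
        if size_range[0] <= len(known) <= size_range[1]:
            tested[cat] = known
    if not tested:
        logger.warning(
            "no category has %d-%d annotated genes in the universe", *size_range
        )
        return pd.DataFrame(
            columns=["category_id", "n_annotated", "mean_gene_score", "p_raw", "p_cor"]
        )

    if ensemble is None:
        ensemble = generate_surrogates(
            activation,
            k_neighbors=k_neighbors,
            n_surrogates=n_nulls,
            seed=seed,
        )
    elif ensemble.n_surrogates < n_nulls:
        raise ParameterError("provided ensemble smaller than n_nulls")

    gene_order = list(scores.index)
    expr = expression.loc[gene_order, list(activation.unit_ids)].to_numpy(dtype=float)
    # null rho: every gene against every surrogate activation map
    null_rho = np.empty((n_nulls, len(gene_order)))
    for b in range(n_nulls):
        null_rho[b] = spearman_matrix(expr, ensemble.surrogates[b])
    null_scores = _direction_transform(null_rho, direction)

    cat_ids = sorted(tested)
    gene_pos = {g: i for i, g in enumerate(gene_order)}
    indicator = np.zeros((len(cat_ids), len(gene_order)))
    for ci, cat in enumerate(cat_ids):
        for g in tested[cat]:
            indicator[ci, gene_pos[g]] = 1.0
    sizes = indicator.sum(axis=1)
    observed = (indicator @ scores.to_numpy()) / sizes
    null_means = (null_scores @ indicator.T) / sizes  # (n_nulls, n_cats)
    p_raw = (null_means >= observed[None, :]).mean(axis=0)

    p_for_bh = np.where(p_raw == 0, 1.0 / (2 * n_nulls), p_raw)
    p_cor = bh_adjust(p_for_bh)
    out = pd.DataFrame(
        {
            "category_id": cat_ids,
            "n_annotated": sizes.astype(int),
            "mean_gene_score": observed,
            "p_raw": p_raw,
            "p_cor": p_cor,
        }
    )
    return out.sort_values(
        ["p_cor", "mean_gene_score"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def _validate_set(table: CorrelationTable, gene_set) -> np.ndarray:
    genes = table.gene_ids
    gene_set = set(gene_set)
    unknown = gene_set - set(genes.tolist())
    if unknown:
        raise ParameterError(f"gene set members outside universe: {sorted(unknown)[:5]}")
    if len(gene_set) == 0 or len(gene_set) >= len(genes):
        raise DegenerateSetError(
            "gene set must be nonempty and a strict subset of the universe"
        )
    return np.array([g in gene_set for g in genes])


def _es_from_membership(
    rho_sorted: np.ndarray, member: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray, int]:
    """Running-sum ES for a membership mask aligned with the sorted list."""
    n = len(rho_sorted)
    m = int(member.sum())
    w = np.abs(rho_sorted) ** weight_exponent
    hit_total = w[member].sum()
    if hit_total == 0:
        # all member weights zero: hits step uniformly (KS limit)
        hit_steps = member / m
    else:
        hit_steps = np.where(member, w / hit_total, 0.0)
    miss_steps = np.where(member, 0.0, 1.0 / (n - m))
    curve = np.cumsum(hit_steps - miss_steps)
    pos = int(np.argmax(np.abs(curve)))
    return float(curve[pos]), curve, pos + 1


def gsea_es(
    table: CorrelationTable, gene_set, weight_exponent: float = 1.0
) -> GSEAResult:
    """Weighted KS enrichment score of a gene set on the rho-ranked list.

    The running sum increases by |rho|^w / sum_set |rho|^w at set members
    and decreases by 1/(N - m) elsewhere; ES is its value at the maximal
    absolute deviation from zero. The sum returns to zero at the end of the
    list (checked on every call).
    """
    member = _validate_set(table, gene_set)
    rho = table.data["rho"].to_numpy()
    es, curve, pos = _es_from_membership(rho, member, weight_exponent)
    if abs(curve[-1]) > 1e-9:
        raise AssertionError("GSEA running sum did not return to zero")
    return GSEAResult(es=es, es_curve=curve, p=None, max_position=pos)


def gsea_pvalue(
    table: CorrelationTable,
    gene_set,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """GSEA ES with a two-sided gene-label permutation p-value.

    Null ES values come from random re-assignments of set membership over
    list positions (set size preserved); p is the proportion of null |ES|
    >= observed |ES|. No multiple-testing adjustment: this tests one set.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    member = _validate_set(table, gene_set)
    rho = table.data["rho"].to_numpy()
    es, curve, pos = _es_from_membership(rho, member, weight_exponent)

    n = len(rho)
    m = int(member.sum())
    rng = np.random.default_rng(seed)
    w = np.abs(rho) ** weight_exponent
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=m, replace=False)] = True
        hit_total = w[mask].sum()
        if hit_total == 0:
            hit_steps = mask / m
        else:
            hit_steps = np.where(mask, w / hit_total, 0.0)
        c = np.cumsum(hit_steps - np.where(mask, 0.0, 1.0 / (n - m)))
        null_es[b] = c[np.argmax(np.abs(c))]
    p = float(np.mean(np.abs(null_es) >= abs(es)))
    return GSEAResult(es=es, es_curve=curve, p=p, max_position=pos)
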