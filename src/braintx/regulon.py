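"""Master-regulator nomination from motif gene rankings.

Given a motif database that ranks the whole gene universe per motif (rank 1
= strongest motif evidence), a query gene set (here: the genes whose
expression correlates with an activation map beyond |rho| > 0.5) is scored
per motif by the area under its rank-recovery curve within the top
``auc_max_fraction`` of the ranking. AUCs are z-scored across the database
into a normalized enrichment score (NES); motifs with NES above a threshold
(default 3) nominate their annotated regulator as a master regulator, and
the final report intersects nominated regulators with a risk-gene list,
quoting targets as "n_targets/n_possible".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlate import CorrelationTable, threshold_correlations
from .errors import DegenerateDatabaseError, ParameterError

__all__ = [
    "RegulonRecord",
    "MasterRegulatorReport",
    "recovery_auc",
    "nes_scores",
    "master_regulators",
]

logger = logging.getLogger(__name__)


@dataclass
class RegulonRecord:
    motif_id: str
    regulator_gene_id: str
    auc: float
    nes: float
    targets: tuple[str, ...]
    n_possible: int

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def target_label(self) -> str:
        return f"{self.n_targets}/{self.n_possible}"


@dataclass
class MasterRegulatorReport:
    """Per-direction NES tables and risk-filtered regulator records."""

    nes_tables: dict[str, pd.DataFrame]  # direction -> motif table
    records: dict[str, list[RegulonRecord]]  # direction -> risk-matched records

    def grid_cell(self, direction: str) -> str:
        """Table-style cell: 'REG (n/N); ...' or '-' when empty."""
        recs = self.records.get(direction, [])
        if not recs:
            return "-"
        return "; ".join(
            f"{r.regulator_gene_id} ({r.target_label})" for r in recs
        )


def recovery_auc(ranking: pd.Series, gene_set, auc_max_fraction: float = 0.05) -> float:
    """Area under the rank-recovery curve of ``gene_set`` in ``ranking``.

    ``ranking`` maps gene id -> rank (1..N, no ties). With
    R = ceil(auc_max_fraction * N), the recovery curve y(x) counts set
    genes at rank <= x for x = 1..R; the AUC is sum(y) / (|set| * R), so 1
    means every set gene sits at the very top and 0 means none appear
    within the window.
    """
    if not 0 < auc_max_fraction <= 0.2:
        raise ParameterError("auc_max_fraction must be in (0, 0.2]")
    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ParameterError("gene_set must be nonempty")
    N = len(ranking)
    R = int(np.ceil(auc_max_fraction * N))
    ranks = ranking.loc[gene_set].to_numpy()
    inside = ranks[ranks <= R]
    # sum_x y(x) = sum over recovered genes of (R - rank + 1)
    return float((R - inside + 1).sum() / (len(gene_set) * R))


def nes_scores(aucs: pd.Series) -> pd.Series:
    """Normalized enrichment: z-score of each motif's AUC across the
    database (sample standard deviation)."""
    if len(aucs) < 3:
        raise ParameterError("need at least 3 motifs")
    sd = float(aucs.std(ddof=1))
    if not sd > 1e-12 * max(1.0, float(aucs.abs().max())):
        raise DegenerateDatabaseError("all motif AUCs identical; NES undefined")
    return (aucs - aucs.mean()) / sd


def _direction_records(
    gene_set: set[str],
    db,
    risk_genes: set[str],
    nes_min: float,
    auc_max_fraction: float,
) -> tuple[pd.DataFrame, list[RegulonRecord]]:
    motifs = db.motif_ids
    aucs = pd.Series(
        {
            m: recovery_auc(db.ranks.loc[m], gene_set, auc_max_fraction)
            for m in motifs
        }
    )
    nes = nes_scores(aucs)
    table = pd.DataFrame(
        {
            "motif_id": motifs,
            "regulator_gene_id": [db.regulators[m] for m in motifs],
            "auc": aucs.loc[motifs].to_numpy(),
            "nes": nes.loc[motifs].to_numpy(),
        }
    ).sort_values("nes", ascending=False, kind="mergesort").reset_index(drop=True)

    N = db.ranks.shape[1]
    R = int(np.ceil(auc_max_fraction * N))
    records: list[RegulonRecord] = []
    retained = table[table["nes"] > nes_min]  # strict: NES above threshold
    # several motifs may share a regulator: keep each regulator's best motif
    best = retained.loc[retained.groupby("regulator_gene_id")["nes"].idxmax()]
    for row in best.sort_values("nes", ascending=False).itertuples(index=False):
        if row.regulator_gene_id not in risk_genes:
            continue
        ranking = db.ranks.loc[row.motif_id]
        targets = tuple(
            sorted(g for g in gene_set if ranking[g] <= R)
        )
        records.append(
            RegulonRecord(
                motif_id=row.motif_id,
                regulator_gene_id=row.regulator_gene_id,
                auc=row.auc,
                nes=row.nes,
                targets=targets,
                n_possible=len(gene_set),
            )
        )
    return table, records


def master_regulators(
    corr_table: CorrelationTable,
    db,
    risk_genes,
    rho_min: float = 0.5,
    nes_min: float = 3.0,
    auc_max_fraction: float = 0.05,
) -> MasterRegulatorReport:
    """Nominate master regulators separately for the positive (rho >
    rho_min) and negative (rho < -rho_min) correlated gene sets.

    Per direction: motif AUCs and NES over the whole database, retention of
    motifs with NES strictly above ``nes_min``, target extraction within
    the AUC window, and intersection of the retained regulators with the
    risk list. An empty input set yields an empty report cell ('-').
    """
    if len(db.motif_ids) == 0:
        raise ParameterError("motif database is empty")
    risk = set(risk_genes)
    positive, negative = threshold_correlations(corr_table, rho_min)
    nes_tables: dict[str, pd.DataFrame] = {}
    records: dict[str, list[RegulonRecord]] = {}
    for direction, gene_set in (("positive", positive), ("negative", negative)):
        if not gene_set:
            logger.warning(
                "no genes with %s correlation beyond |rho| > %.2f (%s/%s)",
                direction, rho_min, corr_table.compartment, corr_table.granularity,
            )
            nes_tables[direction] = pd.DataFrame(
                columns=["motif_id", "regulator_gene_id", "auc", "nes"]
            )
            records[direction] = []
            continue
        table, recs = _direction_records(
            gene_set, db, risk, nes_min, auc_max_fraction
        )
        nes_tables[direction] = table
        records[direction] = recs
    return MasterRegulatorReport(nes_tables=nes_tables, records=records)
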