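"""End-to-end orchestration: simulate (or load) -> extract -> correlate ->
spatial p -> RRHO -> GCEA -> GSEA -> master regulators.

The pipeline runs every stage per compartment (cortex, subcortex) and
paradigm, never mixing compartments, and writes a deterministic results
bundle: ranked correlation tables, RRHO summaries, enrichment tables and a
master-regulator grid, each TSV carrying a provenance header (config hash +
seed). Identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .correlate import CorrelationTable, correlate_genes
from .enrichment import gcea, gene_scores, gsea_pvalue
from .errors import ParameterError
from .io import Atlas, SpatialProfile
from .regulon import MasterRegulatorReport, master_regulators
from .rrho import RRHOResult, rrho_map
from .surrogates import (
    ensemble_correlations,
    format_p_value,
    generate_surrogates,
    spatial_pvalue,
)
from .synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_activation,
    generate_annotations,
    generate_atlas,
    generate_expression,
    planted_gene_ids,
    split_profile,
)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "compare_parcellations"]

logger = logging.getLogger(__name__)

VALID_COMPARTMENTS = ("cortex", "subcortex")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings. Defaults are the study conventions: 1000
    surrogates per map, k = 20 (cortex) / 5 (subcortex) nearest neighbors,
    |rho| > 0.5 effect-size threshold, NES > 3, GSEA weight 1, categories
    with 5-200 annotations."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    paradigms: tuple[str, ...] = ("task", "control")
    compartments: tuple[str, ...] = ("cortex", "subcortex")
    n_surrogates: int = 1000
    k_cortex: int = 20
    k_subcortex: int = 5
    rho_min: float = 0.5
    nes_min: float = 3.0
    gsea_weight: float = 1.0
    category_size: tuple[int, int] = (5, 200)
    n_perm_gsea: int = 1000
    n_nulls_gcea: int = 1000
    auc_max_fraction: float = 0.05
    gene_pvalues: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.compartments) - set(VALID_COMPARTMENTS)
        if bad:
            raise ParameterError(
                f"unsupported compartment(s) {sorted(bad)}; the analysis covers "
                f"{VALID_COMPARTMENTS} only (cerebellum is out of scope)"
            )
        for name, v in (
            ("n_surrogates", self.n_surrogates),
            ("n_perm_gsea", self.n_perm_gsea),
            ("n_nulls_gcea", self.n_nulls_gcea),
        ):
            if v < 1:
                raise ParameterError(f"{name} must be positive")

    def k_for(self, compartment: str) -> int:
        return self.k_cortex if compartment == "cortex" else self.k_subcortex

    def content_hash(self) -> str:
        # output_dir is excluded: where results land must not change them
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ResultBundle:
    config: PipelineConfig
    config_hash: str
    atlas: Atlas
    expression: pd.DataFrame
    ground_truth: GroundTruth
    annotations: dict[str, list[str]]
    risk_genes: list[str]
    regulon_db: object
    activations: dict[str, SpatialProfile] = field(default_factory=dict)
    tables: dict[tuple[str, str, str], CorrelationTable] = field(default_factory=dict)
    rrho: dict[tuple[str, str], RRHOResult] = field(default_factory=dict)
    gcea: dict[tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    gsea: dict[tuple[str, str], object] = field(default_factory=dict)
    regulons: dict[tuple[str, str], MasterRegulatorReport] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def regulator_grid(self, paradigm: str) -> pd.DataFrame:
        """Compartment x direction grid of 'regulator (n/N)' cells."""
        rows = {}
        for comp in self.config.compartments:
            report = self.regulons.get((paradigm, comp))
            rows[comp] = {
                d: (report.grid_cell(d) if report else "-")
                for d in ("positive", "negative")
            }
        return pd.DataFrame(rows).T


def _header(bundle_hash: str, seed: int) -> list[str]:
    return [f"braintx {_pkg_version} config={bundle_hash} seed={seed}"]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-18s %6.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run the full synthetic-mode analysis and (optionally) write a
    results bundle to ``config.output_dir``."""
    syn = config.synthetic
    t0 = time.perf_counter()

    atlas = generate_atlas(syn)
    expression = generate_expression(syn, atlas)
    t0 = _stage("simulate", t0)

    truth: GroundTruth | None = None
    activations: dict[str, SpatialProfile] = {}
    planted_primary = planted_gene_ids(syn)
    for i, paradigm in enumerate(config.paradigms):
        if i == 0:
            act, truth = generate_activation(syn, expression, atlas, stage="activation")
        else:
            # control paradigms plant a disjoint gene set of the same size
            rng = np.random.default_rng([syn.seed & 0x7FFFFFFF, 1000 + i])
            pool = [g for g in expression.index if g not in set(planted_primary)]
            alt = tuple(
                sorted(np.asarray(pool)[rng.permutation(len(pool))[: len(planted_primary)]])
            )
            act, _ = generate_activation(
                syn, expression, atlas, planted=alt, stage=f"activation_{paradigm}"
            )
        activations[paradigm] = act
    annotations, risk_genes, db = generate_annotations(syn, truth)
    t0 = _stage("activation", t0)

    bundle = ResultBundle(
        config=config,
        config_hash=config.content_hash(),
        atlas=atlas,
        expression=expression,
        ground_truth=truth,
        annotations=annotations,
        risk_genes=risk_genes,
        regulon_db=db,
    )
    bundle.activations = activations

    # correlate + per-gene spatial p
    for paradigm, act in activations.items():
        for comp in config.compartments:
            prof = split_profile(act, atlas, comp)
            expr_c = expression.loc[:, prof.unit_ids]
            table = correlate_genes(expr_c, prof)
            if config.gene_pvalues:
                table = attach_gene_pvalues(
                    table,
                    expr_c,
                    prof,
                    k_neighbors=config.k_for(comp),
                    n_surrogates=config.n_surrogates,
                    seed=config.seed,
                )
            bundle.tables[(paradigm, comp, "region")] = table
    t0 = _stage("correlate", t0)

    # RRHO between paradigm pairs, per compartment
    names = list(config.paradigms)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            for comp in config.compartments:
                res = rrho_map(
                    bundle.tables[(names[a], comp, "region")],
                    bundle.tables[(names[b], comp, "region")],
                    seed=config.seed,
                )
                bundle.rrho[(f"{names[a]}|{names[b]}", comp)] = res
    t0 = _stage("rrho", t0)

    # enrichment + regulons for the primary paradigm
    primary = names[0]
    for comp in config.compartments:
        table = bundle.tables[(primary, comp, "region")]
        prof = split_profile(activations[primary], atlas, comp)
        ensemble = generate_surrogates(
            prof,
            k_neighbors=config.k_for(comp),
            n_surrogates=config.n_nulls_gcea,
            seed=config.seed,
        )
        for direction in ("positive", "negative"):
            scores = gene_scores(table, direction)
            bundle.gcea[(primary, comp, direction)] = gcea(
                scores,
                annotations,
                prof,
                expression,
                n_nulls=config.n_nulls_gcea,
                seed=config.seed,
                direction=direction,
                size_range=config.category_size,
                k_neighbors=config.k_for(comp),
                ensemble=ensemble,
            )
        risk_in_universe = sorted(set(risk_genes) & set(table.gene_ids.tolist()))
        bundle.gsea[(primary, comp)] = gsea_pvalue(
            table,
            risk_in_universe,
            weight_exponent=config.gsea_weight,
            n_perm=config.n_perm_gsea,
            seed=config.seed,
        )
        bundle.regulons[(primary, comp)] = master_regulators(
            table,
            db,
            risk_genes,
            rho_min=config.rho_min,
            nes_min=config.nes_min,
            auc_max_fraction=config.auc_max_fraction,
        )
    t0 = _stage("enrichment", t0)

    if config.output_dir is not None:
        write_bundle(bundle, Path(config.output_dir))
        _stage("write", t0)
    return bundle


def attach_gene_pvalues(
    table: CorrelationTable,
    expression: pd.DataFrame,
    activation: SpatialProfile,
    k_neighbors: int,
    n_surrogates: int,
    seed: int,
) -> CorrelationTable:
    """Fill the p_spatial column: per gene, generate a variogram-matched
    surrogate ensemble of the *gene's* map (activation held fixed) and take
    the two-sided proportion of surrogate |rho| exceeding the observed."""
    dist = activation.distance_matrix()
    pvals = {}
    for i, gene in enumerate(table.gene_ids):
        values = expression.loc[gene, activation.unit_ids].to_numpy(dtype=float)
        ens = generate_surrogates(
            values,
            distance_matrix=dist,
            k_neighbors=k_neighbors,
            n_surrogates=n_surrogates,
            seed=(seed + i) & 0x7FFFFFFF,
        )
        rhos = ensemble_correlations(ens, activation.values)
        obs = float(table.rho_series().loc[gene])
        pvals[gene] = spatial_pvalue(obs, rhos)
    data = table.data.copy()
    data["p_spatial"] = data["gene_id"].map(pvals)
    return CorrelationTable(
        data,
        table.compartment,
        table.granularity,
        table.n_units,
        table.excluded_genes,
    )


def parcellate_matrix(volumes: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """Region means of a stack of voxel maps (n_maps, *grid), fast path.

    Zero-valued voxels are excluded from each region's mean (the background
    convention); a region whose voxels are all zero for a map yields NaN.
    """
    labels = atlas.labels.ravel()
    flat = volumes.reshape(volumes.shape[0], -1)
    region_ids = atlas.regions["region_id"].to_numpy()
    out = np.empty((flat.shape[0], len(region_ids)))
    nonzero = flat != 0
    for j, rid in enumerate(region_ids):
        mask = labels == rid
        vals = flat[:, mask]
        nz = nonzero[:, mask]
        counts = nz.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, j] = np.where(
                counts > 0, (vals * nz).sum(axis=1) / np.maximum(counts, 1), np.nan
            )
    return pd.DataFrame(out, columns=region_ids)


def compare_parcellations(
    syn: SyntheticConfig,
    compartment: str = "cortex",
    jitter_sd: float = 0.05,
    seed: int | None = None,
) -> RRHOResult:
    """Run the same synthetic voxel maps under two different parcellations
    and RRHO the resulting ranked gene lists.

    Atlas A is the config's parcellation; atlas B re-parcellates the same
    grid from a different random seeding. Gene and activation volumes are
    painted from atlas-A region values (plus within-region jitter) and then
    reduced to region means under each atlas, mimicking an atlas-robustness
    analysis; high rho_rrho means the ranking is parcellation-stable.
    """
    from .synthetic import activation_volume, expression_volumes
    from ._rng import substream

    atlas_a = generate_atlas(syn)
    # second parcellation: same grid geometry, different random seeding
    syn_b = replace(syn, seed=(syn.seed + 104729) & 0x7FFFFFFF)
    atlas_b = generate_atlas(syn_b)

    expression = generate_expression(syn, atlas_a)
    act, _ = generate_activation(syn, expression, atlas_a)

    rng = substream(syn.seed, "parcellation_compare")
    labels = atlas_a.labels
    region_ids = atlas_a.regions["region_id"].to_numpy()
    vol_stack = np.zeros((len(expression) + 1, *labels.shape))
    values_by_region = {
        rid: np.flatnonzero(labels.ravel() == rid) for rid in region_ids
    }
    flat_stack = vol_stack.reshape(vol_stack.shape[0], -1)
    act_series = pd.Series(act.values, index=act.unit_ids)
    for rid in region_ids:
        idx = values_by_region[rid]
        jitter = rng.standard_normal((vol_stack.shape[0], len(idx))) * jitter_sd
        jitter -= jitter.mean(axis=1, keepdims=True)
        base = np.concatenate(
            [expression[rid].to_numpy(), [act_series.loc[rid]]]
        )
        flat_stack[:, idx] = base[:, None] + jitter

    tables = []
    for atlas in (atlas_a, atlas_b):
        means = parcellate_matrix(vol_stack, atlas)
        comp_ids = atlas.region_ids(compartment)
        expr_df = means.iloc[:-1][comp_ids]
        expr_df.index = expression.index
        prof = SpatialProfile(
            comp_ids,
            means.iloc[-1][comp_ids].to_numpy(),
            compartment,
            atlas.centroids(compartment),
            granularity="region",
        )
        tables.append(correlate_genes(expr_df.dropna(axis=1), prof)
                      if expr_df.isna().any().any() else correlate_genes(expr_df, prof))
    return rrho_map(tables[0], tables[1], seed=seed if seed is not None else syn.seed)


# ---------------------------------------------------------------------------
# output writing


def write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    """Write all bundle artifacts as TSV/JSON plus a MANIFEST."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _header(bundle.config_hash, bundle.config.seed)
    manifest: dict[str, object] = {
        "package": f"braintx {_pkg_version}",
        "config_hash": bundle.config_hash,
        "seed": bundle.config.seed,
        "files": [],
    }

    def record(path: Path) -> None:
        manifest["files"].append(str(path.relative_to(out_dir)))

    for (paradigm, comp, gran), table in bundle.tables.items():
        path = out_dir / f"correlations_{paradigm}_{comp}_{gran}.tsv"
        table.to_tsv(path, header)
        record(path)

    for (pair, comp), res in bundle.rrho.items():
        stem = pair.replace("|", "_vs_")
        mat = out_dir / f"rrho_{stem}_{comp}.tsv"
        with open(mat, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            pd.DataFrame(
                res.signed_logp, index=res.thresholds_1, columns=res.thresholds_2
            ).to_csv(fh, sep="\t", lineterminator="\n")
        record(mat)
        summary = out_dir / f"rrho_{stem}_{comp}.json"
        summary.write_text(
            json.dumps(
                {"rho_rrho": res.rho_rrho, "p_rrho": res.p_rrho, "step": res.step},
                sort_keys=True,
            )
        )
        record(summary)

    for (paradigm, comp, direction), df in bundle.gcea.items():
        path = out_dir / f"gcea_{paradigm}_{comp}_{direction}.tsv"
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        record(path)

    for (paradigm, comp), res in bundle.gsea.items():
        path = out_dir / f"gsea_{paradigm}_{comp}.json"
        path.write_text(
            json.dumps(
                {"es": res.es, "p": res.p, "max_position": res.max_position},
                sort_keys=True,
            )
        )
        record(path)
        curve = out_dir / f"gsea_curve_{paradigm}_{comp}.tsv"
        with open(curve, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            pd.DataFrame(
                {"position": np.arange(1, len(res.es_curve) + 1),
                 "running_sum": res.es_curve}
            ).to_csv(fh, sep="\t", index=False, lineterminator="\n")
        record(curve)

    primary = bundle.config.paradigms[0]
    grid = bundle.regulator_grid(primary)
    path = out_dir / f"master_regulators_{primary}.tsv"
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        grid.to_csv(fh, sep="\t", lineterminator="\n")
    record(path)
    for (paradigm, comp), report in bundle.regulons.items():
        for direction, table in report.nes_tables.items():
            p = out_dir / f"nes_{paradigm}_{comp}_{direction}.tsv"
            with open(p, "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                table.to_csv(fh, sep="\t", index=False, lineterminator="\n")
            record(p)

    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(bundle.ground_truth.to_json())
    record(truth_path)

    (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
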