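"""Synthetic study generator.

Emulates the statistical structure the analysis assumes, so every downstream
stage is testable without external downloads:

* a labeled parcellation (cortex + subcortex compartments) on a voxel grid,
* spatially autocorrelated gene expression fields (Gaussian random fields
  with exponential covariance ``exp(-d / correlation_length)`` over region
  centroids),
* an activation map with a planted association to a subset of genes,
* a toy GO-like ontology with one category seeded from the planted genes,
* a risk-gene list and a motif/regulon database with one planted master
  regulator whose targets sit at the top of its genome-wide ranking.

Planted genes share a common latent spatial factor with per-gene loadings in
``PLANTED_LOADING_RANGE``; the activation map mixes the standardized mean of
the planted genes' profiles with an independent smooth field and white
noise, weighted by ``planted_effect``. With the default loadings, a planted
gene's correlation with the activation map is approximately
``planted_effect * loading``, which makes the planted signal recoverable at
the rho > 0.5 effect-size threshold while non-planted genes stay near zero.

All outputs are pure functions of (config, seed); each stage draws from its
own named substream so stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ParameterError, SizingError
from .io import Atlas, BrainVolume, SpatialProfile

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "RegulonDB",
    "generate_atlas",
    "generate_expression",
    "generate_activation",
    "generate_annotations",
    "expression_volumes",
    "activation_volume",
]

#: per-gene loading of planted genes on the shared latent factor
PLANTED_LOADING_RANGE = (0.7, 0.9)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults give a desk-scale analogue of a whole-brain study: 500 genes
    over 100 cortical and 30 subcortical regions, a strong planted effect
    (0.9) with modest observation noise (0.2), and a 6 mm spatial
    correlation length on a 40 x 40 x 24 mm grid (2 mm voxels) — about
    0.15 of the grid extent, mirroring the ratio of expression-map
    autocorrelation length to brain size at full scale.
    """

    n_genes: int = 500
    n_regions_cortex: int = 100
    n_regions_subcortex: int = 30
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    correlation_length: float = 6.0
    planted_gene_fraction: float = 0.05
    planted_effect: float = 0.9
    noise_sd: float = 0.2
    n_categories: int = 40
    category_size_range: tuple[int, int] = (5, 50)
    n_motifs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_categories < 1 or self.n_motifs < 1:
            raise ParameterError("counts must be positive")
        if self.n_regions_cortex < 2 or self.n_regions_subcortex < 2:
            raise ParameterError("need at least 2 regions per compartment")
        if not 0.0 <= self.planted_gene_fraction <= 1.0:
            raise ParameterError("planted_gene_fraction must be in [0, 1]")
        if not 0.0 <= self.planted_effect <= 1.0:
            raise ParameterError("planted_effect must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.correlation_length <= 0:
            raise ParameterError("correlation_length must be positive")
        lo, hi = self.category_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ParameterError(
                f"category sizes must lie within [2, n_genes], got {self.category_size_range}"
            )
        if any(g < 1 for g in self.grid_shape):
            raise ParameterError("grid_shape entries must be positive")

    @property
    def n_regions(self) -> int:
        return self.n_regions_cortex + self.n_regions_subcortex

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    planted_gene_ids: tuple[str, ...]
    true_mixing_weights: dict[str, float]
    planted_category_id: str | None = None
    planted_regulator_id: str | None = None
    regulator_targets: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_gene_ids": list(self.planted_gene_ids),
                "true_mixing_weights": self.true_mixing_weights,
                "planted_category_id": self.planted_category_id,
                "planted_regulator_id": self.planted_regulator_id,
                "regulator_targets": list(self.regulator_targets),
            },
            sort_keys=True,
        )


@dataclass
class RegulonDB:
    """Motif database: per motif a regulator gene and a complete, tie-free
    ranking of the gene universe (rank 1 = best)."""

    ranks: pd.DataFrame  # index: motif_id, columns: gene ids, values: ranks 1..N
    regulators: dict[str, str]  # motif_id -> regulator gene id

    def __post_init__(self) -> None:
        n = self.ranks.shape[1]
        expected = np.arange(1, n + 1)
        for motif_id, row in self.ranks.iterrows():
            if not np.array_equal(np.sort(row.to_numpy()), expected):
                raise ParameterError(
                    f"motif {motif_id}: ranking is not a permutation of 1..{n}"
                )
        missing = set(self.ranks.index) - set(self.regulators)
        if missing:
            raise ParameterError(f"motifs without regulator annotation: {sorted(missing)}")

    @property
    def motif_ids(self) -> list[str]:
        return list(self.ranks.index)


def planted_gene_ids(config: SyntheticConfig) -> tuple[str, ...]:
    """Deterministic planted-gene subset derived from (config, seed).

    Shared between expression and activation generation so both agree on
    which genes carry the planted signal.
    """
    k = int(np.ceil(config.planted_gene_fraction * config.n_genes))
    rng = substream(config.seed, "planted")
    idx = rng.permutation(config.n_genes)[:k]
    genes = config.gene_ids
    return tuple(sorted(genes[i] for i in idx))


# ---------------------------------------------------------------------------
# atlas


def generate_atlas(config: SyntheticConfig) -> Atlas:
    """Voronoi parcellation of the voxel grid into cortex + subcortex.

    The grid is split along z into a subcortical slab (proportional to the
    requested region ratio, at least one slice) and a cortical remainder;
    within each compartment, voxels are assigned to the nearest of randomly
    placed seed voxels, which guarantees nonempty, contiguous-ish parcels.
    """
    rng = substream(config.seed, "atlas")
    nx, ny, nz = config.grid_shape
    frac_sub = config.n_regions_subcortex / config.n_regions
    nz_sub = min(max(1, int(round(frac_sub * nz))), nz - 1)

    coords = np.indices(config.grid_shape).reshape(3, -1).T  # (V, 3) int
    is_sub = coords[:, 2] < nz_sub

    labels = np.zeros(coords.shape[0], dtype=int)
    rows = []
    next_id = 1
    for compartment, mask, n_req in (
        ("subcortex", is_sub, config.n_regions_subcortex),
        ("cortex", ~is_sub, config.n_regions_cortex),
    ):
        vox = coords[mask]
        if n_req > len(vox):
            raise SizingError(
                f"cannot host {n_req} {compartment} regions in {len(vox)} voxels"
            )
        seed_idx = rng.choice(len(vox), size=n_req, replace=False)
        seeds = vox[seed_idx]
        d2 = ((vox[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        labels[np.flatnonzero(mask)] = assign + next_id
        vs = np.array(config.voxel_size)
        for j in range(n_req):
            members = vox[assign == j]
            centroid = members.mean(axis=0) * vs
            rows.append(
                {
                    "region_id": next_id + j,
                    "compartment": compartment,
                    "x": centroid[0],
                    "y": centroid[1],
                    "z": centroid[2],
                    "n_voxels": len(members),
                }
            )
        next_id += n_req

    regions = pd.DataFrame(rows).sort_values("region_id").reset_index(drop=True)
    return Atlas(
        labels.reshape(config.grid_shape),
        regions,
        voxel_size=config.voxel_size,
    )


# ---------------------------------------------------------------------------
# expression


def _grf_factor(centroids: np.ndarray, correlation_length: float) -> np.ndarray:
    """Cholesky factor of the exponential covariance exp(-d / lambda)."""
    diff = centroids[:, None, :] - centroids[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    cov = np.exp(-d / correlation_length)
    # small jitter keeps the factorization stable for near-duplicate centroids
    return np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_expression(
    config: SyntheticConfig,
    atlas: Atlas,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Region-level gene expression: genes x regions DataFrame.

    Every gene is a zero-mean Gaussian random field over region centroids
    with covariance ``exp(-d / correlation_length)``; planted genes blend a
    shared latent field (loading w) with their own field (sqrt(1 - w^2)),
    and the loadings are recorded in ``df.attrs["mixing_weights"]``.
    ``noise_sd`` adds independent observation noise on top.
    """
    if config.correlation_length <= 0:
        raise ParameterError("correlation_length must be positive")
    regions = atlas.regions.sort_values("region_id")
    centroids = regions[["x", "y", "z"]].to_numpy(dtype=float)
    L = _grf_factor(centroids, config.correlation_length)
    n_units = len(centroids)

    rng = substream(config.seed, "expression")
    fields = (L @ rng.standard_normal((n_units, config.n_genes))).T  # genes x regions
    latent = _zscore(L @ rng.standard_normal(n_units))

    genes = config.gene_ids
    planted = planted_gene_ids(config)
    lo, hi = PLANTED_LOADING_RANGE
    weights = {g: 0.0 for g in genes}
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in planted:
        w = float(rng.uniform(lo, hi))
        weights[g] = w
        i = gene_index[g]
        fields[i] = w * latent + np.sqrt(1.0 - w**2) * _zscore(fields[i])
    if noise_sd > 0:
        fields = fields + noise_sd * rng.standard_normal(fields.shape)

    df = pd.DataFrame(fields, index=genes, columns=regions["region_id"].to_numpy())
    df.attrs["planted_gene_ids"] = planted
    df.attrs["mixing_weights"] = weights
    return df


# ---------------------------------------------------------------------------
# activation


def generate_activation(
    config: SyntheticConfig,
    expression: pd.DataFrame,
    atlas: Atlas,
    planted: tuple[str, ...] | None = None,
    stage: str = "activation",
) -> tuple[SpatialProfile, GroundTruth]:
    """Whole-brain activation profile with a planted gene association.

    activation = planted_effect * z(mean of planted genes' profiles)
               + (1 - planted_effect) * z(independent smooth field)
               + noise_sd * white noise

    ``planted`` overrides the config-derived planted set (used to build
    control paradigms on disjoint genes); ``stage`` names the random
    substream so several paradigms can coexist under one seed.
    """
    if planted is None:
        planted = planted_gene_ids(config)
    if len(planted) == 0:
        raise ParameterError("planted gene set is empty")
    unknown = set(planted) - set(expression.index)
    if unknown:
        raise ParameterError(f"planted genes not in expression matrix: {sorted(unknown)}")

    regions = atlas.regions.sort_values("region_id")
    centroids = regions[["x", "y", "z"]].to_numpy(dtype=float)
    region_ids = regions["region_id"].to_numpy()
    expr = expression.loc[:, region_ids]

    rng = substream(config.seed, stage)
    planted_mean = _zscore(expr.loc[list(planted)].mean(axis=0).to_numpy())
    L = _grf_factor(centroids, config.correlation_length)
    background = _zscore(L @ rng.standard_normal(len(centroids)))
    act = (
        config.planted_effect * planted_mean
        + (1.0 - config.planted_effect) * background
        + config.noise_sd * rng.standard_normal(len(centroids))
    )

    weights = expression.attrs.get("mixing_weights", {})
    truth = GroundTruth(
        planted_gene_ids=tuple(planted),
        true_mixing_weights={g: weights.get(g, float("nan")) for g in planted},
    )
    # the profile spans both compartments ("all"); slice with split_profile
    profile = SpatialProfile(region_ids, act, "all", centroids, granularity="region")
    return profile, truth


def split_profile(profile: SpatialProfile, atlas: Atlas, compartment: str) -> SpatialProfile:
    """Restrict a whole-brain region profile to one compartment."""
    ids = atlas.region_ids(compartment)
    mask = np.isin(profile.unit_ids, ids)
    return SpatialProfile(
        profile.unit_ids[mask],
        profile.values[mask],
        compartment,
        profile.coordinates[mask],
        granularity=profile.granularity,
    )


# ---------------------------------------------------------------------------
# annotations, risk list, regulons


def generate_annotations(
    config: SyntheticConfig,
    ground_truth: GroundTruth,
) -> tuple[dict[str, list[str]], list[str], RegulonDB]:
    """Toy ontology, risk-gene list and motif/regulon database.

    One category is seeded predominantly with planted genes; one motif ranks
    the planted regulator's targets (a subset of the planted genes) at the
    top while all other motif rankings are uniform permutations. The risk
    list contains the planted regulator, half of the planted genes, and a
    few decoys. Updates ``ground_truth`` in place with the planted category
    and regulator ids.
    """
    rng = substream(config.seed, "annotations")
    genes = config.gene_ids
    planted = list(ground_truth.planted_gene_ids)
    lo, hi = config.category_size_range
    if lo > config.n_genes:
        raise ParameterError("category_size_range infeasible for gene universe")

    width = len(str(config.n_categories))
    categories: dict[str, list[str]] = {}
    for c in range(1, config.n_categories + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(config.n_genes, size=size, replace=False)
        categories[f"CAT{c:0{width}d}"] = sorted(genes[i] for i in members)
    # planted category: all planted genes plus ~20% random padding
    pad = rng.choice(
        [g for g in genes if g not in set(planted)],
        size=max(1, len(planted) // 5),
        replace=False,
    )
    planted_cat_id = f"CAT{config.n_categories + 1:0{width}d}"
    categories[planted_cat_id] = sorted(planted + list(pad))

    # regulator: a non-planted gene whose targets are most of the planted set
    non_planted = [g for g in genes if g not in set(planted)]
    regulator = str(rng.choice(non_planted))
    n_targets = max(1, int(round(0.8 * len(planted))))
    targets = sorted(rng.choice(planted, size=n_targets, replace=False))

    # motif database
    mwidth = len(str(config.n_motifs))
    motif_ids = [f"MOT{m:0{mwidth}d}" for m in range(1, config.n_motifs + 1)]
    planted_motif = str(rng.choice(motif_ids))
    rank_rows = np.empty((config.n_motifs, config.n_genes), dtype=int)
    regulators: dict[str, str] = {}
    target_idx = [genes.index(g) for g in targets]
    other_idx = [i for i in range(config.n_genes) if i not in set(target_idx)]
    for m, motif in enumerate(motif_ids):
        if motif == planted_motif:
            order = np.concatenate(
                [rng.permutation(target_idx), rng.permutation(other_idx)]
            )
            regulators[motif] = regulator
        else:
            order = rng.permutation(config.n_genes)
            regulators[motif] = str(rng.choice(genes))
        ranks = np.empty(config.n_genes, dtype=int)
        ranks[order] = np.arange(1, config.n_genes + 1)
        rank_rows[m] = ranks
    db = RegulonDB(
        pd.DataFrame(rank_rows, index=motif_ids, columns=genes), regulators
    )

    half = rng.choice(planted, size=max(1, len(planted) // 2), replace=False)
    decoys = rng.choice(
        [g for g in non_planted if g != regulator], size=5, replace=False
    )
    risk_genes = sorted({regulator, *half, *decoys})

    ground_truth.planted_category_id = planted_cat_id
    ground_truth.planted_regulator_id = regulator
    ground_truth.regulator_targets = tuple(targets)
    return categories, risk_genes, db


# ---------------------------------------------------------------------------
# voxel volumes


def expression_volumes(
    config: SyntheticConfig,
    atlas: Atlas,
    expression: pd.DataFrame,
    jitter_sd: float = 0.05,
) -> dict[str, BrainVolume]:
    """Paint region-level expression into voxel volumes.

    Each region's voxels get the region value plus zero-mean within-region
    jitter, so region means recover the generating values exactly.
    """
    rng = substream(config.seed, "volumes")
    out: dict[str, BrainVolume] = {}
    labels = atlas.labels
    region_ids = atlas.regions["region_id"].to_numpy()
    masks = {rid: labels == rid for rid in region_ids}
    for gene in expression.index:
        vol = np.zeros(labels.shape, dtype=float)
        for rid in region_ids:
            mask = masks[rid]
            jitter = rng.standard_normal(int(mask.sum())) * jitter_sd
            jitter -= jitter.mean()  # zero-mean per region: means are exact
            vol[mask] = expression.at[gene, rid] + jitter
        out[str(gene)] = BrainVolume(vol, atlas.voxel_size, atlas.origin)
    return out


def activation_volume(
    config: SyntheticConfig, atlas: Atlas, activation: SpatialProfile, jitter_sd: float = 0.05
) -> BrainVolume:
    """Paint a whole-brain region activation profile into a voxel volume."""
    rng = substream(config.seed, "activation_volume")
    vol = np.zeros(atlas.labels.shape, dtype=float)
    for rid, val in zip(activation.unit_ids, activation.values):
        mask = atlas.labels == rid
        jitter = rng.standard_normal(int(mask.sum())) * jitter_sd
        jitter -= jitter.mean()
        vol[mask] = val + jitter
    return BrainVolume(vol, atlas.voxel_size, atlas.origin)
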