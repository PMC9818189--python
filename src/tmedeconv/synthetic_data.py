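"""Synthetic atlases, bulk cohorts, and survival tables with known truth.

Every downstream stage (signature construction, deconvolution, pseudo-bulk
validation, survival stratification) is testable against ground truth
produced here, without downloading any accession.

The atlas generator plants, for each leaf cell type, a block of marker genes
whose expected expression is ``marker_fold_change`` times the shared
background; counts are negative-binomial with a common overdispersion and
log-normal library-size variation across cells. Subtypes inherit their
parent's marker block and add a small private block, so collapsing the
cell-type tree has measurable consequences for marker selection.

The cohort generator composes bulk samples as Dirichlet-weighted convex
combinations of per-type mean profiles (multiplicative log-normal noise,
scale 0 = exact mixture) and draws survival times from an exponential model
whose log-hazard is linear in one chosen cell-type fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas, GeneMatrix, TypeTree, type_mean_profiles
from .errors import ConfigurationError, DataError
from .survival import SurvivalRecord

__all__ = [
    "AtlasSpec",
    "CohortSpec",
    "make_atlas",
    "make_cohort",
]

# library-size spread (log-normal sigma); modest depth variation typical of
# droplet scRNA-seq after basic QC
_LIBSIZE_SIGMA = 0.25


@dataclass
class AtlasSpec:
    """Parameters of a synthetic annotated scRNA-seq atlas.

    ``subtype_map`` maps a top-level type name (``type_0`` ... by default)
    to its subtype names; subtypes become the leaves carrying cells.
    ``dispersion`` is the negative-binomial overdispersion alpha in
    Var = mu + alpha * mu^2.
    """

    n_types: int = 4
    subtype_map: dict[str, list[str]] = field(default_factory=dict)
    n_cells_per_type: int = 100
    n_genes: int = 1000
    n_markers_per_type: int = 20
    marker_fold_change: float = 8.0
    dispersion: float = 0.5
    library_size_mean: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ConfigurationError("invalid AtlasSpec: n_types must be >= 2")
        if self.marker_fold_change <= 1:
            raise ConfigurationError(
                "invalid AtlasSpec: marker_fold_change must be > 1"
            )
        if self.n_markers_per_type < 1 or self.n_cells_per_type < 1 or self.n_genes < 1:
            raise ConfigurationError("invalid AtlasSpec: counts must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("invalid AtlasSpec: dispersion must be positive")
        if self.library_size_mean <= 0:
            raise ConfigurationError(
                "invalid AtlasSpec: library_size_mean must be positive"
            )
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ConfigurationError(
                "invalid AtlasSpec: n_markers_per_type x n_types must be <= n_genes"
            )
        known = set(self.type_names())
        bad = set(self.subtype_map) - known
        if bad:
            raise ConfigurationError(
                f"invalid AtlasSpec: subtype_map keys {sorted(bad)} are not top-level "
                f"types {sorted(known)}"
            )

    def type_names(self) -> list[str]:
        return [f"type_{i}" for i in range(self.n_types)]

    def leaf_names(self) -> list[str]:
        leaves: list[str] = []
        for t in self.type_names():
            leaves.extend(self.subtype_map.get(t, [t]))
        return leaves

    def n_private_markers(self) -> int:
        """Size of a subtype's private marker block (quarter of the shared block)."""
        return max(1, self.n_markers_per_type // 4)


@dataclass
class CohortSpec:
    """Parameters of a synthetic bulk cohort with linked survival.

    ``log_hazard_ratio_per_unit_fraction`` is the log hazard ratio between a
    patient with fraction 1 and fraction 0 of ``effect_type``;
    ``baseline_hazard`` is events per month at fraction 0. ``noise_scale``
    is the sigma of multiplicative log-normal noise on the mixed profile
    (0 = exact convex combination).
    """

    n_patients: int = 100
    fraction_prior: Sequence[float] | None = None
    effect_type: str = ""
    log_hazard_ratio_per_unit_fraction: float = 0.0
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.2
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("invalid CohortSpec: n_patients must be >= 2")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigurationError(
                "invalid CohortSpec: censoring_rate must lie in [0, 1)"
            )
        if self.baseline_hazard <= 0:
            raise ConfigurationError(
                "invalid CohortSpec: baseline_hazard must be positive"
            )
        if self.noise_scale < 0:
            raise ConfigurationError("invalid CohortSpec: noise_scale must be >= 0")
        if self.fraction_prior is not None and np.any(
            np.asarray(self.fraction_prior, dtype=float) <= 0
        ):
            raise ConfigurationError(
                "invalid CohortSpec: fraction_prior concentrations must be strictly positive"
            )


def _marker_layout(spec: AtlasSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Assign disjoint marker-gene index blocks to each leaf type.

    Parents with subtypes contribute one shared block inherited by all their
    subtypes; each subtype additionally receives a small private block.
    """
    m, mp = spec.n_markers_per_type, spec.n_private_markers()
    need = 0
    for t in spec.type_names():
        subs = spec.subtype_map.get(t)
        need += m + (len(subs) * mp if subs else 0)
    if need > spec.n_genes:
        raise ConfigurationError(
            f"invalid AtlasSpec: marker blocks need {need} genes "
            f"(shared {m}/type + private {mp}/subtype) but n_genes={spec.n_genes}"
        )
    pool = rng.permutation(spec.n_genes)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        block = pool[cursor : cursor + k]
        cursor += k
        return block

    markers: dict[str, np.ndarray] = {}
    for t in spec.type_names():
        shared = take(m)
        subs = spec.subtype_map.get(t)
        if subs:
            for s in subs:
                markers[s] = np.concatenate([shared, take(mp)])
        else:
            markers[t] = shared
    return markers


def make_atlas(
    spec: AtlasSpec,
    rate_jitter: float = 0.0,
    jitter_seed: int | None = None,
) -> Atlas:
    """Generate a synthetic annotated atlas.

    ``rate_jitter`` > 0 perturbs the per-gene baseline rates with log-normal
    noise of that sigma (seeded by ``jitter_seed``), producing a sibling
    "study" whose per-type profiles differ from the unjittered atlas --
    useful for cross-study validation experiments.

    The returned atlas records ground truth under ``uns``: the planted
    marker gene IDs per leaf type and the baseline rates.
    """
    rng = np.random.default_rng(spec.seed)
    base_rate = rng.gamma(shape=2.0, scale=1.0, size=spec.n_genes) + 0.05
    markers = _marker_layout(spec, rng)
    if rate_jitter > 0:
        jrng = np.random.default_rng(
            spec.seed + 1 if jitter_seed is None else jitter_seed
        )
        base_rate = base_rate * jrng.lognormal(0.0, rate_jitter, size=spec.n_genes)

    leaves = spec.leaf_names()
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    # expected relative expression per type: background + fold-change markers
    mean = np.tile(base_rate[:, None], (1, len(leaves)))
    for j, leaf in enumerate(leaves):
        mean[markers[leaf], j] *= spec.marker_fold_change
    prop = mean / mean.sum(axis=0)

    n_cells = spec.n_cells_per_type * len(leaves)
    labels = np.repeat(leaves, spec.n_cells_per_type)
    lib = spec.library_size_mean * rng.lognormal(
        -0.5 * _LIBSIZE_SIGMA**2, _LIBSIZE_SIGMA, size=n_cells
    )
    type_index = np.repeat(np.arange(len(leaves)), spec.n_cells_per_type)
    mu = prop[:, type_index] * lib[None, :]
    k = 1.0 / spec.dispersion  # NB size parameter
    counts = rng.negative_binomial(k, k / (k + mu)).astype(float)

    children: dict[str, list[str]] = {"root": spec.type_names()}
    for t, subs in spec.subtype_map.items():
        if subs:
            children[t] = list(subs)
    tree = TypeTree(children)
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    uns = {
        "markers": {leaf: [gene_ids[g] for g in np.sort(markers[leaf])] for leaf in leaves},
        "base_rate": base_rate,
        "spec": spec,
    }
    return Atlas(counts, gene_ids, cell_ids, labels, tree, uns)


def make_cohort(
    spec: CohortSpec, atlas: Atlas
) -> tuple[GeneMatrix, pd.DataFrame, list[SurvivalRecord]]:
    """Simulate a bulk cohort with survival linked to one cell-type fraction.

    Each bulk sample is the fraction-weighted combination of the atlas's
    per-type mean expression profiles, with multiplicative log-normal noise.
    Survival times are exponential with log-hazard linear in the
    ``effect_type`` fraction; censoring is applied independently per patient
    with probability ``censoring_rate`` (censoring time uniform on the
    latent event time).

    Returns the bulk matrix, the true fraction table (patients x types),
    and the survival records (times in months).
    """
    profiles, types = type_mean_profiles(atlas)
    if spec.effect_type not in types:
        raise DataError(
            f"effect_type {spec.effect_type!r} is not a cell type of this atlas; "
            f"available types: {types}"
        )
    prior = (
        np.ones(len(types))
        if spec.fraction_prior is None
        else np.asarray(spec.fraction_prior, dtype=float)
    )
    if prior.shape != (len(types),):
        raise ConfigurationError(
            f"fraction_prior length {prior.size} does not match {len(types)} cell types"
        )
    rng = np.random.default_rng(spec.seed)
    fractions = rng.dirichlet(prior, size=spec.n_patients)  # patients x types
    bulk = profiles @ fractions.T  # genes x patients
    if spec.noise_scale > 0:
        s = spec.noise_scale
        bulk = bulk * rng.lognormal(-0.5 * s**2, s, size=bulk.shape)

    j = types.index(spec.effect_type)
    hazard = spec.baseline_hazard * np.exp(
        spec.log_hazard_ratio_per_unit_fraction * fractions[:, j]
    )
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(spec.n_patients) < spec.censoring_rate
    observed = np.where(censored, rng.uniform(0, event_time), event_time)

    sample_ids = [f"P{i:04d}" for i in range(spec.n_patients)]
    bulk_gm = GeneMatrix(bulk, atlas.gene_ids, sample_ids)
    frac_df = pd.DataFrame(fractions, index=sample_ids, columns=types)
    records = [
        SurvivalRecord(sid, float(t), bool(e))
        for sid, t, e in zip(sample_ids, observed, ~censored)
    ]
    return bulk_gm, frac_df, records
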