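"""Synthetic cohorts with planted group structure for pipeline testing.

Generates subjects x regions tables of non-negative, overdispersed
activation counts (negative binomial), demographic covariates drawn from
per-class moment specifications, optional case subgroup labels, and —
when voxel-level inputs are needed — full statistical maps over a toy
atlas whose suprathreshold counts reproduce the generated table exactly.

The default parameters mirror a two-class cohort of 80 cases and 31
controls over 117 regions with a 23/46/11 three-way case subgroup split.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SizingError, ValidationError
from .parcellation_features import (
    AtlasParcellation,
    FeatureTable,
    StatMap,
)

DEFAULT_N_REGIONS = 117
DEFAULT_SUBGROUP_LABELS = ("START", "STOPP", "POTS")


def region_name(region_id: int) -> str:
    return f"Region_{region_id:03d}"


@dataclass
class CovariateParams:
    """Per-class covariate moments: truncated-normal age/BMI, Bernoulli sex."""

    age_mean: float = 45.0
    age_sd: float = 10.0
    bmi_mean: float = 29.0
    bmi_sd: float = 5.0
    prop_male: float = 0.7
    age_bounds: tuple[float, float] = (18.0, 80.0)
    bmi_bounds: tuple[float, float] = (15.0, 60.0)

    def validate(self, cls_label: str) -> None:
        if self.age_sd <= 0 or self.bmi_sd <= 0:
            raise ValidationError(f"covariate_params[{cls_label}]: SDs must be > 0")
        if not 0.0 <= self.prop_male <= 1.0:
            raise ValidationError(f"covariate_params[{cls_label}].prop_male must be in [0,1]")


# Defaults follow the two-class demographic profile the simulator emulates:
# cases  age 46.9 +/- 7.8, BMI 29.6 +/- 5.6, 73.8% male
# controls age 43.9 +/- 16.3, BMI 28.4 +/- 4.5, 61.3% male
DEFAULT_COVARIATES = {
    "case": CovariateParams(46.9, 7.8, 29.6, 5.6, 0.738),
    "control": CovariateParams(43.9, 16.3, 28.4, 4.5, 0.613),
}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``effect_regions`` maps region id -> per-class additive shift of the
    expected count; ``subgroup_effect_regions`` maps region id ->
    per-subgroup shift applied to case subjects on top of the class
    shift.  ``correlation_block`` lists (region_a, region_b, rho) pairs
    whose counts are coupled through a Gaussian copula.
    """

    n_per_group: list[int] = field(default_factory=lambda: [80, 31])
    group_labels: tuple[str, ...] = ("case", "control")
    n_regions: int = DEFAULT_N_REGIONS
    effect_regions: dict[int, list[float]] = field(default_factory=dict)
    baseline_mean: float = 20.0
    dispersion: float = 5.0
    covariate_params: dict[str, CovariateParams] = field(default_factory=dict)
    correlation_block: list[tuple[int, int, float]] = field(default_factory=list)
    subgroup_sizes: list[int] | None = None
    subgroup_labels: tuple[str, ...] = DEFAULT_SUBGROUP_LABELS
    subgroup_effect_regions: dict[int, list[float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.covariate_params:
            self.covariate_params = {
                lbl: DEFAULT_COVARIATES.get(lbl, CovariateParams()) for lbl in self.group_labels
            }

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))

    @property
    def n_classes(self) -> int:
        return len(self.n_per_group)

    def validate(self) -> None:
        if len(self.group_labels) != len(self.n_per_group):
            raise ValidationError("n_per_group: length must match group_labels")
        if any(n <= 0 for n in self.n_per_group):
            raise ValidationError("n_per_group: every class must be non-empty")
        if self.n_subjects < 2:
            raise ValidationError("n_per_group: need at least 2 subjects in total")
        if self.n_regions < 1:
            raise ValidationError("n_regions: must be >= 1")
        if self.baseline_mean < 0:
            raise ValidationError("baseline_mean: must be >= 0")
        if not self.dispersion > 0:
            raise ValidationError("dispersion: must be > 0")
        for rid, shifts in self.effect_regions.items():
            if not 1 <= rid <= self.n_regions:
                raise ValidationError(f"effect_regions: region id {rid} outside 1..{self.n_regions}")
            if len(shifts) != self.n_classes:
                raise ValidationError(f"effect_regions[{rid}]: need one shift per class")
            if any(self.baseline_mean + s < 0 for s in shifts):
                raise ValidationError(f"effect_regions[{rid}]: expected count would be negative")
        for lbl in self.group_labels:
            if lbl not in self.covariate_params:
                raise ValidationError(f"covariate_params: missing class {lbl!r}")
            self.covariate_params[lbl].validate(lbl)
        for a, b, rho in self.correlation_block:
            if not (1 <= a <= self.n_regions and 1 <= b <= self.n_regions) or a == b:
                raise ValidationError(f"correlation_block: bad pair ({a},{b})")
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"correlation_block: rho {rho} outside (-1,1)")
        if self.subgroup_sizes is not None:
            if len(self.subgroup_sizes) != len(self.subgroup_labels):
                raise ValidationError("subgroup_sizes: length must match subgroup_labels")
            if any(s < 0 for s in self.subgroup_sizes):
                raise ValidationError("subgroup_sizes: must be non-negative")
            if sum(self.subgroup_sizes) != self.n_per_group[0]:
                raise ValidationError(
                    "subgroup_sizes: must sum to the case class size "
                    f"({self.n_per_group[0]})"
                )
        for rid, shifts in self.subgroup_effect_regions.items():
            if not 1 <= rid <= self.n_regions:
                raise ValidationError(f"subgroup_effect_regions: region id {rid} out of range")
            if len(shifts) != len(self.subgroup_labels):
                raise ValidationError(f"subgroup_effect_regions[{rid}]: need one shift per subgroup")

    # -- JSON config round trip -------------------------------------------
    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["effect_regions"] = {str(k): v for k, v in payload["effect_regions"].items()}
        payload["subgroup_effect_regions"] = {
            str(k): v for k, v in payload["subgroup_effect_regions"].items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CohortSpec":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        payload["group_labels"] = tuple(payload["group_labels"])
        payload["subgroup_labels"] = tuple(payload["subgroup_labels"])
        payload["effect_regions"] = {int(k): list(v) for k, v in payload["effect_regions"].items()}
        payload["subgroup_effect_regions"] = {
            int(k): list(v) for k, v in payload["subgroup_effect_regions"].items()
        }
        payload["correlation_block"] = [tuple(t) for t in payload["correlation_block"]]
        payload["covariate_params"] = {
            k: CovariateParams(**{**v, "age_bounds": tuple(v["age_bounds"]), "bmi_bounds": tuple(v["bmi_bounds"])})
            for k, v in payload["covariate_params"].items()
        }
        return cls(**payload)


@dataclass
class ToyAtlasSpec:
    """Deterministic toy parcellation: contiguous equal blocks on a grid."""

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 8
    voxels_per_region: int = 10

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(d <= 0 for d in self.grid_shape):
            raise ValidationError("grid_shape: must be three positive dimensions")
        if self.n_regions < 1:
            raise ValidationError("n_regions: must be >= 1")
        if self.voxels_per_region < 1:
            raise ValidationError("voxels_per_region: must be >= 1")
        if int(np.prod(self.grid_shape)) < self.n_regions * self.voxels_per_region:
            raise SizingError(
                f"grid of {int(np.prod(self.grid_shape))} voxels cannot hold "
                f"{self.n_regions} regions of >= {self.voxels_per_region} voxels"
            )


# ---------------------------------------------------------------------------


def _truncnorm(rng: np.random.Generator, mean, sd, bounds, size):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _nb_p(mu: np.ndarray, theta: float) -> np.ndarray:
    return theta / (theta + mu)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Negative-binomial counts, optionally coupled through a Gaussian copula."""
    theta = spec.dispersion
    if not spec.correlation_block:
        return rng.negative_binomial(theta, _nb_p(mu, theta))
    corr = np.eye(spec.n_regions)
    for a, b, rho in spec.correlation_block:
        corr[a - 1, b - 1] = corr[b - 1, a - 1] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("correlation_block: target matrix is not positive definite") from exc
    z = rng.standard_normal(mu.shape) @ chol.T
    u = stats.norm.cdf(z)
    counts = stats.nbinom.ppf(u, theta, _nb_p(mu, theta))
    return counts.astype(int)


def generate_feature_table(spec: CohortSpec) -> FeatureTable:
    """Draw a full cohort table: counts, covariates, class and subgroup labels.

    Identical spec and seed give a bitwise-identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = [region_name(i) for i in range(1, spec.n_regions + 1)]

    count_blocks, meta_rows = [], []
    offset = 0
    for cls_idx, (label, n_cls) in enumerate(zip(spec.group_labels, spec.n_per_group)):
        # case subgroups (first class only, when requested)
        if cls_idx == 0 and spec.subgroup_sizes is not None:
            sub = np.repeat(list(spec.subgroup_labels), spec.subgroup_sizes)
            sub = rng.permutation(sub)
        else:
            sub = np.array(["none"] * n_cls, dtype=object)

        mu = np.full((n_cls, spec.n_regions), float(spec.baseline_mean))
        for rid, shifts in spec.effect_regions.items():
            mu[:, rid - 1] += shifts[cls_idx]
        if cls_idx == 0:
            for rid, shifts in spec.subgroup_effect_regions.items():
                for g_idx, g_label in enumerate(spec.subgroup_labels):
                    mu[sub == g_label, rid - 1] += shifts[g_idx]
        mu = np.clip(mu, 0.0, None)

        counts = _draw_counts(rng, mu, spec)
        cov = spec.covariate_params[label]
        age = _truncnorm(rng, cov.age_mean, cov.age_sd, cov.age_bounds, n_cls)
        bmi = _truncnorm(rng, cov.bmi_mean, cov.bmi_sd, cov.bmi_bounds, n_cls)
        sex = (rng.random(n_cls) < cov.prop_male).astype(int)

        count_blocks.append(counts)
        for i in range(n_cls):
            meta_rows.append(
                {
                    "subject_id": f"sub-{offset + i + 1:03d}",
                    "group": label,
                    "subgroup": sub[i],
                    "age": age[i],
                    "sex": int(sex[i]),
                    "bmi": bmi[i],
                }
            )
        offset += n_cls

    meta = pd.DataFrame(meta_rows).set_index("subject_id")
    counts = pd.DataFrame(np.vstack(count_blocks), index=meta.index, columns=names)
    return FeatureTable(counts, meta)


def generate_toy_atlas(spec: ToyAtlasSpec) -> AtlasParcellation:
    """Tile the grid into ``n_regions`` contiguous equal blocks (label 0 = background)."""
    spec.validate()
    total = int(np.prod(spec.grid_shape))
    block = total // spec.n_regions
    flat = np.zeros(total, dtype=int)
    for rid in range(1, spec.n_regions + 1):
        flat[(rid - 1) * block : rid * block] = rid
    regions = pd.DataFrame(
        {
            "id": np.arange(1, spec.n_regions + 1),
            "name": [region_name(i) for i in range(1, spec.n_regions + 1)],
        }
    )
    return AtlasParcellation(flat.reshape(spec.grid_shape), regions)


def generate_statmaps(
    cohort: CohortSpec,
    atlas: AtlasParcellation,
    t_threshold: float = 3.17,
) -> tuple[list[StatMap], FeatureTable]:
    """Jointly generate voxel maps and the count table they reduce to.

    Background voxels are sub-threshold Gaussian noise (truncated at the
    threshold); each region receives exactly its table count of planted
    strictly-suprathreshold voxels, so re-extraction with
    :func:`roilogit.parcellation_features.count_suprathreshold` recovers
    the returned table cell-for-cell.  Counts exceeding a region's voxel
    capacity are clipped (and the table reflects the clip).
    """
    if not np.isfinite(t_threshold):
        raise ValidationError("t_threshold must be finite")
    atlas_ids = set(atlas.region_ids.tolist())
    cohort_ids = set(range(1, cohort.n_regions + 1))
    if not cohort_ids <= atlas_ids:
        raise ValidationError("atlas regions must cover every cohort region")

    table = generate_feature_table(cohort)
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 0x5A7]))

    # voxel indices per region, in atlas-table order
    flat_labels = atlas.labels.ravel()
    region_voxels = {int(rid): np.flatnonzero(flat_labels == rid) for rid in atlas.region_ids}
    capacity = {rid: idx.size for rid, idx in region_voxels.items()}

    # table over atlas regions: cohort regions keep generated counts,
    # extra atlas regions count zero
    counts = pd.DataFrame(0, index=table.counts.index, columns=atlas.region_names)
    for rid, name in zip(atlas.region_ids, atlas.region_names):
        if int(rid) in cohort_ids:
            col = table.counts[region_name(int(rid))].to_numpy()
            counts[name] = np.minimum(col, capacity[int(rid)])
    out_table = FeatureTable(counts, table.metadata.copy())

    tail = stats.norm.cdf(t_threshold)
    count_matrix = out_table.counts.to_numpy()
    maps: list[StatMap] = []
    for pos, sid in enumerate(out_table.subject_ids):
        noise = stats.norm.ppf(rng.random(flat_labels.size) * tail)
        for col, rid in enumerate(atlas.region_ids):
            k = int(count_matrix[pos, col])
            if k > 0:
                chosen = rng.choice(region_voxels[int(rid)], size=k, replace=False)
                noise[chosen] = t_threshold + 0.5 + rng.exponential(1.0, size=k)
        maps.append(StatMap(noise.reshape(atlas.labels.shape), subject_id=sid))
    return maps, out_table
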