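"""Pearson correlation screening of region features.

Two consumers: the |R| >= r_max multicollinearity gate that decides
which regions survive into feature selection, and the descriptive census
of strongly correlated region pairs used to compare groups and days.

The gate always *eliminates* (drops the later region in column order)
rather than combining; every drop is reported with the offending pair
and coefficient so the decision is reversible downstream.  The gate uses
|R|: a near-perfect negative correlation is just as collinear as a
positive one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SampleSizeError, ValidationError
from .parcellation_features import FeatureTable


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over region features.

    Columns with zero variance cannot carry a correlation; they are
    listed in ``zero_variance`` (their entries are set to 0) rather than
    silently propagating NaN.
    """

    values: np.ndarray
    region_names: list[str]
    n_subjects: int
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.region_names)
        if self.values.shape != (k, k):
            raise ValidationError("matrix shape must match region_names")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.values)) > 1 + 1e-9:
            raise ValidationError("correlation entries must lie in [-1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_names, columns=self.region_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def pair(self, a: str, b: str) -> float:
        i, j = self.region_names.index(a), self.region_names.index(b)
        return float(self.values[i, j])


@dataclass
class ScreenReport:
    """Outcome of the multicollinearity gate."""

    retained: list[str]
    dropped: list[dict]
    r_max: float

    def to_json(self) -> str:
        return json.dumps({"r_max": self.r_max, "retained": self.retained, "dropped": self.dropped}, indent=2)


@dataclass
class CensusResult:
    """Counts of unordered off-diagonal pairs beyond strict cutoffs."""

    above: dict[float, int]
    below_neg_half: int
    n_pairs: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs_above": {str(k): v for k, v in self.above.items()},
                "pairs_below_-0.5": self.below_neg_half,
                "n_pairs": self.n_pairs,
            },
            indent=2,
        )


def correlation_matrix(table: FeatureTable) -> CorrelationMatrix:
    """Pearson product-moment correlations between all region count columns."""
    if table.n_subjects < 3:
        raise SampleSizeError(f"need >= 3 subjects, got {table.n_subjects}")
    x = table.counts.to_numpy(dtype=float)
    sd = x.std(axis=0)
    flagged = [name for name, s in zip(table.region_names, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return CorrelationMatrix(corr, list(table.region_names), table.n_subjects, flagged)


def multicollinearity_screen(matrix: CorrelationMatrix, r_max: float = 0.9) -> ScreenReport:
    """Drop regions until no retained pair reaches |R| >= r_max.

    Pairs are visited in column order; the later member of the first
    offending pair is dropped (deterministic tie-break, recorded in the
    report).  Zero-variance columns are exempt from the gate — they carry
    no correlation signal to act on.
    """
    if not 0.0 < r_max <= 1.0:
        raise ValidationError(f"r_max must be in (0, 1], got {r_max}")
    names = matrix.region_names
    skip = set(matrix.zero_variance)
    retained = [n for n in names]
    alive = {n: True for n in names}
    dropped: list[dict] = []
    k = len(names)
    for i in range(k):
        if not alive[names[i]] or names[i] in skip:
            continue
        for j in range(i + 1, k):
            if not alive[names[j]] or names[j] in skip:
                continue
            r = matrix.values[i, j]
            if abs(r) >= r_max:
                alive[names[j]] = False
                dropped.append(
                    {
                        "dropped": names[j],
                        "kept": names[i],
                        "r": float(r),
                        "rule": "later-ordered member of offending pair removed",
                    }
                )
    retained = [n for n in names if alive[n]]
    return ScreenReport(retained=retained, dropped=dropped, r_max=r_max)


def screen_across_splits(
    table: FeatureTable,
    train_ids,
    test_ids,
    r_max: float = 0.9,
) -> ScreenReport:
    """Run the gate on training, test, and full data; drop the union.

    A region failing the gate in *any* of the three runs is dropped
    globally.  Splits with fewer than 3 subjects cannot support a
    correlation estimate and are skipped.
    """
    reports = []
    for ids in (list(train_ids), list(test_ids), list(table.subject_ids)):
        if len(ids) < 3:
            continue
        reports.append(multicollinearity_screen(correlation_matrix(table.subset(ids)), r_max))
    dropped_names = set()
    dropped_records: list[dict] = []
    for split, rep in zip(("train", "test", "full"), reports):
        for rec in rep.dropped:
            if rec["dropped"] not in dropped_names:
                dropped_names.add(rec["dropped"])
                dropped_records.append({**rec, "split": split})
    retained = [n for n in table.region_names if n not in dropped_names]
    return ScreenReport(retained=retained, dropped=dropped_records, r_max=r_max)


def strong_correlation_census(
    matrix: CorrelationMatrix,
    cutoffs: list[float] = (0.7, 0.8, 0.9),
) -> CensusResult:
    """Count unordered pairs with R strictly above each cutoff, plus R < -0.5."""
    vals = matrix.values
    iu = np.triu_indices(len(matrix.region_names), k=1)
    upper = vals[iu]
    above = {float(c): int((upper > c).sum()) for c in cutoffs}
    return CensusResult(above=above, below_neg_half=int((upper < -0.5).sum()), n_pairs=int(upper.size))


def plot_heatmap(matrix: CorrelationMatrix, path, title: str = "") -> None:
    """Presentation-only heatmap export (values untested numerically)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_title(title or f"Pearson R ({matrix.n_subjects} subjects)")
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120)
    plt.close(fig)
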