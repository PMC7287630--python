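"""Machine-readable transcriptions of the published model tables.

Four printed models are packaged: the binary case/control logits for
Day 1 and Day 2 (a single coefficient per region, transcribed from the
cerebellar/thalamic and cerebral coefficient tables, which share one
intercept row per day), and the three-subgroup (START/STOPP/POTS)
one-vs-rest models for Day 1 and Day 2 (three coefficients per region).

The transcriptions are shipped as CSV inside the package; SHA-256
checksums guard against drift.  Region naming follows the tables'
underscored AAL strings, with the AAL index as the primary key.

Fixture notes (transcription discrepancies kept as printed):
- the running text assigns coefficient 0.5282 to Temporal_Pole_Sup_L
  while the table assigns it to Temporal_Sup_L; the fixture follows the
  table;
- the running text counts 49 subgroup Day-1 regions while the table
  prints 47 rows; the fixture follows the table;
- the subgroup table prints region names with spaces; the fixture
  normalizes them to the underscored form used everywhere else.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..classifier_core import FittedLogit
from ..exceptions import ValidationError

MODEL_LABELS = ("Day1", "Day2", "Subgroup-Day1", "Subgroup-Day2")
SUBGROUP_CLASSES = ("START", "STOPP", "POTS")

_CHECKSUMS = {
    "case_control_models.csv": "ad377c9d28251bb3f81636ab654b979fb3134136b6f8219931e6fdccb3ef5410",
    "subgroup_models.csv": "63c8b0461d50b3e4ebf451843803ebe92bdb58550d94f3b2d4f1288d1a4440cd",
    "intercepts.json": "e2c7fc15b475d34d6217ac0799b31857000c145f3fccdbeff754061ebf727047",
}


def _read_data(filename: str) -> bytes:
    raw = resources.files(__package__).joinpath("data", filename).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise ValidationError(
            f"fixture {filename} checksum mismatch (transcription drift?): {digest}"
        )
    return raw


def _load_tables():
    import io

    cc = pd.read_csv(io.BytesIO(_read_data("case_control_models.csv")))
    sub = pd.read_csv(io.BytesIO(_read_data("subgroup_models.csv")))
    intercepts = json.loads(_read_data("intercepts.json"))
    return cc, sub, intercepts


@dataclass
class PrintedModel:
    """One printed model: intercept(s) plus per-region coefficient entries.

    ``entries`` has columns aal_id, name, hemisphere and either a single
    ``coefficient`` column (binary models) or one column per subgroup
    class.  Only regions with a populated coefficient for the model's
    day are included.
    """

    label: str
    intercept: float | dict
    entries: pd.DataFrame
    classes: tuple[str, ...] | None = None

    @property
    def region_ids(self) -> set[int]:
        return set(int(i) for i in self.entries["aal_id"])

    @property
    def region_names(self) -> list[str]:
        return self.entries["name"].tolist()

    def name_of(self, aal_id: int) -> str:
        row = self.entries.loc[self.entries["aal_id"] == aal_id]
        if row.empty:
            raise ValidationError(f"AAL id {aal_id} not in model {self.label}")
        return str(row["name"].iloc[0])

    def to_fitted_logit(self) -> FittedLogit:
        """Binary printed model as a FittedLogit (for the logit-evaluation path)."""
        if self.classes is not None:
            raise ValidationError("only the binary printed models convert to a single logit")
        coefs = dict(zip(self.entries["name"], self.entries["coefficient"].astype(float)))
        return FittedLogit(
            classes=["control", "case"],
            intercept=float(self.intercept),
            coefficients=coefs,
            p_values={},
            p_values_sidak={},
            feature_names=list(coefs),
            covariates=[],
            multiclass=False,
            training={"source": f"printed table ({self.label})", "training_ids": []},
        )


def load_printed_model(label: str) -> PrintedModel:
    """Load one of Day1, Day2, Subgroup-Day1, Subgroup-Day2."""
    if label not in MODEL_LABELS:
        raise LookupError(f"unknown model label {label!r}; expected one of {MODEL_LABELS}")
    cc, sub, intercepts = _load_tables()
    if label in ("Day1", "Day2"):
        col = "day1" if label == "Day1" else "day2"
        entries = cc.loc[cc[col].notna(), ["aal_id", "name", "hemisphere", col]].copy()
        entries = entries.rename(columns={col: "coefficient"}).reset_index(drop=True)
        return PrintedModel(label=label, intercept=float(intercepts[label]), entries=entries)
    day = "day1" if label.endswith("Day1") else "day2"
    cols = [f"{day}_{cls}" for cls in SUBGROUP_CLASSES]
    mask = sub[cols].notna().all(axis=1)
    entries = sub.loc[mask, ["aal_id", "name", "hemisphere", *cols]].copy()
    entries = entries.rename(columns=dict(zip(cols, SUBGROUP_CLASSES))).reset_index(drop=True)
    return PrintedModel(
        label=label,
        intercept={k: float(v) for k, v in intercepts[label].items()},
        entries=entries,
        classes=SUBGROUP_CLASSES,
    )


def region_list() -> pd.DataFrame:
    """Union of all regions appearing in the printed tables (id, name, hemisphere)."""
    cc, sub, _ = _load_tables()
    combined = pd.concat(
        [cc[["aal_id", "name", "hemisphere"]], sub[["aal_id", "name", "hemisphere"]]]
    )
    out = combined.drop_duplicates("aal_id").sort_values("aal_id").reset_index(drop=True)
    return out


def region_count(model: PrintedModel) -> int:
    """Number of regions carrying a coefficient in this model."""
    return len(model.entries)


@dataclass
class SharedRegions:
    shared: set[int]
    a_only: set[int]
    b_only: set[int]


def shared_regions(a: PrintedModel, b: PrintedModel) -> SharedRegions:
    """Intersection / differences of two models' region sets by AAL index."""
    sa, sb = a.region_ids, b.region_ids
    return SharedRegions(shared=sa & sb, a_only=sa - sb, b_only=sb - sa)


def extreme_coefficient(model: PrintedModel) -> tuple[str, float]:
    """(region name, signed coefficient) maximizing |coefficient|.

    For subgroup models the scan runs over all per-class coefficients;
    ties break toward the lower AAL index.
    """
    if model.entries.empty:
        raise ValidationError(f"model {model.label} has no entries")
    value_cols = ["coefficient"] if model.classes is None else list(model.classes)
    best = None
    for _, row in model.entries.sort_values("aal_id").iterrows():
        for col in value_cols:
            val = float(row[col])
            if best is None or abs(val) > abs(best[1]) + 1e-15:
                best = (str(row["name"]), val)
    return best


def subset_check(a: PrintedModel, b: PrintedModel) -> bool:
    """True iff every region of ``a`` appears in ``b``."""
    return a.region_ids <= b.region_ids
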