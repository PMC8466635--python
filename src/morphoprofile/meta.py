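"""Parameter metadata: biological category, data type, CV pairing, trials source.

Each morphological parameter is annotated with

* ``category`` — which staining channel it describes: ``actin``, ``cell``
  (cell wall / shape) or ``nucleus`` (nuclear DNA);
* ``data_type`` — ``nonneg`` (positive measurements), ``ratio`` (values in
  (0,1)), ``cv`` (a coefficient of variation paired with a mean parameter),
  ``proportion`` (success counts out of a trials column) or ``noise`` (the
  LOESS residual of a former CV parameter);
* ``mean_partner`` — for CV parameters, the id of the paired mean parameter;
* ``trials_column`` — for proportions, the table column holding the trial
  counts (the detected cell count of the relevant cell-cycle class);
* ``unimodal`` — whether the parameter enters the unimodal-GLM analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

CATEGORIES = ("actin", "cell", "nucleus")
DATA_TYPES = ("nonneg", "ratio", "cv", "proportion", "noise")


class MetaError(ValueError):
    """Invalid parameter metadata."""


@dataclass(frozen=True)
class ParameterMeta:
    param_id: str
    category: str
    data_type: str
    mean_partner: Optional[str] = None
    trials_column: Optional[str] = None
    unimodal: bool = True

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise MetaError(f"{self.param_id}: unknown category {self.category!r}")
        if self.data_type not in DATA_TYPES:
            raise MetaError(f"{self.param_id}: unknown data_type {self.data_type!r}")
        if self.data_type == "cv" and not self.mean_partner:
            raise MetaError(f"{self.param_id}: cv parameter requires mean_partner")
        if self.data_type != "cv" and self.mean_partner:
            raise MetaError(f"{self.param_id}: mean_partner only valid for cv parameters")
        if self.data_type == "proportion" and not self.trials_column:
            raise MetaError(f"{self.param_id}: proportion parameter requires trials_column")
        if self.data_type != "proportion" and self.trials_column:
            raise MetaError(f"{self.param_id}: trials_column only valid for proportions")


class MetaTable:
    """Ordered collection of :class:`ParameterMeta`, keyed by ``param_id``."""

    def __init__(self, entries):
        self._entries = {}
        for e in entries:
            if e.param_id in self._entries:
                raise MetaError(f"duplicate param_id {e.param_id!r}")
            self._entries[e.param_id] = e
        self.validate()

    def validate(self):
        for e in self._entries.values():
            if e.data_type == "cv":
                partner = self._entries.get(e.mean_partner)
                if partner is None:
                    raise MetaError(
                        f"{e.param_id}: mean_partner {e.mean_partner!r} not in table")
                if partner.data_type not in ("nonneg", "ratio"):
                    raise MetaError(
                        f"{e.param_id}: mean_partner {e.mean_partner!r} must be "
                        f"nonneg or ratio, is {partner.data_type}")

    # -- mapping-ish access -------------------------------------------------
    def __getitem__(self, pid) -> ParameterMeta:
        return self._entries[pid]

    def __contains__(self, pid):
        return pid in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self):
        return len(self._entries)

    @property
    def param_ids(self):
        return list(self._entries)

    def unimodal_ids(self):
        return [e.param_id for e in self if e.unimodal]

    def ids_of_type(self, *data_types):
        return [e.param_id for e in self if e.data_type in data_types]

    def trials_columns(self):
        return sorted({e.trials_column for e in self if e.trials_column})

    def replace(self, entry: ParameterMeta) -> "MetaTable":
        entries = [entry if e.param_id == entry.param_id else e for e in self]
        return MetaTable(entries)

    # -- frame conversion ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [{"param_id": e.param_id, "category": e.category,
                 "data_type": e.data_type,
                 "mean_partner": e.mean_partner or "",
                 "trials_column": e.trials_column or "",
                 "unimodal": int(e.unimodal)} for e in self]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetaTable":
        required = {"param_id", "category", "data_type"}
        missing = required - set(df.columns)
        if missing:
            raise MetaError(f"metadata table missing columns: {sorted(missing)}")
        entries = []
        for _, r in df.iterrows():
            def _opt(col):
                v = r.get(col)
                if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                    return None
                return str(v)
            uni = r.get("unimodal", 1)
            entries.append(ParameterMeta(
                param_id=str(r["param_id"]), category=str(r["category"]),
                data_type=str(r["data_type"]), mean_partner=_opt("mean_partner"),
                trials_column=_opt("trials_column"),
                unimodal=bool(int(uni)) if not isinstance(uni, bool) else uni))
        return cls(entries)
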