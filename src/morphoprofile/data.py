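"""Replicate-level morphological dataset container."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .meta import MetaTable

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A value violates its parameter's domain."""


class MissingWTError(RuntimeError):
    """The wild-type strain has no replicates left (no null distribution)."""


@dataclass
class MorphDataset:
    """Replicate-level (strain x parameter) value table with cell counts.

    ``values`` is indexed by a (strain, replicate) MultiIndex; its columns are
    parameter ids.  Proportion parameters store integer success counts whose
    trial counts live in ``trials`` under the column named by the parameter's
    ``trials_column``.  ``cell_count`` holds the number of cells the imaging
    software detected per replicate experiment.
    """

    values: pd.DataFrame
    cell_count: pd.Series
    meta: MetaTable
    wt_strain_id: str
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- basic accessors ----------------------------------------------------
    @property
    def strains(self):
        return list(self.values.index.get_level_values("strain").unique())

    @property
    def mutants(self):
        return [s for s in self.strains if s != self.wt_strain_id]

    @property
    def param_ids(self):
        return list(self.values.columns)

    def analyzable_params(self):
        """Parameters that enter the unimodal pipeline (flagged unimodal and
        present in the table)."""
        present = set(self.values.columns)
        return [p for p in self.meta.unimodal_ids() if p in present]

    def rows_of(self, strain):
        return self.values.loc[strain]

    def param_values(self, param_id, strain=None):
        col = self.values[param_id] if strain is None else self.values[param_id].loc[strain]
        return col

    def trials_of(self, param_id, strain=None):
        tcol = self.meta[param_id].trials_column
        if tcol is None:
            return None
        col = self.trials[tcol]
        return col if strain is None else col.loc[strain]

    def n_rows(self):
        return len(self.values)

    # -- validation ---------------------------------------------------------
    def validate(self):
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].tolist()
            raise ValidationError(f"duplicate (strain, replicate) keys: {dup[:5]}")
        if self.wt_strain_id not in self.strains:
            raise MissingWTError(
                f"wild-type strain {self.wt_strain_id!r} not present in dataset")
        cc = self.cell_count
        if (cc.dropna() < 0).any():
            bad = cc.index[cc < 0][0]
            raise ValidationError(f"negative cell count at row {bad}")
        for pid in self.values.columns:
            if pid not in self.meta:
                continue
            m = self.meta[pid]
            col = self.values[pid]
            obs = col.dropna()
            if m.data_type in ("nonneg", "cv"):
                bad = obs[obs <= 0]
                if len(bad):
                    raise ValidationError(
                        f"parameter {pid!r} ({m.data_type}) must be > 0; "
                        f"value {bad.iloc[0]!r} at row {bad.index[0]}")
            elif m.data_type == "ratio":
                bad = obs[(obs <= 0) | (obs >= 1)]
                if len(bad):
                    raise ValidationError(
                        f"parameter {pid!r} (ratio) must lie in (0,1); "
                        f"value {bad.iloc[0]!r} at row {bad.index[0]}")
            elif m.data_type == "proportion":
                t = self.trials[m.trials_column].reindex(obs.index)
                neg = obs[obs < 0]
                if len(neg):
                    raise ValidationError(
                        f"parameter {pid!r} (proportion) successes must be >= 0; "
                        f"row {neg.index[0]}")
                over = obs[obs > t]
                if len(over):
                    raise ValidationError(
                        f"parameter {pid!r} (proportion) successes exceed trials "
                        f"at row {over.index[0]}")
        return self

    # -- transforms ---------------------------------------------------------
    def copy(self):
        return MorphDataset(self.values.copy(), self.cell_count.copy(),
                            self.meta, self.wt_strain_id, self.trials.copy())

    def drop_strains(self, strains):
        keep = ~self.values.index.get_level_values("strain").isin(strains)
        return MorphDataset(self.values[keep], self.cell_count[keep],
                            self.meta, self.wt_strain_id, self.trials[keep])


def filter_min_cells(ds: MorphDataset, min_cells: int = 200) -> MorphDataset:
    """Drop replicate experiments with fewer than ``min_cells`` detected cells.

    Mirrors the imaging QC rule that only experiments with enough detected
    cells enter statistical analysis.  Dropping every replicate of the
    wild-type strain is fatal (there is no null distribution left); a mutant
    losing all replicates is logged and simply disappears from downstream
    tests.
    """
    if ds.cell_count.isna().any():
        bad = ds.cell_count.index[ds.cell_count.isna()][0]
        raise ValidationError(f"cell count missing at row {bad}")
    keep = ds.cell_count >= min_cells
    n_removed = int((~keep).sum())
    if n_removed:
        log.warning("filter_min_cells: removed %d/%d replicate rows (< %d cells)",
                    n_removed, len(keep), min_cells)
    out = MorphDataset(ds.values[keep], ds.cell_count[keep], ds.meta,
                       ds.wt_strain_id, ds.trials[keep] if len(ds.trials) else ds.trials)
    if ds.wt_strain_id not in out.strains:
        raise MissingWTError(
            f"all replicates of wild-type {ds.wt_strain_id!r} removed by "
            f"min_cells={min_cells}; no null distribution")
    lost = set(ds.strains) - set(out.strains)
    if lost:
        log.warning("filter_min_cells: strains dropped entirely: %s", sorted(lost))
    return out
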