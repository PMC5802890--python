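"""Core cohort containers.

A *trait* is one continuous value per sample (typically the expression of a
single gene on the dataset's native scale); the scan engine only ever uses it
through its ranks.  Survival outcomes carry a positive follow-up time and an
event indicator (1 = event observed, 0 = censored).  Binary traits hold a 0/1
group membership used as the reference in Fisher-mode scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTrait",
    "SurvivalOutcome",
    "BinaryTrait",
    "ClinicalTable",
    "align",
]

MIN_COHORT = 3


def _as_id_array(sample_ids: Sequence[str]) -> np.ndarray:
    ids = np.asarray(sample_ids, dtype=object)
    if ids.ndim != 1:
        raise ValueError("sample_ids must be one-dimensional")
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for s in ids:
            if s in seen:
                dups.append(s)
            seen.add(s)
        raise ValueError(f"duplicate sample IDs: {sorted(set(dups))}")
    return ids


@dataclass(frozen=True)
class CohortTrait:
    """Continuous dichotomization variable, one value per sample."""

    sample_ids: np.ndarray
    values: np.ndarray
    name: str = "trait"

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", _as_id_array(self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.sample_ids.shape:
            raise ValueError("values and sample_ids must have equal length")
        if np.isnan(vals).any():
            raise ValueError("trait values contain NaN after alignment")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def ranks(self) -> np.ndarray:
        """Zero-based ascending ranks; ties keep input order (stable sort)."""
        order = np.argsort(self.values, kind="stable")
        r = np.empty(len(order), dtype=np.intp)
        r[order] = np.arange(len(order))
        return r

    def subset(self, index: np.ndarray) -> "CohortTrait":
        return CohortTrait(self.sample_ids[index], self.values[index], self.name)


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored overall-survival outcome."""

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", _as_id_array(self.sample_ids))
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event)
        if t.shape != self.sample_ids.shape or e.shape != self.sample_ids.shape:
            raise ValueError("time/event length mismatch with sample_ids")
        if np.isnan(t).any() or (t <= 0).any():
            raise ValueError("survival times must be positive and non-missing")
        if not np.isin(e, [0, 1]).all():
            raise ValueError("event status must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e.astype(np.int8))

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, index: np.ndarray) -> "SurvivalOutcome":
        return SurvivalOutcome(self.sample_ids[index], self.time[index], self.event[index])


@dataclass(frozen=True)
class BinaryTrait:
    """0/1 group membership per sample (e.g. marker-low vs marker-high)."""

    sample_ids: np.ndarray
    group: np.ndarray
    name: str = "group"

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", _as_id_array(self.sample_ids))
        g = np.asarray(self.group)
        if g.shape != self.sample_ids.shape:
            raise ValueError("group length mismatch with sample_ids")
        if not np.isin(g, [0, 1]).all():
            raise ValueError("group labels must be 0 or 1")
        object.__setattr__(self, "group", g.astype(np.int8))

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, index: np.ndarray) -> "BinaryTrait":
        return BinaryTrait(self.sample_ids[index], self.group[index], self.name)


@dataclass(frozen=True)
class ClinicalTable:
    """Named covariates with declared types ('categorical' or 'continuous')."""

    data: pd.DataFrame  # indexed by sample ID
    covariate_types: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs in clinical table")
        for name, kind in self.covariate_types.items():
            if name not in self.data.columns:
                raise ValueError(f"declared covariate {name!r} not in table")
            if kind not in ("categorical", "continuous"):
                raise ValueError(f"covariate {name!r}: unknown type {kind!r}")
            if kind == "continuous" and not pd.api.types.is_numeric_dtype(self.data[name]):
                raise ValueError(f"covariate {name!r} declared continuous but non-numeric")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, index: np.ndarray) -> "ClinicalTable":
        sub = self.data.iloc[index]
        # drop empty categorical levels so downstream contingency tables stay dense
        sub = sub.copy()
        for name, kind in self.covariate_types.items():
            if kind == "categorical" and isinstance(sub[name].dtype, pd.CategoricalDtype):
                sub[name] = sub[name].cat.remove_unused_categories()
        return ClinicalTable(sub, self.covariate_types)


def align(trait: CohortTrait, other, logger=None):
    """Restrict ``trait`` and ``other`` to their shared samples.

    The output order follows the order of appearance in ``trait``.  Returns
    the aligned ``(trait, other)`` pair; raises if fewer than three samples
    are shared.  A summary of dropped samples is emitted through ``logger``
    (any callable taking a string) when provided.
    """
    other_ids = other.sample_ids
    other_pos = {s: i for i, s in enumerate(other_ids)}
    keep = [i for i, s in enumerate(trait.sample_ids) if s in other_pos]
    if len(keep) < MIN_COHORT:
        raise ValueError(
            f"only {len(keep)} samples shared between trait and outcome; need >= {MIN_COHORT}"
        )
    keep = np.asarray(keep, dtype=np.intp)
    idx_other = np.asarray([other_pos[s] for s in trait.sample_ids[keep]], dtype=np.intp)
    dropped_trait = len(trait) - len(keep)
    dropped_other = len(other_ids) - len(keep)
    if logger is not None:
        logger(
            f"aligned on {len(keep)} shared samples "
            f"(dropped {dropped_trait} from trait, {dropped_other} from outcome)"
        )
    return trait.subset(keep), other.subset(idx_other)
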