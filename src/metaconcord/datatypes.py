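"""Shared domain types for the metastasis-concordance pipeline.

Samples carry TNM staging, recurrence and adjuvant-treatment annotations;
molecular data live in feature-by-sample matrices (log2 microarray
intensities, RNA-seq counts, promoter CpG beta values, or binary
alteration calls). All matrix types wrap a pandas DataFrame whose index is
the feature axis and whose columns are sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NStage",
    "MStage",
    "YesNoUnknown",
    "Group",
    "Policy",
    "SampleRecord",
    "ExpressionMatrix",
    "ProbeGeneMap",
    "MethylationMatrix",
    "GeneSet",
    "GeneSetCollection",
    "BinaryAlterationMatrix",
    "GroupAssignment",
]


class NStage(str, Enum):
    """Nodal stage: N0 = no lymph-node metastasis, N+ = nodal metastasis."""

    N0 = "N0"
    N_PLUS = "N+"
    UNKNOWN = "unknown"


class MStage(str, Enum):
    """Distant-metastasis stage: M0 = none detected, M+ = distant metastasis."""

    M0 = "M0"
    M_PLUS = "M+"
    UNKNOWN = "unknown"


class YesNoUnknown(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Group(str, Enum):
    METASTASIS = "metastasis"
    NON_METASTASIS = "non_metastasis"
    EXCLUDED = "excluded"


class Policy(str, Enum):
    TNM_ONLY = "tnm_only"
    TNM_PLUS_RECURRENCE = "tnm_plus_recurrence"


@dataclass(frozen=True)
class SampleRecord:
    """One patient's staging / follow-up annotations.

    ``follow_up_months`` is carried through for user-side filtering only;
    no grouping rule consumes it.
    """

    sample_id: str
    n_stage: NStage = NStage.UNKNOWN
    m_stage: MStage = MStage.UNKNOWN
    recurrence: YesNoUnknown = YesNoUnknown.UNKNOWN
    adjuvant: YesNoUnknown = YesNoUnknown.UNKNOWN
    follow_up_months: float | None = None

    def __post_init__(self) -> None:
        if self.follow_up_months is not None and self.follow_up_months < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: follow_up_months must be non-negative"
            )


@dataclass(frozen=True)
class GroupAssignment:
    """Per-sample label under a named grouping policy."""

    sample_id: str
    group: Group
    policy: Policy
    reason: str


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicated {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values.

    scale:
        ``log2_intensity`` for normalized microarray data (probe- or
        gene-level), ``raw_count`` for RNA-seq integer counts.
    """

    values: pd.DataFrame
    scale: str  # "log2_intensity" | "raw_count"

    def __post_init__(self) -> None:
        if self.scale not in ("log2_intensity", "raw_count"):
            raise ValueError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "feature_id")
        _check_unique(self.values.columns, "sample_id")
        if self.scale == "raw_count":
            arr = self.values.to_numpy()
            if np.any(arr < 0):
                raise ValueError("raw_count matrix contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw_count matrix contains non-integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeGeneMap:
    """(probe_id, gene_id) pairs; many-to-one and one-to-many both allowed."""

    pairs: pd.DataFrame  # columns: probe_id, gene_id

    def __post_init__(self) -> None:
        cols = list(self.pairs.columns)
        if cols[:2] != ["probe_id", "gene_id"]:
            raise ValueError("ProbeGeneMap needs columns probe_id, gene_id")
        if self.pairs.duplicated(["probe_id", "gene_id"]).any():
            dup = self.pairs[self.pairs.duplicated(["probe_id", "gene_id"])]
            raise ValueError(
                f"duplicated (probe_id, gene_id) pairs: {dup.iloc[0].tolist()}"
            )

    @property
    def probe_ids(self) -> set[str]:
        return set(self.pairs["probe_id"])


@dataclass
class MethylationMatrix:
    """Promoter-CpG beta values (in [0, 1]) plus the locus-to-gene map."""

    betas: pd.DataFrame  # locus x sample
    promoter_map: pd.DataFrame  # columns: locus_id, gene_id

    def __post_init__(self) -> None:
        _check_unique(self.betas.index, "locus_id")
        arr = self.betas.to_numpy()
        if np.any(np.isnan(arr)):
            raise ValueError(
                "MethylationMatrix contains missing beta values; "
                "drop incomplete loci at load time"
            )
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        cols = list(self.promoter_map.columns)
        if cols[:2] != ["locus_id", "gene_id"]:
            raise ValueError("promoter_map needs columns locus_id, gene_id")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets (the GMT abstraction used for pathway enrichment)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in out:
                raise ValueError(f"duplicated set_id: {s.set_id!r}")
            out[s.set_id] = s
        return cls(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


@dataclass
class BinaryAlterationMatrix:
    """Binary presence/absence calls (CNV peaks, mutations) per sample."""

    calls: pd.DataFrame  # feature x sample, entries in {0, 1}

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "feature_id")
        arr = self.calls.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("alteration calls must be strictly binary (0/1)")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)
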