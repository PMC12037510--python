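"""Core in-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasSpec

__all__ = ["SubjectRecord", "SUVRTable", "GroupNetwork", "PermutationResult"]


@dataclass
class SubjectRecord:
    """One subject: group label, demographic covariates, biomarker panel.

    ``sex`` is numerically coded (male=1, female=0 by default; the reader
    accepts a configurable mapping). Missing biomarker values are stored as
    NaN and are never imputed.
    """

    subject_id: str
    group: str
    age: float
    sex: int
    bmi: float | None = None
    biomarkers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0, got {self.age}")
        if self.bmi is not None and not np.isnan(self.bmi) and not self.bmi > 0:
            raise ValueError(f"subject {self.subject_id}: bmi must be > 0, got {self.bmi}")


@dataclass
class SUVRTable:
    """Subjects x analysis-regions matrix of uptake values tied to an atlas.

    ``kind`` tags the processing stage: ``raw_suv`` (tracer uptake before
    reference normalization), ``suvr`` (divided by the cerebellar reference
    mean), or ``corrected_suvr`` (age/sex residual-corrected). Raw SUV and
    SUVR values must be finite and strictly positive.
    """

    subject_ids: list[str]
    atlas: AtlasSpec
    values: np.ndarray
    kind: str = "suvr"

    _KINDS = ("raw_suv", "suvr", "corrected_suvr")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        n_sub, n_reg = self.values.shape
        if n_sub != len(self.subject_ids):
            raise ValueError("row count does not match number of subject ids")
        if n_reg != self.atlas.n_analysis:
            raise ValueError(
                f"table has {n_reg} columns but atlas declares "
                f"{self.atlas.n_analysis} analysis regions"
            )
        if self.kind in ("raw_suv", "suvr"):
            if not np.all(np.isfinite(self.values)) or not np.all(self.values > 0):
                raise ValueError(f"{self.kind} values must be finite and > 0")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, subject_ids: list[str]) -> "SUVRTable":
        """Row subset in the given order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return SUVRTable(list(subject_ids), self.atlas, self.values[rows], self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.atlas.analysis_names
        )


@dataclass
class GroupNetwork:
    """One group's metabolic covariance network.

    ``weights`` holds across-subject Pearson correlations between regional
    SUVRs (diagonal is not meaningful and kept at zero); ``adjacency`` is the
    binarized network at sparsity ``sparsity`` (fraction of retained edges).
    """

    atlas: AtlasSpec
    weights: np.ndarray
    adjacency: np.ndarray
    sparsity: float
    n_subjects: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        a = np.asarray(self.adjacency)
        n = self.atlas.n_analysis
        if w.shape != (n, n) or a.shape != (n, n):
            raise ValueError("weights/adjacency shape does not match atlas")
        off = ~np.eye(n, dtype=bool)
        if np.any(np.abs(w[off]) > 1 + 1e-12):
            raise ValueError("correlation weights must lie in [-1, 1]")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must lie in (0, 1]")
        self.weights = w
        self.adjacency = a.astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class PermutationResult:
    """Edge-wise permutation test output for a two-group contrast.

    ``delta`` is the observed disease-minus-control edge statistic (raw
    correlation difference or Fisher-z difference); ``pvalues`` are add-one
    empirical two-tailed p-values, bounded below by 1/(n_perm+1).
    """

    delta: np.ndarray
    pvalues: np.ndarray
    n_perm: int
    seed: int
    statistic_mode: str = "raw_r"
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.delta.shape != self.pvalues.shape:
            raise ValueError("delta and pvalues must have the same shape")
        if not np.allclose(self.pvalues, self.pvalues.T):
            raise ValueError("pvalues must be symmetric")
        pmin = 1.0 / (self.n_perm + 1)
        if np.any(self.pvalues < pmin - 1e-12) or np.any(self.pvalues > 1 + 1e-12):
            raise ValueError("pvalues must lie in [1/(n_perm+1), 1]")
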