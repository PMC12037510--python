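"""SUVR computation and the age/sex residual correction.

SUVR normalization divides each region's mean SUV by the subject's
cerebellar reference mean: ``SUVR = SUV_target / SUV_reference``. The
nuisance correction regresses SUVR on age and sex per region and adds the
residual back onto the group mean, yielding "corrected" SUVRs whose group
contrast is free of linear age/sex confounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import SubjectRecord, SUVRTable

__all__ = ["CorrectionModel", "compute_suvr", "fit_correction", "apply_correction"]


def compute_suvr(raw: SUVRTable, reference_means: np.ndarray) -> SUVRTable:
    """Divide each subject's regional SUVs by their reference mean.

    Parameters
    ----------
    raw
        Table of kind ``raw_suv``.
    reference_means
        One positive cerebellar reference mean per subject, in table order.
    """
    if raw.kind != "raw_suv":
        raise ValueError(f"expected a raw_suv table, got kind={raw.kind!r}")
    ref = np.asarray(reference_means, dtype=float)
    if ref.shape != (raw.n_subjects,):
        raise ValueError("need exactly one reference mean per subject")
    bad = np.nonzero(~(ref > 0))[0]
    if bad.size:
        names = [raw.subject_ids[i] for i in bad[:5]]
        raise ValueError(f"non-positive reference mean for subject(s): {names}")
    return SUVRTable(list(raw.subject_ids), raw.atlas, raw.values / ref[:, None], "suvr")


def _design(records: list[SubjectRecord]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(records)), [r.age for r in records], [r.sex for r in records]]
    )


@dataclass
class CorrectionModel:
    """Per-region OLS coefficients (intercept, b_age, b_sex) + mean levels.

    ``fit_scope`` is ``pooled`` (one regression over all included groups,
    which removes between-group age/sex composition differences) or
    ``per_group`` (separate regressions within each group).

    ``apply_correction`` adds the residual back onto a mean SUVR level:
    the *pooled* sample mean under pooled scope (a group-independent
    constant, so the corrected group contrast equals the covariate-adjusted
    contrast), or the group's own mean under per_group scope (residuals are
    zero-mean within each group, so raw group means are preserved).
    """

    coefficients: dict[str, np.ndarray]  # scope key -> (3, n_regions)
    group_means: dict[str, np.ndarray]  # group -> (n_regions,) raw SUVR means
    pooled_mean: np.ndarray | None = None  # (n_regions,) mean over the fit sample
    fit_scope: str = "pooled"
    region_names: list[str] = field(default_factory=list)

    def predict(self, records: list[SubjectRecord]) -> np.ndarray:
        X = _design(records)
        if self.fit_scope == "pooled":
            return X @ self.coefficients["pooled"]
        out = np.empty((len(records), next(iter(self.group_means.values())).size))
        for i, r in enumerate(records):
            out[i] = X[i] @ self.coefficients[r.group]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fit_scope": self.fit_scope,
            "region_names": self.region_names,
            "coefficients": {k: v.tolist() for k, v in self.coefficients.items()},
            "group_means": {k: v.tolist() for k, v in self.group_means.items()},
            "pooled_mean": None if self.pooled_mean is None else self.pooled_mean.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients={k: np.asarray(v) for k, v in d["coefficients"].items()},
            group_means={k: np.asarray(v) for k, v in d["group_means"].items()},
            pooled_mean=None if d["pooled_mean"] is None else np.asarray(d["pooled_mean"]),
            fit_scope=d["fit_scope"],
            region_names=d["region_names"],
        )


def fit_correction(
    suvr: SUVRTable,
    records: list[SubjectRecord],
    groups: list[str] | None = None,
    fit_scope: str = "pooled",
) -> CorrectionModel:
    """Fit the per-region age/sex regression for the included groups.

    Raises
    ------
    ValueError
        If a fitted design has fewer than 4 subjects or is rank deficient
        (e.g. a single-sex group under ``per_group`` scope).
    """
    if fit_scope not in ("pooled", "per_group"):
        raise ValueError(f"fit_scope must be 'pooled' or 'per_group', got {fit_scope!r}")
    by_id = {r.subject_id: r for r in records}
    recs = [by_id[s] for s in suvr.subject_ids]
    if groups is None:
        groups = sorted({r.group for r in recs})
    idx = [i for i, r in enumerate(recs) if r.group in groups]
    recs = [recs[i] for i in idx]
    Y = suvr.values[idx]

    def _ols(rows: list[int], label: str) -> np.ndarray:
        if len(rows) < 4:
            raise ValueError(f"correction fit for {label} needs >= 4 subjects, got {len(rows)}")
        X = _design([recs[i] for i in rows])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"rank-deficient age/sex design for {label} "
                "(constant age or single-sex sample)"
            )
        beta, *_ = np.linalg.lstsq(X, Y[rows], rcond=None)
        return beta

    group_means = {
        g: Y[[i for i, r in enumerate(recs) if r.group == g]].mean(axis=0) for g in groups
    }
    if fit_scope == "pooled":
        coefficients = {"pooled": _ols(list(range(len(recs))), "pooled groups " + "/".join(groups))}
    else:
        coefficients = {
            g: _ols([i for i, r in enumerate(recs) if r.group == g], f"group {g!r}")
            for g in groups
        }
    return CorrectionModel(
        coefficients,
        group_means,
        pooled_mean=Y.mean(axis=0),
        fit_scope=fit_scope,
        region_names=list(suvr.atlas.analysis_names),
    )


def apply_correction(
    model: CorrectionModel, suvr: SUVRTable, records: list[SubjectRecord]
) -> SUVRTable:
    """corrected[i, r] = mean level + age/sex regression residual.

    The mean level is the fit-sample pooled mean under pooled scope (one
    constant per region, so the corrected group contrast is the
    covariate-adjusted contrast) and the subject's own group mean under
    per_group scope (which preserves raw group means exactly, since OLS
    residuals are zero-mean within each fitted group).
    """
    by_id = {r.subject_id: r for r in records}
    recs = [by_id[s] for s in suvr.subject_ids]
    unknown = sorted({r.group for r in recs} - set(model.group_means))
    if unknown:
        raise ValueError(f"groups absent from correction model: {unknown}")
    predicted = model.predict(recs)
    if model.fit_scope == "pooled":
        means = np.broadcast_to(model.pooled_mean, suvr.values.shape)
    else:
        means = np.stack([model.group_means[r.group] for r in recs])
    corrected = means + (suvr.values - predicted)
    return SUVRTable(list(suvr.subject_ids), suvr.atlas, corrected, "corrected_suvr")
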