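"""Disease-vs-control contrast: model object, fitted results, matching.

`MetabolicContrast` bundles the inputs and settings for one contrast
(e.g. hypertension vs control); `fit()` runs the full analysis — nuisance
correction, region screen, biomarker partial-correlation screen on the
flagged regions, group covariance networks, percolation sparsity, and the
edge-wise permutation test — and returns a `ContrastResults` carrying the
estimates, a text `summary()`, plotting helpers, and disk export.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _version
from .covnet import min_connected_sparsity
from .datatypes import GroupNetwork, PermutationResult, SubjectRecord, SUVRTable
from .io import write_brainnet_edge, write_brainnet_node
from .permtest import compare_at_sparsity, significant_edges
from .screening import (
    PartialCorrResult,
    RegionTestResult,
    results_to_frame,
    screen_biomarkers,
    screen_regions,
)
from .suvr import apply_correction, fit_correction

__all__ = ["MetabolicContrast", "ContrastResults", "run_matched_control_selection", "MatchResult"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent per-stage seed from the run seed (crc32 mix)."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


class MetabolicContrast:
    """Model for one disease-vs-control contrast of regional SUVRs.

    Parameters
    ----------
    suvr
        Subjects x regions SUVR table covering both groups.
    records
        Subject metadata (group, age, sex, BMI, biomarkers).
    disease, control
        Group labels to contrast; the edge/region statistics are
        disease minus control.
    correction
        ``"pooled"`` (default; one age/sex regression over both groups),
        ``"per_group"``, or ``None`` to skip the correction.
    sparsity
        Number in (0, 1] or ``"auto_min_connected"`` to use the larger of
        the two groups' percolation thresholds.
    biomarkers
        Biomarker names to screen on the flagged regions (default: all
        present in the records).
    """

    def __init__(
        self,
        suvr: SUVRTable,
        records: list[SubjectRecord],
        disease: str,
        control: str,
        correction: str | None = "pooled",
        variance_rule: str = "auto",
        alpha: float = 0.05,
        multiple_testing: str | None = None,
        sparsity: float | str = 0.35,
        n_perm: int = 5000,
        statistic_mode: str = "raw_r",
        biomarkers: list[str] | None = None,
        covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    ):
        groups = {r.group for r in records}
        for g in (disease, control):
            if g not in groups:
                raise ValueError(f"group {g!r} not present in records (have {sorted(groups)})")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        self.suvr = suvr
        self.records = records
        self.disease = disease
        self.control = control
        self.correction = correction
        self.variance_rule = variance_rule
        self.alpha = alpha
        self.multiple_testing = multiple_testing
        self.sparsity = sparsity
        self.n_perm = n_perm
        self.statistic_mode = statistic_mode
        self.covariates = covariates
        if biomarkers is None:
            names: list[str] = []
            for r in records:
                for b in r.biomarkers:
                    if b not in names:
                        names.append(b)
            biomarkers = names
        self.biomarkers = biomarkers

    @classmethod
    def from_tables(
        cls, suvr_path, subjects_path, atlas, disease: str, control: str, **kwargs
    ) -> "MetabolicContrast":
        from .io import read_subject_table, read_suvr_table

        records = read_subject_table(subjects_path)
        suvr = read_suvr_table(suvr_path, atlas)
        return cls(suvr, records, disease, control, **kwargs)

    def _group_ids(self, group: str) -> list[str]:
        wanted = {r.subject_id for r in self.records if r.group == group}
        return [s for s in self.suvr.subject_ids if s in wanted]

    def fit(self, seed: int = 0) -> "ContrastResults":
        """Run the full contrast analysis. Deterministic given the seed."""
        ids_d = self._group_ids(self.disease)
        ids_c = self._group_ids(self.control)
        both = self.suvr.subset(ids_d + ids_c)

        correction_model = None
        if self.correction is not None:
            correction_model = fit_correction(
                both, self.records, [self.disease, self.control], self.correction
            )
            analysed = apply_correction(correction_model, both, self.records)
        else:
            analysed = both
        table_d = analysed.subset(ids_d)
        table_c = analysed.subset(ids_c)

        region_tests = screen_regions(
            table_d, table_c, self.alpha, self.variance_rule, self.multiple_testing
        )
        flagged = [r.region_id for r in region_tests if r.significant]

        partial = screen_biomarkers(
            analysed.subset(ids_d),
            self.records,
            flagged,
            self.biomarkers,
            self.covariates,
            self.alpha,
        )

        s_min_d = min_connected_sparsity(np.corrcoef(table_d.values, rowvar=False) - np.eye(table_d.values.shape[1]))
        s_min_c = min_connected_sparsity(np.corrcoef(table_c.values, rowvar=False) - np.eye(table_c.values.shape[1]))
        if self.sparsity == "auto_min_connected":
            sparsity = max(s_min_d, s_min_c)
        else:
            sparsity = float(self.sparsity)

        (net_d, net_c), perm = compare_at_sparsity(
            table_d,
            table_c,
            sparsity,
            self.n_perm,
            stage_seed(seed, "permutation"),
            self.statistic_mode,
        )
        sig_edges = significant_edges(perm, self.alpha)

        return ContrastResults(
            model=self,
            seed=seed,
            corrected=analysed,
            correction_model=correction_model,
            region_tests=region_tests,
            partial_correlations=partial,
            network_disease=net_d,
            network_control=net_c,
            min_connected=(s_min_d, s_min_c),
            sparsity_used=sparsity,
            permutation=perm,
            sig_edges=sig_edges,
        )


@dataclass
class ContrastResults:
    """Fitted output of `MetabolicContrast.fit`."""

    model: MetabolicContrast
    seed: int
    corrected: SUVRTable
    correction_model: object | None
    region_tests: list[RegionTestResult]
    partial_correlations: list[PartialCorrResult]
    network_disease: GroupNetwork
    network_control: GroupNetwork
    min_connected: tuple[float, float]
    sparsity_used: float
    permutation: PermutationResult
    sig_edges: list[tuple] = field(default_factory=list)

    # -- tabular views ------------------------------------------------------
    @property
    def region_table(self) -> pd.DataFrame:
        return results_to_frame(self.region_tests)

    @property
    def partial_table(self) -> pd.DataFrame:
        return results_to_frame(self.partial_correlations)

    @property
    def edge_table(self) -> pd.DataFrame:
        names = self.model.suvr.atlas.analysis_names
        rows = [
            dict(region_i=names[i], region_j=names[j], delta=d, p=p)
            for i, j, d, p in self.sig_edges
        ]
        return pd.DataFrame(rows, columns=["region_i", "region_j", "delta", "p"])

    @property
    def flagged_regions(self) -> list[int]:
        return [r.region_id for r in self.region_tests if r.significant]

    def summary(self) -> str:
        m = self.model
        n_d = len([r for r in m.records if r.group == m.disease])
        n_c = len([r for r in m.records if r.group == m.control])
        n_sig_bm = sum(r.significant for r in self.partial_correlations)
        n_up = sum(1 for r in self.region_tests if r.significant and r.direction > 0)
        n_down = sum(1 for r in self.region_tests if r.significant and r.direction < 0)
        weak = sum(1 for e in self.sig_edges if e[2] < 0)
        strong = len(self.sig_edges) - weak
        lines = [
            "Metabolic contrast results",
            "=" * 58,
            f"contrast:             {m.disease} (n={n_d}) vs {m.control} (n={n_c})",
            f"regions:              {m.suvr.atlas.n_analysis}",
            f"correction:           {m.correction or 'none'}",
            f"region screen:        {n_up + n_down} flagged at p < {m.alpha}"
            f" ({n_down} decreased, {n_up} increased)",
            f"biomarker screen:     {n_sig_bm} of {len(self.partial_correlations)}"
            f" (region, biomarker) pairs at p < {m.alpha}",
            f"min-connected S:      disease {self.min_connected[0]:.4f},"
            f" control {self.min_connected[1]:.4f}",
            f"sparsity used:        {self.sparsity_used:.4f}"
            f" ({self.network_disease.n_edges} edges/group)",
            f"permutation test:     B = {self.permutation.n_perm},"
            f" statistic = {self.permutation.statistic_mode}",
            f"significant edges:    {len(self.sig_edges)}"
            f" ({weak} weakened, {strong} strengthened)",
            "=" * 58,
        ]
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------
    def plot_region_effects(self, ax=None):
        """Bar plot of per-region t statistics, flagged regions highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = [r.t for r in self.region_tests]
        colors = ["tab:red" if r.significant else "0.7" for r in self.region_tests]
        ax.bar(range(len(t)), t, color=colors)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("region index")
        ax.set_ylabel("t (disease - control)")
        return ax

    def plot_delta_matrix(self, ax=None):
        """Heatmap of the observed edge-wise connectivity difference."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        v = np.nanmax(np.abs(self.permutation.delta)) or 1.0
        im = ax.imshow(self.permutation.delta, cmap="coolwarm", vmin=-v, vmax=v)
        ax.figure.colorbar(im, ax=ax, label="delta r (disease - control)")
        return ax

    # -- export -------------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        """Write result tables, BrainNet files, and a run manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(index=False, float_format="%.10g")
        self.region_table.to_csv(out / "region_tests.csv", **fmt)
        self.partial_table.to_csv(out / "partial_correlations.csv", **fmt)
        self.edge_table.to_csv(out / "significant_edges.csv", **fmt)
        if self.correction_model is not None:
            self.correction_model.to_json(out / "correction_model.json")

        atlas = self.model.suvr.atlas
        colors = np.array([float(r.direction) if r.significant else 0.0 for r in self.region_tests])
        sizes = np.array([abs(r.t) for r in self.region_tests])
        write_brainnet_node(atlas, colors, sizes, out / "regions.node")
        write_brainnet_edge(self.permutation.delta, out / "delta.edge")
        write_brainnet_edge(self.network_disease.weights, out / "disease.edge")
        write_brainnet_edge(self.network_control.weights, out / "control.edge")

        manifest = {
            "package_version": _version,
            "seed": self.seed,
            "contrast": [self.model.disease, self.model.control],
            "alpha": self.model.alpha,
            "correction": self.model.correction,
            "variance_rule": self.model.variance_rule,
            "sparsity_requested": self.model.sparsity,
            "sparsity_used": self.sparsity_used,
            "min_connected_sparsity": list(self.min_connected),
            "n_perm": self.permutation.n_perm,
            "statistic_mode": self.permutation.statistic_mode,
            "stage_seeds": {"permutation": stage_seed(self.seed, "permutation")},
            "row_counts": {
                "region_tests": len(self.region_tests),
                "partial_correlations": len(self.partial_correlations),
                "significant_edges": len(self.sig_edges),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Matched control selection
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    selected: list[SubjectRecord]
    p_age: float
    p_sex: float


def run_matched_control_selection(
    records: list[SubjectRecord],
    disease_group: str,
    control_group: str,
    seed: int = 0,
    caliper_years: float = 5.0,
    n_per_case: int = 1,
) -> MatchResult:
    """Select an age/sex-matched control subset for a disease group.

    Sex is frequency-matched (each case draws from same-sex controls);
    age uses greedy nearest-neighbour matching within ``caliper_years``.
    Reports post-match balance: two-sample t-test p on age and chi-square
    p on sex composition.
    """
    cases = [r for r in records if r.group == disease_group]
    pool = [r for r in records if r.group == control_group]
    n_wanted = n_per_case * len(cases)
    if n_wanted > len(pool):
        raise ValueError(
            f"requested {n_wanted} matched controls but pool has only {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    available = {r.subject_id: r for r in pool}
    selected: list[SubjectRecord] = []
    unmatched: list[str] = []
    for idx in order:
        case = cases[idx]
        for _ in range(n_per_case):
            candidates = [r for r in available.values() if r.sex == case.sex]
            if not candidates:
                unmatched.append(case.subject_id)
                continue
            best = min(candidates, key=lambda r: (abs(r.age - case.age), r.subject_id))
            if abs(best.age - case.age) > caliper_years:
                unmatched.append(case.subject_id)
                continue
            selected.append(best)
            del available[best.subject_id]

    age_case = [r.age for r in cases]
    age_sel = [r.age for r in selected] or [np.nan]
    t_p = stats.ttest_ind(age_case, age_sel, equal_var=False).pvalue if selected else np.nan
    obs = np.array(
        [
            [sum(r.sex for r in cases), len(cases) - sum(r.sex for r in cases)],
            [sum(r.sex for r in selected), len(selected) - sum(r.sex for r in selected)],
        ]
    )
    if selected and obs[:, 0].sum() > 0 and obs[:, 1].sum() > 0:
        chi_p = stats.chi2_contingency(obs).pvalue
    else:
        chi_p = 1.0
    if unmatched:
        raise ValueError(
            f"matching infeasible within caliper {caliper_years} y for "
            f"{len(unmatched)} case(s) {unmatched[:5]}; achieved balance so far: "
            f"age p={t_p:.3g}, sex p={chi_p:.3g}"
        )
    return MatchResult(selected=selected, p_age=float(t_p), p_sex=float(chi_p))
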