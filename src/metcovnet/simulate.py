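"""Synthetic cohort generator with planted ground truth.

Emulates multi-group FDG-PET cohorts at the region level: each subject's
regional SUVR is a base level plus a group effect, linear age and sex
trends, and a residual drawn from a block-structured multivariate normal.
Group-specific scaling of the residual correlations plants connectivity
differences; biomarkers are linked to chosen regions at an exact target
partial correlation (given age, sex, BMI) through a shared-residual
loading, with completely-at-random missingness.

Every downstream stage — the age/sex correction, the region and biomarker
screens, covariance-network construction, and the permutation test — has a
known truth here, which is what the test suite exercises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .atlas import synthetic_atlas
from .datatypes import SubjectRecord, SUVRTable

__all__ = [
    "CovariateModel",
    "CovarianceModel",
    "BiomarkerLink",
    "ScenarioConfig",
    "generate_cohort",
    "preset_scenario",
    "PRESET_NAMES",
]


@dataclass
class CovariateModel:
    """Per-group covariate distributions and region-level nuisance slopes.

    ``age_mean``/``age_sd`` and ``sex_p_male`` are per-group (years and
    proportion male); BMI is kg/m^2. ``beta_age`` (SUVR per year) and
    ``beta_sex`` (SUVR, male minus female) are shared across groups so the
    pooled residual correction is well specified.
    """

    age_mean: dict[str, float]
    age_sd: dict[str, float]
    sex_p_male: dict[str, float]
    bmi_mean: dict[str, float]
    bmi_sd: dict[str, float]
    beta_age: float | np.ndarray = -0.002
    beta_sex: float | np.ndarray = 0.02


@dataclass
class CovarianceModel:
    """Block-structured residual correlation, scalable per group.

    ``modules`` assigns each region a block id; residual correlation is
    ``r_within`` inside a block and ``r_between`` across blocks, with unit
    diagonal and residual sd ``sigma`` (SUVR units). ``group_scale``
    multiplies the off-diagonal correlations for a group (values < 1
    attenuate connectivity, > 1 elevate it — the shared-latent loading of
    the disease scenarios); the scaled matrix must remain positive
    definite.
    """

    modules: np.ndarray
    r_within: float = 0.45
    r_between: float = 0.15
    sigma: float = 0.1
    group_scale: dict[str, float] = field(default_factory=dict)

    def correlation(self, group: str) -> np.ndarray:
        m = np.asarray(self.modules)
        same = m[:, None] == m[None, :]
        corr = np.where(same, self.r_within, self.r_between).astype(float)
        corr *= self.group_scale.get(group, 1.0)
        np.fill_diagonal(corr, 1.0)
        return corr

    def cholesky(self, group: str) -> np.ndarray:
        corr = self.correlation(group)
        try:
            return np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"residual correlation for group {group!r} is not positive "
                f"definite (r_within={self.r_within}, r_between={self.r_between}, "
                f"scale={self.group_scale.get(group, 1.0)})"
            ) from exc


@dataclass
class BiomarkerLink:
    """Plant a biomarker with target partial correlation ``rho`` to a region.

    The biomarker is a linear function of age/sex/BMI plus ``lam * eps_region
    + eta`` where ``lam = rho * eta_sd / (sigma_eps * sqrt(1 - rho^2))``, so
    the partial correlation with the region's SUVR given the covariates is
    exactly ``rho`` in expectation. ``missing_rate`` masks values completely
    at random.
    """

    name: str
    region: int
    rho: float
    missing_rate: float = 0.0
    alpha0: float = 0.0
    alpha_age: float = 0.01
    alpha_sex: float = 0.5
    alpha_bmi: float = 0.05
    eta_sd: float = 1.0

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")


@dataclass
class ScenarioConfig:
    """Full description of one synthetic study."""

    group_sizes: dict[str, int]
    n_regions: int = 90
    base_mean: float | np.ndarray = 1.2
    effect: dict[str, np.ndarray] = field(default_factory=dict)
    covariate_model: CovariateModel | None = None
    covariance_model: CovarianceModel | None = None
    biomarker_links: list[BiomarkerLink] = field(default_factory=list)
    t_dof: int | None = None  # heavier-tailed residuals when set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariate_model is None:
            groups = list(self.group_sizes)
            self.covariate_model = CovariateModel(
                age_mean={g: 53.0 for g in groups},
                age_sd={g: 15.0 for g in groups},
                sex_p_male={g: 0.5 for g in groups},
                bmi_mean={g: 24.0 for g in groups},
                bmi_sd={g: 3.5 for g in groups},
            )
        if self.covariance_model is None:
            self.covariance_model = CovarianceModel(
                modules=np.arange(self.n_regions) % 3
            )
        for g, e in self.effect.items():
            self.effect[g] = np.broadcast_to(np.asarray(e, float), (self.n_regions,)).copy()


def _draw_residuals(rng, chol, n, sigma, t_dof):
    z = rng.standard_normal((n, chol.shape[0]))
    if t_dof is not None:
        # scale-mixture construction: multivariate t with the same correlation
        chi = rng.chisquare(t_dof, size=(n, 1))
        z = z * np.sqrt(t_dof / chi) * math.sqrt((t_dof - 2) / t_dof)
    return sigma * (z @ chol.T)


def generate_cohort(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[list[SubjectRecord], SUVRTable]:
    """Sample one cohort; fully reproducible from the seed.

    Returns the subject records (covariates + biomarkers with missingness)
    and the subjects x regions SUVR table on a synthetic atlas.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = config.covariate_model
    cvm = config.covariance_model
    p = config.n_regions
    base = np.broadcast_to(np.asarray(config.base_mean, float), (p,))
    beta_age = np.broadcast_to(np.asarray(cov.beta_age, float), (p,))
    beta_sex = np.broadcast_to(np.asarray(cov.beta_sex, float), (p,))

    chols = {g: cvm.cholesky(g) for g in config.group_sizes}  # PD check up front

    records: list[SubjectRecord] = []
    all_values = []
    all_ids = []
    for group, n in config.group_sizes.items():
        age = np.clip(rng.normal(cov.age_mean[group], cov.age_sd[group], n), 18.0, 90.0)
        sex = rng.binomial(1, cov.sex_p_male[group], n)
        bmi = np.clip(rng.normal(cov.bmi_mean[group], cov.bmi_sd[group], n), 15.0, None)
        eps = _draw_residuals(rng, chols[group], n, cvm.sigma, config.t_dof)
        effect = config.effect.get(group, np.zeros(p))
        values = (
            base[None, :]
            + effect[None, :]
            + beta_age[None, :] * age[:, None]
            + beta_sex[None, :] * sex[:, None]
            + eps
        )

        biomarkers = {}
        for link in config.biomarker_links:
            lam = link.rho * link.eta_sd / (cvm.sigma * math.sqrt(1 - link.rho**2))
            eta = rng.normal(0.0, link.eta_sd, n)
            bm = (
                link.alpha0
                + link.alpha_age * age
                + link.alpha_sex * sex
                + link.alpha_bmi * bmi
                + lam * eps[:, link.region]
                + eta
            )
            mask = rng.random(n) < link.missing_rate
            bm = bm.copy()
            bm[mask] = np.nan
            biomarkers[link.name] = bm

        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{group}_{i:04d}",
                    group=group,
                    age=float(age[i]),
                    sex=int(sex[i]),
                    bmi=float(bmi[i]),
                    biomarkers={k: float(v[i]) for k, v in biomarkers.items()},
                )
            )
        all_values.append(values)
        all_ids.extend(f"{group}_{i:04d}" for i in range(n))

    table = SUVRTable(
        subject_ids=all_ids,
        atlas=synthetic_atlas(p),
        values=np.vstack(all_values),
        kind="suvr",
    )
    return records, table


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

# cohort moments: control 53.37+-15.22 y, 52.52% male; disease groups as
# reported for the hypertension / T2DM / obesity / gout cohorts
_CONTROL_AGE = (53.37, 15.22)
_CONTROL_MALE = 0.5252

_PRESET_DEMOGRAPHICS = {
    "hypertension": dict(age=(63.02, 11.38), p_male=0.6339, bmi=(24.5, 3.5)),
    "t2dm": dict(age=(59.68, 10.57), p_male=0.5714, bmi=(24.5, 3.5)),
    "obesity": dict(age=(48.18, 12.38), p_male=0.4545, bmi=(33.19, 3.05)),
    "gout": dict(age=(58.57, 14.93), p_male=0.8571, bmi=(24.5, 3.5)),
}

PRESET_NAMES = (
    "hypertension_like",
    "t2dm_like",
    "obesity_like",
    "gout_like",
    "null",
    "age_confounded_null",
    "two_block",
)


def _covariates(groups: dict[str, tuple], beta_age=-0.002, beta_sex=0.02) -> CovariateModel:
    return CovariateModel(
        age_mean={g: v[0][0] for g, v in groups.items()},
        age_sd={g: v[0][1] for g, v in groups.items()},
        sex_p_male={g: v[1] for g, v in groups.items()},
        bmi_mean={g: v[2][0] for g, v in groups.items()},
        bmi_sd={g: v[2][1] for g, v in groups.items()},
        beta_age=beta_age,
        beta_sex=beta_sex,
    )


def preset_scenario(name: str, n_regions: int = 90, seed: int = 0) -> ScenarioConfig:
    """Named study scenarios mirroring the reported group designs.

    ``hypertension_like``: 497 controls vs 112 cases; 49 regions shifted
    down by 0.5 residual sd and the right-amygdala slot shifted up;
    attenuated residual connectivity in the disease group.
    ``t2dm_like``: 497 vs 56; 38 regions down; attenuated connectivity.
    ``obesity_like``: 497 vs 11; 4 regions up; attenuated connectivity.
    ``gout_like``: 14 vs 14 (matched design); right-paracentral slot up;
    elevated shared-latent connectivity in the gout group.
    ``null``: two exchangeable groups of 30, no effects anywhere.
    ``age_confounded_null``: no group effect but a 10-year age shift, with
    independent regions — exercises the pooled age/sex correction.
    ``two_block``: one group of 200 with a 45+45 block residual correlation
    (within 0.8, between 0.1) — exercises modularity recovery.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid names: {PRESET_NAMES}")
    sigma = 0.1
    shift = 0.5 * sigma  # planted effects are 0.5 residual sd
    modules = np.arange(n_regions) % 3

    if name == "null":
        return ScenarioConfig(
            group_sizes={"control": 30, "disease": 30},
            n_regions=n_regions,
            covariance_model=CovarianceModel(modules=modules, sigma=sigma),
            seed=seed,
        )

    if name == "age_confounded_null":
        # the hypertension-contrast cohort composition with no true effect:
        # group sizes and age/sex moments as reported, independent regions
        demo = _PRESET_DEMOGRAPHICS["hypertension"]
        cov = _covariates(
            {
                "control": (_CONTROL_AGE, _CONTROL_MALE, (23.5, 3.0)),
                "disease": (demo["age"], demo["p_male"], demo["bmi"]),
            }
        )
        return ScenarioConfig(
            group_sizes={"control": 497, "disease": 112},
            n_regions=n_regions,
            covariate_model=cov,
            covariance_model=CovarianceModel(
                modules=np.arange(n_regions), r_within=0.0, r_between=0.0, sigma=sigma
            ),
            seed=seed,
        )

    if name == "two_block":
        half = n_regions // 2
        blocks = np.repeat([0, 1], [half, n_regions - half])
        return ScenarioConfig(
            group_sizes={"control": 200},
            n_regions=n_regions,
            covariance_model=CovarianceModel(
                modules=blocks, r_within=0.8, r_between=0.1, sigma=sigma
            ),
            seed=seed,
        )

    disease = name.removesuffix("_like")
    demo = _PRESET_DEMOGRAPHICS[disease]
    sizes = {
        "hypertension": {"control": 497, "hypertension": 112},
        "t2dm": {"control": 497, "t2dm": 56},
        "obesity": {"control": 497, "obesity": 11},
        "gout": {"control": 14, "gout": 14},
    }[disease]
    effect = np.zeros(n_regions)
    if disease == "hypertension":
        down = [i for i in range(50) if i != 41]  # slot 41 ~ right amygdala
        effect[down] = -shift
        effect[41] = +shift
    elif disease == "t2dm":
        effect[:38] = -shift
    elif disease == "obesity":
        effect[[18, 19, 32, 68]] = +shift  # SMA L/R, median cingulate L, paracentral L
    elif disease == "gout":
        effect[69] = +shift  # slot 69 ~ right paracentral lobule
    scale = {"hypertension": 0.6, "t2dm": 0.6, "obesity": 0.6, "gout": 2.0}[disease]

    cov = _covariates(
        {
            "control": (_CONTROL_AGE, _CONTROL_MALE, (23.5, 3.0)),
            disease: (demo["age"], demo["p_male"], demo["bmi"]),
        }
    )
    # matched gout design: controls drawn to resemble the gout demographics
    if disease == "gout":
        cov.age_mean["control"] = demo["age"][0]
        cov.age_sd["control"] = demo["age"][1]
        cov.sex_p_male["control"] = demo["p_male"]

    links = [
        BiomarkerLink("uric_acid", region=45, rho=0.5, missing_rate=0.4,
                      alpha0=300.0, alpha_age=0.5, alpha_sex=60.0, alpha_bmi=3.0, eta_sd=70.0),
        BiomarkerLink("creatinine", region=2, rho=-0.4, missing_rate=0.4,
                      alpha0=70.0, alpha_age=0.2, alpha_sex=15.0, alpha_bmi=0.5, eta_sd=18.0),
        BiomarkerLink("potassium", region=1, rho=-0.3, missing_rate=0.5,
                      alpha0=4.0, alpha_age=0.002, alpha_sex=0.05, alpha_bmi=0.0, eta_sd=0.4),
        BiomarkerLink("apolipoprotein_b", region=4, rho=0.3, missing_rate=0.5,
                      alpha0=0.9, alpha_age=0.002, alpha_sex=-0.05, alpha_bmi=0.01, eta_sd=0.2),
        BiomarkerLink("sodium", region=0, rho=0.0, missing_rate=0.3,
                      alpha0=140.0, alpha_age=0.0, alpha_sex=0.2, alpha_bmi=0.0, eta_sd=3.0),
        BiomarkerLink("chloride", region=0, rho=0.0, missing_rate=0.3,
                      alpha0=103.0, alpha_age=0.0, alpha_sex=0.1, alpha_bmi=0.0, eta_sd=3.0),
    ]

    return ScenarioConfig(
        group_sizes=sizes,
        n_regions=n_regions,
        effect={disease: effect},
        covariate_model=cov,
        covariance_model=CovarianceModel(
            modules=modules, sigma=sigma, group_scale={disease: scale}
        ),
        biomarker_links=links,
        seed=seed,
    )


def null_copy(config: ScenarioConfig) -> ScenarioConfig:
    """Same design with every group effect and connectivity scale removed."""
    cvm = replace(config.covariance_model, group_scale={})
    return replace(config, effect={}, covariance_model=cvm)
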