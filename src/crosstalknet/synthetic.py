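"""Synthetic tri-omics cohort generator with planted cross-block structure.

Emulates the statistical shape of a metabolic-syndrome cohort profiled on
three layers — genus-level 16S counts, fecal metabolites and plasma
metabolites — so the whole integration pipeline can be exercised end to end
without access to any real cohort. A small number of latent factors is
shared across the blocks: a sparse set of features in each block loads on
each factor, genus counts are drawn from a logistic-normal-multinomial so
they stay compositional, metabolite blocks receive missing cells, and the
clinical outcomes are linear in the factors and the covariates.

Ground truth (which feature loads on which factor) is carried along so
recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import ConfigurationError, OmicsBlock

#: Outcome columns, named as a cardiometabolic risk panel prints them.
OUTCOME_NAMES = (
    "Cholesterol (mg/dL)",
    "LDLc (mg/dL)",
    "HDLc (mg/dL)",
    "VLDLc (mg/dL)",
    "Triglycerides (mg/dL)",
    "Glucose (mg/dL)",
    "Insulin (mcUI/mL)",
    "HOMA IR",
    "SBP (mmHg)",
    "DBP (mmHg)",
)

COVARIATE_NAMES = ("age", "sex", "BMI")

# Cohort-level outcome means and SDs (SD back-computed from 95% CIs at n=47).
_OUTCOME_MEAN_SD = {
    "Cholesterol (mg/dL)": (215.3, 32.2),
    "LDLc (mg/dL)": (135.8, 27.1),
    "HDLc (mg/dL)": (50.5, 10.3),
    "VLDLc (mg/dL)": (28.1, 11.9),
    "Triglycerides (mg/dL)": (147.7, 75.0),
    "Glucose (mg/dL)": (100.2, 12.9),
    "Insulin (mcUI/mL)": (13.4, 7.3),
    "HOMA IR": (3.3, 1.9),
    "SBP (mmHg)": (135.1, 12.1),
    "DBP (mmHg)": (85.0, 9.4),
}

_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 50.6, 7.13, 30.0, 65.0
_BMI_MEAN, _BMI_SD, _BMI_LO, _BMI_HI = 30.5, 2.28, 25.0, 35.0
_P_FEMALE = 0.638


def _default_outcome_effects() -> dict[str, dict[int, float]]:
    # Two factors carry lipid signal, echoing the kind of cluster-lipid
    # associations the pipeline is meant to detect; the rest are null.
    return {
        "Cholesterol (mg/dL)": {0: 10.0, 4: 6.0},
        "LDLc (mg/dL)": {0: 8.0},
        "VLDLc (mg/dL)": {4: 4.0},
        "Triglycerides (mg/dL)": {4: 25.0},
    }


def _default_covariate_effects() -> dict[str, tuple[float, float, float]]:
    # (beta_age, beta_sex, beta_bmi) per outcome; mild, plausible magnitudes.
    return {
        "Cholesterol (mg/dL)": (0.5, -5.0, 1.0),
        "LDLc (mg/dL)": (0.4, -4.0, 0.8),
        "HDLc (mg/dL)": (0.1, 4.0, -0.5),
        "Triglycerides (mg/dL)": (0.5, -10.0, 3.0),
        "Glucose (mg/dL)": (0.2, -2.0, 0.8),
        "SBP (mmHg)": (0.4, -2.0, 0.6),
        "DBP (mmHg)": (0.2, -1.0, 0.4),
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic tri-omics cohort.

    Defaults mirror the study conditions the pipeline targets: 47 subjects,
    226 fecal and 378 plasma metabolites measured, a genus panel in which
    151 genera are prevalent, and five shared latent factors.
    """

    n_subjects: int = 47
    n_genera_raw: int = 180
    n_core_genera: int = 151
    n_fecal_raw: int = 226
    n_plasma_raw: int = 378
    n_factors: int = 5
    loading_sparsity: float = 0.03
    noise_sd: float = 0.3
    library_size: int = 10_000
    n_high_missing_fecal: int = 23
    n_high_missing_plasma: int = 5
    high_missing_rate: float = 0.40
    low_missing_rate_fecal: float = 0.05
    low_missing_rate_plasma: float = 0.03
    missing_profile: dict[str, dict[str, float]] | None = None
    outcome_effects: dict[str, dict[int, float]] | None = None
    covariate_effects: dict[str, tuple[float, float, float]] | None = None
    outcome_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_subjects",
            "n_genera_raw",
            "n_core_genera",
            "n_fecal_raw",
            "n_plasma_raw",
            "n_factors",
            "library_size",
        ):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_core_genera > self.n_genera_raw:
            raise ConfigurationError("n_core_genera cannot exceed n_genera_raw")
        if not 0 < self.loading_sparsity <= 1:
            raise ConfigurationError("loading_sparsity must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for rate_name in (
            "high_missing_rate",
            "low_missing_rate_fecal",
            "low_missing_rate_plasma",
        ):
            rate = getattr(self, rate_name)
            if not 0 <= rate < 1:
                raise ConfigurationError(f"{rate_name} must be in [0, 1)")
        if self.missing_profile is not None:
            for block, profile in self.missing_profile.items():
                for feat, rate in profile.items():
                    if not 0 <= rate < 1:
                        raise ConfigurationError(
                            f"missing rate for {block}:{feat} must be in [0, 1)"
                        )
        if self.outcome_effects is None:
            # default lipid signal, restricted to the factors that exist
            self.outcome_effects = {
                name: kept
                for name, effects in _default_outcome_effects().items()
                if (kept := {h: g for h, g in effects.items() if h < self.n_factors})
            }
        if self.covariate_effects is None:
            self.covariate_effects = _default_covariate_effects()
        for outcome in self.outcome_effects:
            if outcome not in OUTCOME_NAMES:
                raise ConfigurationError(f"unknown outcome name {outcome!r}")
        for outcome in self.covariate_effects:
            if outcome not in OUTCOME_NAMES:
                raise ConfigurationError(f"unknown outcome name {outcome!r}")

    def loaded_per_factor(self, n_features: int) -> int:
        return max(2, round(self.loading_sparsity * n_features))


@dataclass
class SyntheticCohort:
    """A generated cohort: factors, omics blocks, covariates, outcomes, truth."""

    latent_factors: pd.DataFrame
    covariates: pd.DataFrame
    blocks: dict[str, OmicsBlock] = field(default_factory=dict)
    outcomes: pd.DataFrame | None = None
    truth: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.latent_factors.index]


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    # Independent stream per stage so stages are insensitive to call order.
    return np.random.default_rng([stage, config.seed])


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_latent_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw the latent factor matrix and the covariate table.

    Factors are independent standard normals; age and BMI are truncated
    normals matching the cohort's demographics; sex is Bernoulli with the
    cohort's observed fraction of women (female coded 1).
    """
    rng = _rng(config, 1)
    n, q = config.n_subjects, config.n_factors
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    factors = pd.DataFrame(
        rng.standard_normal((n, q)),
        index=sample_ids,
        columns=[f"factor_{h + 1}" for h in range(q)],
    )
    covariates = pd.DataFrame(
        {
            "age": _truncnorm(rng, _AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI, n),
            "sex": rng.binomial(1, _P_FEMALE, size=n).astype(float),
            "BMI": _truncnorm(rng, _BMI_MEAN, _BMI_SD, _BMI_LO, _BMI_HI, n),
        },
        index=sample_ids,
    )
    return SyntheticCohort(latent_factors=factors, covariates=covariates)


def _plant_loadings(
    rng: np.random.Generator, feature_names: list[str], n_factors: int, per_factor: int
) -> tuple[np.ndarray, dict[str, int]]:
    """Sparse loading matrix with disjoint per-factor supports."""
    m = len(feature_names)
    need = per_factor * n_factors
    if need > m:
        raise ConfigurationError(
            f"loading_sparsity too high: {need} loaded features requested, {m} available"
        )
    chosen = rng.choice(m, size=need, replace=False)
    loadings = np.zeros((m, n_factors))
    truth: dict[str, int] = {}
    for h in range(n_factors):
        idx = chosen[h * per_factor : (h + 1) * per_factor]
        signs = rng.choice([-1.0, 1.0], size=per_factor)
        mags = rng.uniform(0.7, 1.3, size=per_factor)
        loadings[idx, h] = signs * mags
        for j in idx:
            truth[feature_names[j]] = h
    return loadings, truth


def generate_blocks(cohort: SyntheticCohort, config: CohortConfig) -> SyntheticCohort:
    """Fill the three omics blocks from the latent factors.

    Metabolite feature j is ``sum_h loading[j,h] * factor[h] + noise``.
    Genus counts are logistic-normal-multinomial: per-subject multinomial
    draws with probabilities ``softmax(baseline + loadings @ factors + noise)``
    over the genus panel, at a fixed library size, so rows are nonnegative
    integer compositions. A core subset of genera gets high baselines
    (prevalent in nearly every subject); the rest get very low baselines so
    they fall below a 10% prevalence cut.
    """
    if cohort.latent_factors is None:
        raise ConfigurationError("latent factors must be generated first")
    rng = _rng(config, 2)
    factors = cohort.latent_factors.to_numpy()
    n = factors.shape[0]
    sample_ids = cohort.sample_ids

    blocks: dict[str, OmicsBlock] = {}
    truth: dict[str, dict[str, int]] = {}

    for label, m in (("fecal", config.n_fecal_raw), ("plasma", config.n_plasma_raw)):
        names = [f"{label.capitalize()[:3]}_{j + 1:03d}" for j in range(m)]
        loadings, block_truth = _plant_loadings(
            rng, names, config.n_factors, config.loaded_per_factor(m)
        )
        values = factors @ loadings.T + rng.normal(0.0, config.noise_sd, size=(n, m))
        blocks[label] = OmicsBlock(
            pd.DataFrame(values, index=sample_ids, columns=names), label
        )
        truth[label] = block_truth

    m = config.n_genera_raw
    names = [f"Genus_{j + 1:03d}" for j in range(m)]
    core = np.zeros(m, dtype=bool)
    core[rng.choice(m, size=config.n_core_genera, replace=False)] = True
    baseline = np.where(
        core, rng.normal(0.0, 1.0, size=m), rng.normal(-8.0, 0.25, size=m)
    )
    core_names = [names[j] for j in np.flatnonzero(core)]
    core_loadings, genus_truth = _plant_loadings(
        rng, core_names, config.n_factors, config.loaded_per_factor(m)
    )
    loadings = np.zeros((m, config.n_factors))
    loadings[np.flatnonzero(core), :] = core_loadings
    eta = baseline + factors @ loadings.T + rng.normal(0.0, config.noise_sd, size=(n, m))
    probs = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(config.library_size, probs[i]) for i in range(n)]
    )
    blocks["genus"] = OmicsBlock(
        pd.DataFrame(counts, index=sample_ids, columns=names), "genus"
    )
    truth["genus"] = genus_truth

    cohort.blocks = blocks
    cohort.truth = truth
    return cohort


def default_missing_profile(config: CohortConfig, cohort: SyntheticCohort) -> dict[str, dict[str, float]]:
    """Per-feature missingness rates for the metabolite blocks.

    A fixed number of features per block (23 fecal, 5 plasma by default) gets
    a high rate, the remainder a low one, placing per-feature missingness on
    either side of the 20% exclusion threshold. High-rate features are chosen
    among features that do not load on any factor, so the exclusion step does
    not delete planted signal.
    """
    rng = _rng(config, 3)
    profile: dict[str, dict[str, float]] = {}
    for label, n_high, low_rate in (
        ("fecal", config.n_high_missing_fecal, config.low_missing_rate_fecal),
        ("plasma", config.n_high_missing_plasma, config.low_missing_rate_plasma),
    ):
        names = cohort.blocks[label].feature_names
        unplanted = [f for f in names if f not in cohort.truth.get(label, {})]
        if n_high > len(unplanted):
            raise ConfigurationError(
                f"cannot place {n_high} high-missingness features among "
                f"{len(unplanted)} unplanted {label} features"
            )
        high = set(rng.choice(unplanted, size=n_high, replace=False).tolist())
        profile[label] = {
            f: (config.high_missing_rate if f in high else low_rate) for f in names
        }
    return profile


def inject_missingness(
    block: OmicsBlock, profile: dict[str, float], seed: int
) -> OmicsBlock:
    """Blank cells missing-completely-at-random with per-feature rates."""
    for feat, rate in profile.items():
        if not 0 <= rate < 1:
            raise ConfigurationError(f"missing rate for {feat!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    data = block.data.copy()
    for feat in data.columns:
        rate = profile.get(str(feat), 0.0)
        if rate > 0:
            mask = rng.random(len(data)) < rate
            data.loc[mask, feat] = np.nan
    return block.with_data(data)


def _inject_with_guarantee(
    block: OmicsBlock,
    profile: dict[str, float],
    seed: int,
    threshold: float = 0.20,
    max_tries: int = 100,
) -> OmicsBlock:
    """Inject missingness, regenerating until every feature's empirical
    missing fraction falls on the side of ``threshold`` its rate intends."""
    for attempt in range(max_tries):
        out = inject_missingness(block, profile, seed + attempt)
        frac = out.missing_fraction()
        ok = all(
            (frac[f] > threshold) == (profile.get(str(f), 0.0) > 0.25)
            for f in out.data.columns
        )
        if ok:
            return out
    raise RuntimeError("missingness profile could not be realized")  # pragma: no cover


def generate_outcomes(cohort: SyntheticCohort, config: CohortConfig) -> SyntheticCohort:
    """Fill the 10-outcome table: linear in factors and covariates plus noise."""
    if cohort.covariates is None or cohort.latent_factors is None:
        raise ConfigurationError("factors and covariates must be generated first")
    rng = _rng(config, 4)
    factors = cohort.latent_factors.to_numpy()
    cov = cohort.covariates
    age_c = cov["age"].to_numpy() - _AGE_MEAN
    sex = cov["sex"].to_numpy()
    bmi_c = cov["BMI"].to_numpy() - _BMI_MEAN
    n = len(cov)

    out = {}
    for name in OUTCOME_NAMES:
        mean, sd = _OUTCOME_MEAN_SD[name]
        y = np.full(n, mean, dtype=float)
        for h, gamma in config.outcome_effects.get(name, {}).items():
            if not 0 <= int(h) < config.n_factors:
                raise ConfigurationError(
                    f"outcome effect references factor {h} outside 0..{config.n_factors - 1}"
                )
            y += gamma * factors[:, int(h)]
        b_age, b_sex, b_bmi = config.covariate_effects.get(name, (0.0, 0.0, 0.0))
        y += b_age * age_c + b_sex * sex + b_bmi * bmi_c
        y += rng.normal(0.0, sd * config.outcome_noise_scale, size=n)
        out[name] = y
    cohort.outcomes = pd.DataFrame(out, index=cohort.sample_ids)
    return cohort


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a complete cohort: factors, blocks, missingness, outcomes."""
    config = config or CohortConfig()
    cohort = generate_latent_cohort(config)
    cohort = generate_blocks(cohort, config)
    profile = (
        config.missing_profile
        if config.missing_profile is not None
        else default_missing_profile(config, cohort)
    )
    for label in ("fecal", "plasma"):
        block_profile = profile.get(label, {})
        if block_profile:
            cohort.blocks[label] = _inject_with_guarantee(
                cohort.blocks[label], block_profile, seed=config.seed + 1000
            )
    cohort = generate_outcomes(cohort, config)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as TSV fixtures plus truth.json.

    genus.tsv / fecal.tsv / plasma.tsv: samples as rows, feature header,
    missing cells empty. subjects.tsv: covariates then outcomes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label in ("genus", "fecal", "plasma"):
        p = outdir / f"{label}.tsv"
        cohort.blocks[label].data.to_csv(p, sep="\t", index_label="sample_id")
        paths[label] = p
    subjects = cohort.covariates.join(cohort.outcomes)
    paths["subjects"] = outdir / "subjects.tsv"
    subjects.to_csv(paths["subjects"], sep="\t", index_label="sample_id")
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return paths


def read_block(path: str | Path, block_label: str) -> OmicsBlock:
    data = pd.read_csv(path, sep="\t", index_col="sample_id")
    data.index = data.index.astype(str)
    return OmicsBlock(data, block_label)


def read_subjects(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read subjects.tsv; return (covariates, outcomes)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    cov = df[list(COVARIATE_NAMES)]
    outcomes = df[[c for c in df.columns if c not in COVARIATE_NAMES]]
    return cov, outcomes
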