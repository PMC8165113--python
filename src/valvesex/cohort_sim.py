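"""Synthetic matched-cohort and expression generator with known planted truth.

Emulates the study design: a pool of male and female surgical patients with
Table-1-style clinical covariates, three valve tissue samples per patient
(nondiseased / intermediate / calcified), and a log2 expression matrix with
planted sex effects, calcification effects, sex-by-calcification
interactions, X-escape-like and Y-linked genes.

Generative model per gene g and sample (patient i, tissue score t):

    x = mu_g + alpha_g * male_i + beta_g * t + gamma_g * male_i * t
        + b_i + eps,   eps ~ N(0, noise_sd^2),  b_i ~ N(0, patient_sd^2)

with t in {0, 0.5, 1} for nondiseased / intermediate / calcified. All
distributional choices here are stand-ins for a study whose raw data are
not public; they exist so that every downstream stage has a ground-truth
oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, TISSUE_LEVELS, TISSUE_SCORE

GENE_ROLES = ("null", "sex", "calcification", "interaction", "chrX_escape", "chrY")

#: Default clinical covariate distributions (loosely Table-1-like).
#: Binary probabilities may be a single float or a {"M": .., "F": ..} dict
#: so that propensity matching is non-trivially exercised.
DEFAULT_COVARIATE_PARAMS: dict = {
    "age": {"mean": 75.0, "sd": 5.5},
    "bmi": {"mean": 29.0, "sd": 5.0},
    "cabg": {"p": {"M": 0.50, "F": 0.28}},
    "diabetes": {"p": 0.17},
    "ckd": {"p": 0.25},
    # never / former / current
    "smoking": {"p": [0.43, 0.54, 0.03]},
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort generator."""

    n_pool_per_sex: int = 18
    n_pairs_target: int = 18
    n_genes: int = 2000
    n_sex_genes: int = 30
    n_cal_genes: int = 30
    n_interaction_genes: int = 30
    n_x_genes: int = 10
    n_y_genes: int = 10
    effect_sex: float = 1.0
    effect_cal: float = 1.0
    effect_interaction: float = 1.0
    #: optional shared (both-sex) calcification slope added to interaction genes
    interaction_cal_effect: float = 0.0
    noise_sd: float = 0.5
    patient_sd: float = 0.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    #: expression floor of Y-linked genes in females
    y_background: float = 4.0
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_pool_per_sex": self.n_pool_per_sex,
            "n_pairs_target": self.n_pairs_target,
            "n_genes": self.n_genes,
            "n_sex_genes": self.n_sex_genes,
            "n_cal_genes": self.n_cal_genes,
            "n_interaction_genes": self.n_interaction_genes,
            "n_x_genes": self.n_x_genes,
            "n_y_genes": self.n_y_genes,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        planted = (
            self.n_sex_genes
            + self.n_cal_genes
            + self.n_interaction_genes
            + self.n_x_genes
            + self.n_y_genes
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene counts ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd < 0 or self.patient_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        _validate_covariate_params(self.covariate_params)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _validate_covariate_params(params: dict) -> None:
    for name, spec in params.items():
        if "sd" in spec and spec["sd"] < 0:
            raise ValueError(f"covariate {name!r}: sd must be >= 0")
        if "p" in spec:
            p = spec["p"]
            if isinstance(p, dict):
                values = list(p.values())
            elif isinstance(p, (list, tuple)):
                values = list(p)
                if abs(sum(values) - 1.0) > 1e-9:
                    raise ValueError(f"covariate {name!r}: category probabilities must sum to 1")
            else:
                values = [p]
            for v in np.ravel([np.asarray(v, dtype=float) for v in values]):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"covariate {name!r}: probability {v} outside [0, 1]")


# ----------------------------------------------------------------------
# clinical table
# ----------------------------------------------------------------------

SMOKING_LEVELS = ("never", "former", "current")


def _sexed_prob(p, sex: str) -> float:
    return float(p[sex]) if isinstance(p, dict) else float(p)


def simulate_clinical(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a clinical covariate table for the male and female patient pools.

    Returns one row per patient with columns ``patient_id``, ``sex``,
    ``age``, ``bmi``, ``cabg``, ``diabetes``, ``ckd``, ``smoking``.
    Reproducible for a fixed (config, seed).
    """
    if config.n_pool_per_sex < config.n_pairs_target:
        raise ValueError("n_pool_per_sex must be >= n_pairs_target")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(101,)))
    params = config.covariate_params
    rows = []
    for sex in ("M", "F"):
        for i in range(config.n_pool_per_sex):
            row = {"patient_id": f"{sex}{i + 1:03d}", "sex": sex}
            row["age"] = rng.normal(params["age"]["mean"], params["age"]["sd"])
            row["bmi"] = rng.normal(params["bmi"]["mean"], params["bmi"]["sd"])
            for cov in ("cabg", "diabetes", "ckd"):
                row[cov] = int(rng.random() < _sexed_prob(params[cov]["p"], sex))
            p_smoke = params["smoking"]["p"]
            p_smoke = p_smoke[sex] if isinstance(p_smoke, dict) else p_smoke
            row["smoking"] = SMOKING_LEVELS[rng.choice(3, p=np.asarray(p_smoke, dtype=float))]
            rows.append(row)
    columns = ["patient_id", "sex", "age", "bmi", "cabg", "diabetes", "ckd", "smoking"]
    return pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)


# ----------------------------------------------------------------------
# expression matrix + planted truth
# ----------------------------------------------------------------------


def _assign_roles(config: SimConfig) -> pd.DataFrame:
    """Gene role labels, true coefficients, and chromosome placement."""
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    roles = np.array(["null"] * n, dtype=object)
    alpha = np.zeros(n)
    beta = np.zeros(n)
    gamma = np.zeros(n)

    start = 0
    blocks = [
        ("sex", config.n_sex_genes),
        ("calcification", config.n_cal_genes),
        ("interaction", config.n_interaction_genes),
        ("chrX_escape", config.n_x_genes),
        ("chrY", config.n_y_genes),
    ]
    for role, count in blocks:
        sl = slice(start, start + count)
        roles[sl] = role
        if role == "sex":
            alpha[sl] = config.effect_sex
        elif role == "calcification":
            beta[sl] = config.effect_cal
        elif role == "interaction":
            gamma[sl] = config.effect_interaction
            beta[sl] = config.interaction_cal_effect
        elif role == "chrX_escape":
            # XIST-like: elevated in females
            alpha[sl] = -abs(config.effect_sex)
        elif role == "chrY":
            # males at background + shift, females exactly at background
            alpha[sl] = abs(config.effect_sex)
        start += count

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(102,)))
    chrom = np.array([str(c) for c in rng.integers(1, 23, size=n)], dtype=object)
    chrom[roles == "chrX_escape"] = "X"
    chrom[roles == "chrY"] = "Y"
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": roles,
            "alpha_sex": alpha,
            "beta_cal": beta,
            "gamma_int": gamma,
            "chromosome": chrom,
        }
    ).set_index("gene_id")


def simulate_expression(
    clinical: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate the log2 expression matrix and its planted truth.

    Three samples are emitted per patient, one per tissue grade. The
    returned truth table (one row per gene) carries the role label, the
    true coefficients and the chromosome assignment; it is the oracle for
    all recovery tests.
    """
    if clinical.empty:
        raise ValueError("clinical table is empty")
    seed = config.seed if seed is None else seed
    truth = _assign_roles(config)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(103,)))

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    is_y = (truth["role"] == "chrY").to_numpy()
    mu[is_y] = config.y_background

    patients = clinical["patient_id"].to_numpy()
    male_by_patient = (clinical["sex"] == "M").to_numpy().astype(float)
    intercepts = rng.normal(0.0, config.patient_sd, size=len(patients)) if config.patient_sd > 0 else np.zeros(len(patients))

    sample_ids, sample_patient, sample_sex, sample_tissue = [], [], [], []
    male = np.empty(3 * len(patients))
    tscore = np.empty(3 * len(patients))
    b = np.empty(3 * len(patients))
    j = 0
    for i, pid in enumerate(patients):
        for tissue in TISSUE_LEVELS:
            sample_ids.append(f"{pid}_{tissue}")
            sample_patient.append(pid)
            sample_sex.append("M" if male_by_patient[i] else "F")
            sample_tissue.append(tissue)
            male[j] = male_by_patient[i]
            tscore[j] = TISSUE_SCORE[tissue]
            b[j] = intercepts[i]
            j += 1

    alpha = truth["alpha_sex"].to_numpy()[:, None]
    beta = truth["beta_cal"].to_numpy()[:, None]
    gamma = truth["gamma_int"].to_numpy()[:, None]
    x = (
        mu[:, None]
        + alpha * male[None, :]
        + beta * tscore[None, :]
        + gamma * (male * tscore)[None, :]
        + b[None, :]
    )
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)

    values = pd.DataFrame(x, index=truth.index.copy(), columns=sample_ids)
    samples = pd.DataFrame(
        {
            "patient_id": sample_patient,
            "sex": sample_sex,
            "tissue": sample_tissue,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(values, samples), truth


def make_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """Gene annotation table (gene_id, symbol, chromosome) from a truth table."""
    return pd.DataFrame(
        {
            "gene_id": truth.index,
            "symbol": [g.upper() for g in truth.index],
            "chromosome": truth["chromosome"].to_numpy(),
        }
    ).set_index("gene_id")


def truth_contrasts(truth: pd.DataFrame) -> pd.DataFrame:
    """Closed-form expected log2 differences implied by the planted coefficients.

    Columns: male-minus-female within each tissue grade, and
    calcified-minus-nondiseased within each sex.
    """
    required = {"alpha_sex", "beta_cal", "gamma_int"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    a = truth["alpha_sex"]
    b = truth["beta_cal"]
    g = truth["gamma_int"]
    return pd.DataFrame(
        {
            "mf_nondiseased": a + g * 0.0,
            "mf_intermediate": a + g * 0.5,
            "mf_calcified": a + g * 1.0,
            "cal_vs_non_male": b + g,
            "cal_vs_non_female": b.copy(),
        },
        index=truth.index,
    )
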