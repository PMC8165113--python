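import numpy as np
import pandas as pd
import pytest

from valvesex import ExpressionMatrix, MatchResult, SimConfig, simulate_clinical, simulate_expression


def make_expr(values: dict, samples: list) -> ExpressionMatrix:
    """Hand-built ExpressionMatrix.

    ``values``: gene_id -> list of values; ``samples``: list of
    (sample_id, patient_id, sex, tissue) tuples in column order.
    """
    sample_ids = [s[0] for s in samples]
    frame = pd.DataFrame(values, index=sample_ids).T
    sheet = pd.DataFrame(
        [s[1:] for s in samples],
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["patient_id", "sex", "tissue"],
    )
    return ExpressionMatrix(frame, sheet)


def full_pairs(clinical: pd.DataFrame) -> MatchResult:
    """Trivial i-th-male-to-i-th-female pairing (no propensity model)."""
    males = clinical.loc[clinical["sex"] == "M", "patient_id"].tolist()
    females = clinical.loc[clinical["sex"] == "F", "patient_id"].tolist()
    return MatchResult(pairs=list(zip(males, females)), caliper=None)


@pytest.fixture(scope="session")
def strong_cohort():
    """18+18 cohort with strongly planted effects; shared across tests."""
    cfg = SimConfig(
        n_pool_per_sex=18,
        n_genes=1200,
        n_sex_genes=20,
        n_cal_genes=25,
        n_interaction_genes=25,
        n_x_genes=8,
        n_y_genes=8,
        effect_sex=1.5,
        effect_cal=2.0,
        effect_interaction=2.0,
        interaction_cal_effect=2.0,
        noise_sd=0.5,
        seed=42,
    )
    clinical = simulate_clinical(cfg, 42)
    expr, truth = simulate_expression(clinical, cfg, 42)
    return cfg, clinical, expr, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects at all."""
    cfg = SimConfig(
        n_pool_per_sex=18,
        n_genes=800,
        n_sex_genes=0,
        n_cal_genes=0,
        n_interaction_genes=0,
        n_x_genes=0,
        n_y_genes=0,
        noise_sd=1.0,
        seed=11,
    )
    clinical = simulate_clinical(cfg, 11)
    expr, truth = simulate_expression(clinical, cfg, 11)
    return cfg, clinical, expr, truth
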