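"""End-to-end study reproduction: simulate, fit, predict, call, evaluate.

The one-command workflow mirrors the published study design: a large
training cohort with the Slovenian genotype-phenotype structure calibrates
the multinomial-logistic coefficients (standing in for the n=3804 reference
panel the published model was built on), the model then predicts a fresh
n=105 study-scale cohort, and the thresholded calls are scored with the
inconclusive-as-negative convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CohortEvaluation, evaluate_cohort
from .model import EyeColorModel, EyeColorResults, call_eye_color, predict_probabilities
from .panel import CATEGORIES
from .simulate import (
    CohortConfig,
    SyntheticCohort,
    default_slovenian_config,
    expected_phenotype_given_herc2,
    expected_t_carrier_stats,
    generate_cohort,
)

#: Scale of the reference panel the published coefficients were fitted on.
DUTCH_TRAINING_N = 3804


def subseeds(seed: int, k: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(k) % (2**31)]


def predict_cohort(cohort: SyntheticCohort, results_or_params, threshold: float = 0.7):
    """(sample_id, ProbabilityTriple, EyeColorCall) rows for a cohort."""
    params = (
        results_or_params.parameter_set
        if isinstance(results_or_params, EyeColorResults)
        else results_or_params
    )
    rows = []
    for g in cohort.genotypes:
        trip = predict_probabilities(g, params)
        rows.append((g.sample_id, trip, call_eye_color(trip, threshold)))
    return rows


@dataclass
class ReproductionResult:
    config: CohortConfig
    fit: EyeColorResults
    study: SyntheticCohort
    predictions: list
    evaluation: CohortEvaluation
    contingency: pd.DataFrame


def contingency_table(config: CohortConfig, sim_n: int = 100_000,
                      seed: int | None = None) -> pd.DataFrame:
    """The study's printed composition figures: exact expectations under the
    default configuration next to a large-cohort empirical check.

    Rows cover category prevalences, P(phenotype | rs12913832 genotype) for
    the strongly associated genotypes, and the T-carrier brown/dark-iris
    fractions; all values are percentages.
    """
    exact = {}
    for c in CATEGORIES:
        exact[f"prevalence_{c}"] = 100.0 * config.category_prevalence[c]
    cond = expected_phenotype_given_herc2(config)
    exact["p_blue_given_CC"] = 100.0 * cond["CC"]["blue"]
    exact["p_brown_given_CT"] = 100.0 * cond["CT"]["brown"]
    exact["p_brown_given_TT"] = 100.0 * cond["TT"]["brown"]
    tc = expected_t_carrier_stats(config)
    exact["p_brown_given_T_carrier"] = 100.0 * tc["p_brown_given_t_carrier"]
    exact["p_dark_given_T_carrier"] = 100.0 * tc["p_dark_given_t_carrier"]

    big = generate_cohort(
        CohortConfig(
            n=sim_n,
            category_prevalence=config.category_prevalence,
            herc2_genotype_given_category=config.herc2_genotype_given_category,
            minor_snp_frequencies=config.minor_snp_frequencies,
            assumed_frequencies=config.assumed_frequencies,
            hazel_fraction_intermediate_ct=config.hazel_fraction_intermediate_ct,
        ),
        seed=seed,
    )
    from .simulate import HERC2_RS

    panel = big.genotypes[0].panel
    j = panel.index_of(HERC2_RS)
    herc2 = np.array([g.dosages[j] for g in big.genotypes])  # T count: CC=0 CT=1 TT=2
    cats = np.array([p.category for p in big.phenotypes])
    sim = {}
    for c in CATEGORIES:
        sim[f"prevalence_{c}"] = 100.0 * np.mean(cats == c)
    sim["p_blue_given_CC"] = 100.0 * np.mean(cats[herc2 == 0] == "blue")
    sim["p_brown_given_CT"] = 100.0 * np.mean(cats[herc2 == 1] == "brown")
    sim["p_brown_given_TT"] = 100.0 * np.mean(cats[herc2 == 2] == "brown")
    tcar = herc2 >= 1
    sim["p_brown_given_T_carrier"] = 100.0 * np.mean(cats[tcar] == "brown")
    # dark = brown + the hazel share of intermediate CT carriers (in
    # expectation; the generator does not sub-classify intermediate irises)
    n_tc = tcar.sum()
    n_brown_tc = np.sum(cats[tcar] == "brown")
    n_int_ct = np.sum((herc2 == 1) & (cats == "intermediate"))
    sim["p_dark_given_T_carrier"] = 100.0 * (
        (n_brown_tc + n_int_ct * config.hazel_fraction_intermediate_ct) / n_tc
    )
    return pd.DataFrame(
        {
            "quantity": list(exact),
            "expected_pct": [exact[k] for k in exact],
            "simulated_pct": [sim[k] for k in exact],
        }
    )


def reproduce(
    seed: int,
    n_train: int = DUTCH_TRAINING_N,
    n_study: int | None = None,
    threshold: float = 0.7,
    sim_n: int = 100_000,
) -> ReproductionResult:
    """Run the full study-shaped analysis from a single seed."""
    s_train, s_study, s_sim = subseeds(seed, 3)
    config = default_slovenian_config()
    train_cfg = CohortConfig(
        n=n_train,
        category_prevalence=config.category_prevalence,
        herc2_genotype_given_category=config.herc2_genotype_given_category,
        minor_snp_frequencies=config.minor_snp_frequencies,
        assumed_frequencies=config.assumed_frequencies,
        hazel_fraction_intermediate_ct=config.hazel_fraction_intermediate_ct,
    )
    train = generate_cohort(train_cfg, seed=s_train)
    model = EyeColorModel.from_records(train.genotypes, train.phenotypes, reference="blue")
    fit = model.fit()

    study_cfg = config if n_study is None else CohortConfig(
        n=n_study,
        category_prevalence=config.category_prevalence,
        herc2_genotype_given_category=config.herc2_genotype_given_category,
        minor_snp_frequencies=config.minor_snp_frequencies,
        assumed_frequencies=config.assumed_frequencies,
        hazel_fraction_intermediate_ct=config.hazel_fraction_intermediate_ct,
    )
    study = generate_cohort(study_cfg, seed=s_study)
    predictions = predict_cohort(study, fit, threshold)
    P = np.vstack([t.as_array() for _, t, _ in predictions])
    calls = [c for _, _, c in predictions]
    evaluation = evaluate_cohort(
        P, calls, study.phenotypes, threshold,
        sample_ids=[sid for sid, _, _ in predictions],
    )
    contingency = contingency_table(config, sim_n=sim_n, seed=s_sim)
    return ReproductionResult(
        config=config,
        fit=fit,
        study=study,
        predictions=predictions,
        evaluation=evaluation,
        contingency=contingency,
    )
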