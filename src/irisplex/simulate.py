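"""Synthetic genotype-phenotype cohorts with the Slovenian study structure.

The default configuration encodes the published Slovenian sample of n=105:
category prevalences 47 blue / 27 intermediate / 31 brown, and the joint
distribution of rs12913832 (HERC2) genotype with phenotype.  The joint
counts below are the unique table consistent with every reported figure —
45/49 CC carriers blue, 19/41 CT and 12/15 TT carriers brown, 31/56
T-carriers brown and 49/56 T-carriers dark-eyed, with the 47/27/31
marginals; this places the two blue-with-brown-ring CT carriers in the
blue category.

Only rs12913832 is conditioned on phenotype: the study reports joint counts
for no other marker.  The remaining five SNPs are drawn phenotype-
independently under Hardy-Weinberg (dosage ~ Binomial(2, effect-allele
frequency)); rs1800407's allele-A frequency (0.119) is reported, the other
four frequencies are plausible European defaults flagged ``assumed`` and
never asserted on by tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .model import GenotypeRecord, ParameterSet, PhenotypeRecord
from .panel import CATEGORIES, SnpPanel, default_panel

HERC2_RS = "rs12913832"
HERC2_GENOTYPES = ("CC", "CT", "TT")  # effect allele T: dosages 0, 1, 2

#: rs12913832 genotype x phenotype joint counts of the n=105 Slovenian sample.
HERC2_JOINT_COUNTS = {
    "CC": {"blue": 45, "intermediate": 4, "brown": 0},
    "CT": {"blue": 2, "intermediate": 20, "brown": 19},
    "TT": {"blue": 0, "intermediate": 3, "brown": 12},
}

#: Of the 20 intermediate CT carriers, 18 had hazel (dark) irises.
CT_HAZEL_COUNT = 18

#: Reported effect-allele frequency of rs1800407 (allele A) in the sample.
RS1800407_A_FREQ = 0.119

#: Effect-allele frequencies for the four markers whose genotype counts are
#: not reported; plausible European values, explicitly assumptions.
ASSUMED_FREQUENCIES = {
    "rs16891982": 0.05,   # SLC45A2 C
    "rs1393350": 0.26,    # TYR A
    "rs12896399": 0.45,   # SLC24A4 G
    "rs12203592": 0.14,   # IRF4 T
}


@dataclass(frozen=True)
class CohortConfig:
    """Sampling scheme for a synthetic cohort.

    Phenotype is drawn from ``category_prevalence``; the rs12913832
    genotype from the phenotype-conditional table; every other panel SNP
    independently as Binomial(2, frequency).  ``assumed_frequencies`` names
    the markers whose frequency is an assumption rather than a reported
    value.  ``hazel_fraction_intermediate_ct`` is the share of intermediate
    CT carriers with dark (hazel) irises, used only for dark-iris
    expectations, not for sampling.
    """

    n: int
    category_prevalence: dict[str, float]
    herc2_genotype_given_category: dict[str, dict[str, float]]
    minor_snp_frequencies: dict[str, float]
    assumed_frequencies: frozenset[str] = frozenset()
    hazel_fraction_intermediate_ct: float = CT_HAZEL_COUNT / 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        self._check_probs("category_prevalence", self.category_prevalence, set(CATEGORIES))
        for cat, tbl in self.herc2_genotype_given_category.items():
            self._check_probs(f"herc2 table[{cat}]", tbl, set(HERC2_GENOTYPES))
        for rs, f in self.minor_snp_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency of {rs} outside [0,1]: {f}")

    @staticmethod
    def _check_probs(name, d, keys) -> None:
        if set(d) != keys:
            raise ValueError(f"{name}: keys {sorted(d)} != expected {sorted(keys)}")
        vals = np.array(list(d.values()), dtype=float)
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"{name}: probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SyntheticCohort:
    genotypes: list[GenotypeRecord]
    phenotypes: list[PhenotypeRecord]
    seed: int | None
    config: CohortConfig | None = None

    def __len__(self) -> int:
        return len(self.genotypes)


def default_slovenian_config(seed: int | None = None) -> CohortConfig:
    """The Slovenian study structure as exact sampling probabilities."""
    cat_totals = {
        c: sum(HERC2_JOINT_COUNTS[g][c] for g in HERC2_GENOTYPES) for c in CATEGORIES
    }
    n = sum(cat_totals.values())
    prevalence = {c: cat_totals[c] / n for c in CATEGORIES}
    conditional = {
        c: {g: HERC2_JOINT_COUNTS[g][c] / cat_totals[c] for g in HERC2_GENOTYPES}
        for c in CATEGORIES
    }
    freqs = {"rs1800407": RS1800407_A_FREQ, **ASSUMED_FREQUENCIES}
    return CohortConfig(
        n=n,
        category_prevalence=prevalence,
        herc2_genotype_given_category=conditional,
        minor_snp_frequencies=freqs,
        assumed_frequencies=frozenset(ASSUMED_FREQUENCIES),
        seed=seed,
    )


def slovenian_snp_frequencies() -> dict[str, float]:
    """Effect-allele frequency of all six panel SNPs under the default
    configuration (rs12913832 T from the genotype counts: 71/210)."""
    t_alleles = sum(
        {"CC": 0, "CT": 1, "TT": 2}[g] * sum(HERC2_JOINT_COUNTS[g].values())
        for g in HERC2_GENOTYPES
    )
    n = sum(sum(HERC2_JOINT_COUNTS[g].values()) for g in HERC2_GENOTYPES)
    return {
        HERC2_RS: t_alleles / (2 * n),
        "rs1800407": RS1800407_A_FREQ,
        **ASSUMED_FREQUENCIES,
    }


# ---------------------------------------------------------------------------
# Exact expectations implied by a configuration (no simulation involved)


def expected_phenotype_given_herc2(config: CohortConfig) -> dict[str, dict[str, float]]:
    """P(category | rs12913832 genotype) by Bayes from the config."""
    prev = config.category_prevalence
    cond = config.herc2_genotype_given_category
    out = {}
    for g in HERC2_GENOTYPES:
        joint = {c: prev[c] * cond[c][g] for c in CATEGORIES}
        tot = sum(joint.values())
        out[g] = {c: joint[c] / tot for c in CATEGORIES}
    return out


def expected_t_carrier_stats(config: CohortConfig) -> dict[str, float]:
    """Brown and dark-iris fractions among rs12913832 T-allele carriers."""
    prev = config.category_prevalence
    cond = config.herc2_genotype_given_category
    p_joint = lambda c, g: prev[c] * cond[c][g]
    p_tc = sum(p_joint(c, g) for c in CATEGORIES for g in ("CT", "TT"))
    p_brown_tc = sum(p_joint("brown", g) for g in ("CT", "TT"))
    p_dark_tc = p_brown_tc + p_joint("intermediate", "CT") * config.hazel_fraction_intermediate_ct
    return {
        "p_brown_given_t_carrier": p_brown_tc / p_tc,
        "p_dark_given_t_carrier": p_dark_tc / p_tc,
    }


# ---------------------------------------------------------------------------
# Generators


def generate_cohort(config: CohortConfig, seed: int | None = None,
                    panel: SnpPanel | None = None) -> SyntheticCohort:
    """Draw a cohort under the configured scheme; deterministic given seed."""
    if panel is None:
        panel = default_panel()
    if HERC2_RS not in panel.rs_ids:
        raise ValueError(f"panel lacks {HERC2_RS}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    j_herc2 = panel.index_of(HERC2_RS)
    prev = np.array([config.category_prevalence[c] for c in CATEGORIES])
    cond = {
        c: np.array([config.herc2_genotype_given_category[c][g] for g in HERC2_GENOTYPES])
        for c in CATEGORIES
    }
    n = config.n
    cat_idx = rng.choice(3, size=n, p=prev)
    D = np.empty((n, len(panel)))
    herc2 = np.empty(n)
    for ci, c in enumerate(CATEGORIES):
        mask = cat_idx == ci
        # T-allele count: CC=0 CT=1 TT=2
        herc2[mask] = rng.choice(3, size=int(mask.sum()), p=cond[c])
    for j, snp in enumerate(panel):
        if j == j_herc2:
            D[:, j] = herc2
        else:
            if snp.rs_id not in config.minor_snp_frequencies:
                raise ValueError(f"no frequency configured for {snp.rs_id}")
            D[:, j] = rng.binomial(2, config.minor_snp_frequencies[snp.rs_id], size=n)
    genotypes = [GenotypeRecord(f"S{i + 1:05d}", D[i], panel) for i in range(n)]
    phenotypes = [
        PhenotypeRecord(f"S{i + 1:05d}", CATEGORIES[cat_idx[i]]) for i in range(n)
    ]
    return SyntheticCohort(genotypes, phenotypes, seed=seed, config=config)


def generate_training_cohort(
    params: ParameterSet,
    snp_frequencies: dict[str, float],
    n: int,
    seed: int | None = None,
) -> SyntheticCohort:
    """A model-consistent cohort: genotypes under Hardy-Weinberg, phenotype
    drawn from the model's own predicted probabilities.

    This mirrors how the published model was calibrated on a large
    (n=3804) reference panel; at that scale the fitted coefficients
    recover the generating ones.
    """
    panel = params.panel
    if n < 2 * (len(panel) + 1):
        warnings.warn(
            f"n={n} is below the parameter count; the fit will be unstable",
            stacklevel=2,
        )
    missing = [rs for rs in panel.rs_ids if rs not in snp_frequencies]
    if missing:
        raise ValueError(f"no frequency supplied for {missing}")
    rng = np.random.default_rng(seed)
    freqs = np.array([snp_frequencies[rs] for rs in panel.rs_ids])
    X = rng.binomial(2, freqs, size=(n, len(panel))).astype(float)
    P = params.predict_proba(X) if n else np.empty((0, 3))
    u = rng.random(n)
    cum = np.cumsum(P, axis=1)
    cat_idx = (u[:, None] > cum).sum(axis=1) if n else np.array([], dtype=int)
    genotypes = [GenotypeRecord(f"T{i + 1:06d}", X[i], panel) for i in range(n)]
    phenotypes = [
        PhenotypeRecord(f"T{i + 1:06d}", CATEGORIES[cat_idx[i]]) for i in range(n)
    ]
    return SyntheticCohort(genotypes, phenotypes, seed=seed, config=None)


# ---------------------------------------------------------------------------
# Config file I/O (CLI `simulate --config`)

CONFIG_FORMAT_TAG = "irisplex-cohort-v1"


def load_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != CONFIG_FORMAT_TAG:
        raise ValueError(f"unrecognised cohort-config format tag: {doc.get('format')!r}")
    return CohortConfig(
        n=int(doc["n"]),
        category_prevalence={k: float(v) for k, v in doc["category_prevalence"].items()},
        herc2_genotype_given_category={
            c: {g: float(p) for g, p in tbl.items()}
            for c, tbl in doc["herc2_genotype_given_category"].items()
        },
        minor_snp_frequencies={k: float(v) for k, v in doc["minor_snp_frequencies"].items()},
        assumed_frequencies=frozenset(doc.get("assumed_frequencies", [])),
        hazel_fraction_intermediate_ct=float(
            doc.get("hazel_fraction_intermediate_ct", CT_HAZEL_COUNT / 20.0)
        ),
        seed=doc.get("seed"),
    )


def save_cohort_config(config: CohortConfig, path) -> None:
    doc = {
        "format": CONFIG_FORMAT_TAG,
        "n": config.n,
        "category_prevalence": dict(config.category_prevalence),
        "herc2_genotype_given_category": {
            c: dict(tbl) for c, tbl in config.herc2_genotype_given_category.items()
        },
        "minor_snp_frequencies": dict(config.minor_snp_frequencies),
        "assumed_frequencies": sorted(config.assumed_frequencies),
        "hazel_fraction_intermediate_ct": config.hazel_fraction_intermediate_ct,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
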