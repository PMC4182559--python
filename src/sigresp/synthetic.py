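"""Synthetic cohorts with the statistical structure of a small in vitro drug
screen on patient-derived cultures.

Each patient contributes four expression profiles in a 2x2 factorial
(control/drug x with/without growth-factor supplementation).  Between-patient
differences dominate the variance; drug-response genes react only in
patient-specific subsets ("stripes"); a small set of causal response genes
links post-treatment expression linearly to the proliferation phenotype,
while the migration phenotype is generated independently of expression.
The full ground truth is recorded so recovery tests can score the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

GRADE_SYMBOLS = ("++", "+", "0", "-", "--", "u.e.", "n.S.")
#: grades counting as a phospho-signal decrease
DECREASE_GRADES = ("-", "--")
#: grades excluded from the evaluable denominator
NON_EVALUABLE_GRADES = ("u.e.", "n.S.")

RESPONSE_CLIP = (0.3, 1.2)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Scales are additive effects on log2-intensity expression unless noted.
    The defaults emulate the study conditions the analysis is built for:
    18 patients profiled in a 2x2 drug x growth-factor factorial, dominant
    between-patient variance, ~300 drug-responsive genes reacting in
    patient-specific subsets, and a sparse 6-gene linear link from
    post-treatment expression to the proliferation response on the
    fraction-of-control scale.  Drug effect sizes on expression are not
    quantified by the assay itself; ``treatment_effect_sd`` and
    ``causal_effect_scale`` are calibration choices reproducing the observed
    response spread (inhibition of up to ~56%, i.e. responses ~0.44-1.05).
    ``stripe_concentration`` sets how strongly response masks cluster by
    patient (smaller = sharper responder/non-responder dichotomy; the
    per-case stripes of the treatment heat map).
    """

    n_patients: int = 18
    n_genes: int = 2000
    patient_sd: float = 1.5
    residual_sd: float = 0.3
    n_treatment_genes: int = 300
    treatment_effect_sd: float = 1.0
    stripe_fraction: float = 0.5
    stripe_concentration: float = 1.0
    n_gf_genes: int = 200
    n_causal_genes: int = 6
    causal_effect_scale: float = 0.1
    response_noise_sd: float = 0.05
    null_link: bool = False
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_genes": self.n_genes,
            "n_treatment_genes": self.n_treatment_genes,
            "n_gf_genes": self.n_gf_genes,
            "n_causal_genes": self.n_causal_genes,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not self.n_causal_genes <= self.n_treatment_genes <= self.n_genes:
            raise ConfigError(
                "require n_causal_genes <= n_treatment_genes <= n_genes, got "
                f"{self.n_causal_genes} / {self.n_treatment_genes} / {self.n_genes}"
            )
        if self.n_gf_genes > self.n_genes - self.n_treatment_genes:
            raise ConfigError("n_gf_genes exceeds the genes left after treatment genes")
        sds = {
            "patient_sd": self.patient_sd,
            "residual_sd": self.residual_sd,
            "treatment_effect_sd": self.treatment_effect_sd,
            "response_noise_sd": self.response_noise_sd,
        }
        for name, value in sds.items():
            if not np.isfinite(value) or value < 0:
                raise ConfigError(f"{name} must be a finite non-negative scale, got {value!r}")
        if not 0.0 <= self.stripe_fraction <= 1.0:
            raise ConfigError(f"stripe_fraction must lie in [0, 1], got {self.stripe_fraction!r}")
        if not self.stripe_concentration > 0:
            raise ConfigError(
                f"stripe_concentration must be positive, got {self.stripe_concentration!r}"
            )
        if not np.isfinite(self.causal_effect_scale):
            raise ConfigError("causal_effect_scale must be finite")


@dataclass
class CohortTruth:
    """Ground-truth record of a generated cohort.

    ``patient_effects`` stores, per patient, the expected expression of every
    gene in that patient absent any treatment or growth-factor effect
    (gene baseline plus the patient's additive offset); subtracting it from a
    treated profile isolates the drug-induced component the response link
    acts on.
    """

    treatment_gene_ids: list[str]
    gf_gene_ids: list[str]
    causal_gene_ids: list[str]
    causal_weights: dict[str, float]
    patient_effects: pd.DataFrame  # genes x patients
    treatment_effects: pd.DataFrame = field(default=None)  # genes x patients, masked drug effect

    def __post_init__(self) -> None:
        if not set(self.causal_gene_ids) <= set(self.treatment_gene_ids):
            raise ConfigError("causal genes must be a subset of treatment genes")


def _sample_id(patient: str, treated: bool, gf: bool) -> str:
    return f"{patient}_{'drug' if treated else 'ctrl'}_{'gf' if gf else 'nogf'}"


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate one synthetic cohort.

    Returns
    -------
    matrix : DataFrame, genes x samples
        Log2-scale expression, 4 samples per patient covering the 2x2
        treatment x growth-factor factorial.
    design : DataFrame, indexed by sample
        Columns ``patient`` (str), ``treated`` (bool), ``gf`` (bool).
    response : DataFrame, indexed by patient
        Columns ``proliferation`` and ``migration``, both on the
        fraction-of-control scale, clipped to [0.3, 1.2].
    truth : CohortTruth
        Full ground-truth record for recovery tests.

    The proliferation response of a patient is
    ``clip(1 - sum_g w_g * (x_g - patient_effect_g) + noise)`` evaluated on
    the patient's treated, growth-factor-supplemented profile; with
    ``null_link`` the weights ``w_g`` are zero.  Migration is drawn from the
    same marginal family but from an independent responder draw, so it
    carries no expression link by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_p, n_g = config.n_patients, config.n_genes
    width = max(2, len(str(n_p)))
    patients = [f"P{i + 1:0{width}d}" for i in range(n_p)]
    genes = [f"g{i + 1:05d}" for i in range(n_g)]

    # sample layout: per patient, (treated, gf) in fixed order
    layout = [(False, False), (False, True), (True, False), (True, True)]
    samples, pat_col, trt_col, gf_col = [], [], [], []
    for p in patients:
        for treated, gf in layout:
            samples.append(_sample_id(p, treated, gf))
            pat_col.append(p)
            trt_col.append(treated)
            gf_col.append(gf)
    design = pd.DataFrame(
        {"patient": pat_col, "treated": trt_col, "gf": gf_col},
        index=pd.Index(samples, name="sample"),
    )

    baseline = rng.normal(7.0, 1.0, size=n_g)
    patient_offsets = rng.normal(0.0, config.patient_sd, size=(n_g, n_p))

    special = rng.choice(n_g, size=config.n_treatment_genes + config.n_gf_genes, replace=False)
    trt_idx = np.sort(special[: config.n_treatment_genes])
    gf_idx = np.sort(special[config.n_treatment_genes :])

    # per-gene drug effect direction/magnitude, gated per patient by a
    # Bernoulli mask whose probability is the patient's responder propensity:
    # responder patients react across many genes at once, producing the
    # per-case "stripes" of the treatment heat map
    trt_magnitude = rng.normal(0.0, config.treatment_effect_sd, size=config.n_treatment_genes)
    f, kappa = config.stripe_fraction, config.stripe_concentration
    if 0.0 < f < 1.0:
        propensity = rng.beta(f * kappa, (1.0 - f) * kappa, size=n_p)
    else:
        propensity = np.full(n_p, f)
    stripe_mask = rng.random((config.n_treatment_genes, n_p)) < propensity[None, :]
    treatment_effects = np.zeros((n_g, n_p))
    treatment_effects[trt_idx, :] = trt_magnitude[:, None] * stripe_mask

    gf_magnitude = rng.normal(0.0, config.treatment_effect_sd, size=config.n_gf_genes)
    gf_effects = np.zeros(n_g)
    gf_effects[gf_idx] = gf_magnitude

    causal_sub = np.sort(
        rng.choice(config.n_treatment_genes, size=config.n_causal_genes, replace=False)
    )
    causal_idx = trt_idx[causal_sub]
    # each causal gene's regulation pushes the response the same way:
    # stronger molecular response means stronger proliferation inhibition
    signs = np.sign(trt_magnitude[causal_sub])
    signs[signs == 0] = 1.0
    weights = signs * config.causal_effect_scale
    if config.null_link:
        weights = np.zeros(config.n_causal_genes)

    pat_of_sample = np.array([patients.index(p) for p in pat_col])
    trt_flag = np.array(trt_col, dtype=float)
    gf_flag = np.array(gf_col, dtype=float)

    values = (
        baseline[:, None]
        + patient_offsets[:, pat_of_sample]
        + treatment_effects[:, pat_of_sample] * trt_flag[None, :]
        + gf_effects[:, None] * gf_flag[None, :]
        + rng.normal(0.0, config.residual_sd, size=(n_g, len(samples)))
    )
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)

    patient_effects = pd.DataFrame(
        baseline[:, None] + patient_offsets,
        index=pd.Index(genes, name="gene"),
        columns=patients,
    )

    # response link: treated+GF profile of the causal genes, patient-centered
    treated_gf_cols = [_sample_id(p, True, True) for p in patients]
    centered = (
        matrix.loc[[genes[i] for i in causal_idx], treated_gf_cols].to_numpy()
        - patient_effects.iloc[causal_idx].to_numpy()
    )
    linear = weights @ centered
    prolif_noise = rng.normal(0.0, config.response_noise_sd, size=n_p)
    proliferation = np.clip(1.0 - linear + prolif_noise, *RESPONSE_CLIP)

    # migration: same marginal family as proliferation but driven by an
    # independent responder draw, so it carries no expression link
    if 0.0 < f < 1.0:
        propensity_mig = rng.beta(f * kappa, (1.0 - f) * kappa, size=n_p)
    else:
        propensity_mig = np.full(n_p, f)
    mask_mig = rng.random((config.n_causal_genes, n_p)) < propensity_mig[None, :]
    linear_mig = (np.abs(weights) * np.abs(trt_magnitude[causal_sub])) @ mask_mig
    mig_noise = rng.normal(0.0, config.response_noise_sd, size=n_p)
    migration = np.clip(1.0 - linear_mig + mig_noise, *RESPONSE_CLIP)

    response = pd.DataFrame(
        {"proliferation": proliferation, "migration": migration},
        index=pd.Index(patients, name="patient"),
    )

    truth = CohortTruth(
        treatment_gene_ids=[genes[i] for i in trt_idx],
        gf_gene_ids=[genes[i] for i in gf_idx],
        causal_gene_ids=[genes[i] for i in causal_idx],
        causal_weights={genes[i]: float(w) for i, w in zip(causal_idx, weights)},
        patient_effects=patient_effects,
        treatment_effects=pd.DataFrame(
            treatment_effects, index=pd.Index(genes, name="gene"), columns=patients
        ),
    )
    return matrix, design, response, truth


GRADING_CONDITIONS = ("GF", "Sunitinib", "Sunitinib+GF")


def generate_grading_table(
    seed: int,
    n_lines: int,
    decrease_probs: dict[str, float],
    unevaluable_prob: float = 0.0,
    conditions: tuple[str, ...] = GRADING_CONDITIONS,
) -> pd.DataFrame:
    """Draw a synthetic semi-quantitative phospho-grading table.

    One ordinal grade from ``{++, +, 0, -, --, u.e., n.S.}`` is drawn per
    protein x condition x line.  A cell is unevaluable (``u.e.`` or ``n.S.``,
    equiprobable) with probability ``unevaluable_prob``; otherwise it is a
    decrease (``-`` or ``--``, equiprobable) with the protein's probability
    from ``decrease_probs``, and else uniform over ``{0, +, ++}``.
    """
    if n_lines < 0:
        raise ConfigError("n_lines must be non-negative")
    for prot, p in decrease_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"decrease probability for {prot} outside [0, 1]: {p!r}")
    if not 0.0 <= unevaluable_prob <= 1.0:
        raise ConfigError(f"unevaluable_prob outside [0, 1]: {unevaluable_prob!r}")

    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_lines)))
    rows = []
    for protein in decrease_probs:
        for condition in conditions:
            for i in range(n_lines):
                line = f"L{i + 1:0{width}d}"
                u = rng.random()
                if u < unevaluable_prob:
                    grade = "u.e." if rng.random() < 0.5 else "n.S."
                elif rng.random() < decrease_probs[protein]:
                    grade = "-" if rng.random() < 0.5 else "--"
                else:
                    grade = str(rng.choice(["0", "+", "++"]))
                rows.append((protein, condition, line, grade))
    return pd.DataFrame(rows, columns=["protein", "condition", "line", "grade"])
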