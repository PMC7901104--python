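"""Synthetic fixtures with known generating structure.

Three generators emulate the pipeline's real inputs without any downloads:

* :func:`simulate_training_set` — annotated variants whose proxy labels are
  drawn from a logistic model with known sparse weights, plus splice
  submodel score blocks with class-dependent structure so the masking /
  swap / delta / imputation rules are all exercised. Fitting on this data
  and comparing recovered coefficients to the generating weights is the
  repository's core regression test.
* :func:`simulate_mfass_like` — reporter-assay-style records where a latent
  splice-disruption effect drives both the percent-spliced-in change and the
  splice submodel scores, so score-based classifiers beat the prevalence
  baseline; sdv prevalence defaults to the ~3.8% of the real assay.
* :func:`simulate_frequencies` — heavy-tailed population allele frequencies
  with optional negative coupling between deleteriousness score and
  frequency, reproducing singleton-enrichment behaviour qualitatively.

All draws flow from one ``numpy`` generator seeded by the config, so every
output is reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _sigmoid

from .core_model import (
    MISSING,
    PROXY_BENIGN,
    PROXY_DELETERIOUS,
    AnnotatedVariant,
    FeatureSchema,
    Variant,
    compact_schema,
)
from .design_matrix import build_matrix, enumerate_aa_exchanges
from .scorer import TrainingSet
from .splice_prep import (
    MMSPLICE_KEYS,
    SPLICEAI_KEYS,
    PsiMeasurement,
    SpliceFeatureBlock,
    classify_sdv,
    impute_splice,
    mask_spliceai,
    mmsplice_delta,
    swap_then_mask_derived,
)
from .evaluation import FrequencyRecord

__all__ = [
    "SimulationConfig",
    "simulate_training_set",
    "simulate_annotated_variants",
    "simulate_mfass_like",
    "simulate_frequencies",
]

# Real-assay sdv prevalence: 1050 disrupting out of 27,733 tested variants.
MFASS_SDV_PREVALENCE = 1050 / 27733


@dataclass
class SimulationConfig:
    """Parameters of the synthetic generators.

    ``true_weights`` maps numeric annotation names to generating logistic
    coefficients (annotations not named get weight 0); labels are Bernoulli
    with probability sigmoid(intercept + x . w). ``splice_effect_fraction``
    is the share of variants placed at/near splice sites whose splice blocks
    carry class signal. ``missingness_rates`` maps indicator-group names to
    MCAR missingness probabilities.
    """

    n_variants: int = 1000
    seed: int = 0
    schema: FeatureSchema | None = None
    true_weights: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    deterministic_labels: bool = False
    splice_effect_fraction: float = 0.3
    splice_signal: float = 0.6
    annotation_means: dict[str, float] = field(default_factory=dict)
    annotation_sds: dict[str, float] = field(default_factory=dict)
    missingness_rates: dict[str, float] = field(default_factory=dict)
    # reporter-assay generator
    sdv_prevalence: float = MFASS_SDV_PREVALENCE
    psi_noise_sd: float = 0.05
    score_noise_sd: float = 0.15
    # allele-frequency generator
    n_chromosomes: int = 31416
    frequency_coupling: float = 0.0
    log_ac_mean: float = 0.0
    log_ac_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        for name, rate in self.missingness_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
        if not (0.0 <= self.splice_effect_fraction <= 1.0):
            raise ValueError("splice_effect_fraction outside [0, 1]")
        if not (0.0 < self.sdv_prevalence < 1.0):
            raise ValueError("sdv_prevalence must be in (0, 1)")
        if self.deterministic_labels and not any(
            w != 0 for w in self.true_weights.values()
        ):
            raise ValueError(
                "deterministic labels require at least one non-zero weight"
            )

    def resolved_schema(self) -> FeatureSchema:
        return self.schema if self.schema is not None else compact_schema()




def _random_variant(rng, i: int) -> Variant:
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    alt = rng.choice([b for b in bases if b != ref])
    return Variant(
        chrom=str(rng.integers(1, 23)),
        pos=int(rng.integers(1, 10_000_000)),
        ref=ref,
        alt=str(alt),
        gene_id=f"G{i % 50:03d}",
    )


def _splice_block(rng, label: int, near_splice: bool, signal: float,
                  annotated_side: str | None) -> SpliceFeatureBlock:
    """Raw (pre-masking) splice scores with class-dependent asymmetry.

    Proxy-deleterious variants near splice sites get elevated loss scores at
    annotated sites (which masking keeps) and elevated gains elsewhere;
    proxy-benign blocks are emitted in reversed-allele orientation (gain and
    loss exchanged), matching how derived alleles are scored upstream, so the
    swap-then-mask recipe restores their signal orientation.
    """
    base = rng.beta(1.0, 30.0, size=4)  # mostly-small background scores
    spliceai = dict(zip(SPLICEAI_KEYS, base))
    mm_ref = {k: rng.normal(0.0, 0.3) for k in MMSPLICE_KEYS}
    mm_alt = {k: mm_ref[k] + rng.normal(0.0, 0.05) for k in MMSPLICE_KEYS}

    if near_splice and label == 1:
        strength = signal * rng.uniform(0.5, 1.0)
        if annotated_side is not None:
            spliceai[f"{annotated_side}_loss"] = min(1.0, strength)
        else:
            side = "acceptor" if rng.random() < 0.5 else "donor"
            spliceai[f"{side}_gain"] = min(1.0, strength)
        drop = signal * rng.uniform(0.5, 1.5)
        for k in MMSPLICE_KEYS:
            mm_alt[k] = mm_ref[k] - drop * rng.uniform(0.3, 1.0)

    block = SpliceFeatureBlock(
        spliceai=spliceai, mmsplice_ref=mm_ref, mmsplice_alt=mm_alt,
        at_annotated_acceptor=annotated_side == "acceptor",
        at_annotated_donor=annotated_side == "donor",
    )
    if label == 0:
        # emit in reversed-allele orientation: swap gain/loss, and the
        # ref/alt roles of the MMSplice scores
        for side in ("acceptor", "donor"):
            g, l = f"{side}_gain", f"{side}_loss"
            block.spliceai[g], block.spliceai[l] = block.spliceai[l], block.spliceai[g]
        block.mmsplice_ref, block.mmsplice_alt = block.mmsplice_alt, block.mmsplice_ref
    return block


def simulate_annotated_variants(
    config: SimulationConfig,
) -> tuple[list[AnnotatedVariant], np.ndarray]:
    """Generate annotated variants and their 0/1 proxy labels.

    Continuous annotations are Gaussian (per-name mean/sd overridable);
    splice submodel features are produced as raw score blocks, preprocessed
    according to the drawn class (mask for proxy-deleterious, swap-then-mask
    for proxy-benign, class-oriented clipped MMSplice deltas), imputed, and
    written into the numeric annotations. Missingness is applied MCAR per
    indicator group after label generation.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.resolved_schema()
    splice_names = [n for n in schema.numeric_annotation_names
                    if n.startswith(("SpliceAI_", "MMSplice_"))]
    plain_names = [n for n in schema.numeric_annotation_names
                   if n not in splice_names]

    variants: list[AnnotatedVariant] = []
    labels = np.empty(config.n_variants, dtype=int)
    for i in range(config.n_variants):
        variant = _random_variant(rng, i)
        consequence = schema.consequence_categories[
            rng.integers(len(schema.consequence_categories))
        ]
        numeric = {}
        for name in plain_names:
            mu = config.annotation_means.get(name, 0.0)
            sd = config.annotation_sds.get(name, 1.0)
            numeric[name] = rng.normal(mu, sd)

        eta = config.intercept + sum(
            w * numeric.get(name, 0.0)
            for name, w in config.true_weights.items()
        )
        if config.deterministic_labels:
            label = int(eta > 0)
        else:
            label = int(rng.random() < _sigmoid(eta))
        labels[i] = label

        near_splice = rng.random() < config.splice_effect_fraction
        annotated_side = None
        if near_splice and rng.random() < 0.5:
            annotated_side = "acceptor" if rng.random() < 0.5 else "donor"
        block = _splice_block(
            rng, label, near_splice, config.splice_signal, annotated_side
        )
        class_label = PROXY_DELETERIOUS if label == 1 else PROXY_BENIGN
        if class_label == PROXY_BENIGN:
            prepped = swap_then_mask_derived(block)
        else:
            prepped = mask_spliceai(block)
        deltas = mmsplice_delta(prepped, class_label)
        splice_features, _ = impute_splice(prepped, deltas)
        for name in splice_names:
            numeric[name] = splice_features[name]

        categorical = {}
        for name, levels in schema.categorical_annotations.items():
            if name == "Consequence":
                continue
            categorical[name] = levels[rng.integers(len(levels))]

        aa_exchange = None
        if consequence in schema.coding_consequences:
            exchanges = enumerate_aa_exchanges()
            aa_exchange = exchanges[rng.integers(len(exchanges))]

        av = AnnotatedVariant(
            variant=variant,
            consequence=consequence,
            numeric_annotations=numeric,
            categorical_annotations=categorical,
            aa_exchange=aa_exchange,
            class_label=class_label,
        )
        variants.append(av)

    # MCAR missingness per indicator group (drawn after labels so it is
    # uninformative)
    for av in variants:
        for indicator, rate in config.missingness_rates.items():
            if rng.random() < rate:
                group = schema.indicator_groups.get(indicator, (indicator,))
                for name in group:
                    if name == "aa_exchange":
                        av.aa_exchange = None
                    elif name in schema.categorical_annotations:
                        av.categorical_annotations[name] = MISSING
                    elif name in schema.numeric_annotation_names:
                        av.numeric_annotations[name] = MISSING
    return variants, labels


def simulate_training_set(config: SimulationConfig) -> TrainingSet:
    """Annotated variants expanded to a design matrix with proxy labels."""
    variants, labels = simulate_annotated_variants(config)
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "degenerate simulation: only one class drawn; adjust weights, "
            "intercept, or n_variants"
        )
    matrix = build_matrix(variants, config.resolved_schema())
    return TrainingSet(matrix=matrix, labels=labels)


def simulate_mfass_like(
    config: SimulationConfig,
) -> tuple[list[Variant], dict[str, np.ndarray], list[PsiMeasurement]]:
    """Reporter-assay-style psi pairs with score columns.

    A latent disruption effect drives the psi drop and, with noise, the
    splice scores, so ranking by score recovers the sdv labels above the
    prevalence baseline; as ``score_noise_sd`` grows the scores decouple
    from the labels and classifier performance falls to prevalence.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    is_disrupting = rng.random(n) < config.sdv_prevalence
    effect = np.where(
        is_disrupting,
        rng.uniform(0.6, 1.0, size=n),
        np.abs(rng.normal(0.0, 0.08, size=n)),
    )
    psi_ref = _sigmoid(rng.normal(2.0, 1.0, size=n))
    psi_alt = np.clip(
        psi_ref - effect + rng.normal(0.0, config.psi_noise_sd, size=n),
        0.0, 1.0,
    )

    spliceai_max = np.clip(
        _sigmoid(6.0 * (effect - 0.4) + rng.normal(0, 8 * config.score_noise_sd, n)),
        0.0, 1.0,
    )
    mmsplice = -3.0 * effect + rng.normal(0, 6 * config.score_noise_sd, n)
    scores = {
        "SpliceAI": spliceai_max,
        "MMSplice_delta_logit_psi": mmsplice,
        "psi_ref": psi_ref,
    }
    variants = [_random_variant(rng, i) for i in range(n)]
    measurements = [
        classify_sdv(float(psi_ref[i]), float(psi_alt[i])) for i in range(n)
    ]
    return variants, scores, measurements


def simulate_frequencies(
    config: SimulationConfig,
    scores: np.ndarray | None = None,
) -> tuple[list[FrequencyRecord], np.ndarray]:
    """Population frequency records with optional score coupling.

    Allele counts are log-normal (heavy-tailed, many singletons); a positive
    ``frequency_coupling`` pushes high-scoring (deleterious-like) variants
    toward lower allele counts, reproducing singleton enrichment at high
    score percentiles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    if scores is None:
        scores = rng.normal(0.0, 1.0, size=n)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != n:
        raise ValueError("scores length must equal n_variants")

    log_ac = rng.normal(
        config.log_ac_mean - config.frequency_coupling * scores,
        config.log_ac_sd,
    )
    ac = np.maximum(1, np.floor(np.exp(log_ac)).astype(int))
    ac = np.minimum(ac, config.n_chromosomes // 2)
    maf = ac / config.n_chromosomes
    records = [
        FrequencyRecord(
            variant=_random_variant(rng, i),
            maf=float(min(maf[i], 0.5)),
            ac=int(ac[i]),
        )
        for i in range(n)
    ]
    return records, scores
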