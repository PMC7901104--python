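"""Domain types shared by all pipeline stages.

The scoring framework follows the CADD (Combined Annotation Dependent
Depletion) design: variants carry a collection of opaque numeric and
categorical annotations plus a coarse consequence category, and a declarative
:class:`FeatureSchema` describes how those annotations expand into the model's
feature space — annotation features ``X``, ordered base-substitution pairs,
SNV-reachable amino-acid exchanges, Boolean missingness indicators ``W``, and
consequence x annotation interaction terms over a designated annotation set
``D``.

Missing annotation values are represented by the explicit :data:`MISSING`
sentinel, never by 0: imputation-to-zero plus a set indicator is part of the
model definition, so the distinction must survive I/O and preprocessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "MISSING",
    "is_missing",
    "Variant",
    "AnnotatedVariant",
    "FeatureSchema",
    "ModelWeights",
    "validate_schema",
    "default_schema",
    "NUCLEOTIDES",
    "AA_ALPHABET",
    "PROXY_BENIGN",
    "PROXY_DELETERIOUS",
    "UNLABELED",
    "MAX_INDEL_LENGTH",
]


class _MissingType:
    """Singleton sentinel for an undefined annotation value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


MISSING = _MissingType()


def is_missing(value: Any) -> bool:
    """True for the MISSING sentinel, None, empty string, or NaN."""
    if value is MISSING or value is None:
        return True
    if isinstance(value, str):
        return value == ""
    if isinstance(value, float):
        return math.isnan(value)
    return False


NUCLEOTIDES = ("A", "C", "G", "T")

# 20 amino acids plus the stop symbol, alphabetical with '*' last.
AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)

PROXY_BENIGN = "proxy-benign"
PROXY_DELETERIOUS = "proxy-deleterious"
UNLABELED = "unlabeled"
CLASS_LABELS = (PROXY_BENIGN, PROXY_DELETERIOUS, UNLABELED)

# InDels longer than this are rejected throughout the pipeline.
MAX_INDEL_LENGTH = 50


@dataclass(frozen=True)
class Variant:
    """A sequence variant in 1-based, forward-strand, VCF-style coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty allele strings")
        for allele in (self.ref, self.alt):
            if any(b not in NUCLEOTIDES for b in allele):
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")
        if self.indel_length > MAX_INDEL_LENGTH:
            raise ValueError(
                f"InDel of length {self.indel_length} exceeds the "
                f"{MAX_INDEL_LENGTH} bp limit"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass
class AnnotatedVariant:
    """A variant with its annotation values, consequence, and proxy label.

    ``numeric_annotations`` / ``categorical_annotations`` map annotation names
    (which must exist in the active schema) to values or :data:`MISSING`.
    ``aa_exchange`` is the ordered (ref_residue, alt_residue) pair and may be
    set only for coding consequences.
    """

    variant: Variant
    consequence: str
    numeric_annotations: dict[str, Any] = field(default_factory=dict)
    categorical_annotations: dict[str, Any] = field(default_factory=dict)
    aa_exchange: tuple[str, str] | None = None
    class_label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def ref_base_category(self) -> str | None:
        return self.variant.ref if self.variant.is_snv else None

    @property
    def alt_base_category(self) -> str | None:
        return self.variant.alt if self.variant.is_snv else None


@dataclass
class FeatureSchema:
    """Declarative description of the full feature space.

    Fields mirror the model's five coefficient groups: numeric and categorical
    annotations expand into the ``X`` block, ``indicator_names`` is the ordered
    Boolean missingness group ``W``, ``consequence_categories`` crossed with
    ``interaction_set`` (the annotation set ``D``) gives the interaction block.
    ``indicator_groups`` maps each ``W`` entry to the annotation names it
    covers (an indicator fires when the whole group is undefined);
    ``coding_consequences`` are the categories for which an amino-acid
    exchange may be present.
    """

    numeric_annotation_names: tuple[str, ...]
    categorical_annotations: dict[str, tuple[str, ...]]
    indicator_names: tuple[str, ...]
    consequence_categories: tuple[str, ...]
    interaction_set: tuple[str, ...]
    indicator_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    coding_consequences: tuple[str, ...] = ()
    base_categories: tuple[str, ...] = NUCLEOTIDES
    aa_alphabet: tuple[str, ...] = AA_ALPHABET

    @property
    def n_x_features(self) -> int:
        """Size of the X block: numerics plus one-hot categorical levels."""
        return len(self.numeric_annotation_names) + sum(
            len(levels) for levels in self.categorical_annotations.values()
        )

    @property
    def n_interactions(self) -> int:
        return len(self.consequence_categories) * len(self.interaction_set)

    def annotation_names(self) -> set[str]:
        return set(self.numeric_annotation_names) | set(self.categorical_annotations)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "numeric_annotation_names": list(self.numeric_annotation_names),
            "categorical_annotations": {
                k: list(v) for k, v in self.categorical_annotations.items()
            },
            "indicator_names": list(self.indicator_names),
            "consequence_categories": list(self.consequence_categories),
            "interaction_set": list(self.interaction_set),
            "indicator_groups": {k: list(v) for k, v in self.indicator_groups.items()},
            "coding_consequences": list(self.coding_consequences),
            "base_categories": list(self.base_categories),
            "aa_alphabet": list(self.aa_alphabet),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FeatureSchema":
        return cls(
            numeric_annotation_names=tuple(data["numeric_annotation_names"]),
            categorical_annotations={
                k: tuple(v) for k, v in data["categorical_annotations"].items()
            },
            indicator_names=tuple(data["indicator_names"]),
            consequence_categories=tuple(data["consequence_categories"]),
            interaction_set=tuple(data["interaction_set"]),
            indicator_groups={
                k: tuple(v) for k, v in data.get("indicator_groups", {}).items()
            },
            coding_consequences=tuple(data.get("coding_consequences", ())),
            base_categories=tuple(data.get("base_categories", NUCLEOTIDES)),
            aa_alphabet=tuple(data.get("aa_alphabet", AA_ALPHABET)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_schema(schema: FeatureSchema) -> list[str]:
    """Check all schema invariants; return human-readable violations.

    An empty list means the schema is valid. Violations are returned rather
    than raised so callers can report all problems at once.
    """
    violations: list[str] = []

    def check_unique(names: Sequence[str], label: str) -> None:
        seen = set()
        for name in names:
            if name in seen:
                violations.append(f"{label}: duplicated name {name!r}")
            seen.add(name)

    check_unique(schema.numeric_annotation_names, "numeric_annotation_names")
    check_unique(list(schema.categorical_annotations), "categorical_annotations")
    check_unique(schema.indicator_names, "indicator_names")
    check_unique(schema.consequence_categories, "consequence_categories")
    check_unique(schema.interaction_set, "interaction_set")

    overlap = set(schema.numeric_annotation_names) & set(schema.categorical_annotations)
    for name in sorted(overlap):
        violations.append(
            f"annotation {name!r} is both numeric and categorical"
        )

    for name, levels in schema.categorical_annotations.items():
        check_unique(levels, f"categorical_annotations[{name!r}] levels")
        if not levels:
            violations.append(f"categorical_annotations[{name!r}]: empty level list")

    allowed_d = set(schema.numeric_annotation_names)
    for name in schema.interaction_set:
        if name not in allowed_d:
            violations.append(
                f"interaction_set: {name!r} is not a known numeric annotation"
            )

    for indicator, group in schema.indicator_groups.items():
        if indicator not in schema.indicator_names:
            violations.append(
                f"indicator_groups: {indicator!r} not in indicator_names"
            )
        for name in group:
            if name not in allowed_d and name not in schema.categorical_annotations \
                    and name != "aa_exchange":
                violations.append(
                    f"indicator_groups[{indicator!r}]: unknown annotation {name!r}"
                )

    if "Consequence" in schema.categorical_annotations:
        if schema.categorical_annotations["Consequence"] != tuple(
            schema.consequence_categories
        ):
            violations.append(
                "categorical 'Consequence' levels must equal consequence_categories"
            )

    for cons in schema.coding_consequences:
        if cons not in schema.consequence_categories:
            violations.append(
                f"coding_consequences: {cons!r} not a consequence category"
            )

    if set(schema.base_categories) != set(NUCLEOTIDES):
        violations.append("base_categories must be the four nucleotides")
    if len(schema.aa_alphabet) != 21:
        violations.append("aa_alphabet must contain 20 amino acids plus stop")

    return violations


@dataclass
class ModelWeights:
    """Fitted coefficients of the five-term logistic model.

    beta0       intercept
    beta        over the X block (annotation features, one-hots expanded)
    gamma       over the 12 ordered base-substitution pairs
    delta       over the SNV-reachable amino-acid exchanges
    tau         over the missingness indicators W
    alpha       matrix (consequence category x interaction-set member)
    """

    beta0: float
    beta: "Any"  # np.ndarray, shape (|X|,)
    gamma: "Any"  # np.ndarray, shape (12,)
    delta: "Any"  # np.ndarray, shape (189,)
    tau: "Any"  # np.ndarray, shape (|W|,)
    alpha: "Any"  # np.ndarray, shape (|categories|, |D|)

    def n_coefficients(self) -> int:
        return (
            len(self.beta)
            + len(self.gamma)
            + len(self.delta)
            + len(self.tau)
            + self.alpha.size
        )

    def validate_against(self, schema: FeatureSchema) -> None:
        expected = {
            "beta": schema.n_x_features,
            "gamma": len(schema.base_categories) * (len(schema.base_categories) - 1),
            "tau": len(schema.indicator_names),
        }
        if len(self.beta) != expected["beta"]:
            raise ValueError(
                f"beta has {len(self.beta)} entries, schema implies {expected['beta']}"
            )
        if len(self.gamma) != expected["gamma"]:
            raise ValueError("gamma dimension does not match base categories")
        if len(self.tau) != expected["tau"]:
            raise ValueError("tau dimension does not match indicator list")
        if self.alpha.shape != (
            len(schema.consequence_categories),
            len(schema.interaction_set),
        ):
            raise ValueError("alpha shape does not match categories x interaction set")


# ---------------------------------------------------------------------------
# Default GRCh37-style schema
# ---------------------------------------------------------------------------

# The 37-member interaction set D: positional/conservation/mutation-density
# annotations plus the nine splice submodel features.
_D_NON_SPLICE = (
    "bStatistic", "cDNApos", "CDSpos", "Dst2Splice", "GerpN", "GerpS",
    "mamPhCons", "mamPhyloP", "minDistTSE", "minDistTSS", "priPhCons",
    "priPhyloP", "protPos", "relcDNApos", "relCDSpos", "relProtPos",
    "verPhCons", "verPhyloP", "Dist2Mutation", "freq100", "freq1000",
    "freq10000", "rare100", "rare1000", "rare10000", "sngl100", "sngl1000",
    "sngl10000",
)

SPLICEAI_FEATURES = (
    "SpliceAI_accgain", "SpliceAI_accloss", "SpliceAI_dongain",
    "SpliceAI_donloss",
)
MMSPLICE_FEATURES = (
    "MMSplice_acceptorIntron", "MMSplice_acceptor", "MMSplice_donorIntron",
    "MMSplice_donor", "MMSplice_exon",
)
SPLICE_FEATURES = SPLICEAI_FEATURES + MMSPLICE_FEATURES

DEFAULT_INTERACTION_SET = _D_NON_SPLICE + SPLICE_FEATURES

_OTHER_NUMERIC = (
    # substitution-effect and miRNA-target scores
    "targetScan", "mirSVR", "Grantham", "PolyPhenVal", "SIFTval",
    "dbscSNV_ada", "dbscSNV_rf",
    # sequence composition and motif context
    "Length", "GC", "CpG", "motifECount", "motifEScoreChng", "motifDist",
    "tOverlapMotifs",
    # DNA shape
    "dnaHelT", "dnaMGW", "dnaProT", "dnaRoll",
    # regulatory element overlap counts
    "RemapOverlapTF", "RemapOverlapCL",
    # constrained-element scores
    "GerpRS", "GerpRSpval",
    # expression / open chromatin / histone mark summaries
    "EncExp", "EncNucleo", "EncOCC", "EncOCCombPVal", "EncOCDNasePVal",
    "EncOCFairePVal", "EncOCpolIIPVal",
    "EncodeH3K4me1_sum", "EncodeH3K4me1_max",
    "EncodeH3K4me2_sum", "EncodeH3K4me2_max",
    "EncodeH3K4me3_sum", "EncodeH3K4me3_max",
    "EncodeH3K9ac_sum", "EncodeH3K9ac_max",
    "EncodeH3K9me3_sum", "EncodeH3K9me3_max",
    "EncodeH3K27ac_sum", "EncodeH3K27ac_max",
    "EncodeH3K27me3_sum", "EncodeH3K27me3_max",
    "EncodeH3K36me3_sum", "EncodeH3K36me3_max",
    "EncodeH4K20me1_sum", "EncodeH4K20me1_max",
    "EncodeH2AFZ_sum", "EncodeH2AFZ_max",
    "EncodeDNase_sum", "EncodeDNase_max",
    "EncodetotalRNA_sum", "EncodetotalRNA_max",
)

DEFAULT_NUMERIC_ANNOTATIONS = _D_NON_SPLICE + SPLICE_FEATURES + _OTHER_NUMERIC

DEFAULT_CONSEQUENCE_CATEGORIES = (
    "stop-gained", "stop-lost", "missense", "synonymous", "canonical-splice",
    "splice-site", "intronic", "5utr", "3utr", "upstream", "downstream",
    "regulatory", "noncoding-change", "intergenic", "frameshift", "inframe",
)

# 12 categorical annotations contributing 132 one-hot columns: the variant
# consequence (16 levels, always defined) plus 11 opaque categoricals whose
# level cardinalities (6 x 11 + 5 x 10 = 116) are a convention of this
# implementation — only the totals are fixed by the model definition.
_CATEGORICAL_CARDINALITIES = {
    "chromHMM": 11, "Segway": 11, "Domain": 11, "Dst2SplType": 11,
    "SIFTcat": 11, "PolyPhenCat": 11,
    "EnsembleRegulatoryFeature": 10, "AnnoType": 10, "motifEName": 10,
    "oAAclass": 10, "DnaseClus": 10,
}

DEFAULT_CATEGORICAL_ANNOTATIONS = {
    "Consequence": DEFAULT_CONSEQUENCE_CATEGORIES,
    **{
        name: tuple(f"{name}_lvl{i:02d}" for i in range(1, n + 1))
        for name, n in _CATEGORICAL_CARDINALITIES.items()
    },
}

DEFAULT_INDICATOR_NAMES = (
    "cDNApos", "CDSpos", "protPos", "aminoacid_substitution", "targetScan",
    "mirSVR", "Grantham", "PolyPhenVal", "SIFTval", "Dist2Mutation",
    "chromHMM", "dbscSNV_ada", "dbscSNV_rf", "SpliceAI",
)

DEFAULT_INDICATOR_GROUPS = {
    "cDNApos": ("cDNApos", "relcDNApos"),
    "CDSpos": ("CDSpos", "relCDSpos"),
    "protPos": ("protPos", "relProtPos"),
    "aminoacid_substitution": ("aa_exchange",),
    "targetScan": ("targetScan",),
    "mirSVR": ("mirSVR",),
    "Grantham": ("Grantham",),
    "PolyPhenVal": ("PolyPhenVal", "PolyPhenCat"),
    "SIFTval": ("SIFTval", "SIFTcat"),
    "Dist2Mutation": ("Dist2Mutation",),
    "chromHMM": ("chromHMM",),
    "dbscSNV_ada": ("dbscSNV_ada",),
    "dbscSNV_rf": ("dbscSNV_rf",),
    "SpliceAI": SPLICEAI_FEATURES,
}

DEFAULT_CODING_CONSEQUENCES = (
    "stop-gained", "stop-lost", "missense", "synonymous",
)


def default_schema() -> FeatureSchema:
    """The shipped GRCh37-style schema: 222 X features, 14 indicators,
    16 consequence categories, and the 37-member interaction set."""
    return FeatureSchema(
        numeric_annotation_names=DEFAULT_NUMERIC_ANNOTATIONS,
        categorical_annotations=dict(DEFAULT_CATEGORICAL_ANNOTATIONS),
        indicator_names=DEFAULT_INDICATOR_NAMES,
        consequence_categories=DEFAULT_CONSEQUENCE_CATEGORIES,
        interaction_set=DEFAULT_INTERACTION_SET,
        indicator_groups=dict(DEFAULT_INDICATOR_GROUPS),
        coding_consequences=DEFAULT_CODING_CONSEQUENCES,
    )


def compact_schema(
    n_numeric: int = 24,
    n_categories: int = 4,
    interaction_size: int = 5,
) -> FeatureSchema:
    """A small schema for simulations and examples.

    Keeps the nine splice submodel features plus the first few default
    numeric annotations (``n_numeric`` total; the interaction set is drawn
    from the non-splice ones), one toy categorical column besides the
    consequence, and a reduced consequence list.
    """
    if n_numeric <= len(SPLICE_FEATURES):
        raise ValueError("n_numeric must exceed the 9 splice features")
    numerics = (
        _D_NON_SPLICE[: n_numeric - len(SPLICE_FEATURES)] + SPLICE_FEATURES
    )
    consequences = DEFAULT_CONSEQUENCE_CATEGORIES[:n_categories]
    return FeatureSchema(
        numeric_annotation_names=numerics,
        categorical_annotations={
            "Consequence": consequences,
            "chromHMM": ("chromHMM_lvl01", "chromHMM_lvl02", "chromHMM_lvl03"),
        },
        indicator_names=("cDNApos", "chromHMM"),
        consequence_categories=consequences,
        interaction_set=numerics[:interaction_size],
        indicator_groups={
            "cDNApos": ("cDNApos",),
            "chromHMM": ("chromHMM",),
        },
        coding_consequences=tuple(
            c for c in DEFAULT_CODING_CONSEQUENCES if c in consequences
        ),
    )


def copy_schema(schema: FeatureSchema, **changes) -> FeatureSchema:
    return replace(schema, **changes)
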