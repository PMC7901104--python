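"""Preprocessing of SpliceAI and MMSplice submodel scores.

SpliceAI emits four per-variant probabilities (acceptor/donor x gain/loss);
MMSplice emits reference- and alternative-allele scores for five submodels
(acceptor, acceptor intron, exon, donor, donor intron). Before entering the
model these are:

* masked — a predicted splice *gain* at an already annotated splice site, or a
  predicted *loss* away from any annotated site, carries no class signal and
  is set to 0 (donor and acceptor handled independently);
* swapped for derived-allele (proxy-benign) variants, which are scored with
  ref/alt reversed: gain and loss are exchanged within donor and within
  acceptor, then masking is applied after the swap;
* differenced for MMSplice — alt minus ref for the proxy-deleterious class
  and plain scoring, ref minus alt for the proxy-benign class — and clipped
  so positive differences become 0;
* imputed — any variant without splice scores gets all-zero features and the
  SpliceAI missingness indicator set.

The module also builds the standalone combined splice scores used for
benchmarking (max over SpliceAI submodels; MMAI and MMAIpsi linear
combinations of SD-normalised scores) and classifies percent-spliced-in
measurements into splice-disrupting (sdv) vs non-disrupting labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import (
    MISSING,
    PROXY_BENIGN,
    is_missing,
)

__all__ = [
    "SPLICEAI_KEYS",
    "MMSPLICE_KEYS",
    "SpliceFeatureBlock",
    "PsiMeasurement",
    "SpliceSiteIndex",
    "mask_spliceai",
    "swap_then_mask_derived",
    "mmsplice_delta",
    "impute_splice",
    "collapse_max",
    "combine_mmai",
    "classify_sdv",
    "classify_sdv_two_sided",
    "MFASS_SD_MMSPLICE",
    "MFASS_SD_SPLICEAI",
    "MFASS_SD_PSI",
]

SPLICEAI_KEYS = ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss")
MMSPLICE_KEYS = ("acceptor", "acceptor_intron", "exon", "donor", "donor_intron")

# Score standard deviations across the MFASS variant set, used to give the
# combined MMAI / MMAIpsi scores equal component weight.
MFASS_SD_MMSPLICE = 0.5291
MFASS_SD_SPLICEAI = 0.1206
MFASS_SD_PSI = 0.0622


@dataclass
class SpliceFeatureBlock:
    """Splice submodel scores for one variant, before or after preprocessing.

    ``spliceai`` values are probabilities in [0, 1] (or MISSING); the
    ``mmsplice_ref`` / ``mmsplice_alt`` maps hold raw submodel scores.
    ``at_annotated_acceptor`` / ``at_annotated_donor`` say whether the variant
    falls on an annotated acceptor/donor site, which drives masking.
    """

    spliceai: dict = field(default_factory=dict)
    mmsplice_ref: dict = field(default_factory=dict)
    mmsplice_alt: dict = field(default_factory=dict)
    at_annotated_acceptor: bool = False
    at_annotated_donor: bool = False
    gene_id: str | None = None

    def __post_init__(self) -> None:
        for key in SPLICEAI_KEYS:
            self.spliceai.setdefault(key, MISSING)
        for key in MMSPLICE_KEYS:
            self.mmsplice_ref.setdefault(key, MISSING)
            self.mmsplice_alt.setdefault(key, MISSING)
        for key, value in self.spliceai.items():
            if key not in SPLICEAI_KEYS:
                raise ValueError(f"unknown SpliceAI submodel {key!r}")
            if not is_missing(value) and not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"SpliceAI {key} score {value} outside [0, 1]"
                )

    def copy(self) -> "SpliceFeatureBlock":
        return replace(
            self,
            spliceai=dict(self.spliceai),
            mmsplice_ref=dict(self.mmsplice_ref),
            mmsplice_alt=dict(self.mmsplice_alt),
        )

    def spliceai_missing(self) -> bool:
        return all(is_missing(self.spliceai[k]) for k in SPLICEAI_KEYS)


@dataclass(frozen=True)
class PsiMeasurement:
    """A percent-spliced-in pair and its derived splice-disruption label."""

    psi_ref: float
    psi_alt: float
    delta_psi: float
    sdv: bool


class SpliceSiteIndex:
    """Annotated donor/acceptor positions, queried by exact position match.

    Built from a BED-like table with columns chrom, position (1-based),
    type (``donor``/``acceptor``), gene_id, strand.
    """

    def __init__(self, records: Iterable[tuple[str, int, str, str | None]] = ()):
        self._sites: dict[str, set[tuple[str, int]]] = {
            "donor": set(),
            "acceptor": set(),
        }
        for chrom, pos, site_type, _gene in records:
            if site_type not in self._sites:
                raise ValueError(f"site type must be donor/acceptor, got {site_type!r}")
            self._sites[site_type].add((str(chrom), int(pos)))

    @classmethod
    def from_tsv(cls, path) -> "SpliceSiteIndex":
        df = pd.read_csv(
            path, sep="\t",
            names=["chrom", "position", "type", "gene_id", "strand"],
            comment="#", dtype={"chrom": str},
        )
        return cls(
            (row.chrom, row.position, row.type, row.gene_id)
            for row in df.itertuples()
        )

    def is_annotated(self, chrom: str, pos: int, site_type: str) -> bool:
        return (str(chrom), int(pos)) in self._sites[site_type]

    def annotate_block(
        self, block: SpliceFeatureBlock, chrom: str, pos: int
    ) -> SpliceFeatureBlock:
        out = block.copy()
        out.at_annotated_acceptor = self.is_annotated(chrom, pos, "acceptor")
        out.at_annotated_donor = self.is_annotated(chrom, pos, "donor")
        return out


def _mask_pair(block: SpliceFeatureBlock, side: str, annotated: bool) -> None:
    gain_key, loss_key = f"{side}_gain", f"{side}_loss"
    if annotated:
        if not is_missing(block.spliceai[gain_key]):
            block.spliceai[gain_key] = 0.0
    else:
        if not is_missing(block.spliceai[loss_key]):
            block.spliceai[loss_key] = 0.0


def mask_spliceai(block: SpliceFeatureBlock) -> SpliceFeatureBlock:
    """Zero splice-gain predictions at annotated sites and splice-loss
    predictions away from annotated sites, per side (donor/acceptor).

    A gain where a site already exists, or a loss where none exists, is
    uninformative noise; masking it improves the signal-to-noise ratio of the
    features. MISSING values pass through untouched (imputation is separate).
    """
    out = block.copy()
    _mask_pair(out, "acceptor", out.at_annotated_acceptor)
    _mask_pair(out, "donor", out.at_annotated_donor)
    return out


def swap_then_mask_derived(block: SpliceFeatureBlock) -> SpliceFeatureBlock:
    """Preprocess SpliceAI scores of a derived-allele (proxy-benign) variant.

    Such variants are scored with reference and alternative alleles reversed
    (the scoring model requires ref to match the genome), so a predicted gain
    is really a loss and vice versa: gain/loss are swapped within donor and
    within acceptor, and masking is applied after the swap.
    """
    out = block.copy()
    for side in ("acceptor", "donor"):
        gain_key, loss_key = f"{side}_gain", f"{side}_loss"
        out.spliceai[gain_key], out.spliceai[loss_key] = (
            out.spliceai[loss_key], out.spliceai[gain_key],
        )
    return mask_spliceai(out)


def mmsplice_delta(
    block: SpliceFeatureBlock, class_label: str
) -> dict[str, float]:
    """Class-oriented, clipped MMSplice score differences per submodel.

    alt - ref for the proxy-deleterious class and plain scoring applications;
    ref - alt for proxy-benign variants (scored with alleles reversed).
    Positive differences are set to 0, so the returned features are <= 0.
    MISSING ref or alt propagates as MISSING.
    """
    deltas: dict[str, float] = {}
    for key in MMSPLICE_KEYS:
        ref, alt = block.mmsplice_ref[key], block.mmsplice_alt[key]
        if is_missing(ref) or is_missing(alt):
            deltas[key] = MISSING
            continue
        d = (ref - alt) if class_label == PROXY_BENIGN else (alt - ref)
        deltas[key] = min(d, 0.0)
    return deltas


def impute_splice(
    block: SpliceFeatureBlock | None,
    mmsplice_deltas: Mapping[str, float] | None = None,
) -> tuple[dict[str, float], int]:
    """Replace every MISSING splice feature by 0.

    Returns the flat feature map (four SpliceAI + five MMSplice-delta values,
    keyed by the schema feature names) and the SpliceAI missingness indicator
    (1 when no SpliceAI score was available at all, else 0). ``block=None``
    means the variant was not annotated by either model: everything imputes
    to 0 with the indicator set.
    """
    features: dict[str, float] = {}
    if block is None:
        indicator = 1
        for key in SPLICEAI_KEYS:
            features[_spliceai_feature_name(key)] = 0.0
        for key in MMSPLICE_KEYS:
            features[_mmsplice_feature_name(key)] = 0.0
        return features, indicator

    indicator = 1 if block.spliceai_missing() else 0
    for key in SPLICEAI_KEYS:
        value = block.spliceai[key]
        features[_spliceai_feature_name(key)] = 0.0 if is_missing(value) else float(value)
    deltas = mmsplice_deltas if mmsplice_deltas is not None else {
        k: MISSING for k in MMSPLICE_KEYS
    }
    for key in MMSPLICE_KEYS:
        value = deltas.get(key, MISSING)
        features[_mmsplice_feature_name(key)] = 0.0 if is_missing(value) else float(value)
    return features, indicator


def _spliceai_feature_name(key: str) -> str:
    return {
        "acceptor_gain": "SpliceAI_accgain",
        "acceptor_loss": "SpliceAI_accloss",
        "donor_gain": "SpliceAI_dongain",
        "donor_loss": "SpliceAI_donloss",
    }[key]


def _mmsplice_feature_name(key: str) -> str:
    return {
        "acceptor": "MMSplice_acceptor",
        "acceptor_intron": "MMSplice_acceptorIntron",
        "exon": "MMSplice_exon",
        "donor": "MMSplice_donor",
        "donor_intron": "MMSplice_donorIntron",
    }[key]


def attach_blocks_by_gene(
    variants: Sequence,
    blocks: Mapping[tuple, SpliceFeatureBlock],
) -> dict[tuple, SpliceFeatureBlock | None]:
    """Match splice blocks to variants by (chrom, pos, ref, alt) and gene.

    A block is attached only when its gene_id matches the variant's gene_id
    (a block without gene_id matches any gene); unmatched blocks are dropped,
    leaving the variant to be imputed as unscored.
    """
    out: dict[tuple, SpliceFeatureBlock | None] = {}
    for v in variants:
        key = (v.chrom, v.pos, v.ref, v.alt)
        block = blocks.get(key)
        if block is not None and block.gene_id is not None \
                and v.gene_id is not None and block.gene_id != v.gene_id:
            block = None
        out[key] = block
    return out


def collapse_max(submodel_scores: Sequence[float]) -> float:
    """Combine submodel scores into one score by taking the maximum."""
    if len(submodel_scores) == 0:
        raise ValueError("no submodel scores to collapse")
    return max(submodel_scores)


def combine_mmai(
    mmsplice_delta_logit_psi: float,
    spliceai_max: float,
    sd_mm: float = MFASS_SD_MMSPLICE,
    sd_ai: float = MFASS_SD_SPLICEAI,
    psi: float | None = None,
    sd_psi: float | None = MFASS_SD_PSI,
) -> float:
    """Equal-weight linear combination of MMSplice and SpliceAI scores.

    Each component is divided by its standard deviation across the benchmark
    variant set and the normalised scores are added (MMAI). When ``psi`` is
    given, the SD-normalised reference-allele percent-spliced-in is added as
    a third component (MMAIpsi).
    """
    if sd_mm <= 0 or sd_ai <= 0:
        raise ValueError("standard deviations must be positive")
    total = mmsplice_delta_logit_psi / sd_mm + spliceai_max / sd_ai
    if psi is not None:
        if sd_psi is None or sd_psi <= 0:
            raise ValueError("sd_psi must be positive when psi is given")
        total += psi / sd_psi
    return total


def _check_psi(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} = {value} outside [0, 1]")


def classify_sdv(
    psi_ref: float, psi_alt: float, threshold: float = 0.5
) -> PsiMeasurement:
    """Label a psi pair as splice-disrupting when |psi_alt - psi_ref|
    strictly exceeds the threshold (default 0.5; 0.7/0.3/0.1 are the
    explored alternatives)."""
    _check_psi(psi_ref, "psi_ref")
    _check_psi(psi_alt, "psi_alt")
    delta = abs(psi_alt - psi_ref)
    return PsiMeasurement(psi_ref, psi_alt, delta, sdv=delta > threshold)


def classify_sdv_two_sided(
    psi_ref: float,
    psi_alt: float,
    sdv_threshold: float = 0.5,
    no_sdv_threshold: float = 0.1,
) -> PsiMeasurement | None:
    """Two-sided labelling: sdv when delta-psi > 0.5, no-sdv when < 0.1,
    intermediate measurements are excluded (returns None)."""
    _check_psi(psi_ref, "psi_ref")
    _check_psi(psi_alt, "psi_alt")
    delta = abs(psi_alt - psi_ref)
    if delta > sdv_threshold:
        return PsiMeasurement(psi_ref, psi_alt, delta, sdv=True)
    if delta < no_sdv_threshold:
        return PsiMeasurement(psi_ref, psi_alt, delta, sdv=False)
    return None
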