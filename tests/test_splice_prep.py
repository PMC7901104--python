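import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caddsplice.core_model import MISSING, PROXY_BENIGN, PROXY_DELETERIOUS
from caddsplice.splice_prep import (
    MFASS_SD_MMSPLICE,
    MFASS_SD_PSI,
    MFASS_SD_SPLICEAI,
    MMSPLICE_KEYS,
    SPLICEAI_KEYS,
    SpliceFeatureBlock,
    SpliceSiteIndex,
    classify_sdv,
    classify_sdv_two_sided,
    collapse_max,
    combine_mmai,
    impute_splice,
    mask_spliceai,
    mmsplice_delta,
    swap_then_mask_derived,
)


def make_block(ag=0.0, al=0.0, dg=0.0, dl=0.0, acc=False, don=False):
    return SpliceFeatureBlock(
        spliceai={
            "acceptor_gain": ag, "acceptor_loss": al,
            "donor_gain": dg, "donor_loss": dl,
        },
        at_annotated_acceptor=acc,
        at_annotated_donor=don,
    )


unit = st.floats(min_value=0.0, max_value=1.0)


class TestMasking:
    def test_gain_zeroed_at_annotated_donor(self):
        block = make_block(dg=0.8, dl=0.3, don=True)
        masked = mask_spliceai(block)
        assert masked.spliceai["donor_gain"] == 0.0
        assert masked.spliceai["donor_loss"] == 0.3

    def test_loss_zeroed_away_from_acceptor(self):
        block = make_block(ag=0.5, al=0.9, acc=False)
        masked = mask_spliceai(block)
        assert masked.spliceai["acceptor_gain"] == 0.5
        assert masked.spliceai["acceptor_loss"] == 0.0

    def test_zero_block_is_fixed_point(self):
        block = make_block()
        assert mask_spliceai(block).spliceai == block.spliceai

    def test_input_not_mutated(self):
        block = make_block(dg=0.8, don=True)
        mask_spliceai(block)
        assert block.spliceai["donor_gain"] == 0.8

    @given(ag=unit, al=unit, dg=unit, dl=unit,
           acc=st.booleans(), don=st.booleans())
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_bounded(self, ag, al, dg, dl, acc, don):
        block = make_block(ag, al, dg, dl, acc, don)
        once = mask_spliceai(block)
        twice = mask_spliceai(once)
        assert once.spliceai == twice.spliceai
        assert all(0.0 <= once.spliceai[k] <= 1.0 for k in SPLICEAI_KEYS)


class TestSwapThenMask:
    def test_derived_allele_recipe(self):
        # unannotated site: after swap gain=0.1/loss=0.7, mask zeroes loss
        block = make_block(dg=0.7, dl=0.1)
        out = swap_then_mask_derived(block)
        assert out.spliceai["donor_gain"] == 0.1
        assert out.spliceai["donor_loss"] == 0.0

    def test_symmetric_scores_at_annotated_site(self):
        block = make_block(dg=0.4, dl=0.4, don=True)
        out = swap_then_mask_derived(block)
        assert out.spliceai["donor_gain"] == 0.0
        assert out.spliceai["donor_loss"] == 0.4

    def test_all_zero(self):
        out = swap_then_mask_derived(make_block())
        assert all(out.spliceai[k] == 0.0 for k in SPLICEAI_KEYS)

    @given(ag=unit, al=unit, dg=unit, dl=unit)
    @settings(max_examples=50, derandomize=True)
    def test_double_swap_restores_before_masking(self, ag, al, dg, dl):
        block = make_block(ag, al, dg, dl)
        swapped = block.copy()
        for side in ("acceptor", "donor"):
            g, l = f"{side}_gain", f"{side}_loss"
            swapped.spliceai[g], swapped.spliceai[l] = (
                swapped.spliceai[l], swapped.spliceai[g])
        again = swapped.copy()
        for side in ("acceptor", "donor"):
            g, l = f"{side}_gain", f"{side}_loss"
            again.spliceai[g], again.spliceai[l] = (
                again.spliceai[l], again.spliceai[g])
        assert again.spliceai == block.spliceai


class TestMMSpliceDelta:
    @staticmethod
    def block_with(ref, alt):
        return SpliceFeatureBlock(
            mmsplice_ref={k: ref for k in MMSPLICE_KEYS},
            mmsplice_alt={k: alt for k in MMSPLICE_KEYS},
        )

    def test_deleterious_alt_minus_ref(self):
        deltas = mmsplice_delta(self.block_with(-1.0, -3.0), PROXY_DELETERIOUS)
        assert all(deltas[k] == -2.0 for k in MMSPLICE_KEYS)

    def test_benign_ref_minus_alt(self):
        deltas = mmsplice_delta(self.block_with(-3.0, -1.0), PROXY_BENIGN)
        assert all(deltas[k] == -2.0 for k in MMSPLICE_KEYS)

    @pytest.mark.parametrize("label", [PROXY_BENIGN, PROXY_DELETERIOUS, "unlabeled"])
    def test_positive_differences_clipped(self, label):
        ref, alt = (-1.0, -0.5) if label != PROXY_BENIGN else (-0.5, -1.0)
        deltas = mmsplice_delta(self.block_with(ref, alt), label)
        assert all(deltas[k] == 0.0 for k in MMSPLICE_KEYS)

    def test_missing_propagates(self):
        block = self.block_with(-1.0, -3.0)
        block.mmsplice_alt["exon"] = MISSING
        deltas = mmsplice_delta(block, PROXY_DELETERIOUS)
        assert deltas["exon"] is MISSING
        assert deltas["donor"] == -2.0

    @given(ref=st.floats(-5, 5), alt=st.floats(-5, 5))
    @settings(max_examples=100, derandomize=True)
    def test_always_nonpositive_and_antisymmetric(self, ref, alt):
        block = self.block_with(ref, alt)
        d_del = mmsplice_delta(block, PROXY_DELETERIOUS)
        d_ben = mmsplice_delta(block, PROXY_BENIGN)
        for k in MMSPLICE_KEYS:
            assert d_del[k] <= 0.0 and d_ben[k] <= 0.0
            # unclipped differences are negatives of each other, so at most
            # one class sees a non-zero (negative) feature
            assert d_del[k] == 0.0 or d_ben[k] == 0.0


class TestImputation:
    def test_fully_missing_block(self):
        features, indicator = impute_splice(None)
        assert indicator == 1
        assert set(features) == {
            "SpliceAI_accgain", "SpliceAI_accloss", "SpliceAI_dongain",
            "SpliceAI_donloss", "MMSplice_acceptor", "MMSplice_acceptorIntron",
            "MMSplice_exon", "MMSplice_donor", "MMSplice_donorIntron",
        }
        assert all(v == 0.0 for v in features.values())

    def test_fully_present_block(self):
        block = make_block(ag=0.1, al=0.2, dg=0.3, dl=0.4)
        deltas = {k: -0.5 for k in MMSPLICE_KEYS}
        features, indicator = impute_splice(block, deltas)
        assert indicator == 0
        assert features["SpliceAI_accgain"] == 0.1
        assert features["MMSplice_exon"] == -0.5

    def test_partial_missing_only_zeroes_missing(self):
        block = make_block(ag=0.7)
        block.spliceai["donor_loss"] = MISSING
        features, indicator = impute_splice(block, {k: MISSING for k in MMSPLICE_KEYS})
        assert indicator == 0
        assert features["SpliceAI_accgain"] == 0.7
        assert features["SpliceAI_donloss"] == 0.0
        assert features["MMSplice_donor"] == 0.0


class TestCombinedScores:
    def test_collapse_max(self):
        assert collapse_max([0.1, 0.9, 0.0, 0.3]) == 0.9
        assert collapse_max([0.5]) == 0.5
        assert collapse_max([0, 0, 0, 0]) == 0

    def test_collapse_empty_errors(self):
        with pytest.raises(ValueError):
            collapse_max([])

    def test_mmai_zero(self):
        assert combine_mmai(0.0, 0.0) == 0.0

    def test_mmai_forced_arithmetic(self):
        # one SD of each component gives exactly 1 + 1
        assert combine_mmai(MFASS_SD_MMSPLICE, MFASS_SD_SPLICEAI) == pytest.approx(2.0)

    def test_mmaipsi_forced_arithmetic(self):
        value = combine_mmai(
            MFASS_SD_MMSPLICE, MFASS_SD_SPLICEAI, psi=MFASS_SD_PSI
        )
        assert value == pytest.approx(3.0)

    def test_nonpositive_sd_errors(self):
        with pytest.raises(ValueError):
            combine_mmai(1.0, 1.0, sd_mm=0.0)
        with pytest.raises(ValueError):
            combine_mmai(1.0, 1.0, psi=0.5, sd_psi=-1.0)


class TestSdvClassification:
    def test_above_threshold(self):
        m = classify_sdv(0.9, 0.2)
        assert m.delta_psi == pytest.approx(0.7) and m.sdv

    def test_exactly_at_threshold_is_not_sdv(self):
        m = classify_sdv(0.6, 0.1)
        assert m.delta_psi == pytest.approx(0.5) and not m.sdv

    def test_no_change(self):
        m = classify_sdv(0.4, 0.4)
        assert m.delta_psi == 0.0 and not m.sdv

    @pytest.mark.parametrize("threshold", [0.7, 0.3, 0.1])
    def test_alternative_thresholds(self, threshold):
        assert classify_sdv(threshold + 0.05, 0.0, threshold).sdv
        # delta exactly at the threshold stays no-sdv (strict inequality)
        assert not classify_sdv(threshold, 0.0, threshold).sdv

    def test_psi_out_of_range_errors(self):
        with pytest.raises(ValueError):
            classify_sdv(1.2, 0.5)
        with pytest.raises(ValueError):
            classify_sdv(0.5, -0.1)

    def test_two_sided_variant(self):
        assert classify_sdv_two_sided(0.9, 0.2).sdv
        assert classify_sdv_two_sided(0.5, 0.45).sdv is False
        assert classify_sdv_two_sided(0.8, 0.5) is None  # intermediate

    @given(psi_ref=unit, delta=unit)
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_delta(self, psi_ref, delta):
        psi_alt = max(0.0, psi_ref - delta)
        smaller = classify_sdv(psi_ref, (psi_ref + psi_alt) / 2.0)
        larger = classify_sdv(psi_ref, psi_alt)
        # growing |delta psi| never flips sdv from True to False
        assert not (smaller.sdv and not larger.sdv)


class TestSpliceSiteIndex:
    def test_annotation_by_exact_position(self, tmp_path):
        table = tmp_path / "sites.tsv"
        table.write_text(
            "1\t1000\tdonor\tG001\t+\n"
            "1\t2000\tacceptor\tG001\t+\n"
        )
        index = SpliceSiteIndex.from_tsv(table)
        assert index.is_annotated("1", 1000, "donor")
        assert not index.is_annotated("1", 1001, "donor")
        block = index.annotate_block(make_block(), "1", 2000)
        assert block.at_annotated_acceptor and not block.at_annotated_donor
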