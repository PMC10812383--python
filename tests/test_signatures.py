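"""Trinucleotide channel normalization and signature context sets."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import polestrat as ps
from polestrat.signatures import (
    COMPLEMENT,
    SbsChannel,
    SignatureVector,
    all_channels,
)
from polestrat.variants import CodingChange, PoleVariant

BASES = "ACGT"
base = st.sampled_from(BASES)


def test_there_are_exactly_96_channels():
    chans = all_channels()
    assert len(chans) == 96 == len(set(chans))


class TestNormalization:
    @pytest.mark.parametrize(
        "ctx, expected",
        [
            (("T", "C", "A", "T"), "T[C>A]T"),
            (("C", "G", "A", "A"), "T[C>T]G"),
            (("T", "T", "G", "T"), "T[T>G]T"),
        ],
    )
    def test_examples(self, ctx, expected):
        five, ref, alt, three = ctx
        assert str(ps.normalize_to_pyrimidine(five, ref, alt, three)) == expected

    @given(five=base, ref=base, alt=base, three=base)
    def test_strand_involution(self, five, ref, alt, three):
        """A context and its reverse complement map to the same channel."""
        if ref == alt:
            return
        fwd = ps.normalize_to_pyrimidine(five, ref, alt, three)
        rev = ps.normalize_to_pyrimidine(
            COMPLEMENT[three], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[five]
        )
        assert fwd == rev
        # idempotent on already-normalized input
        assert ps.normalize_to_pyrimidine(
            fwd.five_prime, fwd.ref, fwd.alt, fwd.three_prime
        ) == fwd

    def test_non_base_rejected(self):
        with pytest.raises(ValueError):
            ps.normalize_to_pyrimidine("T", "N", "A", "T")


class TestChannelOf:
    def test_reads_flanks_from_transcript(self):
        cds = "AATCTAA"  # TCT centred at position 4 (1-based)
        ch = ps.channel_of(CodingChange(position=4, ref="C", alt="A"), cds)
        assert str(ch) == "T[C>A]T"

    def test_purine_reference_is_normalized(self):
        cds = "AAAGAAA"
        ch = ps.channel_of(CodingChange(position=4, ref="G", alt="A"), cds)
        assert ch.ref == "C"

    def test_missing_coding_change_gives_none(self):
        assert ps.channel_of(None, "ACGT") is None

    def test_reference_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="position 4"):
            ps.channel_of(CodingChange(position=4, ref="G", alt="A"), "AATCTAA")

    def test_sequence_edge_is_an_error(self):
        with pytest.raises(ValueError):
            ps.channel_of(CodingChange(position=1, ref="A", alt="G"), "AATCTAA")


def uniform_vector(sig_id="SBSX"):
    return SignatureVector(sig_id, {c: 1 / 96 for c in all_channels()})


class TestContextSets:
    def test_uniform_vector_includes_everything(self):
        cs = ps.build_context_set(uniform_vector())
        assert len(cs.included_channels) == 96
        assert cs.coverage == pytest.approx(1.0)

    def test_single_dominant_channel(self):
        chans = all_channels()
        probs = {c: 0.005 / 95 for c in chans}
        probs[chans[0]] = 0.995
        cs = ps.build_context_set(SignatureVector("SBSX", probs))
        assert cs.included_channels == {chans[0]}
        assert cs.coverage == pytest.approx(0.995)

    def test_bundled_pole_sets_cover_88_to_90_percent(self, signatures):
        for sig_id, vec in signatures.items():
            cs = ps.build_context_set(vec)
            assert 0.88 <= cs.coverage <= 0.90, sig_id
            assert cs.primary_channels <= cs.included_channels

    def test_threshold_outside_unit_interval_rejected(self, signatures):
        with pytest.raises(ValueError):
            ps.build_context_set(signatures["SBS10a"], inclusion_threshold=1.5)

    def test_brute_force_oracle_equivalence(self, signatures):
        """Independent channel-by-channel enumeration reproduces each set."""
        rng = np.random.default_rng(42)
        vectors = list(signatures.values())
        for _ in range(5):
            p = rng.dirichlet(np.full(96, 0.3))
            vectors.append(SignatureVector("SBSrand", dict(zip(all_channels(), p))))
        for vec in vectors:
            for thr in (0.005, 0.01, 0.05):
                cs = ps.build_context_set(vec, thr)
                expected = set()
                cov = 0.0
                for ch in all_channels():
                    if vec.probs[ch] > thr:
                        expected.add(ch)
                        cov += vec.probs[ch]
                assert cs.included_channels == expected
                assert cs.coverage == pytest.approx(cov)

    def test_coverage_monotone_decreasing_in_threshold(self, signatures):
        for vec in signatures.values():
            covs = [
                ps.build_context_set(vec, t).coverage
                for t in (0.002, 0.01, 0.02, 0.05, 0.2)
            ]
            assert covs == sorted(covs, reverse=True)


class TestClassification:
    def _variant(self, cds_pos, ref, alt):
        return PoleVariant(
            raw_label="A1V", kind="missense", position=1, ref_aa="A", alt_aa="V",
            coding_change=CodingChange(position=cds_pos, ref=ref, alt=alt),
        )

    def test_hotspot_call(self, context_sets, transcript):
        # find a TCG site on the bundled transcript and mutate C>T
        idx = transcript.find("TCG", 1)
        v = self._variant(idx + 2, "C", "T")
        call = ps.classify_variant_context(v, context_sets, transcript)
        assert "SBS10b" in call.hotspot_hit and call.in_pole_context

    def test_minor_channel_matches_both_sbs10a_and_10b(self, context_sets, transcript):
        idx = transcript.find("GCG", 1)
        v = self._variant(idx + 2, "C", "T")
        call = ps.classify_variant_context(v, context_sets, transcript)
        assert {"SBS10a", "SBS10b"} <= call.matching_signatures
        assert not call.hotspot_hit

    def test_non_snv_is_out_of_context(self, context_sets, transcript):
        v = ps.parse_hgvs_protein("S461fs")
        call = ps.classify_variant_context(v, context_sets, transcript)
        assert call.channel is None and not call.in_pole_context


class TestFraction:
    def _call(self, in_ctx, channel="T[C>A]T"):
        ch = SbsChannel.from_string(channel) if channel else None
        v = ps.parse_hgvs_protein("A100V" if channel else "S461fs")
        return ps.ContextCall(
            variant=v, channel=ch, in_pole_context=in_ctx,
            matching_signatures=frozenset({"SBS10a"} if in_ctx else set()),
            hotspot_hit=frozenset(),
        )

    def test_all_in_context(self):
        agg = ps.fraction_in_context([self._call(True)] * 4)
        assert agg.fraction == 1.0

    def test_none_in_context(self):
        agg = ps.fraction_in_context([self._call(False)] * 3)
        assert agg.fraction == 0.0

    def test_non_snvs_reported_separately(self):
        calls = [self._call(True), self._call(True), self._call(False, channel=None)]
        agg = ps.fraction_in_context(calls)
        assert agg.fraction == 1.0
        assert agg.n_non_snv == 1
        assert agg.fraction_all_variants == pytest.approx(2 / 3)

    def test_empty_denominator_flagged_undefined(self):
        agg = ps.fraction_in_context([self._call(False, channel=None)])
        assert agg.fraction is None
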