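import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribobind import rip_enrichment as rip
from conftest import make_models, make_sample


class TestTranscriptModel:
    def test_length_and_introns(self, two_exon_transcript):
        assert two_exon_transcript.length_nt == 200 + 400
        assert two_exon_transcript.introns == ((300, 500),)
        assert not two_exon_transcript.single_exon

    def test_rejects_overlapping_exons(self):
        with pytest.raises(ValueError, match="overlap"):
            rip.TranscriptModel("bad", rip.Biotype.mRNA, ((0, 100), (50, 200)))

    def test_rejects_unsorted_exons(self):
        with pytest.raises(ValueError, match="sorted"):
            rip.TranscriptModel("bad", rip.Biotype.mRNA, ((500, 600), (0, 100)))

    def test_biotype_aliases(self):
        m = rip.TranscriptModel("t", "protein_coding", ((0, 10),))
        assert m.biotype is rip.Biotype.mRNA
        m = rip.TranscriptModel("t", "lincRNA", ((0, 10),))
        assert m.biotype is rip.Biotype.lncRNA


class TestComputeFpkm:
    def test_direct_formula(self):
        models = make_models({"a": 1000})
        sample = make_sample({"a": 100}, total=10**6)
        assert rip.compute_fpkm(sample, models)["a"] == pytest.approx(100.0)

    def test_zero_count(self):
        models = make_models({"a": 1000})
        sample = make_sample({"a": 0}, total=10**6)
        assert rip.compute_fpkm(sample, models)["a"] == 0.0

    def test_hand_computed_value(self):
        # 463 fragments, 2643 nt, 3.1e7 mapped: frozen from manual arithmetic
        models = make_models({"a": 2643})
        sample = make_sample({"a": 463}, total=int(3.1e7))
        assert rip.compute_fpkm(sample, models)["a"] == pytest.approx(
            5.650958710165623, rel=1e-12
        )

    def test_missing_model_lists_ids(self):
        sample = make_sample({"a": 1, "zz": 2}, total=100)
        with pytest.raises(KeyError, match="zz"):
            rip.compute_fpkm(sample, make_models({"a": 100}))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            make_sample({"a": 1}, total=0)

    @given(
        count=st.integers(min_value=0, max_value=10**6),
        length=st.integers(min_value=1, max_value=10**5),
        total=st.integers(min_value=1, max_value=10**8),
        factor=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, count, length, total, factor):
        # FPKM unchanged when counts and library size scale together
        total = max(total, count)
        models = make_models({"a": length})
        f1 = rip.compute_fpkm(make_sample({"a": count}, total), models)["a"]
        f2 = rip.compute_fpkm(
            make_sample({"a": count * factor}, total * factor), models
        )["a"]
        assert f2 == pytest.approx(f1, rel=1e-12)


def _enrichment_from_fpkm(fpkm_rip, fpkm_ctrl, pc=0.1, **kw):
    """Build length-1000/total-1e6 samples so counts equal FPKM values."""
    models = make_models({"a": 1000})
    rips = [
        make_sample({"a": int(v)}, 10**6, rip.Role.RIP, rep=i + 1)
        for i, v in enumerate(fpkm_rip)
    ]
    ctrls = [
        make_sample({"a": int(v)}, 10**6, rip.Role.control, rep=i + 1)
        for i, v in enumerate(fpkm_ctrl)
    ]
    (rec,) = rip.call_enrichment(rips, ctrls, models, pseudocount=pc, **kw)
    return rec


class TestCallEnrichment:
    def test_clear_enrichment(self):
        rec = _enrichment_from_fpkm([4, 4, 4], [1, 1, 1])
        assert rec.n_positive_replicates == 3
        assert rec.stringent

    def test_identity_not_positive(self):
        rec = _enrichment_from_fpkm([3, 3, 3], [3, 3, 3])
        assert rec.n_positive_replicates == 0
        assert not rec.stringent

    def test_zero_control_finite_fold_change(self):
        # control absent in two replicates; pseudocount keeps the ratio finite
        rec = _enrichment_from_fpkm([5, 5, 5], [0, 0, 4])
        assert all(math.isfinite(f) for f in rec.fold_change)
        assert rec.fold_change[0] == pytest.approx(51.0)  # (5+0.1)/0.1, hand calc
        assert rec.stringent

    def test_stringent_needs_two_replicates(self):
        rec = _enrichment_from_fpkm([5, 1, 1], [1, 1, 1])
        assert rec.n_positive_replicates == 1
        assert not rec.stringent

    def test_min_fpkm_floor(self):
        rec = _enrichment_from_fpkm([4, 4, 4], [1, 1, 1], min_fpkm=10.0)
        assert rec.n_positive_replicates == 0

    def test_mismatched_replicates_fail(self):
        models = make_models({"a": 1000})
        rips = [make_sample({"a": 1}, 10**6, rip.Role.RIP, rep=1)]
        ctrls = [make_sample({"a": 1}, 10**6, rip.Role.control, rep=2)]
        with pytest.raises(ValueError, match="replicate"):
            rip.call_enrichment(rips, ctrls, models)

    @given(
        r1=st.floats(min_value=0, max_value=1000),
        r2=st.floats(min_value=0, max_value=1000),
        c=st.floats(min_value=0, max_value=1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_fold_change_monotone(self, r1, r2, c):
        pc = 0.1
        f1 = (r1 + pc) / (c + pc)
        f2 = (r2 + pc) / (c + pc)
        if r1 <= r2:
            assert f1 <= f2 + 1e-12
        else:
            assert f1 >= f2 - 1e-12


class TestReplicateOverlap:
    def _records(self, patterns):
        recs = []
        for i, pat in enumerate(patterns):
            n = len(pat)
            recs.append(
                rip.EnrichmentRecord(
                    transcript_id=f"t{i}",
                    fpkm_rip=tuple(2.0 if p else 0.0 for p in pat),
                    fpkm_ctrl=(1.0,) * n,
                    fold_change=(1.0,) * n,
                    positive=tuple(pat),
                    n_positive_replicates=sum(pat),
                    stringent=False,
                )
            )
        return recs

    def test_simple_enumeration(self):
        cells = rip.replicate_overlap(
            self._records([(1, 1, 1), (1, 0, 0), (0, 1, 0)]), 3
        )
        assert cells[(1, 2, 3)] == 1
        assert cells[(1,)] == 1
        assert cells[(2,)] == 1
        assert sum(cells.values()) == 3

    def test_empty(self):
        cells = rip.replicate_overlap([], 3)
        assert all(v == 0 for v in cells.values())
        assert len(cells) == 7

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        patterns = [tuple(rng.integers(0, 2, 3).astype(bool)) for _ in range(100)]
        cells = rip.replicate_overlap(self._records(patterns), 3)
        # independent enumeration over the patterns
        for k in range(1, 4):
            for combo in combinations((1, 2, 3), k):
                expected = sum(
                    1
                    for pat in patterns
                    if tuple(i + 1 for i, p in enumerate(pat) if p) == combo
                )
                assert cells[combo] == expected
        n_any = sum(1 for pat in patterns if any(pat))
        assert sum(cells.values()) == n_any


class TestIntronClassification:
    def test_no_intronic_reads(self, two_exon_transcript):
        reads = [(120, 220)] * 50
        call = rip.classify_intron_binding(two_exon_transcript, reads)
        assert call.call is rip.IntronCall.post_transcriptional
        assert call.exonic_reads == 50
        assert call.intronic_reads == 0

    def test_intronic_reads_co(self, two_exon_transcript):
        reads = [(120, 220)] * 50 + [(350, 450)] * 10
        call = rip.classify_intron_binding(two_exon_transcript, reads, 1)
        assert call.call is rip.IntronCall.co_transcriptional
        assert call.intronic_reads == 10

    def test_undetected(self, two_exon_transcript):
        call = rip.classify_intron_binding(two_exon_transcript, [])
        assert call.call is rip.IntronCall.undetected

    def test_one_base_intron_overlap_is_intronic(self, two_exon_transcript):
        # read ends 1 base inside the intron (intron is [300, 500))
        call = rip.classify_intron_binding(two_exon_transcript, [(250, 301)])
        assert call.intronic_reads == 1

    def test_read_touching_intron_boundary_is_exonic(self, two_exon_transcript):
        # half-open read ending exactly at the intron start
        call = rip.classify_intron_binding(two_exon_transcript, [(250, 300)])
        assert call.exonic_reads == 1
        assert call.intronic_reads == 0

    def test_single_exon_annotation(self):
        m = rip.TranscriptModel("n", rip.Biotype.lncRNA, ((0, 5000),))
        call = rip.classify_intron_binding(m, [(10, 110)])
        assert call.call is rip.IntronCall.post_transcriptional
        assert call.single_exon


class TestQpcr:
    def test_fold_enrichment_two_cycles(self):
        m = rip.QPCRMeasurement("p", ct_specific_ip=28, ct_control_ip=30, ct_input=25)
        assert rip.qpcr_fold_enrichment(m) == pytest.approx(4.0)

    def test_fold_enrichment_identity(self):
        m = rip.QPCRMeasurement("p", 30, 30, 25)
        assert rip.qpcr_fold_enrichment(m) == pytest.approx(1.0)

    def test_eightfold(self):
        m = rip.QPCRMeasurement("p", ct_specific_ip=27.0, ct_control_ip=30.0, ct_input=24)
        assert rip.qpcr_fold_enrichment(m) == pytest.approx(8.0)

    @given(
        spec=st.floats(min_value=5, max_value=40),
        ctrl=st.floats(min_value=5, max_value=40),
        inp1=st.floats(min_value=5, max_value=40),
        inp2=st.floats(min_value=5, max_value=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_input_ct_cancels(self, spec, ctrl, inp1, inp2):
        f1 = rip.qpcr_fold_enrichment(rip.QPCRMeasurement("p", spec, ctrl, inp1))
        f2 = rip.qpcr_fold_enrichment(rip.QPCRMeasurement("p", spec, ctrl, inp2))
        assert f1 == pytest.approx(f2, rel=1e-9)
        assert f1 == pytest.approx(2.0 ** (ctrl - spec), rel=1e-9)

    def test_percent_input_full_recovery(self):
        m = rip.QPCRMeasurement("p", ct_specific_ip=25 - math.log2(10), ct_control_ip=30,
                                ct_input=25, input_fraction=0.10)
        assert rip.qpcr_percent_input(m) == pytest.approx(100.0, rel=1e-9)

    def test_percent_input_one_percent(self):
        adj = 25 - math.log2(10)
        m = rip.QPCRMeasurement("p", ct_specific_ip=adj + 6.644, ct_control_ip=30,
                                ct_input=25, input_fraction=0.10)
        # frozen hand arithmetic: 100 * 2**(-6.644)
        assert rip.qpcr_percent_input(m) == pytest.approx(0.9999003233158655, rel=1e-9)

    def test_percent_input_undiluted(self):
        m = rip.QPCRMeasurement("p", 25, 30, 25, input_fraction=1.0)
        assert rip.qpcr_percent_input(m) == pytest.approx(100.0)

    def test_ct_range_validated(self):
        with pytest.raises(ValueError):
            rip.QPCRMeasurement("p", 50, 30, 25)


class TestIO:
    def test_count_table_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2"],
                "role": ["RIP", "RIP", "control"],
                "replicate": [1, 1, 1],
                "transcript_id": ["a", "b", "a"],
                "count": [10, 20, 5],
            }
        )
        p = tmp_path / "counts.tsv"
        df.to_csv(p, sep="\t", index=False)
        samples = rip.read_count_table(p)
        by_id = {s.sample_id: s for s in samples}
        assert by_id["s1"].counts == {"a": 10, "b": 20}
        assert by_id["s1"].total_mapped_fragments == 30
        assert by_id["s2"].role is rip.Role.control

    def test_gtf_reader(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        gtf.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
            'transcript_biotype "protein_coding";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; '
            'transcript_biotype "protein_coding";\n'
        )
        models = rip.read_gtf(gtf)
        # 1-based inclusive converted to 0-based half-open
        assert models["t1"].exons == ((100, 200), (300, 400))
        assert models["t1"].length_nt == 200
        assert models["t1"].biotype is rip.Biotype.mRNA
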