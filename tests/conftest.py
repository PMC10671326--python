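import numpy as np
import pytest

from ribobind import mst_binding as mb
from ribobind import rip_enrichment as rip
from ribobind import synthetic_data as sim


@pytest.fixture(scope="session")
def receptor():
    return sim.make_receptor()


@pytest.fixture(scope="session")
def reference_complex(receptor):
    return sim.make_reference_complex(receptor)


@pytest.fixture()
def two_exon_transcript():
    return rip.TranscriptModel(
        transcript_id="tx1",
        biotype=rip.Biotype.mRNA,
        exons=((100, 300), (500, 900)),
    )


@pytest.fixture()
def clean_series():
    return sim.gen_mst_series(sim.MSTSimSpec(true_kd_M=1e-6, seed=11))


@pytest.fixture()
def noiseless_series():
    return sim.gen_mst_series(sim.MSTSimSpec(true_kd_M=1e-6, noise_sd=0.0, seed=11))


def make_sample(counts, total, role=rip.Role.RIP, rep=1, sid=None):
    return rip.QuantSample(
        sample_id=sid or f"{role.value}_rep{rep}",
        role=role,
        replicate_index=rep,
        counts=counts,
        total_mapped_fragments=total,
    )


def make_models(lengths):
    """One single-exon model per transcript with the requested length."""
    return {
        tid: rip.TranscriptModel(
            transcript_id=tid, biotype=rip.Biotype.mRNA, exons=((0, length),)
        )
        for tid, length in lengths.items()
    }
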