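"""RIP-seq enrichment calling from per-replicate fragment-count tables.

Turns RIP/control count tables into FPKM values, per-replicate enrichment
calls, replicate-overlap (Venn) summaries, intron-coverage classifications
and RIP-qPCR fold-enrichment / percent-input numbers.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Biotype",
    "Role",
    "TranscriptModel",
    "QuantSample",
    "EnrichmentRecord",
    "IntronCall",
    "IntronCoverageCall",
    "QPCRMeasurement",
    "compute_fpkm",
    "call_enrichment",
    "replicate_overlap",
    "classify_intron_binding",
    "qpcr_fold_enrichment",
    "qpcr_percent_input",
    "read_gtf",
    "read_transcript_table",
    "read_count_table",
    "read_bed_intervals",
    "records_to_frame",
    "write_outputs",
]


class Biotype(str, Enum):
    mRNA = "mRNA"
    lncRNA = "lncRNA"
    snRNA = "snRNA"
    scaRNA = "scaRNA"
    snoRNA = "snoRNA"
    other = "other"


class Role(str, Enum):
    RIP = "RIP"
    control = "control"
    input = "input"


_BIOTYPE_ALIASES = {
    "protein_coding": Biotype.mRNA,
    "mrna": Biotype.mRNA,
    "lncrna": Biotype.lncRNA,
    "lincrna": Biotype.lncRNA,
    "snrna": Biotype.snRNA,
    "scarna": Biotype.scaRNA,
    "snorna": Biotype.snoRNA,
}


def _coerce_biotype(value: str | Biotype) -> Biotype:
    if isinstance(value, Biotype):
        return value
    return _BIOTYPE_ALIASES.get(str(value).lower(), Biotype.other)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript, 0-based half-open genomic intervals."""

    transcript_id: str
    biotype: Biotype
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >=1 exon")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s}, {e})")
        if list(exons) != sorted(exons):
            raise ValueError(f"{self.transcript_id}: exons must be sorted")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "biotype", _coerce_biotype(self.biotype))

    @property
    def length_nt(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)

    @property
    def single_exon(self) -> bool:
        return len(self.exons) == 1


@dataclass
class QuantSample:
    """Per-sample fragment counts plus library size."""

    sample_id: str
    role: Role
    replicate_index: int
    counts: dict[str, int]
    total_mapped_fragments: int

    def __post_init__(self):
        self.role = Role(self.role)
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if self.total_mapped_fragments <= 0:
            raise ValueError(f"{self.sample_id}: total_mapped_fragments must be > 0")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.sample_id}: negative counts")
        if self.total_mapped_fragments < sum(self.counts.values()):
            raise ValueError(
                f"{self.sample_id}: total_mapped_fragments smaller than summed counts"
            )


@dataclass
class EnrichmentRecord:
    transcript_id: str
    fpkm_rip: tuple[float, ...]
    fpkm_ctrl: tuple[float, ...]
    fold_change: tuple[float, ...]
    positive: tuple[bool, ...]
    n_positive_replicates: int
    stringent: bool


class IntronCall(str, Enum):
    co_transcriptional = "co_transcriptional"
    post_transcriptional = "post_transcriptional"
    undetected = "undetected"


@dataclass
class IntronCoverageCall:
    transcript_id: str
    exonic_reads: int
    intronic_reads: int
    call: IntronCall
    single_exon: bool = False


@dataclass
class QPCRMeasurement:
    """Ct triple for one probe: specific IP, matched non-specific IP, and input.

    ``input_fraction`` is the fraction of lysate kept aside as input (0.10 for
    a 10% input), used to put the input Ct on the same scale as the IPs.
    """

    probe_id: str
    ct_specific_ip: float
    ct_control_ip: float
    ct_input: float
    input_fraction: float = 0.10

    def __post_init__(self):
        for name in ("ct_specific_ip", "ct_control_ip", "ct_input"):
            v = getattr(self, name)
            if not math.isfinite(v) or not (0.0 <= v <= 45.0):
                raise ValueError(f"{self.probe_id}: {name}={v} outside [0, 45]")
        if not (0.0 < self.input_fraction <= 1.0):
            raise ValueError("input_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def compute_fpkm(
    sample: QuantSample, models: Mapping[str, TranscriptModel]
) -> dict[str, float]:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count * 1e9 / (length_nt * total_mapped_fragments).
    """
    missing = sorted(t for t in sample.counts if t not in models)
    if missing:
        raise KeyError(f"no transcript model for: {', '.join(missing)}")
    total = sample.total_mapped_fragments
    out: dict[str, float] = {}
    for tid, count in sample.counts.items():
        if count == 0:
            out[tid] = 0.0
            continue
        length = models[tid].length_nt
        out[tid] = count * 1e9 / (length * total)
    return out


def call_enrichment(
    rip_samples: Sequence[QuantSample],
    ctrl_samples: Sequence[QuantSample],
    models: Mapping[str, TranscriptModel],
    pseudocount: float = 0.1,
    min_fpkm: float = 0.0,
    fold_threshold: float = 2.0,
    min_stringent_replicates: int = 2,
) -> list[EnrichmentRecord]:
    """Per-replicate positive calls (strict FPKM inequality) and the stringent
    class: fold change above ``fold_threshold`` in at least
    ``min_stringent_replicates`` replicates.

    ``min_fpkm`` optionally requires the RIP FPKM to reach a floor before a
    replicate can be called positive (defaults off).
    """
    rip_by_rep = {s.replicate_index: s for s in rip_samples}
    ctrl_by_rep = {s.replicate_index: s for s in ctrl_samples}
    if len(rip_by_rep) != len(rip_samples) or len(ctrl_by_rep) != len(ctrl_samples):
        raise ValueError("duplicate replicate_index within a sample group")
    if set(rip_by_rep) != set(ctrl_by_rep):
        raise ValueError(
            f"replicate indices differ: RIP={sorted(rip_by_rep)} "
            f"control={sorted(ctrl_by_rep)}"
        )
    reps = sorted(rip_by_rep)
    fpkm_rip = {r: compute_fpkm(rip_by_rep[r], models) for r in reps}
    fpkm_ctrl = {r: compute_fpkm(ctrl_by_rep[r], models) for r in reps}

    transcripts = sorted(
        set().union(*(s.counts.keys() for s in list(rip_samples) + list(ctrl_samples)))
    )
    records = []
    for tid in transcripts:
        fr = tuple(fpkm_rip[r].get(tid, 0.0) for r in reps)
        fc_ = tuple(fpkm_ctrl[r].get(tid, 0.0) for r in reps)
        pos = tuple(
            (a > b) and (a >= min_fpkm) for a, b in zip(fr, fc_)
        )
        fold = tuple((a + pseudocount) / (b + pseudocount) for a, b in zip(fr, fc_))
        n_over = sum(f > fold_threshold for f in fold)
        records.append(
            EnrichmentRecord(
                transcript_id=tid,
                fpkm_rip=fr,
                fpkm_ctrl=fc_,
                fold_change=fold,
                positive=pos,
                n_positive_replicates=sum(pos),
                stringent=n_over >= min_stringent_replicates,
            )
        )
    return records


def replicate_overlap(
    records: Iterable[EnrichmentRecord], n_replicates: int
) -> dict[tuple[int, ...], int]:
    """Disjoint Venn cells: for every non-empty replicate subset, the number of
    transcripts positive in exactly that subset. Cells sum to the number of
    transcripts positive in at least one replicate.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    cells: dict[tuple[int, ...], int] = {}
    for k in range(1, n_replicates + 1):
        for combo in combinations(range(1, n_replicates + 1), k):
            cells[combo] = 0
    for rec in records:
        if len(rec.positive) != n_replicates:
            raise ValueError(
                f"{rec.transcript_id}: record has {len(rec.positive)} replicates, "
                f"expected {n_replicates}"
            )
        subset = tuple(i + 1 for i, p in enumerate(rec.positive) if p)
        if subset:
            cells[subset] += 1
    return cells


def _overlaps(iv: tuple[int, int], others: Sequence[tuple[int, int]]) -> bool:
    s, e = iv
    return any(s < oe and os_ < e for os_, oe in others)


def classify_intron_binding(
    transcript: TranscriptModel,
    read_intervals: Sequence[tuple[int, int]],
    min_intronic_reads: int = 1,
) -> IntronCoverageCall:
    """Classify a transcript's binding mode from read placement.

    A read is intronic if it overlaps any intron by >=1 base; otherwise it is
    exonic if it overlaps any exon. Transcripts with intronic coverage below
    ``min_intronic_reads`` but detectable exonic coverage are called
    post-transcriptional; intronic coverage at/above threshold is
    co-transcriptional; no reads at all is undetected. Single-exon transcripts
    have no introns and are annotated as such.
    """
    introns = transcript.introns
    exonic = intronic = 0
    for iv in read_intervals:
        if introns and _overlaps(iv, introns):
            intronic += 1
        elif _overlaps(iv, transcript.exons):
            exonic += 1
    if exonic + intronic == 0:
        call = IntronCall.undetected
    elif intronic >= min_intronic_reads:
        call = IntronCall.co_transcriptional
    else:
        call = IntronCall.post_transcriptional
    return IntronCoverageCall(
        transcript_id=transcript.transcript_id,
        exonic_reads=exonic,
        intronic_reads=intronic,
        call=call,
        single_exon=transcript.single_exon,
    )


def qpcr_fold_enrichment(m: QPCRMeasurement) -> float:
    """2^(-ddCt) of the specific IP over the non-specific control IP.

    Both IPs are normalized to the same dilution-adjusted input Ct, which
    therefore cancels: the result equals 2^(ct_control_ip - ct_specific_ip).
    """
    adj_input = m.ct_input - math.log2(1.0 / m.input_fraction)
    dct_spec = m.ct_specific_ip - adj_input
    dct_ctrl = m.ct_control_ip - adj_input
    return 2.0 ** (-(dct_spec - dct_ctrl))


def qpcr_percent_input(m: QPCRMeasurement) -> float:
    """Recovery of the IP relative to the dilution-adjusted input, in percent."""
    adj_input = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** (adj_input - m.ct_specific_ip)


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> dict[str, TranscriptModel]:
    """Read transcript exon models from a GTF file (1-based inclusive
    coordinates, converted to 0-based half-open on ingestion)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    biotypes: dict[str, str] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        exons[tid].append((ex.start - 1, ex.end))
        for key in ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type"):
            if key in ex.attributes:
                biotypes[tid] = ex.attributes[key][0]
                break
    models = {}
    for tid, ivs in exons.items():
        models[tid] = TranscriptModel(
            transcript_id=tid,
            biotype=_coerce_biotype(biotypes.get(tid, "other")),
            exons=tuple(sorted(ivs)),
        )
    return models


def read_transcript_table(path: str | Path) -> dict[str, TranscriptModel]:
    """Read a pre-flattened transcript table: TSV with columns transcript_id,
    biotype, exon_starts, exon_ends (comma-separated, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = {}
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        models[row.transcript_id] = TranscriptModel(
            transcript_id=row.transcript_id,
            biotype=_coerce_biotype(row.biotype),
            exons=tuple(sorted(zip(starts, ends))),
        )
    return models


def read_count_table(
    path: str | Path, library_sizes: str | Path | None = None
) -> list[QuantSample]:
    """Read a long-format count table: TSV with columns sample_id, role,
    replicate, transcript_id, count. Library sizes come from an optional
    companion TSV (sample_id, total_mapped_fragments) or default to the
    per-sample count sum."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "role", "replicate", "transcript_id", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count table missing columns: {sorted(required - set(df.columns))}")
    totals = {}
    if library_sizes is not None:
        ls = pd.read_csv(library_sizes, sep="\t")
        totals = dict(zip(ls["sample_id"], ls["total_mapped_fragments"]))
    samples = []
    for (sid, role, rep), grp in df.groupby(["sample_id", "role", "replicate"]):
        counts = dict(zip(grp["transcript_id"], grp["count"].astype(int)))
        samples.append(
            QuantSample(
                sample_id=str(sid),
                role=Role(role),
                replicate_index=int(rep),
                counts=counts,
                total_mapped_fragments=int(totals.get(sid, sum(counts.values()))),
            )
        )
    return samples


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read read/fragment intervals from BED (first column is the transcript or
    gene key the intervals belong to)."""
    out: dict[str, list[tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out[parts[0]].append((int(parts[1]), int(parts[2])))
    return dict(out)


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"transcript_id": r.transcript_id}
        for i, (fr, fc, fold, pos) in enumerate(
            zip(r.fpkm_rip, r.fpkm_ctrl, r.fold_change, r.positive), start=1
        ):
            row[f"fpkm_rip_{i}"] = fr
            row[f"fpkm_ctrl_{i}"] = fc
            row[f"fold_change_{i}"] = fold
            row[f"positive_{i}"] = pos
        row["n_positive_replicates"] = r.n_positive_replicates
        row["stringent"] = r.stringent
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(
    out_dir: str | Path,
    records: Sequence[EnrichmentRecord],
    n_replicates: int,
    intron_calls: Sequence[IntronCoverageCall] = (),
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    cells = replicate_overlap(records, n_replicates)
    venn = {"+".join(map(str, k)): v for k, v in cells.items()}
    (out / "venn.json").write_text(json.dumps(venn, indent=2))
    if intron_calls:
        pd.DataFrame(
            [
                {
                    "transcript_id": c.transcript_id,
                    "exonic_reads": c.exonic_reads,
                    "intronic_reads": c.intronic_reads,
                    "call": c.call.value,
                    "single_exon": c.single_exon,
                }
                for c in intron_calls
            ]
        ).to_csv(out / "intron_calls.tsv", sep="\t", index=False)
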