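"""Seeded generators producing inputs with the statistical structure each
pipeline stage assumes: overdispersed RIP/control count tables with planted
binders, piecewise-exponential MST traces driven by a mass-action binding
curve, and rigid-body RNA pose ensembles with planted filter violations and a
controllable contact hotspot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .dock_surface import AtomRecord, Pose, PoseEnsemble, coords, write_pdb
from .mst_binding import (
    MSTConfig,
    MSTSeries,
    MSTTrace,
    TraceShape,
    fraction_bound,
    model_trace,
)
from .rip_enrichment import Biotype, QuantSample, Role, TranscriptModel

__all__ = [
    "RIPSimSpec",
    "MSTSimSpec",
    "PoseSimSpec",
    "gen_rip_counts",
    "gen_mst_series",
    "gen_pose_ensemble",
    "make_receptor",
    "make_reference_complex",
    "write_rip_dataset",
    "write_pose_dataset",
]


# ---------------------------------------------------------------------------
# RIP-seq counts
# ---------------------------------------------------------------------------

@dataclass
class RIPSimSpec:
    n_transcripts: int = 500
    n_replicates: int = 3
    binder_fraction: float = 0.1
    log2_effect: float = 2.0
    dispersion: float = 0.1
    library_size: int = 1_000_000
    intronic_rate_co: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.binder_fraction <= 1.0):
            raise ValueError("binder_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with mean ``mean`` and variance mean + dispersion*mean^2."""
    if mean <= 0:
        return 0
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _random_transcript(
    rng: np.random.Generator, tid: str, biotype: Biotype
) -> TranscriptModel:
    n_exons = int(rng.integers(1, 8))
    pos = int(rng.integers(0, 10_000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(100, 1200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(200, 2000))
    return TranscriptModel(transcript_id=tid, biotype=biotype, exons=tuple(exons))


def gen_rip_counts(
    spec: RIPSimSpec,
) -> tuple[
    dict[str, TranscriptModel],
    list[QuantSample],
    pd.DataFrame,
    dict[str, list[tuple[int, int]]],
]:
    """Generate transcript models, RIP/control count samples, a planted-truth
    table, and per-transcript read intervals (for intron classification).

    Control counts are negative binomial around a log-normal per-transcript
    mean; planted binders have their RIP mean scaled by 2**log2_effect.
    Co-transcriptional binders receive intronic reads at ``intronic_rate_co``;
    post-transcriptional binders receive none.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_transcripts
    ids = [f"tx_{i:05d}" for i in range(n)]

    models = {}
    for tid in ids:
        biotype = Biotype.mRNA if rng.random() < 0.85 else Biotype.lncRNA
        models[tid] = _random_transcript(rng, tid, biotype)

    base_mean = rng.lognormal(mean=math.log(100.0), sigma=0.8, size=n)
    n_binders = int(round(spec.binder_fraction * n))
    binder_idx = set(rng.choice(n, size=n_binders, replace=False).tolist())

    classes = []
    for i, tid in enumerate(ids):
        if i not in binder_idx:
            classes.append("none")
        elif models[tid].single_exon or rng.random() < 0.5:
            classes.append("post_transcriptional")
        else:
            classes.append("co_transcriptional")

    effect = 2.0**spec.log2_effect
    samples: list[QuantSample] = []
    for rep in range(1, spec.n_replicates + 1):
        ctrl = {
            tid: _nb_draw(rng, base_mean[i], spec.dispersion)
            for i, tid in enumerate(ids)
        }
        rip = {
            tid: _nb_draw(
                rng,
                base_mean[i] * (effect if i in binder_idx else 1.0),
                spec.dispersion,
            )
            for i, tid in enumerate(ids)
        }
        for role, counts in ((Role.control, ctrl), (Role.RIP, rip)):
            total = max(spec.library_size, sum(counts.values()))
            samples.append(
                QuantSample(
                    sample_id=f"{role.value}_rep{rep}",
                    role=role,
                    replicate_index=rep,
                    counts=counts,
                    total_mapped_fragments=total,
                )
            )

    # read intervals for the first RIP replicate, used by the intron classifier
    rip1 = next(
        s.counts for s in samples if s.role is Role.RIP and s.replicate_index == 1
    )
    read_len = 100
    reads: dict[str, list[tuple[int, int]]] = {}
    for i, tid in enumerate(ids):
        model = models[tid]
        n_reads = min(int(rip1[tid]), 30)
        if n_reads == 0:
            reads[tid] = []
            continue
        n_intronic = 0
        if classes[i] == "co_transcriptional" and model.introns:
            n_intronic = int(rng.binomial(n_reads, spec.intronic_rate_co))
        ivs = []
        for _ in range(n_reads - n_intronic):
            s, e = model.exons[rng.integers(len(model.exons))]
            start = int(rng.integers(s, max(e - read_len, s) + 1))
            ivs.append((start, min(start + read_len, e)))
        for _ in range(n_intronic):
            s, e = model.introns[rng.integers(len(model.introns))]
            start = int(rng.integers(s, max(e - read_len, s) + 1))
            ivs.append((start, min(start + read_len, e)))
        reads[tid] = ivs

    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "is_binder": [i in binder_idx for i in range(n)],
            "binding_class": classes,
            "single_exon": [models[t].single_exon for t in ids],
            "base_mean": base_mean,
        }
    )
    return models, samples, truth, reads


def write_rip_dataset(
    out_dir: str | Path,
    models: dict[str, TranscriptModel],
    samples: Sequence[QuantSample],
    truth: pd.DataFrame,
    reads: dict[str, list[tuple[int, int]]],
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        for tid, c in s.counts.items():
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "role": s.role.value,
                    "replicate": s.replicate_index,
                    "transcript_id": tid,
                    "count": c,
                }
            )
    pd.DataFrame(rows).to_csv(out / "counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "total_mapped_fragments": s.total_mapped_fragments}
            for s in samples
        ]
    ).to_csv(out / "library_sizes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "transcript_id": m.transcript_id,
                "biotype": m.biotype.value,
                "exon_starts": ",".join(str(s) for s, _ in m.exons),
                "exon_ends": ",".join(str(e) for _, e in m.exons),
            }
            for m in models.values()
        ]
    ).to_csv(out / "transcripts.tsv", sep="\t", index=False)
    with open(out / "reads.bed", "w") as fh:
        for tid, ivs in reads.items():
            for s, e in ivs:
                fh.write(f"{tid}\t{s}\t{e}\n")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# MST traces
# ---------------------------------------------------------------------------

@dataclass
class MSTSimSpec:
    true_kd_M: float = 1e-6
    labeled_conc_M: float = 5e-9
    n_points: int = 16
    top_conc_M: float = 40e-6
    dilution: float = 2.0
    noise_sd: float = 0.002
    aggregation_mode: bool = False
    seed: int = 0
    config: MSTConfig = field(default_factory=MSTConfig)
    shape: TraceShape = field(default_factory=TraceShape)

    def __post_init__(self):
        if self.true_kd_M <= 0:
            raise ValueError("true_kd_M must be > 0")
        if self.n_points < 6:
            raise ValueError("n_points must be >= 6")
        if self.dilution <= 1:
            raise ValueError("dilution must be > 1")


AGGREGATION_NOISE_SD = 0.02
AGGREGATION_ONSET_S = 5.0  # after laser-on; aggregates develop during thermophoresis


def gen_mst_series(spec: MSTSimSpec, rna_id: str = "sim") -> MSTSeries:
    """Simulate a dilution series of traces whose phase amplitudes follow the
    1:1 mass-action fraction-bound curve at the spec's true Kd.

    In aggregation mode the top-quartile concentration traces receive extra
    high-frequency noise and spikes during the late IR-on window, emulating
    the unstable signals of an aggregating sample.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = spec.config
    dt = 1.0 / cfg.sampling_hz
    total = cfg.t_before_s + cfg.t_on_s + cfg.t_after_s
    t = np.arange(0.0, total + dt / 2, dt)

    concs = spec.top_conc_M / spec.dilution ** np.arange(spec.n_points)
    n_agg = max(spec.n_points // 4, 1)
    traces = []
    for i, L in enumerate(concs):
        fb = fraction_bound(L, spec.labeled_conc_M, spec.true_kd_M)
        y = model_trace(t, fb, cfg, spec.shape)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=t.shape)
        if spec.aggregation_mode and i < n_agg:
            window = (t >= cfg.t_before_s + AGGREGATION_ONSET_S) & (
                t < cfg.t_laser_off_s
            )
            y = y + window * rng.normal(0.0, AGGREGATION_NOISE_SD, size=t.shape)
            spike_idx = rng.choice(np.flatnonzero(window), size=5, replace=False)
            spikes = np.zeros_like(y)
            spikes[spike_idx] = rng.uniform(0.03, 0.08, size=5) * rng.choice(
                [-1.0, 1.0], size=5
            )
            y = y + spikes
        scale = rng.uniform(300.0, 500.0)
        traces.append(
            MSTTrace(ligand_conc_M=float(L), time_s=t, fluorescence=scale * y, config=cfg)
        )
    return MSTSeries(traces=traces, labeled_conc_M=spec.labeled_conc_M, rna_id=rna_id)


# ---------------------------------------------------------------------------
# docked-pose ensembles
# ---------------------------------------------------------------------------

@dataclass
class PoseSimSpec:
    n_poses: int = 10
    rna_length_nt: int = 30
    hotspot_residues: frozenset[int] = frozenset(range(45, 55))
    hotspot_bias: float = 4.0
    clash_fraction: float = 0.0
    terminal_contact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("clash_fraction", "terminal_contact_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hotspot_bias < 0:
            raise ValueError("hotspot_bias must be >= 0")


_AA_CYCLE = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
_RNA_CYCLE = ["A", "U", "G", "C"]

# target / margin geometry (Å) used when planting poses; margins keep the
# planted category unambiguous under the default filter thresholds
_CONTACT_TARGET = 4.0
_TERMINAL_SAFE = 6.0
_TERMINAL_PLANT = 4.5
_CLASH_PLANT = 2.0
_CLASH_SAFE = 3.5
_PARTNER_CENTER = np.array([40.0, 0.0, 0.0])


def _globule_ca(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """CA trace meandering on a spherical shell (radial wobble ±1.5 Å).

    Keeping every residue near the surface makes the whole chain reachable by
    a docked ligand, which the hotspot-bias machinery relies on.
    """
    u = _unit(rng.normal(size=3))
    tangent = _unit(np.cross(u, rng.normal(size=3)))
    step_angle = 3.8 / radius
    out = []
    for _ in range(n):
        out.append((radius + rng.uniform(-1.5, 1.5)) * u)
        tangent = _unit(tangent + 0.5 * rng.normal(size=3))
        tangent = _unit(tangent - np.dot(tangent, u) * u)
        u = _unit(math.cos(step_angle) * u + math.sin(step_angle) * tangent)
    arr = np.array(out)
    return arr - arr.mean(axis=0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _protein_atoms(
    ca: np.ndarray, rng: np.random.Generator, chain_id: str, start_index: int = 1
) -> list[AtomRecord]:
    atoms = []
    specs = (("N", "N", 1.46), ("CA", "C", 0.0), ("C", "C", 1.52), ("O", "O", 2.40),
             ("CB", "C", 1.54))
    for i, center in enumerate(ca):
        resname = _AA_CYCLE[i % len(_AA_CYCLE)]
        for name, element, bond in specs:
            offset = bond * _unit(rng.normal(size=3)) if bond else np.zeros(3)
            xyz = center + offset
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=element,
                    residue_index=start_index + i,
                    residue_name=resname,
                    chain_id=chain_id,
                    xyz=tuple(float(x) for x in xyz),
                    molecule_class="protein",
                )
            )
    return atoms


def make_receptor(n_residues: int = 100, seed: int = 2024) -> list[AtomRecord]:
    """Deterministic ~100-residue synthetic receptor (compact globule,
    chain A). A stand-in with realistic atom spacing; only inter-atomic
    distances matter to the stage under test."""
    rng = np.random.default_rng(seed)
    ca = _globule_ca(rng, n_residues, radius=14.0)
    return _protein_atoms(ca, rng, chain_id="A")


def make_reference_complex(
    receptor: Sequence[AtomRecord], n_partner_residues: int = 80, seed: int = 7
) -> list[AtomRecord]:
    """Receptor (chain A) plus a synthetic partner chain B offset to one side,
    emulating the larger modeled complex used for clash filtering."""
    rng = np.random.default_rng(seed)
    ca = _globule_ca(rng, n_partner_residues, radius=12.0) + _PARTNER_CENTER
    partner = _protein_atoms(ca, rng, chain_id="B")
    return list(receptor) + partner


_ARC_RADIUS = 40.0  # bend of the pseudo-helix axis; keeps surface contacts local


def _rna_template(n_nt: int) -> list[AtomRecord]:
    """Coarse A-form-like phosphate-trace helix: P, C4' and N1 per nucleotide.

    The helix axis (z) is bent into an arc towards +x so that, docked with +x
    pointing away from the receptor, only a local patch around the pivot
    nucleotide touches the surface while both terminals curve clear of it.
    """
    atoms = []
    rise, twist = 2.81, math.radians(32.7)
    z_mid = (n_nt - 1) * rise / 2.0
    for i in range(n_nt):
        a = i * twist
        z = i * rise
        bend = (z - z_mid) ** 2 / (2.0 * _ARC_RADIUS)
        for name, element, r, da, dz in (
            ("P", "P", 9.0, 0.0, 0.0),
            ("C4'", "C", 7.5, 0.45, 0.6),
            ("N1", "N", 5.5, 0.9, 1.1),
        ):
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=element,
                    residue_index=i + 1,
                    residue_name=_RNA_CYCLE[i % 4],
                    chain_id="R",
                    xyz=(
                        r * math.cos(a + da) + bend,
                        r * math.sin(a + da),
                        z + dz,
                    ),
                    molecule_class="rna",
                )
            )
    xyz = np.array([at.xyz for at in atoms])
    center = xyz.mean(axis=0)
    return [
        AtomRecord(
            atom_name=at.atom_name,
            element=at.element,
            residue_index=at.residue_index,
            residue_name=at.residue_name,
            chain_id=at.chain_id,
            xyz=tuple(float(x) for x in (np.array(at.xyz) - center)),
            molecule_class="rna",
        )
        for at in atoms
    ]


def _place(template_xyz: np.ndarray, rot: Rotation, anchor: np.ndarray,
           normal: np.ndarray, offset: float, pivot: np.ndarray) -> np.ndarray:
    """Rotate the template about its pivot, then translate so the pivot sits at
    anchor + offset * normal."""
    rotated = rot.apply(template_xyz - pivot)
    return rotated + anchor + offset * normal


def _slide_to_contact(
    template_xyz: np.ndarray,
    rot: Rotation,
    anchor: np.ndarray,
    normal: np.ndarray,
    pivot: np.ndarray,
    receptor_tree: cKDTree,
    target: float,
) -> np.ndarray | None:
    """Bisect the offset along the outward normal until the all-atom minimum
    distance to the receptor equals ``target``."""

    def mindist(offset: float) -> float:
        placed = _place(template_xyz, rot, anchor, normal, offset, pivot)
        d, _ = receptor_tree.query(placed, k=1)
        return float(d.min())

    lo, hi = 0.0, 80.0
    if mindist(hi) < target or mindist(lo) > target:
        return None
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if mindist(mid) < target:
            lo = mid
        else:
            hi = mid
    return _place(template_xyz, rot, anchor, normal, hi, pivot)


def _with_coords(template: list[AtomRecord], xyz: np.ndarray) -> list[AtomRecord]:
    return [
        AtomRecord(
            atom_name=a.atom_name,
            element=a.element,
            residue_index=a.residue_index,
            residue_name=a.residue_name,
            chain_id=a.chain_id,
            xyz=tuple(float(v) for v in p),
            molecule_class="rna",
        )
        for a, p in zip(template, xyz)
    ]


def gen_pose_ensemble(
    spec: PoseSimSpec,
) -> tuple[PoseEnsemble, pd.DataFrame]:
    """Generate a pose ensemble with planted filter violations.

    Normal poses touch the receptor at ~4 Å through an internal nucleotide
    with both RNA terminals kept clear (> 6 Å) and no reference clash;
    ``terminal_contact_fraction`` of poses are planted with a terminal
    nucleotide < 5 Å from the receptor; ``clash_fraction`` are planted inside
    the reference partner chain. Anchor residues are drawn with weight
    1 + hotspot_bias on the hotspot set. The truth table records the planted
    category per pose.
    """
    rng = np.random.default_rng(spec.seed)
    receptor = make_receptor()
    reference = make_reference_complex(receptor)
    partner = [a for a in reference if a.chain_id == "B"]
    partner_xyz = coords(partner)
    partner_tree = cKDTree(partner_xyz)
    receptor_xyz = coords(receptor)
    receptor_tree = cKDTree(receptor_xyz)
    centroid = receptor_xyz.mean(axis=0)

    template = _rna_template(spec.rna_length_nt)
    template_xyz = coords(template)
    res_idx = np.array([a.residue_index for a in template])
    terminal_mask = (res_idx == res_idx.min()) | (res_idx == res_idx.max())
    mid_nt = (res_idx.min() + res_idx.max()) // 2
    mid_mask = res_idx == mid_nt
    five_prime_mask = res_idx == res_idx.min()
    axis = np.array([0.0, 0.0, 1.0])  # template helix axis (z), bend towards +x

    ca = {a.residue_index: np.array(a.xyz) for a in receptor if a.atom_name == "CA"}
    res_atoms: dict[int, list[np.ndarray]] = {}
    for a in receptor:
        res_atoms.setdefault(a.residue_index, []).append(np.array(a.xyz))
    res_xyz = {r: np.array(v) for r, v in res_atoms.items()}
    residue_ids = sorted(ca)
    weights = np.array(
        [
            1.0 + (spec.hotspot_bias if r in spec.hotspot_residues else 0.0)
            for r in residue_ids
        ]
    )
    weights = weights / weights.sum()

    n_clash = int(round(spec.clash_fraction * spec.n_poses))
    n_term = int(round(spec.terminal_contact_fraction * spec.n_poses))
    if n_clash + n_term > spec.n_poses:
        raise ValueError("clash_fraction + terminal_contact_fraction exceed 1")
    categories = (
        ["clash"] * n_clash
        + ["terminal"] * n_term
        + ["ok"] * (spec.n_poses - n_clash - n_term)
    )
    categories = [categories[i] for i in rng.permutation(spec.n_poses)]

    poses, rows = [], []
    for pidx, category in enumerate(categories):
        placed, anchor_res = _sample_pose(
            category,
            rng,
            template_xyz,
            terminal_mask,
            mid_mask,
            five_prime_mask,
            axis,
            ca,
            residue_ids,
            weights,
            centroid,
            receptor_tree,
            partner_tree,
            partner_xyz,
            res_xyz,
        )
        pose = Pose(
            pose_id=f"pose_{pidx:03d}",
            rna_atoms=_with_coords(template, placed),
            source="synthetic",
        )
        poses.append(pose)
        rows.append(
            {"pose_id": pose.pose_id, "category": category, "anchor_residue": anchor_res}
        )

    ensemble = PoseEnsemble(
        receptor=receptor, poses=poses, reference_complex=reference
    )
    return ensemble, pd.DataFrame(rows)


def _sample_pose(
    category: str,
    rng: np.random.Generator,
    template_xyz: np.ndarray,
    terminal_mask: np.ndarray,
    mid_mask: np.ndarray,
    five_prime_mask: np.ndarray,
    axis: np.ndarray,
    ca: dict[int, np.ndarray],
    residue_ids: list[int],
    weights: np.ndarray,
    centroid: np.ndarray,
    receptor_tree: cKDTree,
    partner_tree: cKDTree,
    partner_xyz: np.ndarray,
    res_xyz: dict[int, np.ndarray],
) -> tuple[np.ndarray, int]:
    for _ in range(400):
        if category == "clash":
            placed = _try_clash_pose(rng, template_xyz, axis, partner_xyz)
            anchor_res = -1
        else:
            anchor_res = int(rng.choice(residue_ids, p=weights))
            anchor = ca[anchor_res]
            normal = _unit(anchor - centroid)
            placed = _try_surface_pose(
                category,
                rng,
                template_xyz,
                terminal_mask,
                mid_mask,
                five_prime_mask,
                axis,
                anchor,
                normal,
                receptor_tree,
            )
        if placed is None:
            continue
        term_d, _ = receptor_tree.query(placed[terminal_mask], k=1)
        term_min = float(np.min(term_d))
        clash_d, _ = partner_tree.query(placed, k=1)
        clash_min = float(np.min(clash_d))
        if category == "ok":
            # the anchor residue must itself end up in contact (< 5 Å)
            anchor_d = cKDTree(placed).query(res_xyz[anchor_res], k=1)[0].min()
            if term_min >= _TERMINAL_SAFE and clash_min >= _CLASH_SAFE and anchor_d < 5.0:
                return placed, anchor_res
        elif category == "terminal":
            if term_min < _TERMINAL_PLANT and clash_min >= _CLASH_SAFE:
                return placed, anchor_res
        else:  # clash
            if term_min >= _TERMINAL_SAFE and clash_min < _CLASH_PLANT:
                return placed, anchor_res
    raise RuntimeError(f"could not place a '{category}' pose after 400 attempts")


def _try_surface_pose(
    category: str,
    rng: np.random.Generator,
    template_xyz: np.ndarray,
    terminal_mask: np.ndarray,
    mid_mask: np.ndarray,
    five_prime_mask: np.ndarray,
    axis: np.ndarray,
    anchor: np.ndarray,
    normal: np.ndarray,
    receptor_tree: cKDTree,
) -> np.ndarray | None:
    if category == "ok":
        # helix axis tangent to the surface, arc bending away from it, so the
        # contact patch stays local to the anchor and terminals curve clear
        tangent = _unit(np.cross(normal, rng.normal(size=3)))
        base, _ = Rotation.align_vectors(
            np.stack([tangent, normal]), np.stack([axis, np.array([1.0, 0.0, 0.0])])
        )
        jitter = Rotation.from_rotvec(
            math.radians(15.0) * rng.uniform(-1, 1) * _unit(rng.normal(size=3))
        )
        rot = jitter * base
        pivot = template_xyz[mid_mask].mean(axis=0)
    else:  # terminal: point the 5' end at the receptor
        rot = _align_with_jitter(rng, axis, normal, jitter_deg=15.0)
        pivot = template_xyz[five_prime_mask].mean(axis=0)
    placed = _slide_to_contact(
        template_xyz, rot, anchor, normal, pivot, receptor_tree, _CONTACT_TARGET
    )
    if placed is None:
        return None
    if category == "terminal":
        d, _ = receptor_tree.query(placed[terminal_mask], k=1)
        if float(np.min(d)) >= _TERMINAL_PLANT:
            return None
    return placed


def _align_with_jitter(
    rng: np.random.Generator, v_from: np.ndarray, v_to: np.ndarray, jitter_deg: float
) -> Rotation:
    base, _ = Rotation.align_vectors(v_to[None, :], v_from[None, :])
    spin = Rotation.from_rotvec(rng.uniform(0, 2 * math.pi) * v_to)
    jitter = Rotation.from_rotvec(
        math.radians(jitter_deg) * rng.uniform(-1, 1) * _unit(rng.normal(size=3))
    )
    return jitter * spin * base


def _try_clash_pose(
    rng: np.random.Generator,
    template_xyz: np.ndarray,
    axis: np.ndarray,
    partner_xyz: np.ndarray,
) -> np.ndarray:
    # bury the RNA midpoint at a random partner atom, axis kept away from the
    # receptor side (-x) so terminals stay clear of it
    target_atom = partner_xyz[rng.integers(len(partner_xyz))]
    direction = _unit(np.array([0.0, rng.normal(), rng.normal()]))
    rot = _align_with_jitter(rng, axis, direction, jitter_deg=10.0)
    pivot = template_xyz.mean(axis=0)
    placed = rot.apply(template_xyz - pivot) + target_atom
    return placed


def write_pose_dataset(
    out_dir: str | Path, ensemble: PoseEnsemble, truth: pd.DataFrame
) -> None:
    out = Path(out_dir)
    (out / "poses").mkdir(parents=True, exist_ok=True)
    write_pdb(ensemble.receptor, out / "receptor.pdb")
    if ensemble.reference_complex is not None:
        write_pdb(ensemble.reference_complex, out / "reference_complex.pdb")
    for pose in ensemble.poses:
        write_pdb(pose.rna_atoms, out / "poses" / f"{pose.pose_id}.pdb")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
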