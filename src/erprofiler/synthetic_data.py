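"""Synthetic generators with known ground truth for every pipeline stage.

Three generators emulate the structure of the study's data so the analysis
modules can be exercised end to end without any external files:

* :func:`simulate_activity_panel` — scaffold-structured multi-assay panels.
  Each ligand carries a latent AF-2 efficacy ``a_i`` (uniform on
  [−20, 100] % of the reference agonist); cell-type readouts are
  ``y_ic = a_i·g_c + b_ic + ε`` with Gaussian assay noise ε ~ N(0, σ²).
  Scaffold archetypes control the cell-specific component b and which cell
  types share the latent, and map onto the expected signaling clusters:
  ``amplified`` (all cell types track the shared latent, b = 0 →
  cluster 1), ``two_shared`` (two cell types share the latent plus a
  common AF-1 component ~ N(0, τ²); the third runs on its own independent
  latent → cluster 2), ``independent`` (every cell type has its own latent
  plus b_ic ~ N(0, τ²) i.i.d. → cluster 3) and ``null`` (noise only →
  cluster 3). An AB-deletion reporter column scales the liver latent by
  the AF-1 gain (default 0.2), emulating loss of AF-1 amplification.
* :func:`simulate_structure_ensemble` — ideal α-helix "LBD" models (rise
  1.5 Å/residue, radius 2.3 Å, 100° twist) in which a probe helix (the
  h11 tip) is displaced along a fixed unit vector by
  δ_i = δ0 + β·a_i + N(0, σ_δ), plus per-atom jitter and a random rigid
  motion per structure; a two-oxygen ligand component with a fixed
  phenol-to-phenol span rides along.
* :func:`simulate_fingerprints` — block-structured peptide fingerprints:
  each compound class up-modulates its own peptide block (MI +1.5, other
  blocks 0) plus Gaussian noise.

All generators are pure functions of parameters and seed; per-scaffold /
per-structure sub-streams are spawned deterministically so enlarging a
simulation does not perturb earlier units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coreg_fingerprints import FingerprintMatrix
from .ligand_data import ActivityPanel, AssayDescriptor, LigandRecord
from .structure_features import Atom, Chain, LigandComponent, Residue, StructureModel

ARCHETYPES = ("amplified", "two_shared", "independent", "null")

#: cell-type assay columns of a simulated panel, in canonical order
CELL_ASSAYS = (
    AssayDescriptor("GREB1", cell_context="MCF7", construct="endogenous", readout="mRNA"),
    AssayDescriptor("E-Luc", cell_context="Ishikawa", construct="endogenous", readout="luciferase"),
    AssayDescriptor("L-Luc_ERa_WT", cell_context="HepG2", construct="ERalpha_WT", readout="luciferase"),
)
DAB_ASSAY = AssayDescriptor(
    "L-Luc_ERa_dAB", cell_context="HepG2", construct="ERalpha_dAB", readout="luciferase"
)

EXPECTED_CLUSTER = {
    "amplified": "cluster1",
    "two_shared": "cluster2",
    "independent": "cluster3",
    "null": "cluster3",
}


class SimulationError(ValueError):
    pass


@dataclass
class PanelSimParams:
    n_scaffolds: int = 8
    ligands_per_scaffold: int = 12
    archetypes: Sequence[str] | None = None  # default: cycle through ARCHETYPES
    latent_low: float = -20.0
    latent_high: float = 100.0
    cell_gains: Mapping[str, float] = field(
        default_factory=lambda: {"GREB1": 1.0, "E-Luc": 1.0, "L-Luc_ERa_WT": 1.0}
    )
    tau: float = 30.0  # cell-specific component SD, % E2
    sigma: float = 10.0  # assay noise SD, % E2
    af1_gain: float = 0.2  # residual activity of the AB-deletion construct
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.tau < 0:
            raise SimulationError("noise SDs must be >= 0")
        if any(g <= 0 for g in self.cell_gains.values()):
            raise SimulationError("cell gains must be > 0")
        if self.n_scaffolds < 1 or self.ligands_per_scaffold < 1:
            raise SimulationError("need >= 1 scaffold and >= 1 ligand per scaffold")
        if self.archetypes is not None:
            bad = set(self.archetypes) - set(ARCHETYPES)
            if bad:
                raise SimulationError(f"unknown archetypes {sorted(bad)}; allowed: {ARCHETYPES}")


@dataclass
class StructureSimParams:
    n_structures: int = 20
    rise: float = 1.5  # Å per residue
    radius: float = 2.3  # Å
    twist_deg: float = 100.0
    core_residues: tuple[int, int] = (310, 360)  # inclusive range of the fixed core helix
    probe_residues: tuple[int, int] = (520, 530)  # the displaced "h11 tip"
    probe_offset: tuple[float, float, float] = (12.0, 0.0, 60.0)
    displacement_vector: tuple[float, float, float] = (1.0, 0.0, 0.0)
    delta0: float = 1.0  # baseline displacement, Å
    beta: float = 0.02  # Å per % E2 of activity
    sigma_delta: float = 0.1  # displacement noise SD, Å
    jitter_sd: float = 0.05  # per-atom coordinate jitter SD, Å
    phenol_span: float = 12.0  # ligand O-O distance, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise SimulationError("beta must be finite")
        if self.sigma_delta < 0 or self.jitter_sd < 0:
            raise SimulationError("noise SDs must be >= 0")
        if self.n_structures < 1:
            raise SimulationError("need >= 1 structure")


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside every generated data set."""

    latents: dict = field(default_factory=dict)  # ligand_id -> a_i (or per-cell dict)
    archetype: dict = field(default_factory=dict)  # scaffold -> archetype name
    expected_cluster: dict = field(default_factory=dict)  # scaffold -> cluster label
    displacement: dict = field(default_factory=dict)  # structure_id -> true δ_i
    structure_ligand: dict = field(default_factory=dict)  # structure_id -> ligand_id
    reference_model: StructureModel | None = None
    partition: dict = field(default_factory=dict)  # compound -> planted class


def _archetype_for(i: int, params: PanelSimParams) -> str:
    if params.archetypes is None:
        return ARCHETYPES[i % len(ARCHETYPES)]
    return params.archetypes[i % len(params.archetypes)]


def simulate_activity_panel(params: PanelSimParams) -> tuple[ActivityPanel, SyntheticTruth]:
    """Generate a scaffold-structured activity panel with stored ground truth."""
    ss = np.random.SeedSequence(params.seed)
    truth = SyntheticTruth()
    ligands: list[LigandRecord] = []
    rows: list[dict[str, float]] = []
    cells = [a.assay_id for a in CELL_ASSAYS]
    for s_idx, child in enumerate(ss.spawn(params.n_scaffolds)):
        rng = np.random.default_rng(child)
        arch = _archetype_for(s_idx, params)
        scaffold = f"SC{s_idx:03d}-{arch}"
        truth.archetype[scaffold] = arch
        truth.expected_cluster[scaffold] = EXPECTED_CLUSTER[arch]
        n = params.ligands_per_scaffold
        a_shared = rng.uniform(params.latent_low, params.latent_high, size=n)
        # per-cell latent (only used by archetypes that decouple cell types)
        a_cell = {
            c: rng.uniform(params.latent_low, params.latent_high, size=n) for c in cells
        }
        c_shared = rng.normal(0.0, params.tau, size=n)  # AF-1 component shared by two cells
        b = {c: rng.normal(0.0, params.tau, size=n) for c in cells}
        noise = {c: rng.normal(0.0, params.sigma, size=n) for c in cells}
        noise_dab = rng.normal(0.0, params.sigma, size=n)

        signal: dict[str, np.ndarray] = {}
        if arch == "amplified":
            for c in cells:
                signal[c] = a_shared * params.cell_gains[c]
            liver_latent = a_shared
        elif arch == "two_shared":
            for c in cells[:2]:  # GREB1 and E-Luc share latent + AF-1 component
                signal[c] = a_shared * params.cell_gains[c] + c_shared
            c3 = cells[2]
            signal[c3] = a_cell[c3] * params.cell_gains[c3]
            liver_latent = a_cell[c3]
        elif arch == "independent":
            for c in cells:
                signal[c] = a_cell[c] * params.cell_gains[c] + b[c]
            liver_latent = a_cell[cells[2]]
        else:  # null: no receptor-mediated activity
            for c in cells:
                signal[c] = np.zeros(n)
            liver_latent = np.zeros(n)

        dab = params.af1_gain * liver_latent * params.cell_gains[cells[2]] + noise_dab
        for k in range(n):
            lid = f"{scaffold}-L{k:02d}"
            ligands.append(LigandRecord(lid, scaffold, "indirect"))
            truth.latents[lid] = {
                "shared": float(a_shared[k]),
                **{c: float(a_cell[c][k]) for c in cells},
            }
            row = {c: float(signal[c][k] + noise[c][k]) for c in cells}
            row[DAB_ASSAY.assay_id] = float(dab[k])
            rows.append(row)

    assays = list(CELL_ASSAYS) + [DAB_ASSAY]
    values = pd.DataFrame(rows, index=[lg.ligand_id for lg in ligands])
    values = values[[a.assay_id for a in assays]]
    values.index.name = "ligand_id"
    panel = ActivityPanel(ligands=ligands, assays=assays, values=values)
    return panel, truth


def simulate_canonical_panel(
    n_ligands: int = 12, sigma: float = 10.0, seed: int = 0
) -> ActivityPanel:
    """One scaffold following the canonical signaling chain.

    Coactivator recruitment (M2H), GREB1 induction and proliferation all
    track the same latent efficacy with independent assay noise — the
    pattern in which coactivator binding predicts the downstream readouts.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(-20.0, 100.0, size=n_ligands)
    assays = [
        AssayDescriptor("M2H_NCOA3", cell_context="HEK293T", construct="ERalpha_WT", readout="M2H"),
        AssayDescriptor("GREB1", cell_context="MCF7", construct="endogenous", readout="mRNA"),
        AssayDescriptor("MCF7_prolif", cell_context="MCF7", construct="endogenous", readout="proliferation"),
    ]
    values = pd.DataFrame(
        {
            "M2H_NCOA3": a + rng.normal(0, sigma, n_ligands),
            "GREB1": a + rng.normal(0, sigma, n_ligands),
            "MCF7_prolif": a + rng.normal(0, sigma, n_ligands),
        },
        index=pd.Index([f"CANON-L{k:02d}" for k in range(n_ligands)], name="ligand_id"),
    )
    ligands = [LigandRecord(str(i), "CANON", "indirect") for i in values.index]
    return ActivityPanel(ligands=ligands, assays=assays, values=values)


def _helix_coords(n_res: int, rise: float, radius: float, twist_deg: float) -> np.ndarray:
    k = np.arange(n_res)
    theta = np.deg2rad(twist_deg) * k
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * k])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed, det forced to +1
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _build_model(
    sid: str,
    params: StructureSimParams,
    delta: float,
    rng: np.random.Generator | None,
) -> StructureModel:
    core_lo, core_hi = params.core_residues
    probe_lo, probe_hi = params.probe_residues
    u = np.asarray(params.displacement_vector, dtype=float)
    u = u / np.linalg.norm(u)
    chain = Chain(chain_id="A")
    core = _helix_coords(core_hi - core_lo + 1, params.rise, params.radius, params.twist_deg)
    for num, pos in zip(range(core_lo, core_hi + 1), core):
        chain.residues[num] = Residue(num, "ALA", {"CA": Atom("CA", "C", pos.copy())})
    probe = _helix_coords(probe_hi - probe_lo + 1, params.rise, params.radius, params.twist_deg)
    probe = probe + np.asarray(params.probe_offset, dtype=float) + delta * u
    for num, pos in zip(range(probe_lo, probe_hi + 1), probe):
        chain.residues[num] = Residue(num, "ALA", {"CA": Atom("CA", "C", pos.copy())})
    o1 = np.array([4.0, 0.0, 30.0])
    o2 = o1 + np.array([0.0, 0.0, params.phenol_span])
    chain.ligands.append(
        LigandComponent("LIG", {"O1": Atom("O1", "O", o1), "O2": Atom("O2", "O", o2)})
    )
    model = StructureModel(structure_id=sid, chains={"A": chain})
    if rng is not None:
        if params.jitter_sd > 0:
            for atom in model.iter_atoms():
                atom.pos = atom.pos + rng.normal(0.0, params.jitter_sd, size=3)
        R = _random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        model.transform(R, t)
    return model


def simulate_structure_ensemble(
    params: StructureSimParams,
    activities: Mapping[str, float] | None = None,
) -> tuple[list[StructureModel], SyntheticTruth]:
    """Generate an ensemble of helix models with activity-coupled probe displacement.

    ``activities`` maps ligand_id → % activity; when omitted, activities are
    drawn uniform on [−20, 100]. The returned truth carries the per-structure
    true displacement, the structure→ligand mapping and a clean reference
    model (ideal geometry, baseline displacement, no jitter, unrotated).
    """
    ss = np.random.SeedSequence(params.seed)
    top = np.random.default_rng(ss)
    if activities is None:
        n = params.n_structures
        activities = {
            f"SYNLIG{k:03d}": float(a)
            for k, a in enumerate(top.uniform(-20.0, 100.0, size=n))
        }
    lig_ids = list(activities)
    truth = SyntheticTruth()
    truth.reference_model = _build_model("REF", params, params.delta0, rng=None)
    models: list[StructureModel] = []
    for k, (lid, child) in enumerate(zip(lig_ids, ss.spawn(len(lig_ids)))):
        rng = np.random.default_rng(child)
        delta = params.delta0 + params.beta * float(activities[lid]) + rng.normal(0.0, params.sigma_delta)
        sid = f"SYN{k:03d}"
        models.append(_build_model(sid, params, delta, rng))
        truth.displacement[sid] = float(delta)
        truth.structure_ligand[sid] = lid
    return models, truth


def simulate_fingerprints(
    n_classes: int = 3,
    compounds_per_class: int = 4,
    peptides_per_block: int = 8,
    noise_sd: float = 0.2,
    block_mi: float = 1.5,
    seed: int = 0,
) -> tuple[FingerprintMatrix, SyntheticTruth]:
    """Block-structured modulation-index matrix with a planted compound partition.

    Each class up-modulates its own peptide block by ``block_mi`` log2 units
    (other blocks 0) plus N(0, noise_sd²) noise per cell.
    """
    if n_classes < 2 or compounds_per_class < 1 or peptides_per_block < 1:
        raise SimulationError("need >= 2 classes and >= 1 compound/peptide per block")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    peptides = [
        f"PEP{b:02d}_{j:02d}" for b in range(n_classes) for j in range(peptides_per_block)
    ]
    compounds = []
    truth = SyntheticTruth()
    rows = []
    for k in range(n_classes):
        base = np.zeros(n_classes * peptides_per_block)
        base[k * peptides_per_block : (k + 1) * peptides_per_block] = block_mi
        for j in range(compounds_per_class):
            cid = f"CLS{k}-CPD{j:02d}"
            compounds.append(cid)
            truth.partition[cid] = k
            rows.append(base + rng.normal(0.0, noise_sd, size=base.size))
    values = pd.DataFrame(np.array(rows), index=compounds, columns=peptides)
    fp = FingerprintMatrix(
        compounds=compounds, peptides=peptides, values=values, replicate_count=3
    )
    return fp, truth
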