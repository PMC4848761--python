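"""Coordinate-level analysis of ligand-binding-domain (LBD) complexes.

Parses PDB/mmCIF coordinate files, rigidly superposes structure ensembles
on a conserved core (Kabsch least-squares, SVD with determinant
correction), and extracts inter-atomic distance features — e.g. the
Cα–Cα span from helix 3 to the C-terminus of helix 11, whose variation
across ligand classes tracks how a bound modulator perturbs the
coactivator-binding (AF-2) surface. Distances are compared between ligand
classes by Student t-test and regressed against cellular activities.

Residue numbers follow the deposited author numbering (ERα canonical
numbering, LBD ≈ residues 305–550); no renumbering is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy import stats

from .predictors import RegressionResult, fit_simple_regression

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: default CA core used for superposition: helices up to (not including)
#: the flexible h11 C-terminus / h12 region whose variance is being measured
DEFAULT_CORE = range(310, 521)


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise StructureError(f"atom {self.name}: bad coordinates {self.pos}")


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, Atom] = field(default_factory=dict)


@dataclass
class LigandComponent:
    component_code: str
    atoms: dict[str, Atom] = field(default_factory=dict)


@dataclass
class Chain:
    chain_id: str
    residues: dict[int, Residue] = field(default_factory=dict)
    ligands: list[LigandComponent] = field(default_factory=list)


@dataclass
class StructureModel:
    structure_id: str
    chains: dict[str, Chain] = field(default_factory=dict)

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains.values() if c.residues]

    def iter_atoms(self) -> Iterable[Atom]:
        for chain in self.chains.values():
            for res in chain.residues.values():
                yield from res.atoms.values()
            for lig in chain.ligands:
                yield from lig.atoms.values()

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply x → R·x + t to every atom (protein and ligand) in place."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for atom in self.iter_atoms():
            atom.pos = R @ atom.pos + t


@dataclass(frozen=True)
class AtomPairSpec:
    """Two (residue number, atom name) endpoints; Cα by default."""

    residue_a: int
    residue_b: int
    atom_a: str = "CA"
    atom_b: str = "CA"

    def __str__(self) -> str:
        return f"{self.residue_a}.{self.atom_a}-{self.residue_b}.{self.atom_b}"


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_points: int


@dataclass(frozen=True)
class ClassDistanceStats:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    mean_difference: float
    t_stat: float
    p_value: float
    exact_separation: bool


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Protein residues and ligand (non-water hetero) components are
    separated; waters are dropped. Alternate locations are resolved to the
    highest-occupancy conformer, first conformer on ties. Only the first
    model of multi-model files is read.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path.name}: no models")
    st.setup_entities()
    model = StructureModel(structure_id=st.name or path.stem)
    for ch in st[0]:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            if res.name in WATER_NAMES:
                continue
            # resolve altlocs: keep highest occupancy per atom name, first on tie
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atoms = {
                name: Atom(
                    name=name,
                    element=at.element.name,
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                )
                for name, at in best.items()
            }
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_amino_acid():
                chain.residues[res.seqid.num] = Residue(
                    number=res.seqid.num, name=res.name, atoms=atoms
                )
            else:
                chain.ligands.append(LigandComponent(component_code=res.name, atoms=atoms))
        if chain.residues or chain.ligands:
            model.chains[chain.chain_id] = chain
    if not model.chains:
        raise StructureError(f"{path.name}: no non-water atoms found")
    return model


def write_structure_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write a model back out as PDB (protein as ATOM, ligands as HETATM)."""
    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    for chain in model.chains.values():
        gc = gemmi.Chain(chain.chain_id)
        for res in sorted(chain.residues.values(), key=lambda r: r.number):
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, " ")
            gr.het_flag = "A"
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        for i, lig in enumerate(chain.ligands):
            gr = gemmi.Residue()
            gr.name = lig.component_code
            gr.seqid = gemmi.SeqId(900 + i, " ")
            gr.het_flag = "H"
            for atom in lig.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of matched coordinate sets.

    Returns the proper rotation R (det = +1, enforced by flipping the sign
    of the smallest singular vector when needed) and translation t
    minimizing RMSD of R·mobile + t against reference, and the RMSD after
    the transform.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError(f"matched (N,3) coordinate sets required, got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise StructureError(f"need >= 3 points, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2:
        raise StructureError("points are collinear: rotation underdetermined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_points=n)


def _core_ca(chain: Chain, core: Iterable[int]) -> dict[int, np.ndarray]:
    out = {}
    for num in core:
        res = chain.residues.get(num)
        if res is not None and "CA" in res.atoms:
            out[num] = res.atoms["CA"].pos
    return out


def _first_chain(model: StructureModel, chain_id: str | None = None) -> Chain:
    if chain_id is not None:
        if chain_id not in model.chains:
            raise StructureError(f"{model.structure_id}: no chain {chain_id!r}")
        return model.chains[chain_id]
    prot = model.protein_chains()
    if not prot:
        raise StructureError(f"{model.structure_id}: no protein chain")
    return prot[0]


def superpose_ensemble(
    models: Sequence[StructureModel],
    reference_id: str,
    core: Iterable[int] = DEFAULT_CORE,
    chain_id: str | None = None,
) -> dict[str, float]:
    """Superpose every model onto the reference via shared-core CA atoms.

    Each model is transformed in place (ligand atoms carried along by the
    same rigid transform); returns per-structure RMSD over the fitted CA
    core. The reference itself gets RMSD 0.
    """
    core = list(core)
    by_id = {m.structure_id: m for m in models}
    if reference_id not in by_id:
        raise StructureError(f"reference {reference_id!r} not among models")
    ref_ca = _core_ca(_first_chain(by_id[reference_id], chain_id), core)
    rmsds: dict[str, float] = {}
    for m in models:
        mob_ca = _core_ca(_first_chain(m, chain_id), core)
        shared = sorted(set(ref_ca) & set(mob_ca))
        if len(shared) < 3:
            raise StructureError(
                f"{m.structure_id}: only {len(shared)} shared core CA atoms with "
                f"reference {reference_id!r} (need >= 3)"
            )
        res = kabsch_superpose(
            np.array([mob_ca[i] for i in shared]),
            np.array([ref_ca[i] for i in shared]),
        )
        m.transform(res.rotation, res.translation)
        rmsds[m.structure_id] = res.rmsd
    return rmsds


def atom_pair_distance(
    model: StructureModel,
    pair: AtomPairSpec,
    chain_policy: str = "mean_over_chains",
    chain_id: str | None = None,
) -> float | dict[str, float]:
    """Euclidean distance between two named atoms, per chain or aggregated.

    ``each_chain`` returns {chain_id: Å} over every protein chain carrying
    both atoms; ``mean_over_chains`` averages those; ``named_chain``
    measures in ``chain_id`` only. Missing residues or atoms (common for
    disordered helix termini) raise with a listing of what was absent.
    """
    def dist_in(chain: Chain) -> float:
        missing = []
        coords = []
        for num, aname in ((pair.residue_a, pair.atom_a), (pair.residue_b, pair.atom_b)):
            res = chain.residues.get(num)
            if res is None:
                missing.append(f"residue {num}")
            elif aname not in res.atoms:
                missing.append(f"atom {aname} of residue {num} ({res.name})")
            else:
                coords.append(res.atoms[aname].pos)
        if missing:
            raise StructureError(
                f"{model.structure_id} chain {chain.chain_id}: missing " + ", ".join(missing)
            )
        return float(np.linalg.norm(coords[0] - coords[1]))

    if chain_policy == "named_chain":
        return dist_in(_first_chain(model, chain_id))
    per_chain: dict[str, float] = {}
    errors: list[str] = []
    for chain in model.protein_chains():
        try:
            per_chain[chain.chain_id] = dist_in(chain)
        except StructureError as exc:
            errors.append(str(exc))
    if not per_chain:
        raise StructureError(
            f"{model.structure_id}: pair {pair} absent from every chain: " + "; ".join(errors)
        )
    if chain_policy == "each_chain":
        return per_chain
    if chain_policy == "mean_over_chains":
        return float(np.mean(list(per_chain.values())))
    raise StructureError(f"unknown chain_policy {chain_policy!r}")


def ensemble_distance_stats(
    models: Sequence[StructureModel],
    pair: AtomPairSpec,
    class_a: Sequence[str],
    class_b: Sequence[str],
    chain_policy: str = "mean_over_chains",
) -> ClassDistanceStats:
    """Per-class mean ± SEM of one atom-pair distance and a two-sample t-test.

    Pooled-variance two-tailed Student t. If both classes have zero
    variance the degenerate limit is flagged: identical values give p = 1,
    distinct constants are exact separation (p reported as 0).
    """
    by_id = {m.structure_id: m for m in models}
    def gather(ids: Sequence[str]) -> np.ndarray:
        vals = []
        for sid in ids:
            if sid not in by_id:
                raise StructureError(f"structure {sid!r} not among models")
            vals.append(atom_pair_distance(by_id[sid], pair, chain_policy))
        return np.asarray(vals, dtype=float)

    da, db = gather(class_a), gather(class_b)
    if da.size < 2 or db.size < 2:
        raise StructureError(
            f"need >= 2 structures per class, got {da.size} and {db.size}"
        )
    mean_a, mean_b = float(da.mean()), float(db.mean())
    sem_a = float(da.std(ddof=1) / math.sqrt(da.size))
    sem_b = float(db.std(ddof=1) / math.sqrt(db.size))
    diff = mean_a - mean_b
    exact = False
    if np.ptp(da) == 0 and np.ptp(db) == 0:
        if diff == 0:
            t, p = 0.0, 1.0
        else:
            t, p, exact = float(np.sign(diff) * np.inf), 0.0, True
    else:
        t, p = stats.ttest_ind(da, db, equal_var=True)
        t, p = float(t), float(p)
    return ClassDistanceStats(
        mean_a=mean_a, sem_a=sem_a, n_a=int(da.size),
        mean_b=mean_b, sem_b=sem_b, n_b=int(db.size),
        mean_difference=diff, t_stat=t, p_value=p, exact_separation=exact,
    )


def distance_activity_regression(
    distances: Mapping[str, float],
    activities: Mapping[str, float],
    mapping: Mapping[str, str],
) -> tuple[RegressionResult, int]:
    """Regress cellular activity on a structural distance feature.

    ``mapping`` takes structure_id → ligand_id. Structures without a mapped
    ligand activity are excluded; the count of exclusions is returned with
    the fit (distance is the predictor, activity the response).
    """
    xs, ys = [], []
    skipped = 0
    for sid, d in distances.items():
        lid = mapping.get(sid)
        if lid is None or lid not in activities:
            skipped += 1
            continue
        xs.append(d)
        ys.append(activities[lid])
    if len(xs) < 3:
        raise StructureError(f"need >= 3 mapped structure-activity pairs, got {len(xs)}")
    if np.ptp(xs) == 0:
        # constant distance feature explains nothing
        fit = RegressionResult(
            slope=0.0, intercept=float(np.mean(ys)), r2=0.0, p_value=1.0,
            n=len(xs), predictor="distance", response="activity",
        )
        return fit, skipped
    return fit_simple_regression(xs, ys, predictor="distance", response="activity"), skipped


def ligand_dimension(
    model: StructureModel, component_code: str, atom_a: str, atom_b: str
) -> float:
    """Distance (Å) between two named atoms of a bound ligand component.

    E.g. the phenolic-oxygen span of a diphenyl ligand, ~12 Å for the
    elongated thiophene class vs ~10 Å for steroid-like agonists.
    """
    for chain in model.chains.values():
        for lig in chain.ligands:
            if lig.component_code != component_code:
                continue
            missing = [a for a in (atom_a, atom_b) if a not in lig.atoms]
            if missing:
                raise StructureError(
                    f"{model.structure_id} ligand {component_code}: missing atoms "
                    + ", ".join(missing)
                )
            return float(np.linalg.norm(lig.atoms[atom_a].pos - lig.atoms[atom_b].pos))
    raise StructureError(f"{model.structure_id}: no ligand component {component_code!r}")


def distance_table(
    models: Sequence[StructureModel],
    pair: AtomPairSpec,
    chain_policy: str = "each_chain",
) -> str:
    """TSV of per-structure (per-chain) distances for one atom pair."""
    lines = ["structure_id\tchain\tpair\tdistance_A"]
    for m in models:
        d = atom_pair_distance(m, pair, chain_policy="each_chain")
        for ch, v in sorted(d.items()):
            lines.append(f"{m.structure_id}\t{ch}\t{pair}\t{v!r}")
    return "\n".join(lines) + "\n"
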