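"""Data model and I/O for ligand libraries and multi-assay activity panels.

An :class:`ActivityPanel` holds a ligand × assay matrix of efficacies
expressed as percent of the reference agonist (17β-estradiol, E2): vehicle
maps to 0%, E2 to 100%, inverse agonism is negative, superagonism exceeds
100. Missing measurements stay missing (NaN) and shrink ``n`` downstream;
nothing is imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MODULATOR_TYPES = ("direct", "indirect")
CELL_CONTEXTS = ("HepG2", "Ishikawa", "MCF7", "HEK293T", "other")
CONSTRUCTS = ("ERalpha_WT", "ERalpha_dAB", "ERalpha_dF", "ERbeta", "endogenous")
READOUTS = ("luciferase", "mRNA", "M2H", "proliferation", "chip_occupancy")

#: metadata columns of an activity table; every other column is an assay
META_COLUMNS = ("ligand_id", "scaffold", "modulator_type")


class PanelError(ValueError):
    """Malformed ligand library or activity table."""


@dataclass(frozen=True)
class LigandRecord:
    """One library compound with its scaffold (chemical class) label."""

    ligand_id: str
    scaffold: str
    modulator_type: str = "indirect"

    def __post_init__(self) -> None:
        if not self.ligand_id:
            raise PanelError("ligand_id must be non-empty")
        if not self.scaffold:
            raise PanelError(f"ligand {self.ligand_id!r}: scaffold must be non-empty")
        if self.modulator_type not in MODULATOR_TYPES:
            raise PanelError(
                f"ligand {self.ligand_id!r}: modulator_type {self.modulator_type!r} "
                f"not one of {MODULATOR_TYPES}"
            )


@dataclass(frozen=True)
class AssayDescriptor:
    """Metadata for one screening assay (cell context, receptor construct, readout)."""

    assay_id: str
    cell_context: str = "other"
    construct: str = "endogenous"
    readout: str = "luciferase"

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise PanelError("assay_id must be non-empty")
        if self.cell_context not in CELL_CONTEXTS:
            raise PanelError(
                f"assay {self.assay_id!r}: cell_context {self.cell_context!r} "
                f"not one of {CELL_CONTEXTS}"
            )
        if self.construct not in CONSTRUCTS:
            raise PanelError(
                f"assay {self.assay_id!r}: construct {self.construct!r} "
                f"not one of {CONSTRUCTS}"
            )
        if self.readout not in READOUTS:
            raise PanelError(
                f"assay {self.assay_id!r}: readout {self.readout!r} "
                f"not one of {READOUTS}"
            )


@dataclass
class RawControlSet:
    """Raw vehicle and reference-agonist (E2) replicate signals for one assay."""

    vehicle_replicates: np.ndarray
    reference_replicates: np.ndarray

    def __post_init__(self) -> None:
        self.vehicle_replicates = np.asarray(self.vehicle_replicates, dtype=float)
        self.reference_replicates = np.asarray(self.reference_replicates, dtype=float)
        for name, arr in (
            ("vehicle_replicates", self.vehicle_replicates),
            ("reference_replicates", self.reference_replicates),
        ):
            if arr.size < 2:
                raise PanelError(f"{name}: need >= 2 replicates for SD, got {arr.size}")
            if not np.all(np.isfinite(arr)):
                raise PanelError(f"{name}: non-finite values")


@dataclass
class ActivityPanel:
    """Ligand × assay efficacy matrix (% of E2) with library and assay metadata.

    ``values`` is a DataFrame indexed by ligand_id with one column per
    assay_id; NaN marks a missing measurement.
    """

    ligands: list[LigandRecord]
    assays: list[AssayDescriptor]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [lg.ligand_id for lg in self.ligands]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate ligand_id: {', '.join(dup)}")
        aids = [a.assay_id for a in self.assays]
        if len(set(aids)) != len(aids):
            dup = sorted({a for a in aids if aids.count(a) > 1})
            raise PanelError(f"duplicate assay_id: {', '.join(dup)}")
        if list(self.values.index) != ids or list(self.values.columns) != aids:
            raise PanelError("values matrix does not match ligand/assay lists")
        vals = self.values.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise PanelError("non-finite (infinite) activity values")
        self.values = self.values.astype(float)

    @property
    def scaffolds(self) -> list[str]:
        """Scaffold names in order of first appearance."""
        seen: dict[str, None] = {}
        for lg in self.ligands:
            seen.setdefault(lg.scaffold, None)
        return list(seen)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def ligand_ids_for(self, scaffold: str) -> list[str]:
        return [lg.ligand_id for lg in self.ligands if lg.scaffold == scaffold]

    def scaffold_values(self, scaffold: str, assay_id: str) -> pd.Series:
        """Values of one assay restricted to one scaffold (NaNs retained)."""
        if scaffold not in self.scaffolds:
            raise PanelError(f"unknown scaffold {scaffold!r}")
        if assay_id not in self.values.columns:
            raise PanelError(f"unknown assay_id {assay_id!r}")
        return self.values.loc[self.ligand_ids_for(scaffold), assay_id]


@dataclass(frozen=True)
class ClassSummary:
    """Mean ± SD/SEM of one scaffold's efficacies in one assay."""

    scaffold: str
    assay_id: str
    mean: float
    sd: float
    sem: float
    n: int


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_activity_table(
    path: str | Path,
    dialect: str | None = None,
    assay_metadata: str | Path | Mapping[str, AssayDescriptor] | None = None,
) -> ActivityPanel:
    """Read a ligand × assay activity table (CSV/TSV) into an :class:`ActivityPanel`.

    The header row names the assays; ``ligand_id``, ``scaffold`` and
    (optionally) ``modulator_type`` columns carry library metadata. Empty
    cells become missing values — never zero. ``assay_metadata`` may be a
    CSV/TSV with columns assay_id, cell_context, construct, readout, or a
    ready mapping; assays without metadata get permissive defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(
        path, sep=sep, dtype={"ligand_id": str, "scaffold": str},
        float_precision="round_trip",
    )
    for col in ("ligand_id", "scaffold"):
        if col not in df.columns:
            raise PanelError(f"{path.name}: required column {col!r} absent")
    dup = df["ligand_id"][df["ligand_id"].duplicated()]
    if len(dup):
        raise PanelError(
            f"{path.name}: duplicate ligand_id: {', '.join(sorted(set(dup)))}"
        )

    meta: dict[str, AssayDescriptor] = {}
    if isinstance(assay_metadata, (str, Path)):
        mpath = Path(assay_metadata)
        mdf = pd.read_csv(mpath, sep=_infer_sep(mpath, None))
        for row in mdf.to_dict("records"):
            d = AssayDescriptor(
                assay_id=str(row["assay_id"]),
                cell_context=str(row.get("cell_context", "other")),
                construct=str(row.get("construct", "endogenous")),
                readout=str(row.get("readout", "luciferase")),
            )
            meta[d.assay_id] = d
    elif assay_metadata is not None:
        meta = dict(assay_metadata)

    mod = (
        df["modulator_type"].astype(str)
        if "modulator_type" in df.columns
        else pd.Series(["indirect"] * len(df))
    )
    ligands = [
        LigandRecord(str(lid), str(scf), str(mt))
        for lid, scf, mt in zip(df["ligand_id"], df["scaffold"], mod)
    ]
    assay_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not assay_cols:
        raise PanelError(f"{path.name}: no assay columns found")
    assays = [meta.get(c, AssayDescriptor(assay_id=c)) for c in assay_cols]
    values = df[assay_cols].apply(pd.to_numeric, errors="raise")
    values.index = pd.Index([lg.ligand_id for lg in ligands], name="ligand_id")
    return ActivityPanel(ligands=ligands, assays=assays, values=values)


def normalize_to_reference(
    raw: pd.DataFrame,
    controls: Mapping[str, RawControlSet],
    ligands: Sequence[LigandRecord],
    assays: Sequence[AssayDescriptor] | None = None,
) -> ActivityPanel:
    """Convert raw signals to % efficacy relative to the reference agonist.

    value = 100 · (raw − mean(vehicle)) / (mean(reference) − mean(vehicle)),
    per assay, so vehicle replicates map to mean 0 and reference replicates
    to mean 100. Control means are used (not medians).
    """
    if assays is None:
        assays = [AssayDescriptor(assay_id=c) for c in raw.columns]
    out = {}
    for a in assays:
        if a.assay_id not in controls:
            raise PanelError(f"no controls for assay {a.assay_id!r}")
        ctl = controls[a.assay_id]
        mu_v = float(np.mean(ctl.vehicle_replicates))
        mu_r = float(np.mean(ctl.reference_replicates))
        window = mu_r - mu_v
        if window == 0.0:
            raise PanelError(f"assay {a.assay_id!r}: degenerate control window")
        out[a.assay_id] = 100.0 * (raw[a.assay_id].astype(float) - mu_v) / window
    values = pd.DataFrame(out, index=raw.index)
    values.index = pd.Index([lg.ligand_id for lg in ligands], name="ligand_id")
    return ActivityPanel(ligands=list(ligands), assays=list(assays), values=values)


def class_summary(panel: ActivityPanel, scaffold: str, assay_id: str) -> ClassSummary:
    """Mean, sample SD (n−1), SEM and n over one scaffold's non-missing values."""
    vals = panel.scaffold_values(scaffold, assay_id).dropna().to_numpy(dtype=float)
    n = vals.size
    if n == 0:
        raise PanelError(
            f"scaffold {scaffold!r} has no non-missing values in assay {assay_id!r}"
        )
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    sem = sd / math.sqrt(n)
    return ClassSummary(scaffold=scaffold, assay_id=assay_id, mean=mean, sd=sd, sem=sem, n=n)


def write_panel(panel: ActivityPanel, path: str | Path) -> Path:
    """Write a panel as TSV plus a JSON sidecar with assay/ligand metadata.

    Returns the table path; the sidecar is written next to it as
    ``<name>.meta.json``. ``load_activity_table`` round-trips the values
    bit-for-bit (floats serialized with repr precision).
    """
    path = Path(path)
    df = panel.values.copy()
    df.insert(0, "ligand_id", [lg.ligand_id for lg in panel.ligands])
    df.insert(1, "scaffold", [lg.scaffold for lg in panel.ligands])
    df.insert(2, "modulator_type", [lg.modulator_type for lg in panel.ligands])
    df.to_csv(path, sep="\t", index=False, float_format=None)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = {
        "assays": [vars(a) for a in panel.assays],
        "n_ligands": len(panel.ligands),
        "n_missing": panel.n_missing,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path
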