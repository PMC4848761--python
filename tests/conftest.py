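import numpy as np
import pandas as pd
import pytest

from erprofiler.ligand_data import ActivityPanel, AssayDescriptor, LigandRecord


def make_panel(columns: dict[str, list[float]], scaffolds: list[str] | None = None) -> ActivityPanel:
    """Small in-memory panel; one ligand per row, generic assay metadata."""
    n = len(next(iter(columns.values())))
    scaffolds = scaffolds or ["SCF"] * n
    ligands = [LigandRecord(f"L{i:02d}", scaffolds[i]) for i in range(n)]
    assays = [AssayDescriptor(a) for a in columns]
    values = pd.DataFrame(columns, index=pd.Index([lg.ligand_id for lg in ligands], name="ligand_id"), dtype=float)
    return ActivityPanel(ligands=ligands, assays=assays, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
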