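import numpy as np
import pytest

from msmbind import (
    Replica,
    Topology,
    ToyComplexSpec,
    TrajectoryEnsemble,
    generate_toy_complex,
)


@pytest.fixture
def simple_topology() -> Topology:
    """11-residue peptide, ligand with N + 2 C + 1 H, donor/acceptor annotated."""
    return Topology(
        residue_labels=[f"RES{i}" for i in range(11)],
        ligand_atom_names=["N1", "C1", "C2", "H1"],
        ligand_roles=["central_N", "ligand_C", "ligand_C", "ligand_H"],
        peptide_masses=np.full(11, 12.011),
        ligand_masses=np.array([14.007, 12.011, 12.011, 1.008]),
        ligand_donors=[(0, 3)],
        peptide_acceptors=[0, 1],
    )


def make_ensemble(
    topology: Topology,
    peptide_xyz: np.ndarray,
    ligand_frames: np.ndarray,
    box_edge: float = 50.0,
    frame_spacing: float = 1.0,
) -> TrajectoryEnsemble:
    """One-replica ensemble from explicit ligand frames (n_frames, n_atoms, 3)."""
    rep = Replica(
        peptide_xyz=peptide_xyz,
        ligand_xyz=np.asarray(ligand_frames, float),
        box_lengths=np.full(3, box_edge),
    )
    return TrajectoryEnsemble(topology=topology, replicas=[rep], frame_spacing=frame_spacing)


@pytest.fixture
def linear_peptide() -> np.ndarray:
    """11 Cα beads on the x-axis, 3.8 Å apart, starting at the origin."""
    coords = np.zeros((11, 3))
    coords[:, 0] = np.arange(11) * 3.8
    return coords


@pytest.fixture(scope="session")
def small_toy_run():
    """A modest toy-complex ensemble reused by several tests (session scope)."""
    spec = ToyComplexSpec(well_depth=2.0, n_steps=6000, n_replicas=6, seed=42)
    return spec, generate_toy_complex(spec)
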