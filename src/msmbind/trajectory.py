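"""In-memory trajectory container shared by synthetic and real MD data.

A :class:`TrajectoryEnsemble` holds replicated trajectories of one peptide
(represented by its Cα atoms) plus one small-molecule ligand whose atoms are
annotated with roles (``central_N``, ``ligand_C``, ``ligand_H``, ``other``).
Each replica carries per-frame coordinates in Å and an orthorhombic box;
the ensemble carries the frame spacing in ps.

Distances are always computed under the minimum-image convention for
orthorhombic boxes; triclinic cells are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLE_CENTRAL_N = "central_N"
ROLE_LIGAND_C = "ligand_C"
ROLE_LIGAND_H = "ligand_H"
ROLE_OTHER = "other"

_KNOWN_ROLES = {ROLE_CENTRAL_N, ROLE_LIGAND_C, ROLE_LIGAND_H, ROLE_OTHER}


def minimum_image(deltas: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    deltas
        Array of displacement vectors, shape ``(..., 3)``, in Å.
    box_lengths
        Orthorhombic box edge lengths, shape ``(3,)`` or broadcastable
        to ``deltas``.
    """
    deltas = np.asarray(deltas, dtype=float)
    box = np.asarray(box_lengths, dtype=float)
    return deltas - box * np.round(deltas / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between point sets ``a`` and ``b``."""
    d = minimum_image(np.asarray(a, float) - np.asarray(b, float), box_lengths)
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class Topology:
    """Atom-role annotations shared by every replica of an ensemble.

    The peptide is represented by one Cα bead per residue.  H-bond
    annotations are explicit: ``ligand_donors`` lists (heavy-atom, hydrogen)
    index pairs into the ligand atoms, ``peptide_acceptors`` lists residue
    indices whose Cα bead can accept a hydrogen bond.  Masses are optional;
    centre-of-mass computations fall back to geometric centres without them.
    """

    residue_labels: list[str]
    ligand_atom_names: list[str]
    ligand_roles: list[str]
    peptide_masses: np.ndarray | None = None
    ligand_masses: np.ndarray | None = None
    ligand_donors: list[tuple[int, int]] = field(default_factory=list)
    peptide_acceptors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ligand_atom_names) != len(self.ligand_roles):
            raise ValueError("ligand_atom_names and ligand_roles must have equal length")
        bad = set(self.ligand_roles) - _KNOWN_ROLES
        if bad:
            raise ValueError(f"unknown ligand roles: {sorted(bad)}")
        for res in self.peptide_acceptors:
            if not 0 <= res < self.n_residues:
                raise ValueError(f"peptide acceptor residue {res} out of range")
        for heavy, hyd in self.ligand_donors:
            for idx in (heavy, hyd):
                if not 0 <= idx < len(self.ligand_atom_names):
                    raise ValueError(f"ligand donor atom index {idx} out of range")

    @property
    def n_residues(self) -> int:
        return len(self.residue_labels)

    @property
    def central_n_index(self) -> int:
        """Index of the ligand's central nitrogen; error if missing."""
        idx = [i for i, r in enumerate(self.ligand_roles) if r == ROLE_CENTRAL_N]
        if not idx:
            raise ValueError("topology has no ligand atom with role 'central_N'")
        return idx[0]

    @property
    def ligand_carbon_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.ligand_roles) if r == ROLE_LIGAND_C]


@dataclass
class Replica:
    """One contiguous trajectory: per-frame peptide and ligand coordinates.

    ``peptide_xyz`` may be ``(n_frames, n_residues, 3)`` or, for a static
    peptide, ``(n_residues, 3)``.  ``box_lengths`` may be ``(3,)`` (constant
    box) or ``(n_frames, 3)``.
    """

    peptide_xyz: np.ndarray
    ligand_xyz: np.ndarray
    box_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.ligand_xyz = np.asarray(self.ligand_xyz, dtype=float)
        self.peptide_xyz = np.asarray(self.peptide_xyz, dtype=float)
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.ligand_xyz.ndim != 3:
            raise ValueError("ligand_xyz must have shape (n_frames, n_atoms, 3)")
        if self.peptide_xyz.ndim not in (2, 3):
            raise ValueError("peptide_xyz must be (n_res, 3) or (n_frames, n_res, 3)")
        if self.box_lengths.ndim not in (1, 2) or self.box_lengths.shape[-1] != 3:
            raise ValueError("box_lengths must be (3,) or (n_frames, 3)")
        if np.any(self.box_lengths <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.ligand_xyz.shape[0]

    def peptide_frame(self, i: int) -> np.ndarray:
        return self.peptide_xyz if self.peptide_xyz.ndim == 2 else self.peptide_xyz[i]

    def peptide_frames(self) -> np.ndarray:
        """Peptide coordinates broadcast to (n_frames, n_res, 3)."""
        if self.peptide_xyz.ndim == 2:
            return np.broadcast_to(
                self.peptide_xyz, (self.n_frames, *self.peptide_xyz.shape)
            )
        return self.peptide_xyz

    def box_frame(self, i: int) -> np.ndarray:
        return self.box_lengths if self.box_lengths.ndim == 1 else self.box_lengths[i]

    def box_frames(self) -> np.ndarray:
        if self.box_lengths.ndim == 1:
            return np.broadcast_to(self.box_lengths, (self.n_frames, 3))
        return self.box_lengths

    @property
    def box_volumes(self) -> np.ndarray:
        """Per-frame box volume in Å^3."""
        return np.prod(self.box_frames(), axis=-1)


@dataclass
class TrajectoryEnsemble:
    """Replicated trajectories with shared topology and frame spacing (ps)."""

    topology: Topology
    replicas: list[Replica]
    frame_spacing: float

    def __post_init__(self) -> None:
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive (ps)")
        if not self.replicas:
            raise ValueError("ensemble needs at least one replica")
        n_res = self.topology.n_residues
        n_lig = len(self.topology.ligand_atom_names)
        for k, rep in enumerate(self.replicas):
            if rep.peptide_xyz.shape[-2] != n_res:
                raise ValueError(
                    f"replica {k}: peptide has {rep.peptide_xyz.shape[-2]} residues, "
                    f"topology says {n_res}"
                )
            if rep.ligand_xyz.shape[1] != n_lig:
                raise ValueError(
                    f"replica {k}: ligand has {rep.ligand_xyz.shape[1]} atoms, "
                    f"topology says {n_lig}"
                )

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_frames_total(self) -> int:
        return sum(r.n_frames for r in self.replicas)

    def mean_box_volume(self) -> float:
        return float(np.mean(np.concatenate([r.box_volumes for r in self.replicas])))
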