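"""Readers and writers for trajectory ensembles.

Two routes into the same :class:`~msmbind.trajectory.TrajectoryEnsemble`:

* a self-describing ``.npz`` container written by this package (topology as
  embedded JSON, one coordinate block per replica) — the native format of
  the synthetic generators, round-tripping bit-exactly;
* standard MD formats via mdtraj — a PDB topology plus DCD/XTC (or
  multi-frame PDB) coordinate files, one replica per coordinate file.  Atom
  roles are resolved by convention: peptide Cα atoms by name ``CA`` within
  protein residues, the ligand as the sole non-protein, non-water residue, its
  central nitrogen as the first nitrogen and its carbons by element.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .trajectory import (
    ROLE_CENTRAL_N,
    ROLE_LIGAND_C,
    ROLE_LIGAND_H,
    ROLE_OTHER,
    Replica,
    Topology,
    TrajectoryEnsemble,
)

CONTAINER_FORMAT_VERSION = 1


def write_ensemble(ens: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble to the native ``.npz`` container."""
    topo = ens.topology
    meta = {
        "format_version": CONTAINER_FORMAT_VERSION,
        "frame_spacing_ps": ens.frame_spacing,
        "n_replicas": ens.n_replicas,
        "residue_labels": topo.residue_labels,
        "ligand_atom_names": topo.ligand_atom_names,
        "ligand_roles": topo.ligand_roles,
        "ligand_donors": [list(p) for p in topo.ligand_donors],
        "peptide_acceptors": list(topo.peptide_acceptors),
    }
    arrays: dict[str, np.ndarray] = {"meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if topo.peptide_masses is not None:
        arrays["peptide_masses"] = np.asarray(topo.peptide_masses, float)
    if topo.ligand_masses is not None:
        arrays["ligand_masses"] = np.asarray(topo.ligand_masses, float)
    for i, rep in enumerate(ens.replicas):
        arrays[f"rep{i}_peptide"] = rep.peptide_xyz
        arrays[f"rep{i}_ligand"] = rep.ligand_xyz
        arrays[f"rep{i}_box"] = rep.box_lengths
    np.savez_compressed(path, **arrays)


def read_ensemble(path: str | Path) -> TrajectoryEnsemble:
    """Read an ensemble from the native ``.npz`` container."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta.get("format_version") != CONTAINER_FORMAT_VERSION:
            raise ValueError(f"unsupported container version {meta.get('format_version')}")
        topo = Topology(
            residue_labels=list(meta["residue_labels"]),
            ligand_atom_names=list(meta["ligand_atom_names"]),
            ligand_roles=list(meta["ligand_roles"]),
            peptide_masses=data["peptide_masses"] if "peptide_masses" in data else None,
            ligand_masses=data["ligand_masses"] if "ligand_masses" in data else None,
            ligand_donors=[tuple(p) for p in meta["ligand_donors"]],
            peptide_acceptors=list(meta["peptide_acceptors"]),
        )
        replicas = [
            Replica(
                peptide_xyz=data[f"rep{i}_peptide"],
                ligand_xyz=data[f"rep{i}_ligand"],
                box_lengths=data[f"rep{i}_box"],
            )
            for i in range(int(meta["n_replicas"]))
        ]
    return TrajectoryEnsemble(
        topology=topo, replicas=replicas, frame_spacing=float(meta["frame_spacing_ps"])
    )


_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}


def read_trajectories(
    topology_path: str | Path,
    coordinate_paths: list[str | Path] | None = None,
    frame_spacing: float | None = None,
    ligand_resname: str | None = None,
) -> TrajectoryEnsemble:
    """Load an ensemble from standard MD formats (or the native container).

    ``topology_path`` ending in ``.npz`` short-circuits to the container
    reader.  Otherwise mdtraj loads a PDB topology and one replica per
    coordinate file (DCD/XTC/PDB...).  mdtraj stores nanometres; coordinates
    and boxes are converted to Å here.  ``frame_spacing`` (ps) overrides
    whatever the files report; it is required when they report none.
    """
    topology_path = Path(topology_path)
    if topology_path.suffix == ".npz":
        return read_ensemble(topology_path)
    import mdtraj as md

    if not coordinate_paths:
        coordinate_paths = [topology_path]  # multi-frame PDB
    trajs = [md.load(str(p), top=str(topology_path)) for p in coordinate_paths]
    top = trajs[0].topology

    ca_indices = []
    for res in top.residues:
        if res.is_protein:
            cas = [a.index for a in res.atoms if a.name == "CA"]
            if len(cas) != 1:
                raise ValueError(f"residue {res} has {len(cas)} CA atoms; expected 1")
            ca_indices.append((res, cas[0]))
    if not ca_indices:
        raise ValueError("topology contains no protein residues with CA atoms")

    lig_residues = [
        r for r in top.residues
        if not r.is_protein and not r.is_water and r.name not in _WATER_NAMES
        and (ligand_resname is None or r.name == ligand_resname)
    ]
    if len(lig_residues) != 1:
        raise ValueError(
            f"expected exactly one ligand residue, found {[r.name for r in lig_residues]}"
        )
    lig = lig_residues[0]
    lig_atoms = list(lig.atoms)
    nitrogens = [a for a in lig_atoms if a.element is not None and a.element.symbol == "N"]
    if not nitrogens:
        raise ValueError(
            f"ligand residue {lig.name} has no nitrogen to serve as role '{ROLE_CENTRAL_N}'"
        )
    roles = []
    for a in lig_atoms:
        sym = a.element.symbol if a.element is not None else "?"
        if a.index == nitrogens[0].index:
            roles.append(ROLE_CENTRAL_N)
        elif sym == "C":
            roles.append(ROLE_LIGAND_C)
        elif sym == "H":
            roles.append(ROLE_LIGAND_H)
        else:
            roles.append(ROLE_OTHER)

    topo = Topology(
        residue_labels=[f"{r.name}{r.resSeq}" for r, _ in ca_indices],
        ligand_atom_names=[a.name for a in lig_atoms],
        ligand_roles=roles,
        peptide_masses=np.array([top.atom(i).element.mass for _, i in ca_indices]),
        ligand_masses=np.array(
            [a.element.mass if a.element is not None else 0.0 for a in lig_atoms]
        ),
    )
    ca_idx = np.array([i for _, i in ca_indices])
    lig_idx = np.array([a.index for a in lig_atoms])

    replicas = []
    spacing = frame_spacing
    for t in trajs:
        if t.unitcell_lengths is None:
            raise ValueError("trajectory has no box information")
        replicas.append(
            Replica(
                peptide_xyz=t.xyz[:, ca_idx, :] * 10.0,  # nm -> Å
                ligand_xyz=t.xyz[:, lig_idx, :] * 10.0,
                box_lengths=t.unitcell_lengths * 10.0,
            )
        )
        if spacing is None and t.timestep > 0:
            spacing = float(t.timestep)
    if spacing is None:
        raise ValueError("frame spacing not recoverable from files; pass frame_spacing")
    return TrajectoryEnsemble(topology=topo, replicas=replicas, frame_spacing=spacing)


def export_pdb_dcd(ens: TrajectoryEnsemble, out_dir: str | Path, stem: str = "replica") -> list[Path]:
    """Write an ensemble as a PDB topology plus one DCD file per replica.

    The peptide is emitted as one ALA residue per Cα bead; ligand atoms keep
    their names and elements.  Returns the paths written (topology first).
    Coordinates convert from Å to mdtraj's nm internally.
    """
    import mdtraj as md
    from mdtraj.core import element as elem

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topo_in = ens.topology
    top = md.Topology()
    chain = top.add_chain()
    for i in range(topo_in.n_residues):
        res = top.add_residue("ALA", chain, resSeq=i + 1)
        top.add_atom("CA", elem.carbon, res)
    lig_res = top.add_residue("LIG", chain, resSeq=topo_in.n_residues + 1)
    role_elem = {
        ROLE_CENTRAL_N: elem.nitrogen,
        ROLE_LIGAND_C: elem.carbon,
        ROLE_LIGAND_H: elem.hydrogen,
        ROLE_OTHER: elem.carbon,
    }
    for name, role in zip(topo_in.ligand_atom_names, topo_in.ligand_roles):
        top.add_atom(name, role_elem[role], lig_res)

    paths: list[Path] = []
    pdb_path = out / f"{stem}.pdb"
    first = ens.replicas[0]
    xyz0 = np.concatenate([first.peptide_frame(0), first.ligand_xyz[0]], axis=0)
    md.Trajectory(
        xyz0[None] / 10.0, top,
        unitcell_lengths=first.box_frame(0)[None] / 10.0,
        unitcell_angles=np.array([[90.0, 90.0, 90.0]]),
    ).save_pdb(str(pdb_path))
    paths.append(pdb_path)
    for i, rep in enumerate(ens.replicas):
        xyz = np.concatenate([rep.peptide_frames(), rep.ligand_xyz], axis=1) / 10.0
        traj = md.Trajectory(
            xyz, top,
            time=np.arange(rep.n_frames) * ens.frame_spacing,
            unitcell_lengths=rep.box_frames() / 10.0,
            unitcell_angles=np.full((rep.n_frames, 3), 90.0),
        )
        dcd_path = out / f"{stem}_{i}.dcd"
        traj.save_dcd(str(dcd_path))
        paths.append(dcd_path)
    return paths
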