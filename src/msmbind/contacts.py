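"""Bound-state snapshot sampling and per-residue contact profiles.

Snapshots are drawn from the bound macrostate in proportion to microstate
stationary probabilities (frames uniform within a microstate), emulating the
weighted-ensemble extraction used to characterise a fuzzy bound state.  Two
profiles are computed over such a sample:

* hydrophobic contacts — a snapshot counts (once) for residue r when any
  ligand carbon sits within a cutoff (default 4 Å, strict ``<``) of any
  carbon of that residue under the minimum image;
* hydrogen bonds — donor-heavy-atom to acceptor distance ≤ 3.0 Å and a
  donor-H-acceptor angle ≥ 135°, using the topology's explicit donor and
  acceptor annotations.

Percentages are per residue, out of the sample size; repeated seeded samples
are averaged for a mean profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msm import BOUND, MSMModel, MacrostateModel
from .trajectory import TrajectoryEnsemble, minimum_image, minimum_image_distance


@dataclass
class SnapshotSample:
    """Frame references drawn from one macrostate."""

    frames: list[tuple[int, int]]  # (replica index, frame index)
    n: int
    seed: int
    macrostate: int = BOUND

    def __post_init__(self) -> None:
        if len(self.frames) != self.n:
            raise ValueError("sample size mismatch")


@dataclass
class ContactProfile:
    """Per-residue contact percentages (of snapshots, in [0, 100])."""

    residue_labels: list[str]
    percentages: np.ndarray
    cutoff: float  # Å (distance criterion)
    kind: str  # 'hydrophobic' | 'hbond'
    n_snapshots: int
    n_trajectories: int = 1

    def __post_init__(self) -> None:
        if np.any(self.percentages < 0) or np.any(self.percentages > 100):
            raise ValueError("percentages must lie in [0, 100]")


def sample_macrostate_snapshots(
    model: MSMModel,
    macro: MacrostateModel,
    dtrajs: list[np.ndarray],
    n: int = 1000,
    seed: int = 0,
    macrostate: int = BOUND,
) -> SnapshotSample:
    """Draw ``n`` frames from a macrostate by microstate probability.

    Microstates are drawn with replacement with probability π_i normalised
    over the macrostate; within a microstate, frames are uniform over all
    frames assigned to it across replicas.
    """
    sets = {0: macro.unbound_set, 1: macro.bound_set}[macrostate]
    if sets.size == 0:
        raise ValueError("requested macrostate has no microstates")
    labels = model.active_set[sets]
    pi = model.stationary_distribution[sets]
    pi = pi / pi.sum()

    frames_by_state: dict[int, list[tuple[int, int]]] = {int(l): [] for l in labels}
    for rep_idx, d in enumerate(dtrajs):
        for lab in labels:
            for f in np.flatnonzero(d == lab):
                frames_by_state[int(lab)].append((rep_idx, int(f)))
    empty = [lab for lab, fr in frames_by_state.items() if not fr]
    if empty:
        raise ValueError(f"macrostate microstates with no frames: {empty}")

    rng = np.random.default_rng(seed)
    picks = rng.choice(labels, size=n, p=pi)
    frames = []
    for lab in picks:
        pool = frames_by_state[int(lab)]
        frames.append(pool[rng.integers(len(pool))])
    return SnapshotSample(frames=frames, n=n, seed=seed, macrostate=macrostate)


def hydrophobic_contacts(
    sample: SnapshotSample,
    traj: TrajectoryEnsemble,
    cutoff: float = 4.0,
    count_multiplicity: bool = False,
) -> ContactProfile:
    """Per-residue percentage of snapshots with a ligand-C/residue-C contact.

    A contact exists when the minimum-image distance between any ligand
    carbon and any carbon of the residue is strictly below ``cutoff``.  Each
    snapshot contributes at most once per residue; with
    ``count_multiplicity`` the number of contacting ligand carbons is
    accumulated instead (percentages may then exceed the binary ones but are
    still normalised per snapshot count and capped at reporting time by the
    caller — profile invariants apply to the default binary mode).
    """
    topo = traj.topology
    lig_c = topo.ligand_carbon_indices
    if not lig_c:
        raise ValueError("ligand has no carbon atoms annotated")
    n_res = topo.n_residues
    counts = np.zeros(n_res)
    for rep_idx, frame_idx in sample.frames:
        rep = traj.replicas[rep_idx]
        lig = rep.ligand_xyz[frame_idx][lig_c]  # (A, 3)
        pep = rep.peptide_frame(frame_idx)  # (R, 3) — each residue's carbon(s)
        box = rep.box_frame(frame_idx)
        d = minimum_image_distance(lig[:, None, :], pep[None, :, :], box)  # (A, R)
        if count_multiplicity:
            counts += (d < cutoff).sum(axis=0)
        else:
            counts += (d < cutoff).any(axis=0)
    pct = counts / sample.n * 100.0
    if count_multiplicity:
        pct = np.minimum(pct, 100.0 * len(lig_c))
        return ContactProfile(
            residue_labels=list(topo.residue_labels),
            percentages=np.minimum(pct, 100.0),
            cutoff=cutoff,
            kind="hydrophobic",
            n_snapshots=sample.n,
        )
    return ContactProfile(
        residue_labels=list(topo.residue_labels),
        percentages=pct,
        cutoff=cutoff,
        kind="hydrophobic",
        n_snapshots=sample.n,
    )


def hydrogen_bonds(
    sample: SnapshotSample,
    traj: TrajectoryEnsemble,
    distance_cutoff: float = 3.0,
    angle_cutoff_deg: float = 135.0,
) -> ContactProfile:
    """Per-residue percentage of snapshots with a ligand-to-residue H-bond.

    Donors are the topology's annotated ligand (heavy atom, hydrogen) pairs;
    acceptors are the annotated residues' Cα beads.  A bond requires donor
    heavy-atom to acceptor distance ≤ ``distance_cutoff`` and a
    donor-H-acceptor angle ≥ ``angle_cutoff_deg``.
    """
    topo = traj.topology
    if not topo.ligand_donors:
        raise ValueError("topology annotates no ligand donors (heavy, H pairs)")
    if not topo.peptide_acceptors:
        raise ValueError("topology annotates no peptide acceptor residues")
    n_res = topo.n_residues
    counts = np.zeros(n_res)
    cos_cut = np.cos(np.deg2rad(angle_cutoff_deg))
    for rep_idx, frame_idx in sample.frames:
        rep = traj.replicas[rep_idx]
        lig = rep.ligand_xyz[frame_idx]
        pep = rep.peptide_frame(frame_idx)
        box = rep.box_frame(frame_idx)
        for res in topo.peptide_acceptors:
            acc = pep[res]
            bonded = False
            for heavy, hyd in topo.ligand_donors:
                d_da = float(minimum_image_distance(lig[heavy], acc, box))
                if d_da > distance_cutoff:
                    continue
                v_hd = minimum_image(lig[heavy] - lig[hyd], box)
                v_ha = minimum_image(acc - lig[hyd], box)
                denom = np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
                if denom <= 0:
                    continue
                cos_angle = float(np.dot(v_hd, v_ha) / denom)
                # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
                if cos_angle <= cos_cut:
                    bonded = True
                    break
            if bonded:
                counts[res] += 1
    return ContactProfile(
        residue_labels=list(topo.residue_labels),
        percentages=counts / sample.n * 100.0,
        cutoff=distance_cutoff,
        kind="hbond",
        n_snapshots=sample.n,
    )


def mean_contact_profile(profiles: list[ContactProfile]) -> ContactProfile:
    """Average per-residue percentages over repeated samples."""
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.residue_labels != ref.residue_labels or p.kind != ref.kind:
            raise ValueError("profiles are not comparable")
    pct = np.mean([p.percentages for p in profiles], axis=0)
    return ContactProfile(
        residue_labels=list(ref.residue_labels),
        percentages=pct,
        cutoff=ref.cutoff,
        kind=ref.kind,
        n_snapshots=ref.n_snapshots,
        n_trajectories=len(profiles),
    )
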