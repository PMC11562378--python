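"""Synthetic binding trajectories with analytically known ground truth.

Two generators stand in for long all-atom MD of a small molecule binding
reversibly to a disordered 11-residue peptide:

* :func:`generate_discrete_chain` samples microstate-index trajectories from
  a known row-stochastic matrix, for validating the estimator stack end to
  end against exact stationary and kinetic quantities.

* :func:`generate_toy_complex` runs Metropolis Monte Carlo of a rigid
  4-heavy-atom ligand (one central nitrogen, three carbons, plus an amide-like
  hydrogen) diffusing in a periodic cubic box around a fixed bead-per-residue
  peptide.  The interaction is a square well: the energy is ``-well_depth``
  whenever the ligand nitrogen lies within ``well_radius`` of any "sticky"
  bead, else zero.  Because Metropolis sampling with a symmetric proposal is
  exact, the stationary bound probability and hence the standard binding free
  energy are computable by quadrature (:func:`ground_truth_dg`), giving a
  ground truth the full analysis pipeline must recover.

The toy ligand keeps a fixed orientation: the square-well energy depends only
on the nitrogen position, so rotational moves would not change any stationary
probability, while a rigid multi-atom geometry still exercises every distance
metric and the contact/H-bond machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import V_STANDARD_A3, kbt
from .trajectory import (
    ROLE_CENTRAL_N,
    ROLE_LIGAND_C,
    ROLE_LIGAND_H,
    Replica,
    Topology,
    TrajectoryEnsemble,
    minimum_image_distance,
)

# Rigid ligand geometry (Å, relative to the central nitrogen): three carbons
# within 2 Å plus one hydrogen bonded to N, annotated as an H-bond donor.
_LIGAND_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],  # N (central)
        [1.4, 0.0, 0.0],  # C
        [-0.7, 1.2, 0.0],  # C
        [-0.7, -1.2, 0.0],  # C
        [0.0, 0.0, 1.0],  # H on N
    ]
)
_LIGAND_NAMES = ["N1", "C1", "C2", "C3", "H1"]
_LIGAND_ROLES = [ROLE_CENTRAL_N, ROLE_LIGAND_C, ROLE_LIGAND_C, ROLE_LIGAND_C, ROLE_LIGAND_H]

#: c-Myc 402-412 residue labels used for the default 11-bead peptide.
MYC_RESIDUE_LABELS = [
    "Tyr402", "Ile403", "Leu404", "Ser405", "Val406", "Gln407",
    "Ala408", "Glu409", "Glu410", "Gln411", "Asp412",
]


@dataclass
class DiscreteChainSpec:
    """A known Markov chain to sample replicated trajectories from."""

    transition_matrix_true: np.ndarray
    n_steps: int
    n_replicas: int
    frame_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix_true, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition_matrix_true must be square")
        if np.any(T < 0):
            raise ValueError("transition_matrix_true has negative entries")
        rowsums = T.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise ValueError(
                f"rows of transition_matrix_true must sum to 1 within 1e-12, got {rowsums}"
            )
        if self.n_steps <= 0 or self.n_replicas <= 0:
            raise ValueError("n_steps and n_replicas must be positive")
        self.transition_matrix_true = T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalised."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmax(vals.real))
    pi = np.abs(vecs[:, i].real)
    return pi / pi.sum()


def generate_discrete_chain(
    spec: DiscreteChainSpec, start: str | np.ndarray = "stationary"
) -> list[np.ndarray]:
    """Sample ``n_replicas`` microstate trajectories of length ``n_steps``.

    ``start`` is ``"stationary"`` (initial states drawn from the chain's
    stationary distribution), ``"uniform"``, or an explicit array of one
    initial state per replica.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.transition_matrix_true
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against rounding

    if isinstance(start, str):
        if start == "stationary":
            p0 = stationary_distribution(T)
        elif start == "uniform":
            p0 = np.full(n, 1.0 / n)
        else:
            raise ValueError(f"unknown start mode {start!r}")
        states = rng.choice(n, size=spec.n_replicas, p=p0)
    else:
        states = np.asarray(start, dtype=int)
        if states.shape != (spec.n_replicas,):
            raise ValueError("explicit start must give one state per replica")

    out = np.empty((spec.n_replicas, spec.n_steps), dtype=np.int64)
    out[:, 0] = states
    u = rng.random((spec.n_steps - 1, spec.n_replicas))
    for t in range(1, spec.n_steps):
        # vectorised inverse-CDF step for all replicas at once
        states = np.array(
            [np.searchsorted(cum[s], ut) for s, ut in zip(states, u[t - 1])]
        )
        out[:, t] = states
    return [out[k] for k in range(spec.n_replicas)]


def _default_peptide_coords(
    n_residues: int, box_edge: float, sticky_indices: tuple[int, ...] = (0, 1, 2)
) -> np.ndarray:
    """A compact helical Cα chain (≈3.6 Å neighbour spacing).

    The chain is placed with the mean of the sticky beads at the box centre
    so the attractive zone sits well inside one periodic image; a chain
    longer than the box edge would otherwise wrap its far end next to the
    binding site.
    """
    t = np.arange(n_residues) * 1.0
    coords = np.stack(
        [1.4 * t, 4.5 * np.sin(0.75 * t), 4.5 * np.cos(0.75 * t)], axis=1
    )
    anchor = coords[list(sticky_indices)].mean(axis=0)
    return coords - anchor + box_edge / 2.0


@dataclass
class ToyComplexSpec:
    """Parameters of the square-well toy peptide-ligand system.

    Defaults emulate the modelled system: an 11-residue disordered peptide
    whose N-terminal residues (402-404) attract the ligand, in a box sized
    to give a ligand concentration of tens of millimolar.
    """

    n_residues: int = 11
    peptide_bead_coords: np.ndarray | None = None
    box_edge: float = 30.0
    well_depth: float = 2.0
    well_radius: float = 8.0
    sticky_residue_indices: tuple[int, ...] = (0, 1, 2)
    temperature: float = 300.0
    diffusion_step: float = 2.0
    n_steps: int = 20_000
    n_replicas: int = 20
    frame_spacing: float = 1.0
    seed: int = 0
    peptide_jitter_sigma: float = 0.0
    start: str = "mixed"  # 'bound' | 'unbound' | 'mixed'

    def __post_init__(self) -> None:
        if self.peptide_bead_coords is None:
            sticky = tuple(i for i in self.sticky_residue_indices if i < self.n_residues)
            self.peptide_bead_coords = _default_peptide_coords(
                self.n_residues, self.box_edge, sticky or (0,)
            )
        self.peptide_bead_coords = np.asarray(self.peptide_bead_coords, dtype=float)
        if self.peptide_bead_coords.shape != (self.n_residues, 3):
            raise ValueError("peptide_bead_coords must have shape (n_residues, 3)")
        if self.diffusion_step <= 0:
            raise ValueError("diffusion_step must be positive")
        if self.well_radius >= self.box_edge / 2.0:
            raise ValueError("well_radius must be smaller than half the box edge")
        if self.box_edge <= 2.0 * self.well_radius:
            raise ValueError("box_edge must exceed twice the well_radius")
        if self.well_depth < 0:
            raise ValueError("well_depth is the magnitude of attraction, must be >= 0")
        bad = [i for i in self.sticky_residue_indices if not 0 <= i < self.n_residues]
        if bad:
            raise ValueError(f"sticky residue indices out of range: {bad}")
        if self.start not in ("bound", "unbound", "mixed"):
            raise ValueError(f"unknown start mode {self.start!r}")

    @property
    def sticky_coords(self) -> np.ndarray:
        return self.peptide_bead_coords[list(self.sticky_residue_indices)]

    def topology(self) -> Topology:
        labels = (
            list(MYC_RESIDUE_LABELS)
            if self.n_residues == len(MYC_RESIDUE_LABELS)
            else [f"RES{i}" for i in range(self.n_residues)]
        )
        return Topology(
            residue_labels=labels,
            ligand_atom_names=list(_LIGAND_NAMES),
            ligand_roles=list(_LIGAND_ROLES),
            peptide_masses=np.full(self.n_residues, 12.011),
            ligand_masses=np.array([14.007, 12.011, 12.011, 12.011, 1.008]),
            ligand_donors=[(0, 4)],
            peptide_acceptors=list(self.sticky_residue_indices),
        )


@dataclass
class GroundTruth:
    """Exact stationary quantities of a :class:`ToyComplexSpec`."""

    dG_standard_true: float  # kcal/mol
    pi_bound_true: float
    V_bound_true: float  # Å^3
    V_unbound_true: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_bound_true < 1.0:
            raise ValueError("pi_bound_true must lie strictly between 0 and 1")


def bound_zone_volume(spec: ToyComplexSpec, grid_spacing: float = 0.25) -> float:
    """Volume (Å^3) of the union of sticky spheres, by grid quadrature.

    The grid covers one periodic cell; distances use the minimum image, so
    spheres crossing the boundary are handled exactly.
    """
    n = int(np.ceil(spec.box_edge / grid_spacing))
    h = spec.box_edge / n
    ax = (np.arange(n) + 0.5) * h
    # evaluate slab by slab to bound memory
    sticky = spec.sticky_coords
    count = 0
    yz = np.stack(np.meshgrid(ax, ax, indexing="ij"), axis=-1).reshape(-1, 2)
    for x in ax:
        pts = np.concatenate([np.full((yz.shape[0], 1), x), yz], axis=1)
        d = minimum_image_distance(
            pts[:, None, :], sticky[None, :, :], np.full(3, spec.box_edge)
        )
        count += int(np.count_nonzero(d.min(axis=1) < spec.well_radius))
    return count * h**3


def ground_truth_dg(spec: ToyComplexSpec, grid_spacing: float = 0.25) -> GroundTruth:
    """Exact bound probability and standard binding free energy of the toy.

    With a square well the configurational integral factorises:
    ``pi_bound = V_b e^{w/kBT} / (V_b e^{w/kBT} + V_u)`` with ``V_b`` the
    sticky-sphere union volume and ``V_u`` the rest of the box.  The standard
    free energy applies the usual dilute-solution volume correction,
    ``dG = -kBT ln(pi_b/pi_u) - kBT ln(V_u/V°)`` with V° = 1660 Å^3.
    """
    kT = kbt(spec.temperature)
    v_b = bound_zone_volume(spec, grid_spacing)
    v_box = spec.box_edge**3
    v_u = v_box - v_b
    if v_b <= 0 or v_u <= 0:
        raise ValueError("degenerate bound-zone volume")
    w = np.exp(spec.well_depth / kT)
    pi_b = v_b * w / (v_b * w + v_u)
    dg = -kT * np.log(pi_b / (1.0 - pi_b)) - kT * np.log(v_u / V_STANDARD_A3)
    return GroundTruth(
        dG_standard_true=float(dg),
        pi_bound_true=float(pi_b),
        V_bound_true=float(v_b),
        V_unbound_true=float(v_u),
    )


def _is_bound(n_pos: np.ndarray, sticky: np.ndarray, box: np.ndarray, radius: float) -> np.ndarray:
    """Boolean bound flag for nitrogen positions, shape (..., 3) -> (...)."""
    d = minimum_image_distance(n_pos[..., None, :], sticky, box)
    return d.min(axis=-1) < radius


def generate_toy_complex(spec: ToyComplexSpec) -> TrajectoryEnsemble:
    """Metropolis Monte Carlo sampling of the square-well toy complex.

    All replicas are propagated in parallel with independent proposals drawn
    from one seeded generator; every MC step is recorded as one frame with
    nominal spacing ``spec.frame_spacing`` ps.  Proposals are uniform cube
    displacements of half-width ``diffusion_step``; the symmetric proposal
    plus Metropolis acceptance makes the recorded ensemble an exact sample
    of the Boltzmann distribution of the square well.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.full(3, float(spec.box_edge))
    sticky = spec.sticky_coords
    beta = 1.0 / kbt(spec.temperature)
    n_rep, n_steps = spec.n_replicas, spec.n_steps

    # initial nitrogen positions
    if spec.start == "unbound":
        want_bound = np.zeros(n_rep, dtype=bool)
    elif spec.start == "bound":
        want_bound = np.ones(n_rep, dtype=bool)
    else:
        want_bound = np.arange(n_rep) % 2 == 0
    pos = np.empty((n_rep, 3))
    for k in range(n_rep):
        if want_bound[k]:
            centre = sticky[rng.integers(len(sticky))]
            while True:
                trial = centre + rng.uniform(-spec.well_radius, spec.well_radius, 3)
                if minimum_image_distance(trial, centre, box) < spec.well_radius:
                    pos[k] = trial % spec.box_edge
                    break
        else:
            while True:
                trial = rng.uniform(0.0, spec.box_edge, 3)
                if not _is_bound(trial, sticky, box, spec.well_radius):
                    pos[k] = trial
                    break

    bound = _is_bound(pos, sticky, box, spec.well_radius)
    n_traj = np.empty((n_rep, n_steps, 3))
    accept_boltz = np.exp(-beta * spec.well_depth)  # unbinding acceptance
    for t in range(n_steps):
        step = rng.uniform(-spec.diffusion_step, spec.diffusion_step, (n_rep, 3))
        trial = (pos + step) % spec.box_edge
        trial_bound = _is_bound(trial, sticky, box, spec.well_radius)
        # dE = 0 except bound -> unbound (+w, accept with exp(-beta w))
        unbinding = bound & ~trial_bound
        acc = np.ones(n_rep, dtype=bool)
        if np.any(unbinding):
            acc[unbinding] = rng.random(int(unbinding.sum())) < accept_boltz
        pos = np.where(acc[:, None], trial, pos)
        bound = np.where(acc, trial_bound, bound)
        n_traj[:, t] = pos

    topo = spec.topology()
    replicas = []
    jitter = spec.peptide_jitter_sigma
    for k in range(n_rep):
        ligand = n_traj[k][:, None, :] + _LIGAND_OFFSETS[None, :, :]
        if jitter > 0:
            pep = spec.peptide_bead_coords[None, :, :] + rng.normal(
                0.0, jitter, (n_steps, spec.n_residues, 3)
            )
        else:
            pep = spec.peptide_bead_coords
        replicas.append(Replica(peptide_xyz=pep, ligand_xyz=ligand, box_lengths=box.copy()))
    return TrajectoryEnsemble(
        topology=topo, replicas=replicas, frame_spacing=spec.frame_spacing
    )
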