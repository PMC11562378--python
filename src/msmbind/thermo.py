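"""Standard binding free energy from macrostate populations.

The estimator combines the stationary probabilities of the bound (π2) and
unbound (π1) macrostates with a volume correction that references the
unbound state to the standard concentration of 1 M:

    ΔG° = -kBT ln(π2/π1) - kBT ln(V_unbound / V°),   V° = 1660 Å³

V_bound is estimated as the volume of a sphere whose radius is the *mean*
centre-of-mass distance between ligand and peptide over snapshots sampled
from the bound macrostate (radius first, then cube — not the mean of
per-snapshot sphere volumes); V_total is the mean box volume over the same
snapshots and V_unbound = V_total - V_bound.  The reported uncertainty
propagates the standard deviation of the centre-of-mass distance through
V_bound into ΔG°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KCAL_TO_KJ, V_STANDARD_A3, kbt
from .trajectory import TrajectoryEnsemble, minimum_image_distance


@dataclass
class VolumeEstimate:
    """Bound/unbound/total volumes (Å³) from bound-state snapshots."""

    V_bound: float
    V_unbound: float
    V_total: float
    mean_com_distance: float  # Å
    sd_com_distance: float  # Å
    n_snapshots: int

    def __post_init__(self) -> None:
        if self.V_bound < 0 or self.V_unbound <= 0 or self.V_total <= 0:
            raise ValueError("volumes must be positive (V_bound >= 0)")
        if abs(self.V_bound + self.V_unbound - self.V_total) > 1e-6 * self.V_total:
            raise ValueError("V_bound + V_unbound must equal V_total")


@dataclass
class BindingEstimate:
    """Standard binding free energy and derived dissociation constant."""

    dG_standard: float  # kcal/mol
    kBT: float  # kcal/mol
    temperature: float  # K
    pi1: float
    pi2: float
    V_standard: float  # Å³
    K_d: float  # molar
    uncertainty: float  # kcal/mol

    @property
    def dG_standard_kj(self) -> float:
        return self.dG_standard * KCAL_TO_KJ


def _center_of_mass(xyz: np.ndarray, masses: np.ndarray | None) -> np.ndarray:
    """COM over the atom axis; geometric centre when masses are absent."""
    if masses is None:
        return xyz.mean(axis=-2)
    w = masses / masses.sum()
    return np.einsum("...ad,a->...d", xyz, w)


def estimate_volumes(bound_snapshots, traj: TrajectoryEnsemble) -> VolumeEstimate:
    """Volumes from centre-of-mass distances over bound-state snapshots.

    ``bound_snapshots`` is a :class:`~msmbind.contacts.SnapshotSample` (or
    anything with a ``frames`` list of ``(replica, frame)`` pairs) drawn from
    the bound macrostate.
    """
    topo = traj.topology
    dists = []
    vols = []
    for rep_idx, frame_idx in bound_snapshots.frames:
        rep = traj.replicas[rep_idx]
        pep = rep.peptide_frame(frame_idx)
        lig = rep.ligand_xyz[frame_idx]
        box = rep.box_frame(frame_idx)
        com_p = _center_of_mass(pep, topo.peptide_masses)
        com_l = _center_of_mass(lig, topo.ligand_masses)
        dists.append(float(minimum_image_distance(com_l, com_p, box)))
        vols.append(float(np.prod(box)))
    dists = np.asarray(dists)
    r_mean = float(dists.mean())
    v_bound = 4.0 / 3.0 * np.pi * r_mean**3
    v_total = float(np.mean(vols))
    if v_bound >= v_total:
        raise ValueError(
            f"bound sphere ({v_bound:.1f} Å³) exceeds the box ({v_total:.1f} Å³)"
        )
    return VolumeEstimate(
        V_bound=v_bound,
        V_unbound=v_total - v_bound,
        V_total=v_total,
        mean_com_distance=r_mean,
        sd_com_distance=float(dists.std(ddof=1)) if dists.size > 1 else 0.0,
        n_snapshots=len(dists),
    )


def binding_free_energy(
    pi1: float,
    pi2: float,
    vols: VolumeEstimate,
    temperature: float = 300.0,
    V_standard: float = V_STANDARD_A3,
) -> BindingEstimate:
    """ΔG° from macrostate populations with the standard-volume correction.

    ``pi1`` is the unbound and ``pi2`` the bound stationary probability.
    """
    if abs(pi1 + pi2 - 1.0) > 1e-9:
        raise ValueError(f"pi1 + pi2 must equal 1, got {pi1 + pi2}")
    if pi1 <= 0 or pi2 <= 0:
        raise ValueError("both macrostates must be populated (pi1, pi2 > 0)")
    kT = kbt(temperature)
    dg = -kT * np.log(pi2 / pi1) - kT * np.log(vols.V_unbound / V_standard)
    # propagate sd of the COM distance through V_bound = 4/3 π r³
    sd_vb = 4.0 * np.pi * vols.mean_com_distance**2 * vols.sd_com_distance
    sd_dg = kT * sd_vb / vols.V_unbound
    return BindingEstimate(
        dG_standard=float(dg),
        kBT=kT,
        temperature=temperature,
        pi1=pi1,
        pi2=pi2,
        V_standard=V_standard,
        K_d=dg_to_kd(float(dg), temperature),
        uncertainty=float(sd_dg),
    )


def dg_to_kd(dG: float, temperature: float = 300.0) -> float:
    """Dissociation constant (molar) from a standard binding free energy."""
    return float(np.exp(dG / kbt(temperature)))


def kd_to_dg(kd: float, temperature: float = 300.0) -> float:
    """Standard binding free energy (kcal/mol) from K_d in molar."""
    if kd <= 0:
        raise ValueError("K_d must be positive")
    return float(kbt(temperature) * np.log(kd))
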