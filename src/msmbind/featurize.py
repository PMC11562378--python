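"""Protein-ligand distance metrics and tICA projection.

Three feature sets, all built from minimum-image distances between annotated
ligand atoms and the peptide Cα beads:

* ``N_CAS_TICA`` — the full vector of ligand-N to Cα distances, one per
  residue (11 for the modelled peptide), intended to be passed through tICA;
* ``SHORTEST_N_CA`` — the minimum of those distances (1-D);
* ``SHORTEST_NC_CA`` — the minimum over all annotated ligand heavy atoms
  (nitrogen and carbons) against all Cα beads (1-D).

tICA solves the symmetrised time-lagged generalized eigenproblem and keeps
the smallest number of components explaining a target fraction of the
kinetic variance (sum of squared eigenvalues).  When nearly all input
dimensions would be needed — at least ``ceil(10/11 * d)`` of ``d`` — the
projection buys nothing and the raw features are returned unchanged with
``fallback_used`` set, mirroring common practice for this system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .trajectory import TrajectoryEnsemble, minimum_image_distance

logger = logging.getLogger(__name__)

METRIC_N_CAS_TICA = "N_CAS_TICA"
METRIC_SHORTEST_N_CA = "SHORTEST_N_CA"
METRIC_SHORTEST_NC_CA = "SHORTEST_NC_CA"

METRIC_IDS = (METRIC_N_CAS_TICA, METRIC_SHORTEST_N_CA, METRIC_SHORTEST_NC_CA)


@dataclass
class FeatureSeries:
    """Per-replica feature vectors under one metric.

    ``values`` is one ``(n_frames, dimension)`` array per replica; replica
    boundaries are preserved so no time-lagged computation ever crosses them.
    Units are Å for raw distances, unitless after tICA projection.
    """

    metric_id: str
    values: list[np.ndarray]
    dimension: int
    frame_spacing: float  # ps

    def __post_init__(self) -> None:
        for i, v in enumerate(self.values):
            if v.ndim != 2 or v.shape[1] != self.dimension:
                raise ValueError(f"replica {i}: expected (n_frames, {self.dimension})")

    def stacked(self) -> np.ndarray:
        return np.concatenate(self.values, axis=0)


def _n_ca_distances(traj: TrajectoryEnsemble) -> list[np.ndarray]:
    n_idx = traj.topology.central_n_index
    out = []
    for rep in traj.replicas:
        n_pos = rep.ligand_xyz[:, n_idx, :]  # (F, 3)
        pep = rep.peptide_frames()  # (F, R, 3)
        box = rep.box_frames()[:, None, :]
        d = minimum_image_distance(n_pos[:, None, :], pep, box)
        out.append(d)
    return out


def metric_n_cas(traj: TrajectoryEnsemble) -> FeatureSeries:
    """Per frame, the minimum-image distances from ligand N to every Cα."""
    return FeatureSeries(
        metric_id=METRIC_N_CAS_TICA,
        values=_n_ca_distances(traj),
        dimension=traj.topology.n_residues,
        frame_spacing=traj.frame_spacing,
    )


def metric_shortest_n_ca(traj: TrajectoryEnsemble) -> FeatureSeries:
    """Per frame, the shortest ligand-N to Cα distance (1-D feature)."""
    vals = [d.min(axis=1, keepdims=True) for d in _n_ca_distances(traj)]
    return FeatureSeries(
        metric_id=METRIC_SHORTEST_N_CA,
        values=vals,
        dimension=1,
        frame_spacing=traj.frame_spacing,
    )


def metric_shortest_nc_ca(traj: TrajectoryEnsemble) -> FeatureSeries:
    """Per frame, the shortest distance from any annotated ligand heavy atom
    (central N or ligand carbons) to any Cα (1-D feature)."""
    topo = traj.topology
    atom_idx = [topo.central_n_index, *topo.ligand_carbon_indices]
    if not atom_idx:
        raise ValueError("no ligand atoms with roles central_N or ligand_C")
    vals = []
    for rep in traj.replicas:
        lig = rep.ligand_xyz[:, atom_idx, :]  # (F, A, 3)
        pep = rep.peptide_frames()  # (F, R, 3)
        box = rep.box_frames()[:, None, None, :]
        d = minimum_image_distance(lig[:, :, None, :], pep[:, None, :, :], box)
        vals.append(d.min(axis=(1, 2), keepdims=False)[:, None])
    return FeatureSeries(
        metric_id=METRIC_SHORTEST_NC_CA,
        values=vals,
        dimension=1,
        frame_spacing=traj.frame_spacing,
    )


def compute_metric(traj: TrajectoryEnsemble, metric_id: str) -> FeatureSeries:
    """Dispatch on metric identifier."""
    table = {
        METRIC_N_CAS_TICA: metric_n_cas,
        METRIC_SHORTEST_N_CA: metric_shortest_n_ca,
        METRIC_SHORTEST_NC_CA: metric_shortest_nc_ca,
    }
    if metric_id not in table:
        raise ValueError(f"unknown metric {metric_id!r}; choose from {METRIC_IDS}")
    return table[metric_id](traj)


@dataclass
class TicaModel:
    """Fitted tICA projection.

    Eigenvalues are autocorrelations of the independent components at the
    chosen lag and lie in (-1, 1] for the symmetrised estimator; the kinetic
    variance of component i is ``eigenvalue_i**2``.
    """

    lag: float  # ps
    eigenvalues: np.ndarray
    components: np.ndarray  # (dim, dim) columns are projection vectors
    mean: np.ndarray
    kinetic_variance_cutoff: float
    retained_dims: int
    fallback_used: bool


def tica_fit_transform(
    features: FeatureSeries,
    lag: float,
    cutoff: float = 0.95,
    ridge: float = 1e-10,
) -> tuple[TicaModel, FeatureSeries]:
    """Fit tICA at lag ``lag`` (ps) and project, with the fallback rule.

    Uses the symmetrised (reversible) covariance estimator after mean
    centering; the instantaneous covariance receives a small ridge so
    degenerate inputs stay solvable (a warning is logged when it matters).
    If explaining ``cutoff`` of the kinetic variance needs at least
    ``ceil(10/11 * d)`` of the ``d`` input dimensions, the raw features are
    returned unchanged and ``fallback_used`` is set.
    """
    d = features.dimension
    if d < 2:
        raise ValueError("tICA needs at least 2 feature dimensions")
    lag_frames = int(round(lag / features.frame_spacing))
    if lag_frames < 1:
        raise ValueError(f"lag {lag} ps is below the frame spacing")
    if all(v.shape[0] <= lag_frames for v in features.values):
        raise ValueError("lag must be shorter than the longest replica")

    x0_parts, xt_parts = [], []
    for v in features.values:
        if v.shape[0] > lag_frames:
            x0_parts.append(v[:-lag_frames])
            xt_parts.append(v[lag_frames:])
    x0 = np.concatenate(x0_parts, axis=0)
    xt = np.concatenate(xt_parts, axis=0)
    n = x0.shape[0]
    mean = (x0.sum(axis=0) + xt.sum(axis=0)) / (2.0 * n)
    a = x0 - mean
    b = xt - mean

    c0 = (a.T @ a + b.T @ b) / (2.0 * n)
    ct = (a.T @ b + b.T @ a) / (2.0 * n)
    cond = np.linalg.cond(c0)
    if cond > 1e10:
        logger.warning("instantaneous covariance nearly singular (cond=%.2e); ridge applied", cond)
    c0 = c0 + ridge * np.eye(d)

    vals, vecs = scipy.linalg.eigh(ct, c0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, -1.0, 1.0)

    kinetic = vals**2
    total = kinetic.sum()
    frac = np.cumsum(kinetic) / total if total > 0 else np.ones(d)
    retained = int(np.searchsorted(frac, cutoff) + 1)
    retained = min(retained, d)

    fallback = retained >= math.ceil(10.0 / 11.0 * d)
    model = TicaModel(
        lag=lag,
        eigenvalues=vals,
        components=vecs,
        mean=mean,
        kinetic_variance_cutoff=cutoff,
        retained_dims=d if fallback else retained,
        fallback_used=fallback,
    )
    if fallback:
        logger.info(
            "tICA would retain %d/%d dimensions for %.0f%% kinetic variance; "
            "keeping the raw features",
            retained, d, 100 * cutoff,
        )
        return model, features

    projected = [
        (v - mean) @ vecs[:, :retained] for v in features.values
    ]
    out = FeatureSeries(
        metric_id=features.metric_id + "_TICA",
        values=projected,
        dimension=retained,
        frame_spacing=features.frame_spacing,
    )
    return model, out
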