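"""Binding/unbinding rate constants from mean first passage times.

Treating association and dissociation as first-order processes,

    k_off = 1 / MFPT(bound -> unbound)
    k_on  = 1 / (MFPT(unbound -> bound) · C_compound)

with MFPTs converted from ps to s and C_compound the ligand concentration in
the simulation box (one ligand in V_total unless supplied).  Bayesian MSM
MFPT samples map elementwise to rate samples for credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import A3_TO_LITER, AVOGADRO, PS_TO_S


@dataclass
class KineticsEstimate:
    """k_on / k_off with optional Bayesian credible intervals."""

    mfpt_on: float  # ps, unbound -> bound
    mfpt_off: float  # ps, bound -> unbound
    concentration: float  # molar
    k_on: float  # 1/(s·M)
    k_off: float  # 1/s
    k_on_samples: np.ndarray | None = None
    k_off_samples: np.ndarray | None = None

    def credible_interval(self, which: str, level: float = 0.95) -> tuple[float, float]:
        samples = {"k_on": self.k_on_samples, "k_off": self.k_off_samples}[which]
        if samples is None:
            raise ValueError("no Bayesian samples attached")
        a = 100 * (1.0 - level) / 2.0
        return float(np.percentile(samples, a)), float(np.percentile(samples, 100 - a))


def concentration_from_box(V_total: float, n_ligands: int = 1) -> float:
    """Molar concentration of ``n_ligands`` molecules in a box of ``V_total`` Å³."""
    if V_total <= 0:
        raise ValueError("V_total must be positive")
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    return n_ligands / (AVOGADRO * V_total * A3_TO_LITER)


def rates_from_mfpt(
    mfpt_on: float,
    mfpt_off: float,
    concentration: float,
    mfpt_on_samples: np.ndarray | None = None,
    mfpt_off_samples: np.ndarray | None = None,
) -> KineticsEstimate:
    """Convert MFPTs (ps) into k_on (1/s/M) and k_off (1/s)."""
    if mfpt_on <= 0 or mfpt_off <= 0:
        raise ValueError("MFPTs must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    k_off = 1.0 / (mfpt_off * PS_TO_S)
    k_on = 1.0 / (mfpt_on * PS_TO_S * concentration)
    kos = koffs = None
    if mfpt_on_samples is not None:
        s = np.asarray(mfpt_on_samples, float)
        if np.any(s <= 0):
            raise ValueError("MFPT samples must be positive")
        kos = 1.0 / (s * PS_TO_S * concentration)
    if mfpt_off_samples is not None:
        s = np.asarray(mfpt_off_samples, float)
        if np.any(s <= 0):
            raise ValueError("MFPT samples must be positive")
        koffs = 1.0 / (s * PS_TO_S)
    return KineticsEstimate(
        mfpt_on=mfpt_on,
        mfpt_off=mfpt_off,
        concentration=concentration,
        k_on=k_on,
        k_off=k_off,
        k_on_samples=kos,
        k_off_samples=koffs,
    )
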