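"""Pairwise nonbonded energies: Coulomb electrostatics and Lennard-Jones.

E_elec = Σ k_e q_i q_j / r_ij over non-excluded pairs, with
k_e = 332.0636 kcal·Å/(mol·e²) (the constant used by AMBER-family codes);
E_vdw = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with Lorentz–Berthelot combining
(arithmetic-mean σ, geometric-mean ε).  No distance cutoff and no 1-4
scaling are applied: these totals are a self-consistent comparative metric
between systems analysed under the same exclusion scheme, not a
reproduction of a simulation engine's bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .geometry import minimum_image_displacement
from .trajectory import Frame, NonbondedParams, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyReport",
    "coulomb_energy",
    "lj_energy",
    "energy_report",
    "write_energy_tsv",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)
_CLASH_DISTANCE = 0.1  # Å: below this a non-excluded pair is an input error


@dataclass
class EnergyReport:
    """Per-frame electrostatic and van der Waals totals (kcal/mol)."""

    e_elec: np.ndarray
    e_vdw: np.ndarray

    @property
    def mean_elec(self) -> float:
        return float(np.mean(self.e_elec))

    @property
    def mean_vdw(self) -> float:
        return float(np.mean(self.e_vdw))

    @property
    def sd_elec(self) -> float:
        return float(np.std(self.e_elec))

    @property
    def sd_vdw(self) -> float:
        return float(np.std(self.e_vdw))


def _pair_distances(frame: Frame, params: NonbondedParams
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if params.n_atoms != frame.coordinates.shape[0]:
        raise ValueError("parameter table does not cover this frame's atoms")
    i, j = params.interacting_pairs()
    d = minimum_image_displacement(
        frame.coordinates[j] - frame.coordinates[i], frame.box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r < _CLASH_DISTANCE):
        k = int(np.argmin(r))
        raise ValueError(
            f"non-excluded atom pair ({int(i[k])}, {int(j[k])}) at "
            f"{r[k]:.3f} Å (< {_CLASH_DISTANCE} Å): atomic clash or missing "
            "exclusion")
    return i, j, r


def coulomb_energy(frame: Frame, params: NonbondedParams) -> float:
    """Total electrostatic energy (kcal/mol) over non-excluded pairs."""
    i, j, r = _pair_distances(frame, params)
    return float(COULOMB_CONSTANT *
                 np.sum(params.charge[i] * params.charge[j] / r))


def lj_energy(frame: Frame, params: NonbondedParams) -> float:
    """Total Lennard-Jones energy (kcal/mol) over non-excluded pairs."""
    i, j, r = _pair_distances(frame, params)
    sig = 0.5 * (params.sigma[i] + params.sigma[j])
    eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
    sr6 = (sig / r) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def energy_report(traj: Trajectory, params: NonbondedParams,
                  stride: int = 1) -> EnergyReport:
    """Per-frame Coulomb and LJ totals for a trajectory."""
    frames = traj.frames[::stride]
    e_elec = np.empty(len(frames))
    e_vdw = np.empty(len(frames))
    for k, frame in enumerate(frames):
        i, j, r = _pair_distances(frame, params)
        e_elec[k] = COULOMB_CONSTANT * np.sum(
            params.charge[i] * params.charge[j] / r)
        sig = 0.5 * (params.sigma[i] + params.sigma[j])
        eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
        sr6 = (sig / r) ** 6
        e_vdw[k] = np.sum(4.0 * eps * (sr6 * sr6 - sr6))
    return EnergyReport(e_elec=e_elec, e_vdw=e_vdw)


def write_energy_tsv(report: EnergyReport, path: Union[str, Path]) -> None:
    """TSV time series: frame, e_elec_kcal_mol, e_vdw_kcal_mol."""
    lines = ["frame\te_elec_kcal_mol\te_vdw_kcal_mol"]
    for k, (ee, ev) in enumerate(zip(report.e_elec, report.e_vdw)):
        lines.append(f"{k}\t{ee:.6f}\t{ev:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
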