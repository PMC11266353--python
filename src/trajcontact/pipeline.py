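"""Config-driven two-system comparison: contact maps and ΔC, named distance
distributions with peaks, RMSF profiles, interaction counts and nonbonded
energy summaries, written as plot-ready TSV plus a plain-text summary."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .contacts import (ContactMap, DiffContactMap, contact_population,
                       contacts_of_residue, diff_contact_map,
                       write_contact_map_tsv)
from .distributions import (DistanceDistribution, distance_series, find_peaks,
                            histogram, write_distribution_tsv)
from .energetics import EnergyReport, energy_report, write_energy_tsv
from .fluctuations import RMSFProfile, align_trajectory, rmsf, write_rmsf_tsv
from .interactions import (HBondCriteria, InteractionCounts, PiPiCriteria,
                           count_interactions)
from .pdb_io import read_multimodel_pdb, read_params_table
from .trajectory import Trajectory

__all__ = ["AnalysisConfig", "ComparisonReport", "run_compare",
           "summarize_focal_residue"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All knobs of a two-system comparison run.

    ``distance_pairs`` entries are ``{"label": ..., "a": ..., "b": ...,
    "system": "variant"|"reference"|"both"}`` with selection strings like
    ``"A:3:H"`` (atom) or ``"ring:B:29"`` (aromatic-ring center of mass).
    """

    reference: str
    variant: str
    output_dir: str
    params_reference: Optional[str] = None
    params_variant: Optional[str] = None
    contact_cutoff: float = 4.5          # Å, heavy-atom contact cutoff
    population_threshold: float = 0.5    # "stable contact" reporting threshold
    hbond_max_ha: float = 2.5
    hbond_min_angle: float = 120.0
    hbond_max_da: float = 3.5
    pipi_max_com: float = 7.0
    pipi_parallel_max: float = 30.0
    pipi_tshaped_min: float = 60.0
    bin_width: float = 0.1               # Å, histogram bin width
    peak_prominence: float = 0.05
    rmsf_selection: str = "CA"
    align_selection: str = "CA"
    stride: int = 1
    seed: int = 0
    keep_solvent: bool = False
    focal_residues: list[int] = field(default_factory=list)
    distance_pairs: list[dict] = field(default_factory=list)
    ring_templates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be ≥ 1")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not 0 <= self.population_threshold <= 1:
            raise ValueError("population_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def echo(self) -> dict:
        """Analysis parameters for the provenance block (paths excluded so
        reruns into different directories stay byte-identical)."""
        skip = {"reference", "variant", "output_dir",
                "params_reference", "params_variant"}
        return {k: v for k, v in self.__dict__.items() if k not in skip}

    def hbond_criteria(self) -> HBondCriteria:
        return HBondCriteria(max_ha_distance=self.hbond_max_ha,
                             min_dha_angle=self.hbond_min_angle,
                             max_da_distance=self.hbond_max_da)

    def pipi_criteria(self) -> PiPiCriteria:
        return PiPiCriteria(max_com_distance=self.pipi_max_com,
                            parallel_max_angle=self.pipi_parallel_max,
                            tshaped_min_angle=self.pipi_tshaped_min)


@dataclass
class ComparisonReport:
    """In-memory results of :func:`run_compare` plus the output directory."""

    config: AnalysisConfig
    cmap_reference: ContactMap
    cmap_variant: ContactMap
    delta: DiffContactMap
    rmsf_reference: RMSFProfile
    rmsf_variant: RMSFProfile
    counts_reference: InteractionCounts
    counts_variant: InteractionCounts
    distributions: dict[str, tuple[DistanceDistribution, list[tuple[float, float]]]]
    energy_reference: Optional[EnergyReport]
    energy_variant: Optional[EnergyReport]
    focal_summaries: dict[int, str]
    output_dir: Path


def _checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _strided(traj: Trajectory, stride: int) -> Trajectory:
    if stride == 1:
        return traj
    return Trajectory(topology=traj.topology, frames=traj.frames[::stride])


def run_compare(config: AnalysisConfig) -> ComparisonReport:
    """Execute the full reference-vs-variant comparison and write results.

    Steps: contact populations for both systems → ΔC → focal-residue
    contact summaries → configured distance distributions with peak
    detection → alignment + per-residue RMSF → per-frame interaction counts
    → nonbonded energy reports (when parameter tables are configured).
    All outputs are deterministic for a fixed config and inputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    checksums = {"reference": _checksum(config.reference),
                 "variant": _checksum(config.variant)}
    ref = _strided(read_multimodel_pdb(config.reference,
                                       keep_solvent=config.keep_solvent),
                   config.stride)
    var = _strided(read_multimodel_pdb(config.variant,
                                       keep_solvent=config.keep_solvent),
                   config.stride)
    if ref.topology.n_residues != var.topology.n_residues:
        raise ValueError(
            f"residue-count mismatch: reference has "
            f"{ref.topology.n_residues}, variant has "
            f"{var.topology.n_residues}; systems must match by serial index")
    params_needed = (config.params_reference is None) != (config.params_variant is None)
    if params_needed:
        raise ValueError("energetics requested: parameter tables must be "
                         "given for both systems or neither")
    for key, val in sorted(config.echo().items()):
        logger.info("criterion %s = %r", key, val)

    cmap_ref = contact_population(ref, cutoff=config.contact_cutoff)
    cmap_var = contact_population(var, cutoff=config.contact_cutoff)
    delta = diff_contact_map(cmap_var, cmap_ref)
    write_contact_map_tsv(cmap_ref, out / "contact_reference.tsv")
    write_contact_map_tsv(cmap_var, out / "contact_variant.tsv")
    write_contact_map_tsv(delta, out / "contact_delta.tsv")

    distributions: dict[str, tuple[DistanceDistribution, list]] = {}
    for pair in config.distance_pairs:
        system = pair.get("system", "variant")
        targets = {"variant": [("variant", var)], "reference": [("reference", ref)],
                   "both": [("reference", ref), ("variant", var)]}[system]
        for sysname, traj in targets:
            label = f"{pair['label']}_{sysname}"
            series = distance_series(traj, pair["a"], pair["b"],
                                     extra_ring_templates=config.ring_templates)
            dist = histogram(series, bin_width=config.bin_width)
            peaks = find_peaks(dist, min_prominence=config.peak_prominence)
            distributions[label] = (dist, peaks)
            write_distribution_tsv(dist, out / f"dist_{label}.tsv")

    rmsf_ref = rmsf(align_trajectory(ref, config.align_selection),
                    config.rmsf_selection)
    rmsf_var = rmsf(align_trajectory(var, config.align_selection),
                    config.rmsf_selection)
    write_rmsf_tsv(rmsf_ref, out / "rmsf_reference.tsv")
    write_rmsf_tsv(rmsf_var, out / "rmsf_variant.tsv")
    _write_rmsf_delta(rmsf_ref, rmsf_var, out / "rmsf_delta.tsv")

    counts_ref = count_interactions(ref, config.hbond_criteria(),
                                    config.pipi_criteria(),
                                    config.ring_templates)
    counts_var = count_interactions(var, config.hbond_criteria(),
                                    config.pipi_criteria(),
                                    config.ring_templates)
    _write_counts(counts_ref, out / "counts_reference.tsv")
    _write_counts(counts_var, out / "counts_variant.tsv")

    energy_ref = energy_var = None
    if config.params_reference and config.params_variant:
        p_ref = read_params_table(config.params_reference, ref.topology)
        p_var = read_params_table(config.params_variant, var.topology)
        energy_ref = energy_report(ref, p_ref)
        energy_var = energy_report(var, p_var)
        write_energy_tsv(energy_ref, out / "energy_reference.tsv")
        write_energy_tsv(energy_var, out / "energy_variant.tsv")

    report = ComparisonReport(
        config=config, cmap_reference=cmap_ref, cmap_variant=cmap_var,
        delta=delta, rmsf_reference=rmsf_ref, rmsf_variant=rmsf_var,
        counts_reference=counts_ref, counts_variant=counts_var,
        distributions=distributions, energy_reference=energy_ref,
        energy_variant=energy_var, focal_summaries={}, output_dir=out)
    for serial in config.focal_residues:
        report.focal_summaries[serial] = summarize_focal_residue(report, serial)

    (out / "summary.txt").write_text(_render_summary(report, checksums))
    return report


def _write_rmsf_delta(ref: RMSFProfile, var: RMSFProfile,
                      path: Path) -> None:
    lines = ["serial_index\trmsf_reference_A\trmsf_variant_A\tdelta_A"]
    for k, serial in enumerate(ref.serial_indices):
        r, v = ref.values[k], var.values[k]
        d = v - r
        fmt = lambda x: f"{x:.6f}" if np.isfinite(x) else "NA"
        lines.append(f"{serial}\t{fmt(r)}\t{fmt(v)}\t{fmt(d)}")
    path.write_text("\n".join(lines) + "\n")


def _write_counts(counts: InteractionCounts, path: Path) -> None:
    lines = ["frame\tn_hbonds\tn_pipi"]
    for k, (h, p) in enumerate(zip(counts.hbond_counts, counts.pipi_counts)):
        lines.append(f"{k}\t{h}\t{p}")
    path.write_text("\n".join(lines) + "\n")


def summarize_focal_residue(report: ComparisonReport, serial_index: int) -> str:
    """Text block listing one residue's stable contact partners (population
    ≥ threshold) in both systems, with their ΔC."""
    thr = report.config.population_threshold
    n = report.cmap_reference.n_residues
    if not 1 <= serial_index <= n:
        raise ValueError(f"serial_index {serial_index} outside 1..{n}")
    lines = [f"Residue serial {serial_index} "
             f"({report.cmap_variant.labels[serial_index - 1]}) — partners "
             f"with population ≥ {thr:g}:"]
    for sysname, cmap in (("reference", report.cmap_reference),
                          ("variant", report.cmap_variant)):
        partners = contacts_of_residue(cmap, serial_index, thr)
        if not partners:
            lines.append(f"  {sysname}: no partners reach the threshold")
            continue
        lines.append(f"  {sysname}:")
        for partner, pop in partners:
            dc = report.delta.values[serial_index - 1, partner - 1]
            lines.append(f"    {cmap.labels[partner - 1]:<20s} "
                         f"population {pop:.3f}  ΔC {dc:+.3f}")
    return "\n".join(lines)


def _render_summary(report: ComparisonReport, checksums: dict) -> str:
    cfg = report.config
    lines = [
        "trajcontact comparison report",
        "=============================",
        f"package version: {__version__}",
        f"input checksums (sha256/16): reference={checksums['reference']} "
        f"variant={checksums['variant']}",
        "",
        "configuration:",
    ]
    for k, v in sorted(cfg.echo().items()):
        lines.append(f"  {k}: {v}")
    lines += [
        "",
        f"frames analysed: reference={len(report.counts_reference.hbond_counts)}, "
        f"variant={len(report.counts_variant.hbond_counts)}",
        "",
        "interaction counts (trajectory means):",
        f"  H-bonds: reference {report.counts_reference.mean_hbonds:.3f}, "
        f"variant {report.counts_variant.mean_hbonds:.3f}",
        f"  pi-pi:   reference {report.counts_reference.mean_pipi:.3f}, "
        f"variant {report.counts_variant.mean_pipi:.3f}",
    ]
    dmax = np.max(np.abs(report.delta.values)) if report.delta.values.size else 0.0
    lines += ["", f"largest |ΔC| entry: {dmax:.3f}"]
    for label, (dist, peaks) in report.distributions.items():
        lines.append("")
        lines.append(f"distance distribution '{label}':")
        if peaks:
            for c, p in peaks:
                lines.append(f"  peak at {c:.2f} Å (probability {p:.3f})")
        else:
            lines.append("  no peaks above prominence threshold")
    if report.energy_reference is not None:
        er, ev = report.energy_reference, report.energy_variant
        lines += [
            "",
            "nonbonded energies (kcal/mol, mean ± sd):",
            f"  E_elec: reference {er.mean_elec:.3f} ± {er.sd_elec:.3f}, "
            f"variant {ev.mean_elec:.3f} ± {ev.sd_elec:.3f}",
            f"  E_vdw:  reference {er.mean_vdw:.3f} ± {er.sd_vdw:.3f}, "
            f"variant {ev.mean_vdw:.3f} ± {ev.sd_vdw:.3f}",
        ]
    for serial in sorted(report.focal_summaries):
        lines += ["", report.focal_summaries[serial]]
    return "\n".join(lines) + "\n"
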