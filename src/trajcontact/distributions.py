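"""Distance time series, normalized probability distributions and peaks.

This is the analysis behind statements like "the probability distribution of
the donor–acceptor distance has a single prominent peak near 2 Å": extract a
per-frame distance between two selections (single atoms or aromatic-ring
centers of mass), histogram it with bins aligned to absolute multiples of
the bin width, and locate local maxima above a prominence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import scipy.signal

from .geometry import center_of_mass, minimum_image_displacement
from .interactions import AromaticRing, find_aromatic_rings
from .trajectory import Trajectory

__all__ = [
    "AtomSelection",
    "RingSelection",
    "DistanceSeries",
    "DistanceDistribution",
    "parse_selection",
    "distance_series",
    "histogram",
    "find_peaks",
    "write_distribution_tsv",
]

DEFAULT_BIN_WIDTH = 0.1  # Å
DEFAULT_MIN_PROMINENCE = 0.05  # fraction of probability mass


@dataclass(frozen=True)
class AtomSelection:
    """A single named atom: chain, author residue number, atom name."""

    chain_id: str
    author_number: int
    atom_name: str

    def label(self) -> str:
        return f"{self.chain_id}{self.author_number}:{self.atom_name}"


@dataclass(frozen=True)
class RingSelection:
    """The aromatic ring of one residue (its per-frame center of mass)."""

    chain_id: str
    author_number: int

    def label(self) -> str:
        return f"ring({self.chain_id}{self.author_number})"


Selection = Union[AtomSelection, RingSelection]


def parse_selection(text: str) -> Selection:
    """Parse ``"A:3:H"`` into an atom selection or ``"ring:B:29"`` into a
    ring selection."""
    parts = text.split(":")
    if len(parts) == 3 and parts[0].lower() == "ring":
        return RingSelection(chain_id=parts[1], author_number=int(parts[2]))
    if len(parts) == 3:
        return AtomSelection(chain_id=parts[0], author_number=int(parts[1]),
                             atom_name=parts[2])
    raise ValueError(f"cannot parse selection {text!r}; expected "
                     "'chain:resnum:atom' or 'ring:chain:resnum'")


@dataclass
class DistanceSeries:
    """Per-frame distances (Å) for a labelled selection pair."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class DistanceDistribution:
    """Histogram with probabilities normalized to sum to 1."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValueError("need one more edge than probability bin")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.probabilities < 0) or \
                abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _resolve_points(traj: Trajectory, sel: Selection,
                    extra_ring_templates=None) -> np.ndarray:
    """Per-frame 3D point for a selection: atom position or ring COM."""
    top = traj.topology
    if isinstance(sel, AtomSelection):
        hits = top.find_atoms(sel.chain_id, sel.author_number, sel.atom_name)
        if len(hits) != 1:
            raise ValueError(
                f"selection {sel.label()} resolved to {len(hits)} atoms "
                f"(indices {hits}); need exactly one")
        return np.array([fr.coordinates[hits[0]] for fr in traj.frames])
    serial = top.residues[top.residue_by_author(sel.chain_id, sel.author_number)].serial_index
    rings = [r for r in find_aromatic_rings(top, extra_ring_templates)
             if r.residue_serial == serial]
    if not rings:
        raise ValueError(f"no aromatic ring found for {sel.label()}")
    ring: AromaticRing = rings[0]
    masses = top.masses()
    return np.array([center_of_mass(fr.coordinates[ring.atom_indices],
                                    masses[ring.atom_indices])
                     for fr in traj.frames])


def distance_series(traj: Trajectory, selection_a: Union[Selection, str],
                    selection_b: Union[Selection, str],
                    extra_ring_templates=None) -> DistanceSeries:
    """Per-frame minimum-image distance between two resolved selections."""
    if isinstance(selection_a, str):
        selection_a = parse_selection(selection_a)
    if isinstance(selection_b, str):
        selection_b = parse_selection(selection_b)
    pa = _resolve_points(traj, selection_a, extra_ring_templates)
    pb = _resolve_points(traj, selection_b, extra_ring_templates)
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        out[k] = np.linalg.norm(
            minimum_image_displacement(pb[k] - pa[k], frame.box))
    return DistanceSeries(label=f"{selection_a.label()}–{selection_b.label()}",
                          values=out)


def histogram(series: DistanceSeries,
              bin_width: float = DEFAULT_BIN_WIDTH) -> DistanceDistribution:
    """Probability histogram with edges on absolute multiples of bin_width.

    Aligning edges to k·bin_width makes the binning independent of the data
    minimum, so distributions from different systems share a grid.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = series.values
    if v.size == 0:
        raise ValueError("cannot histogram an empty distance series")
    # the small epsilon keeps samples sitting exactly on an edge (up to
    # float division error, e.g. 0.3/0.1) in the higher bin
    idx = np.floor(v / bin_width + 1e-9).astype(int)
    lo, hi = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - lo, minlength=hi - lo + 1).astype(float)
    edges = (np.arange(lo, hi + 2)) * bin_width
    return DistanceDistribution(bin_edges=edges,
                                probabilities=counts / counts.sum())


def find_peaks(dist: DistanceDistribution,
               min_prominence: float = DEFAULT_MIN_PROMINENCE
               ) -> list[tuple[float, float]]:
    """Local maxima of the distribution with prominence ≥ min_prominence.

    Returns (bin center Å, probability) pairs sorted by probability
    descending.  A distribution is *unimodal* at this prominence when
    exactly one peak is returned.
    """
    if not 0 <= min_prominence <= 1:
        raise ValueError("min_prominence must lie in [0, 1]")
    padded = np.concatenate([[0.0], dist.probabilities, [0.0]])
    idx, _ = scipy.signal.find_peaks(padded, prominence=max(min_prominence, 1e-12))
    centers = dist.bin_centers
    peaks = [(float(centers[i - 1]), float(dist.probabilities[i - 1]))
             for i in idx]
    peaks.sort(key=lambda t: (-t[1], t[0]))
    return peaks


def write_distribution_tsv(dist: DistanceDistribution,
                           path: Union[str, Path]) -> None:
    """Two-column TSV: bin_center_A, probability."""
    lines = ["bin_center_A\tprobability"]
    for c, p in zip(dist.bin_centers, dist.probabilities):
        lines.append(f"{c:.6f}\t{p:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")
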