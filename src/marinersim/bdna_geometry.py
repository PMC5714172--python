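"""Idealized B-form duplex and inter-strand scissile-phosphate geometry.

Different transposon families cut the two strands with different
staggers, placing the pair of scissile phosphates at characteristic
positions on the double helix: mariner's 3-bp stagger puts them nearly
opposite each other across the minor groove; the blunt Tn10/Tn5 cut
faces them through the middle of the helix; PiggyBac's 4-bp TTAA stagger
(on the opposite side of the transferred-strand cut from mariner's) puts
them across the major groove.

The duplex is a rigid helically symmetric model: one phosphorus per
residue at radius ``p_radius`` from the axis, advanced by ``twist``
degrees and ``rise`` angstroms per base pair, the two antiparallel
strands related by the duplex dyad.  The phosphate placement constants
were calibrated once (scripts/calibrate_helix.py) against the three
benchmark distances 11.9 / 16.9 / 18.3 angstroms; all three are
reproduced within 0.2 angstroms by the committed parameter set, with the
global inter-strand minimum at stagger +3.

Stagger sign convention: positive staggers run in the mariner direction
(the 5'-recessed cut whose phosphate pair closes across the minor
groove); the PiggyBac pair lies 4 bp the other way, stagger -4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "HelixModel",
    "PhosphateTrace",
    "build_duplex",
    "interstrand_p_distance",
    "min_distance_stagger",
    "export_trace",
    "import_trace",
    "groove_label",
    "MARINER_STAGGER",
    "TN10_STAGGER",
    "PIGGYBAC_STAGGER",
]

MARINER_STAGGER = 3
TN10_STAGGER = 0
PIGGYBAC_STAGGER = -4


@dataclass(frozen=True)
class HelixModel:
    """Helical parameters of the idealized duplex.

    Defaults: canonical B-form fiber twist/rise with the phosphate
    placement constants from the committed calibration.
    """

    twist: float = 36.0               # degrees per bp
    rise: float = 3.38                # angstrom per bp
    p_radius: float = 9.499455        # angstrom, P distance from axis
    p_azimuth_offset: float = 63.802439  # degrees, P angle off the bp dyad
    p_z_offset: float = -0.552699     # angstrom, P axial offset per strand
    handedness: str = "right"

    def __post_init__(self) -> None:
        if not 0.0 < self.twist <= 60.0:
            raise ValueError("twist must lie in (0, 60] degrees")
        if self.rise <= 0 or self.p_radius <= 0:
            raise ValueError("rise and p_radius must be positive")
        if self.handedness != "right":
            raise ValueError("only right-handed duplexes are modelled")


@dataclass
class PhosphateTrace:
    """Phosphorus coordinates of both strands, indexed by base pair.

    ``strand1[i]`` and ``strand2[i]`` belong to base pair ``i``; strand 2
    runs antiparallel (its 5'->3' direction is decreasing ``i``).
    """

    strand1: np.ndarray  # (n_bp, 3)
    strand2: np.ndarray  # (n_bp, 3)
    params: HelixModel

    @property
    def n_bp(self) -> int:
        return len(self.strand1)


def build_duplex(params: HelixModel = HelixModel(), n_bp: int = 21) -> PhosphateTrace:
    """Generate both strands' phosphorus traces by helical symmetry.

    Base pair ``i`` is the reference frame rotated by ``i * twist`` and
    translated by ``i * rise``; within it the two phosphates sit at
    azimuth +/- ``p_azimuth_offset`` and axial offset +/- ``p_z_offset``
    (the duplex dyad exchanges the strands).
    """
    if n_bp < 2:
        raise ValueError("n_bp must be at least 2")
    i = np.arange(n_bp)
    omega = np.deg2rad(params.twist)
    phi = np.deg2rad(params.p_azimuth_offset)
    theta1 = i * omega + phi
    theta2 = i * omega - phi
    z1 = i * params.rise + params.p_z_offset
    z2 = i * params.rise - params.p_z_offset
    r = params.p_radius
    strand1 = np.column_stack([r * np.cos(theta1), r * np.sin(theta1), z1])
    strand2 = np.column_stack([r * np.cos(theta2), r * np.sin(theta2), z2])
    return PhosphateTrace(strand1, strand2, params)


def interstrand_p_distance(trace: PhosphateTrace, stagger: int,
                           ref_index: Optional[int] = None) -> float:
    """Distance between strand-1 phosphate i and strand-2 phosphate i+stagger.

    Translation-invariant along the helix; ``ref_index`` defaults to a
    position keeping both partners inside the trace.  Positive staggers
    follow the mariner convention (see module docstring).
    """
    n = trace.n_bp
    if ref_index is None:
        ref_index = max(0, min(n // 2, n - 1 - stagger))
    j = ref_index + stagger
    if not (0 <= ref_index < n and 0 <= j < n):
        raise ValueError(
            f"stagger {stagger} at reference {ref_index} falls outside the "
            f"{n}-bp trace")
    return float(np.linalg.norm(trace.strand1[ref_index] - trace.strand2[j]))


def min_distance_stagger(trace: PhosphateTrace,
                         stagger_range: Tuple[int, int] = (-10, 10)
                         ) -> Tuple[int, float]:
    """Stagger minimising the inter-strand phosphate distance.

    Scans integer staggers in the closed ``stagger_range``; ties break
    toward the smaller stagger.
    """
    lo, hi = stagger_range
    if lo > hi:
        raise ValueError("empty stagger range")
    best: Optional[Tuple[int, float]] = None
    for s in range(lo, hi + 1):
        d = interstrand_p_distance(trace, s)
        if best is None or d < best[1] - 1e-12:
            best = (s, d)
    return best


def groove_label(params: HelixModel, stagger: int) -> str:
    """Descriptive position of a phosphate pair (not used in computation).

    Classifies by the azimuthal separation of the pair: near zero means
    the phosphates face each other across the narrow (minor) groove,
    near 180 degrees through the helix interior, and in between across
    the wide (major) groove.
    """
    delta = 2 * params.p_azimuth_offset - stagger * params.twist
    sep = abs((delta + 180.0) % 360.0 - 180.0)
    if sep < 45.0:
        return "minor_groove"
    if sep > 110.0:
        return "through_helix"
    return "major_groove"


def export_trace(trace: PhosphateTrace, path) -> None:
    """Write the trace as PDB pseudo-atoms (P atoms, chains A and B).

    Chain B residues are numbered in reverse to reflect the antiparallel
    polarity of strand 2.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = trace.n_bp
    atoms = struc.AtomArray(2 * n)
    atoms.coord = np.vstack([trace.strand1, trace.strand2]).astype(np.float32)
    atoms.chain_id = np.array(["A"] * n + ["B"] * n)
    atoms.res_id = np.array(list(range(1, n + 1)) + list(range(n, 0, -1)))
    atoms.res_name = np.array(["DN"] * 2 * n)
    atoms.atom_name = np.array(["P"] * 2 * n)
    atoms.element = np.array(["P"] * 2 * n)
    atoms.hetero = np.array([True] * 2 * n)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def import_trace(path, params: HelixModel = HelixModel()) -> PhosphateTrace:
    """Read a trace written by :func:`export_trace` (PDB precision)."""
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(path)).get_structure(model=1)
    s1 = atoms.coord[atoms.chain_id == "A"].astype(float)
    s2_atoms = atoms[atoms.chain_id == "B"]
    order = np.argsort(-s2_atoms.res_id)  # restore bp-index order
    s2 = s2_atoms.coord[order].astype(float)
    if len(s1) == 0 or len(s1) != len(s2):
        raise ValueError("not a two-chain phosphate trace")
    return PhosphateTrace(s1, s2, params)
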