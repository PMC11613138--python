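"""NOESY cross-peak volume → inter-proton distance calibration.

Under the isolated-spin-pair approximation the cross-peak volume scales as
the inverse sixth power of the inter-proton distance, I ∝ d⁻⁶, so any peak
can be converted to a distance once a pair of known geometry is available.
The cytosine H5–H6 distance is essentially fixed by covalent geometry at
2.9 Å, and the mean volume of all intranucleotide C H5×H6 cross-peaks
serves as the reference:

    d = d_ref · (I_ref / I)^(1/6),   d_ref = 2.9 Å.

No spin-diffusion or relaxation-matrix corrections are applied.  Thymine
methyl (M7) volumes are divided by 3 before conversion (pseudo-atom
convention for a three-proton group).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrossPeak",
    "DistanceEstimate",
    "D_REF_CH5_H6",
    "calibrate_reference",
    "peak_to_distance",
    "peaks_to_distances",
    "average_symmetric_peaks",
    "compare_to_bdna",
    "export_restraints",
    "read_restraints",
    "restraints_md_block",
    "BDNA_REFERENCE_DISTANCES",
]

#: Calibration distance: average cytosine H5–H6 separation, Å.
D_REF_CH5_H6 = 2.9

#: Reference B-DNA H1'–H6/H8 distances (Å) used by :func:`compare_to_bdna`.
#: Synthetic stand-in constants representing standard B-form fibre/NMR
#: geometry (intranucleotide H1'-to-own-base, internucleotide
#: H1'(i−1)-to-base(i)); only deviations from them are interpreted.
BDNA_REFERENCE_DISTANCES = {
    "intra": 3.7,
    "inter": 3.2,
}


@dataclass(frozen=True)
class CrossPeak:
    """One assigned, integrated NOESY cross-peak.

    Atom labels are ("residue", "atom") pairs such as ("C-4", "H5"); the
    residue part carries the base identity and the signed no-zero position.
    """

    atom_a: tuple[str, str]
    atom_b: tuple[str, str]
    volume: float
    assignment_note: str = ""

    @property
    def usable(self) -> bool:
        return self.volume > 0

    def involves(self, atom_name_a: str, atom_name_b: str) -> bool:
        names = {self.atom_a[1], self.atom_b[1]}
        return names == {atom_name_a, atom_name_b}


@dataclass(frozen=True)
class DistanceEstimate:
    """Calibrated inter-proton distance from one cross-peak."""

    pair: tuple[tuple[str, str], tuple[str, str]]
    d: float  # Å
    I: float
    I_ref: float
    d_ref: float = D_REF_CH5_H6
    kind: str = ""  # "intra" | "inter" | ""

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("distance must be > 0")


def _is_cytosine_h5_h6_reference(peak: CrossPeak) -> bool:
    (res_a, name_a), (res_b, name_b) = peak.atom_a, peak.atom_b
    return (
        res_a == res_b
        and res_a.startswith("C")
        and {name_a, name_b} == {"H5", "H6"}
    )


def calibrate_reference(peaks: Sequence[CrossPeak]) -> float:
    """Mean volume of all intranucleotide cytosine H5×H6 cross-peaks."""
    vols = [p.volume for p in peaks if _is_cytosine_h5_h6_reference(p) and p.usable]
    if not vols:
        raise ValueError("no CH5-H6 calibration peak in the list")
    return float(np.mean(vols))


def _effective_volume(peak: CrossPeak) -> float:
    """Volume corrected for methyl multiplicity (M7 divided by 3)."""
    v = peak.volume
    for _, name in (peak.atom_a, peak.atom_b):
        if name == "M7":
            v /= 3.0
    return v


def peak_to_distance(
    peak: CrossPeak, I_ref: float, d_ref: float = D_REF_CH5_H6
) -> DistanceEstimate:
    """d = d_ref · (I_ref/I)^(1/6) for one cross-peak."""
    if I_ref <= 0:
        raise ValueError("I_ref must be > 0")
    I = _effective_volume(peak)
    if I <= 0:
        raise ValueError(f"non-positive volume for {peak.atom_a}-{peak.atom_b}")
    d = d_ref * (I_ref / I) ** (1.0 / 6.0)
    return DistanceEstimate(pair=(peak.atom_a, peak.atom_b), d=d, I=I, I_ref=I_ref, d_ref=d_ref)


def average_symmetric_peaks(peaks: Sequence[CrossPeak]) -> list[CrossPeak]:
    """Average volumes of symmetric (above/below diagonal) duplicates."""
    groups: dict[tuple, list[CrossPeak]] = {}
    for p in peaks:
        key = tuple(sorted((p.atom_a, p.atom_b)))
        groups.setdefault(key, []).append(p)
    out = []
    for key, members in groups.items():
        vol = float(np.mean([m.volume for m in members]))
        first = members[0]
        out.append(
            CrossPeak(atom_a=key[0], atom_b=key[1], volume=vol,
                      assignment_note=first.assignment_note)
        )
    return out


def peaks_to_distances(
    peaks: Sequence[CrossPeak],
    d_ref: float = D_REF_CH5_H6,
    average_symmetric: bool = True,
) -> list[DistanceEstimate]:
    """Calibrate and convert a full peak list (reference peaks included)."""
    work = average_symmetric_peaks(peaks) if average_symmetric else list(peaks)
    I_ref = calibrate_reference(work)
    return [peak_to_distance(p, I_ref, d_ref) for p in work if p.usable]


def _position_of(residue: str) -> int | None:
    tail = residue[1:]
    try:
        return int(tail)
    except ValueError:
        return None


def compare_to_bdna(
    distances: Sequence[DistanceEstimate],
    outer_min_abs_position: int = 4,
    reference: dict | None = None,
) -> pd.DataFrame:
    """Mean deviation from B-DNA H1'–H6/H8 distances, outer vs central.

    Distances must be tagged ``kind`` "intra" or "inter"; unlabeled entries
    are excluded with a note.  A pair belongs to the outer region when both
    residues satisfy |position| ≥ ``outer_min_abs_position``.
    """
    ref = BDNA_REFERENCE_DISTANCES if reference is None else reference
    rows = []
    for de in distances:
        if de.kind not in ref:
            continue
        positions = [_position_of(res) for res, _ in de.pair]
        if any(p is None for p in positions):
            continue
        region = (
            "outer"
            if all(abs(p) >= outer_min_abs_position for p in positions)
            else "central"
        )
        rows.append({"region": region, "kind": de.kind, "deviation": de.d - ref[de.kind]})
    if not rows:
        return pd.DataFrame(columns=["region", "kind", "mean_deviation", "n", "sign"])
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["region", "kind"])["deviation"]
        .agg(mean_deviation="mean", n="count")
        .reset_index()
    )
    agg["sign"] = np.where(
        agg["mean_deviation"] < -1e-9, "shortened",
        np.where(agg["mean_deviation"] > 1e-9, "lengthened", "matching"),
    )
    return agg


def _atom_str(atom: tuple[str, str]) -> str:
    return f"{atom[0]}{atom[1]}"


def export_restraints(
    distances: Sequence[DistanceEstimate],
    fractional: float = 0.2,
    absolute: float = 0.0,
) -> str:
    """Flat-well distance-restraint table as TSV text.

    Bounds: lower = d·(1−f)−a, upper = d·(1+f)+a.
    """
    lines = ["atom_a\tatom_b\tdistance\tlower\tupper"]
    for de in distances:
        lo = de.d * (1.0 - fractional) - absolute
        hi = de.d * (1.0 + fractional) + absolute
        lines.append(
            f"{_atom_str(de.pair[0])}\t{_atom_str(de.pair[1])}\t"
            f"{de.d:.6f}\t{lo:.6f}\t{hi:.6f}"
        )
    return "\n".join(lines) + "\n"


def read_restraints(text_or_path) -> pd.DataFrame:
    """Re-read an exported restraint table."""
    if isinstance(text_or_path, str) and "\n" in text_or_path:
        return pd.read_csv(_io.StringIO(text_or_path), sep="\t")
    return pd.read_csv(text_or_path, sep="\t")


def restraints_md_block(distances: Sequence[DistanceEstimate],
                        fractional: float = 0.2, absolute: float = 0.0,
                        force_constant: float = 10.0) -> str:
    """Engine-agnostic flat-well restraint block for restrained MD input."""
    out = ["# flat-well distance restraints (Angstrom, kcal/mol/A^2)"]
    for de in distances:
        lo = de.d * (1.0 - fractional) - absolute
        hi = de.d * (1.0 + fractional) + absolute
        out.append(
            f"restraint {_atom_str(de.pair[0])} {_atom_str(de.pair[1])} "
            f"low {lo:.3f} high {hi:.3f} k {force_constant:.2f}"
        )
    return "\n".join(out) + "\n"
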