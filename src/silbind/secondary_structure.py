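"""Secondary 13Ca shifts against a random-coil reference, and helix-face register.

The secondary shift of residue i at one titration point is

    delta_i = delta_obs(13Ca, i) - delta_rc(residue type)

with positive values indicating helical tendency.  The packaged random-coil
reference ships standard literature 13Ca values for unstructured peptides
(Wishart-style tabulation, pH ~5, 25 C); it is user-replaceable via
:meth:`RandomCoilTable.from_tsv` since published tabulations differ by a few
tenths of a ppm.

``same_helix_face`` formalises the ideal alpha-helical-wheel argument that
residues i and i+3 / i+4 present their side chains on the same face: with
100 degrees of rotation per residue, two residues share a face when their
wheel separation (mod 360) is within a tolerance of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .core_io import AMINO_ACIDS, SpectrumType, TitrationSeries, ValidationError

HELIX_DEG_PER_RESIDUE = 100.0
#: Wheel tolerance (degrees) within which two residues count as same-face.
#: 100 deg (inclusive) makes i+1 (100 deg), i+3 (60 deg) and i+4 (40 deg)
#: same-face while i+2 (160 deg) is opposite-face, matching the helical-wheel
#: reading used to group the His/Met binding residues.
DEFAULT_FACE_TOLERANCE_DEG = 100.0


@dataclass(frozen=True)
class RandomCoilTable:
    """Random-coil 13Ca reference shifts (ppm) for all 20 residues."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = AMINO_ACIDS - set(self.values)
        if missing:
            raise ValidationError(f"random-coil table missing residues {sorted(missing)}")
        for res, ppm in self.values.items():
            if not 40.0 <= ppm <= 70.0:
                raise ValidationError(f"random-coil 13Ca for {res} = {ppm} ppm outside 40-70")

    def __getitem__(self, residue_type: str) -> float:
        try:
            return self.values[residue_type.upper()]
        except KeyError:
            raise ValidationError(f"residue type {residue_type!r} absent from random-coil table")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RandomCoilTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["residue_type"].str.upper(), df["delta_rc_ppm"].astype(float))))

    @classmethod
    def default(cls) -> "RandomCoilTable":
        ref = resources.files("silbind.data").joinpath("random_coil_ca13.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class SecondaryShiftRecord:
    residue_index: int
    residue_type: str
    ratio: float
    delta: float  # delta_obs(13Ca) - delta_rc, ppm


def secondary_shifts(
    series: TitrationSeries,
    table: RandomCoilTable | None = None,
    ratio: float = 0.0,
) -> list[SecondaryShiftRecord]:
    """Secondary 13Ca shifts at one titration point of an HSQC series.

    One record per residue whose Ca/Ha cross-peak is present at that point;
    sign convention observed minus random-coil (positive = helical tendency).
    """
    if series.spectrum_type is not SpectrumType.HSQC_CH:
        raise ValidationError("secondary shifts require a 1H-13C HSQC series")
    table = table or RandomCoilTable.default()
    point = series.point_at(ratio)
    records: list[SecondaryShiftRecord] = []
    for peak in point.peaks:
        a = peak.assignment
        if not a.atom_f1.startswith("CA"):
            continue
        if not peak.present:
            continue
        delta = peak.f1_ppm - table[a.residue_type]
        records.append(SecondaryShiftRecord(a.residue_index, a.residue_type, ratio, delta))
    return records


def wheel_separation_deg(i: int, j: int) -> float:
    """Ideal helical-wheel angular separation of residues i and j, in [0, 180]."""
    angle = (HELIX_DEG_PER_RESIDUE * abs(i - j)) % 360.0
    return min(angle, 360.0 - angle)


def same_helix_face(
    i: int, j: int, tolerance_deg: float = DEFAULT_FACE_TOLERANCE_DEG
) -> bool:
    """True when residues i and j fall on the same face of an ideal alpha helix.

    Residue indices may be in any consistent numbering (peptide-local or
    protein); only their difference matters.  Symmetric in i and j.
    """
    if i == j:
        raise ValidationError("same_helix_face requires two distinct residues")
    return wheel_separation_deg(i, j) <= tolerance_deg


def secondary_shift_dataframe(records: list[SecondaryShiftRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "residue_index": r.residue_index,
                "residue_type": r.residue_type,
                "ratio": r.ratio,
                "delta_ppm": r.delta,
            }
            for r in records
        ]
    )
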