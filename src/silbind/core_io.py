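"""Domain types and readers/writers for assigned NMR peak lists and MS centroid lists.

The on-disk dialects are deliberately minimal plain-text formats:

* **Peak lists** — TSV (or CSV) with the header
  ``residue_index  residue_type  atom_f1  atom_f2  f1_ppm  f2_ppm``;
  one file per titration point.  Blank shift cells mark a cross-peak that is
  not visible at that titration point; such peaks are carried through the
  pipeline as ``present=False`` rather than dropped.
* **MS spectra** — two-column CSV/TSV of centroids ``mz, area``.

Residue numbering is peptide-local and 1-based in files; full-protein labels
(e.g. ``"87His"``) are produced for reports through
:attr:`PeptideSequence.numbering_offset`.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}

#: Controlled vocabulary for atom names: amide/side-chain protons and carbons
#: in IUPAC-ish greek lettering (H, HA, HB, HG, HGa, HD, HE, CA, CB, CG, CD,
#: CE, ...) plus the collective methyl label CH3.  Stereospecific suffixes
#: (1, 2, 3, a, b) are allowed.
_ATOM_RE = re.compile(r"^(?:CH3|[HCN](?:[ABGDEZ][1-3AB]?|N)?)$")

PEAKLIST_COLUMNS = ["residue_index", "residue_type", "atom_f1", "atom_f2", "f1_ppm", "f2_ppm"]


class SilbindError(Exception):
    """Base class for package errors."""


class ValidationError(SilbindError):
    """A domain invariant was violated."""


class ParseError(SilbindError):
    """A file could not be parsed; the message names the offending line."""


class SpectrumType(str, Enum):
    """Kind of 2D experiment a peak list came from."""

    TOCSY = "TOCSY"          # homonuclear, both axes 1H
    HSQC_CH = "HSQC_CH"      # heteronuclear, F1 = 13C, F2 = 1H

    @classmethod
    def coerce(cls, value: "SpectrumType | str") -> "SpectrumType":
        if isinstance(value, cls):
            return value
        key = str(value).upper().replace("-", "_")
        aliases = {"HSQC": "HSQC_CH", "HSQC_CH": "HSQC_CH", "TOCSY": "TOCSY"}
        if key not in aliases:
            raise ValidationError(f"unknown spectrum type {value!r}")
        return cls(aliases[key])


def _is_proton_axis(spectrum_type: SpectrumType, axis: int) -> bool:
    """True if the given axis (1 or 2) carries 1H shifts for this experiment."""
    if spectrum_type is SpectrumType.TOCSY:
        return True
    return axis == 2  # HSQC_CH: F1 = 13C, F2 = 1H


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide as a one-letter string with its position in the parent protein.

    Parameters
    ----------
    one_letter
        Standard one-letter amino-acid codes, N- to C-terminus.
    numbering_offset
        Index of the first residue in the parent protein (1-based); e.g. 77
        for the SilE fragment spanning residues 77-92.
    """

    one_letter: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.one_letter:
            raise ValidationError("sequence must be non-empty")
        bad = set(self.one_letter.upper()) - AMINO_ACIDS
        if bad:
            raise ValidationError(f"unknown residue letters: {sorted(bad)}")
        if self.one_letter != self.one_letter.upper():
            object.__setattr__(self, "one_letter", self.one_letter.upper())
        if self.numbering_offset < 1:
            raise ValidationError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.one_letter)

    def residue_type(self, local_index: int) -> str:
        """One-letter code at a peptide-local 1-based index."""
        if not 1 <= local_index <= len(self):
            raise ValidationError(f"residue index {local_index} outside 1..{len(self)}")
        return self.one_letter[local_index - 1]

    def protein_index(self, local_index: int) -> int:
        """Map a peptide-local index to parent-protein numbering."""
        return local_index + self.numbering_offset - 1

    def local_index(self, protein_index: int) -> int:
        """Inverse of :meth:`protein_index`."""
        return protein_index - self.numbering_offset + 1

    def label(self, local_index: int) -> str:
        """Report label in protein numbering, e.g. ``'87His'``."""
        return f"{self.protein_index(local_index)}{THREE_LETTER[self.residue_type(local_index)]}"


@dataclass(frozen=True, order=True)
class Assignment:
    """Identity of one assigned cross-peak: residue plus the two atom names."""

    residue_index: int
    residue_type: str
    atom_f1: str
    atom_f2: str

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValidationError("residue_index must be >= 1")
        if self.residue_type.upper() not in AMINO_ACIDS:
            raise ValidationError(f"unknown residue type {self.residue_type!r}")
        object.__setattr__(self, "residue_type", self.residue_type.upper())
        for atom in (self.atom_f1, self.atom_f2):
            if not _ATOM_RE.match(atom.upper().replace("Α", "A")):
                raise ValidationError(f"atom name {atom!r} not in controlled vocabulary")
        object.__setattr__(self, "atom_f1", self.atom_f1.upper())
        object.__setattr__(self, "atom_f2", self.atom_f2.upper())

    def __str__(self) -> str:
        return f"{self.residue_index}:{self.residue_type}:{self.atom_f1}:{self.atom_f2}"


# plausible chemical-shift windows (ppm) used for validation
_H_WINDOW = (-2.0, 12.0)
_C_WINDOW = (0.0, 190.0)


@dataclass(frozen=True)
class Peak2D:
    """One 2D cross-peak.  ``present=False`` marks a peak invisible at this point."""

    assignment: Assignment
    f1_ppm: float = math.nan
    f2_ppm: float = math.nan
    present: bool = True

    def __post_init__(self) -> None:
        if self.present and not (math.isfinite(self.f1_ppm) and math.isfinite(self.f2_ppm)):
            raise ValidationError(
                f"present peak {self.assignment} must have finite shifts"
            )

    def validate_windows(self, spectrum_type: SpectrumType) -> None:
        if not self.present:
            return
        for axis, ppm in ((1, self.f1_ppm), (2, self.f2_ppm)):
            lo, hi = _H_WINDOW if _is_proton_axis(spectrum_type, axis) else _C_WINDOW
            if not lo <= ppm <= hi:
                raise ValidationError(
                    f"{self.assignment}: F{axis} shift {ppm} ppm outside "
                    f"plausible window [{lo}, {hi}]"
                )


@dataclass
class PeakList:
    """All assigned cross-peaks of one spectrum at one titration point."""

    spectrum_type: SpectrumType
    ratio: float
    peaks: list[Peak2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectrum_type = SpectrumType.coerce(self.spectrum_type)
        if self.ratio < 0:
            raise ValidationError("titration ratio must be >= 0")
        seen: set[Assignment] = set()
        for peak in self.peaks:
            if peak.assignment in seen:
                raise ValidationError(f"duplicate assignment {peak.assignment}")
            seen.add(peak.assignment)
            peak.validate_windows(self.spectrum_type)

    @property
    def assignments(self) -> list[Assignment]:
        return [p.assignment for p in self.peaks]

    def peak(self, assignment: Assignment) -> Peak2D | None:
        for p in self.peaks:
            if p.assignment == assignment:
                return p
        return None


@dataclass
class TitrationSeries:
    """Ordered peak lists of one experiment across Ag+:peptide ratios.

    On construction the points are sorted by ratio and their assignment sets
    reconciled to the union: an assignment absent from a point is inserted as
    a ``present=False`` placeholder, never dropped.
    """

    sequence: PeptideSequence
    points: list[PeakList]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValidationError("a titration series needs >= 2 points")
        types = {p.spectrum_type for p in self.points}
        if len(types) > 1:
            raise ValidationError(f"mixed spectrum types in series: {sorted(t.value for t in types)}")
        ratios = [p.ratio for p in self.points]
        if len(set(ratios)) != len(ratios):
            raise ValidationError("non-unique titration ratios")
        self.points = sorted(self.points, key=lambda p: p.ratio)
        if self.points[0].ratio != 0.0:
            warnings.warn(
                "series does not start at ratio 0.0; CSP reference must be set explicitly",
                stacklevel=2,
            )
        union: list[Assignment] = []
        seen: set[Assignment] = set()
        for point in self.points:
            for a in point.assignments:
                if a not in seen:
                    seen.add(a)
                    union.append(a)
                if a.residue_index > len(self.sequence):
                    raise ValidationError(
                        f"assignment {a} outside sequence of length {len(self.sequence)}"
                    )
                if self.sequence.residue_type(a.residue_index) != a.residue_type:
                    raise ValidationError(
                        f"assignment {a}: residue type disagrees with sequence "
                        f"({self.sequence.residue_type(a.residue_index)!r} expected)"
                    )
        for point in self.points:
            have = set(point.assignments)
            for a in union:
                if a not in have:
                    point.peaks.append(Peak2D(a, present=False))

    @property
    def spectrum_type(self) -> SpectrumType:
        return self.points[0].spectrum_type

    @property
    def ratios(self) -> list[float]:
        return [p.ratio for p in self.points]

    @property
    def assignments(self) -> list[Assignment]:
        return self.points[0].assignments

    def point_at(self, ratio: float, atol: float = 1e-9) -> PeakList:
        for p in self.points:
            if abs(p.ratio - ratio) <= atol:
                return p
        raise ValidationError(
            f"no titration point at ratio {ratio}; available: {self.ratios}"
        )


@dataclass
class MSSpectrum:
    """A centroided ESI-MS spectrum with the sample's total concentrations (uM)."""

    peptide_total: float
    metal_total: float
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.peptide_total < 0 or self.metal_total < 0:
            raise ValidationError("total concentrations must be >= 0")
        for i, (mz, area) in enumerate(self.peaks):
            if mz <= 0:
                raise ValidationError(f"peak {i}: m/z must be > 0 (got {mz})")
            if area < 0:
                raise ValidationError(f"peak {i}: area must be >= 0 (got {area})")

    @property
    def ratio(self) -> float:
        return self.metal_total / self.peptide_total if self.peptide_total else math.nan


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV or CSV table, sniffing the delimiter from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def read_peaklist(
    path: str | Path,
    spectrum_type: SpectrumType | str,
    ratio: float,
) -> PeakList:
    """Read one peak-list file into a validated :class:`PeakList`.

    Rows whose ``f1_ppm`` or ``f2_ppm`` cell is blank become ``present=False``
    peaks (cross-peak not visible at this titration point).
    """
    spectrum_type = SpectrumType.coerce(spectrum_type)
    df = _read_table(path)
    missing_cols = [c for c in PEAKLIST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    peaks: list[Peak2D] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            assignment = Assignment(
                residue_index=int(row["residue_index"]),
                residue_type=str(row["residue_type"]),
                atom_f1=str(row["atom_f1"]),
                atom_f2=str(row["atom_f2"]),
            )
            f1_raw, f2_raw = row["f1_ppm"], row["f2_ppm"]
            blank = any(pd.isna(v) or str(v).strip() == "" for v in (f1_raw, f2_raw))
            if blank:
                peaks.append(Peak2D(assignment, present=False))
            else:
                peaks.append(Peak2D(assignment, float(f1_raw), float(f2_raw)))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return PeakList(spectrum_type=spectrum_type, ratio=ratio, peaks=peaks)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list in the 6-column TSV dialect :func:`read_peaklist` reads."""
    rows = []
    for p in peaklist.peaks:
        a = p.assignment
        rows.append(
            {
                "residue_index": a.residue_index,
                "residue_type": a.residue_type,
                "atom_f1": a.atom_f1,
                "atom_f2": a.atom_f2,
                "f1_ppm": f"{p.f1_ppm:.6f}" if p.present else "",
                "f2_ppm": f"{p.f2_ppm:.6f}" if p.present else "",
            }
        )
    pd.DataFrame(rows, columns=PEAKLIST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_series(
    paths: Sequence[str | Path],
    ratios: Sequence[float],
    spectrum_type: SpectrumType | str,
    sequence: PeptideSequence,
) -> TitrationSeries:
    """Read several peak-list files into one ordered, reconciled series."""
    if len(paths) != len(ratios):
        raise ValidationError("paths and ratios must have equal length")
    if len(paths) < 2:
        raise ValidationError("a titration series needs >= 2 peak lists")
    points = [read_peaklist(p, spectrum_type, r) for p, r in zip(paths, ratios)]
    return TitrationSeries(sequence=sequence, points=points)


def read_ms_spectrum(
    path: str | Path,
    peptide_total: float,
    metal_total: float,
) -> MSSpectrum:
    """Read a two-column (mz, area) centroid list into an :class:`MSSpectrum`."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        logger.warning("%s: empty centroid list", path)
        return MSSpectrum(peptide_total, metal_total, [])
    peaks: list[tuple[float, float]] = []
    lines = text.splitlines()
    start = 0
    # tolerate an optional "mz,area" header
    first = re.split(r"[\t,]", lines[0])
    try:
        float(first[0])
    except ValueError:
        start = 1
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = re.split(r"[\t,]", line)
        if len(fields) < 2:
            raise ParseError(f"{path}: line {ln}: expected two columns")
        try:
            peaks.append((float(fields[0]), float(fields[1])))
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: {exc}") from exc
    return MSSpectrum(peptide_total, metal_total, peaks)


def write_ms_spectrum(spectrum: MSSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mz,area\n")
        for mz, area in spectrum.peaks:
            fh.write(f"{mz:.6f},{area:.6g}\n")
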