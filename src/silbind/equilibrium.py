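"""Peptide masses and the sequential two-site Ag+ binding equilibrium.

The binding model is a two-step (stepwise-constant) scheme for a peptide P
with a high-affinity and a low-affinity Ag+ site:

    P    + Ag+  <->  P.Ag     K_D1 = [P][Ag+] / [P.Ag]       (uM)
    P.Ag + Ag+  <->  P.Ag2    K_D2 = [P.Ag][Ag+] / [P.Ag2]   (uM)

Given total concentrations the species are the unique non-negative root of
the coupled mass balances, found by a bracketed scalar root find on the free
Ag+ concentration: substituting the equilibrium expressions, total silver

    Ag_tot(a) = a + P_tot * (a/K1 + 2 a^2/(K1 K2)) / (1 + a/K1 + a^2/(K1 K2))

is continuous and strictly increasing in the free concentration a, so a
Brent solve on a in [0, Ag_tot] is deterministic and globally convergent.

Masses come from the standard amino-acid composition tables shipped with
pyteomics (average by default — the convention of the printed peptide MWs —
or monoisotopic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

from pyteomics import mass as _ptmass
from scipy.optimize import brentq

from .core_io import PeptideSequence, ValidationError

#: electron mass, Da
_ELECTRON = 0.00054857990946
#: proton mass, Da (charge carrier in positive-mode ESI)
PROTON_MASS = 1.00727646677


class MassMode(str, Enum):
    AVERAGE = "average"
    MONOISOTOPIC = "monoisotopic"


@lru_cache(maxsize=None)
def silver_cation_mass(mode: MassMode = MassMode.AVERAGE) -> float:
    """Mass of Ag+ (Da): elemental silver minus one electron."""
    ag = _ptmass.calculate_mass(formula="Ag", average=(mode is MassMode.AVERAGE))
    return ag - _ELECTRON


def peptide_mass(
    sequence: PeptideSequence | str, mode: MassMode = MassMode.AVERAGE
) -> float:
    """Neutral peptide mass in Da (residue masses plus one water).

    ``mode`` selects the average (default) or monoisotopic atomic-mass
    convention; the average convention matches how peptide MWs are commonly
    printed on synthesis reports.
    """
    if isinstance(sequence, PeptideSequence):
        seq = sequence.one_letter
    else:
        seq = PeptideSequence(sequence).one_letter  # validates the alphabet
    mode = MassMode(mode)
    return float(_ptmass.calculate_mass(sequence=seq, average=(mode is MassMode.AVERAGE)))


@dataclass(frozen=True)
class BindingModel:
    """Stepwise dissociation constants (uM) of the sequential two-site scheme."""

    kd1: float
    kd2: float

    def __post_init__(self) -> None:
        if not (self.kd1 > 0 and self.kd2 > 0):
            raise ValidationError("dissociation constants must be > 0")


@dataclass(frozen=True)
class SpeciesState:
    """Solved species concentrations (uM) at one titration point."""

    p_free: float
    pag: float
    pag2: float
    ag_free: float
    p_total: float
    ag_total: float

    _MASS_BALANCE_RTOL = 1e-9

    def __post_init__(self) -> None:
        for name in ("p_free", "pag", "pag2", "ag_free"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        scale_p = max(self.p_total, 1.0)
        if abs(self.p_free + self.pag + self.pag2 - self.p_total) > self._MASS_BALANCE_RTOL * scale_p:
            raise ValidationError("peptide mass balance violated")
        scale_ag = max(self.ag_total, 1.0)
        if abs(self.ag_free + self.pag + 2 * self.pag2 - self.ag_total) > self._MASS_BALANCE_RTOL * scale_ag:
            raise ValidationError("silver mass balance violated")

    @property
    def mean_occupancy(self) -> float:
        """Mean number of bound Ag+ per peptide."""
        if self.p_total == 0:
            return 0.0
        return (self.pag + 2 * self.pag2) / self.p_total

    @property
    def fractions(self) -> tuple[float, float, float]:
        """Mole fractions (f0, f1, f2) of peptide as P, P.Ag, P.Ag2."""
        if self.p_total == 0:
            return (math.nan, math.nan, math.nan)
        return (
            self.p_free / self.p_total,
            self.pag / self.p_total,
            self.pag2 / self.p_total,
        )


_MAX_ITER = 200


def _species_at_free_ag(model: BindingModel, p_total: float, a: float):
    denom = 1.0 + a / model.kd1 + a * a / (model.kd1 * model.kd2)
    p_free = p_total / denom
    pag = p_free * a / model.kd1
    pag2 = pag * a / model.kd2
    return p_free, pag, pag2


def solve_species(
    model: BindingModel, p_total: float, ag_total: float
) -> SpeciesState:
    """Solve the two-site mass-balance system for one titration point.

    Both conservation laws hold at the returned state to a relative tolerance
    of 1e-9.  Deterministic: bracketed Brent root find on free Ag+ in
    [0, ag_total], no random starts.
    """
    if p_total < 0 or ag_total < 0:
        raise ValidationError("total concentrations must be >= 0")
    if ag_total == 0 or p_total == 0:
        pag = pag2 = 0.0
        return SpeciesState(p_total, pag, pag2, ag_total, p_total, ag_total)

    def residual(a: float) -> float:
        _, pag, pag2 = _species_at_free_ag(model, p_total, a)
        return a + pag + 2 * pag2 - ag_total

    lo, hi = 0.0, ag_total
    # residual(0) = -ag_total < 0; residual(ag_total) >= 0
    try:
        a = brentq(residual, lo, hi, xtol=1e-15, rtol=1e-14, maxiter=_MAX_ITER)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - diagnostics path
        raise ValidationError(
            f"equilibrium solve failed for kd1={model.kd1}, kd2={model.kd2}, "
            f"p_total={p_total}, ag_total={ag_total}: {exc}"
        ) from exc
    p_free, pag, pag2 = _species_at_free_ag(model, p_total, a)
    # absorb residual rounding into the free pools so both balances close exactly
    p_free = p_total - pag - pag2
    a = ag_total - pag - 2 * pag2
    return SpeciesState(max(p_free, 0.0), pag, pag2, max(a, 0.0), p_total, ag_total)


def binding_isotherm(
    model: BindingModel, p_total: float, ratios: list[float]
) -> list[SpeciesState]:
    """Species states along a titration: ag_total = ratio * p_total per point."""
    for r in ratios:
        if r < 0:
            raise ValidationError("ratios must be >= 0")
    return [solve_species(model, p_total, r * p_total) for r in ratios]
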