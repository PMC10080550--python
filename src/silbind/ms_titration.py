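"""ESI-MS species assignment, quantification, and K_D fitting.

Positive-mode metalated-peptide adduct convention: each bound Ag+ carries one
charge and the remaining charges are protons, so a k-mer with n silver ions
at charge z appears at

    m/z = (k*M + n*m(Ag+) + (z - n)*m(H+)) / z

Centroids are matched to the nearest theoretical m/z within a ppm tolerance;
areas are summed over all observed charge states of a species ("all detected
positive charge states considered").  Dimers are treated as nonspecific
gas-phase association of the apo pool: their areas contribute two peptide
equivalents to the apo fraction and no separate equilibrium is fitted.
Species with two or more bound Ag are pooled into the doubly-bound fraction;
the adduct with n = 3 is thereby quantified but not given a third binding
step.

``fit_kds`` performs deterministic least squares on the mole fractions
(f0, f1, f2) against the sequential two-site mass-balance model, with the
dissociation constants log-parameterised and started from a fixed documented
point (1 uM, 10 uM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_io import MSSpectrum, PeptideSequence, ValidationError
from .equilibrium import (
    BindingModel,
    MassMode,
    PROTON_MASS,
    peptide_mass,
    silver_cation_mass,
    solve_species,
)

DEFAULT_TOL_PPM = 10.0
DEFAULT_N_MAX = 3
DEFAULT_Z_RANGE = (2, 3)
DEFAULT_K_RANGE = (1, 2)
#: fixed documented starting point of the K_D fit (uM)
DEFAULT_FIT_START = BindingModel(1.0, 10.0)
#: below this Jacobian-column norm the first constant is reported as an
#: upper bound only (binding too tight to resolve at the working concentration)
KD1_SENSITIVITY_FLOOR = 1e-3


def theoretical_mz(
    peptide_mass_da: float,
    oligomer_k: int = 1,
    n_ag: int = 0,
    charge_z: int = 1,
    mass_mode: MassMode = MassMode.AVERAGE,
) -> float:
    """Theoretical m/z (Th) of a (peptide_k)(Ag)_n adduct at charge z."""
    if charge_z < 1:
        raise ValidationError("charge_z must be >= 1")
    if n_ag < 0 or oligomer_k < 1:
        raise ValidationError("n_ag >= 0 and oligomer_k >= 1 required")
    if charge_z - n_ag < 0:
        raise ValidationError(
            f"charge deficit: z={charge_z} < n_ag={n_ag} under the "
            "one-charge-per-Ag+ convention"
        )
    m = (
        oligomer_k * peptide_mass_da
        + n_ag * silver_cation_mass(mass_mode)
        + (charge_z - n_ag) * PROTON_MASS
    )
    return m / charge_z


@dataclass
class SpeciesAssignment:
    """Matched centroids of one (oligomer, Ag count, charge) species."""

    oligomer_k: int
    n_ag: int
    charge_z: int
    theo_mz: float
    matched_peaks: list[int] = field(default_factory=list)
    total_area: float = 0.0

    @property
    def species_key(self) -> tuple[int, int]:
        return (self.oligomer_k, self.n_ag)


@dataclass
class AssignmentResult:
    """Outcome of annotating one spectrum, with the sample totals carried along."""

    assignments: list[SpeciesAssignment]
    unmatched_peaks: list[int]
    ambiguous_peaks: list[int]
    peptide_total: float
    metal_total: float

    @property
    def max_n_ag(self) -> int:
        return max((a.n_ag for a in self.assignments), default=0)


def _candidate_species(
    mass_da: float,
    n_max: int,
    z_range: tuple[int, int],
    k_range: tuple[int, int],
    dimer_n_max: int,
    mass_mode: MassMode,
) -> list[tuple[int, int, int, float]]:
    out = []
    for k in range(k_range[0], k_range[1] + 1):
        k_n_max = n_max if k == 1 else dimer_n_max
        for n in range(0, k_n_max + 1):
            for z in range(z_range[0], z_range[1] + 1):
                if z < n:
                    continue  # charge deficit under the adduct convention
                out.append((k, n, z, theoretical_mz(mass_da, k, n, z, mass_mode)))
    return out


def assign_species(
    spectrum: MSSpectrum,
    peptide: PeptideSequence | str,
    n_max: int = DEFAULT_N_MAX,
    z_range: tuple[int, int] = DEFAULT_Z_RANGE,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    tol_ppm: float = DEFAULT_TOL_PPM,
    dimer_n_max: int = 0,
    mass_mode: MassMode = MassMode.AVERAGE,
) -> AssignmentResult:
    """Match centroids to the theoretical Ag-adduct series of the peptide.

    Each centroid is assigned to the candidate species with the smallest ppm
    error within ``tol_ppm``; exact ties are flagged ambiguous and excluded
    from quantification.  Dimer candidates default to the apo dimer only
    (``dimer_n_max=0``): metalated dimers are m/z-degenerate with monomer
    species at half the charge and cannot be resolved without isotope
    modelling.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be > 0")
    mass_da = peptide_mass(peptide, mass_mode)
    candidates = _candidate_species(mass_da, n_max, z_range, k_range, dimer_n_max, mass_mode)
    by_candidate: dict[tuple[int, int, int], SpeciesAssignment] = {}
    unmatched: list[int] = []
    ambiguous: list[int] = []
    for idx, (mz, area) in enumerate(spectrum.peaks):
        errors = [
            (abs(mz - theo) / theo * 1e6, (k, n, z, theo))
            for k, n, z, theo in candidates
        ]
        errors.sort(key=lambda e: e[0])
        best_err, (k, n, z, theo) = errors[0]
        if best_err > tol_ppm:
            unmatched.append(idx)
            continue
        if len(errors) > 1 and math.isclose(errors[1][0], best_err, abs_tol=1e-9):
            ambiguous.append(idx)
            continue
        key = (k, n, z)
        if key not in by_candidate:
            by_candidate[key] = SpeciesAssignment(k, n, z, theo)
        by_candidate[key].matched_peaks.append(idx)
        by_candidate[key].total_area += area
    assignments = sorted(
        by_candidate.values(), key=lambda a: (a.oligomer_k, a.n_ag, a.charge_z)
    )
    return AssignmentResult(
        assignments, unmatched, ambiguous, spectrum.peptide_total, spectrum.metal_total
    )


@dataclass(frozen=True)
class TitrationQuant:
    """Peptide mole fractions at one titration point.

    f0, f1, f2 are the fractions of peptide (in peptide equivalents) present
    as P, P.Ag and P.Ag(>=2); ``areas`` stores raw summed areas keyed by
    (oligomer_k, n_ag).
    """

    f0: float
    f1: float
    f2: float
    peptide_total: float
    metal_total: float
    areas: tuple[tuple[tuple[int, int], float], ...] = ()

    def __post_init__(self) -> None:
        total = self.f0 + self.f1 + self.f2
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions must sum to 1 (got {total})")
        for f in (self.f0, self.f1, self.f2):
            if not -1e-12 <= f <= 1 + 1e-12:
                raise ValidationError("fractions must lie in [0, 1]")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


def quantify(result: AssignmentResult) -> TitrationQuant:
    """Peptide mole fractions from the assigned species areas.

    Areas are weighted by the species' peptide count (dimers count twice);
    dimer equivalents join the apo pool (gas-phase artifact convention) and
    monomer species with n >= 2 are pooled into f2.  Equal response factors
    across species are assumed (the proportionality assumption); the result
    is invariant to rescaling all areas.
    """
    if not result.assignments:
        raise ValidationError("no assigned species to quantify")
    area_by_species: dict[tuple[int, int], float] = {}
    pools = {0: 0.0, 1: 0.0, 2: 0.0}
    for a in result.assignments:
        equiv = a.oligomer_k * a.total_area
        area_by_species[a.species_key] = area_by_species.get(a.species_key, 0.0) + a.total_area
        if a.oligomer_k >= 2:
            pools[0] += equiv  # nonspecific dimer -> apo pool
        elif a.n_ag == 0:
            pools[0] += equiv
        elif a.n_ag == 1:
            pools[1] += equiv
        else:
            pools[2] += equiv
    total = sum(pools.values())
    if total <= 0:
        raise ValidationError("zero total area; cannot quantify")
    return TitrationQuant(
        f0=pools[0] / total,
        f1=pools[1] / total,
        f2=pools[2] / total,
        peptide_total=result.peptide_total,
        metal_total=result.metal_total,
        areas=tuple(sorted(area_by_species.items())),
    )


@dataclass(frozen=True)
class FitResult:
    """Recovered stepwise dissociation constants from a titration fit."""

    kd1_hat: float
    kd2_hat: float
    sse: float
    converged: bool
    n_points: int = 0
    kd1_sensitivity: float = math.nan
    kd1_is_upper_bound: bool = False

    def __post_init__(self) -> None:
        if self.converged and not (self.kd1_hat > 0 and self.kd2_hat > 0):
            raise ValidationError("converged estimates must be > 0")


def _model_fractions(log10_kds: np.ndarray, quants: list[TitrationQuant]) -> np.ndarray:
    model = BindingModel(10.0 ** log10_kds[0], 10.0 ** log10_kds[1])
    rows = []
    for q in quants:
        state = solve_species(model, q.peptide_total, q.metal_total)
        rows.append(state.fractions)
    return np.asarray(rows)


def fit_kds(
    quants: list[TitrationQuant],
    init: BindingModel = DEFAULT_FIT_START,
) -> FitResult:
    """Least-squares fit of (K_D1, K_D2) to observed peptide mole fractions.

    Minimises the stacked residuals f_observed - f_model over the titration
    points, with the constants log10-parameterised and bounded in
    [1e-6, 1e9] uM.  Deterministic given the starting model.
    """
    if len(quants) < 3:
        raise ValidationError("K_D fitting needs >= 3 titration points")
    if not any(q.metal_total > 0 for q in quants):
        raise ValidationError("at least one titration point must contain metal")
    observed = np.asarray([q.fractions for q in quants])

    def residuals(x: np.ndarray) -> np.ndarray:
        return (_model_fractions(x, quants) - observed).ravel()

    x0 = np.log10([init.kd1, init.kd2])
    sol = least_squares(
        residuals,
        x0,
        bounds=(np.log10([1e-6, 1e-6]), np.log10([1e9, 1e9])),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        method="trf",
    )
    kd1_hat, kd2_hat = (10.0 ** sol.x).tolist()
    sse = float(np.sum(sol.fun ** 2))
    sensitivity = float(np.linalg.norm(sol.jac[:, 0])) if sol.jac is not None else math.nan
    return FitResult(
        kd1_hat=kd1_hat,
        kd2_hat=kd2_hat,
        sse=sse,
        converged=bool(sol.success),
        n_points=len(quants),
        kd1_sensitivity=sensitivity,
        kd1_is_upper_bound=bool(sensitivity < KD1_SENSITIVITY_FLOOR),
    )
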