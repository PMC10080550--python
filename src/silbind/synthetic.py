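"""Synthetic NMR titration series and ESI-MS spectra for end-to-end testing.

Two NMR generator modes:

* ``equilibrium`` — physically grounded fast-exchange behaviour: at each
  titration ratio the occupancies of the two sites are solved from the
  sequential two-site mass balance, and each peak sits at the
  population-weighted average position
  ``base + f1 * site1_vector + f2 * site2_vector``.
* ``piecewise`` — a phenomenological two-mode path with an explicit vertex:
  the peak moves linearly towards its pre-break displacement up to the break
  ratio, then linearly along a different direction to the final ratio.  This
  mode reproduces a clean direction change at a chosen equivalence point and
  is used by the ``sp2-paper`` preset.

The MS generator builds stick spectra from the two-site isotherm: species
areas are proportional to concentration times a response factor, distributed
over charge states, with optional apo-dimer peaks (nonspecific gas-phase
association drawn from the free-peptide pool) and an optional small n=3
adduct split off the doubly-bound pool, so the 0-3 Ag adduct family appears
while the solution equilibrium stays two-site.

All randomness flows through one seeded generator; seeded runs are
bit-reproducible.  Presets are packaged YAML files loadable by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .core_io import (
    Assignment,
    MSSpectrum,
    Peak2D,
    PeakList,
    PeptideSequence,
    SpectrumType,
    TitrationSeries,
    ValidationError,
)
from .equilibrium import BindingModel, binding_isotherm, peptide_mass
from .ms_titration import theoretical_mz
from .secondary_structure import RandomCoilTable

DEFAULT_SEED = 1722
#: general-purpose noise defaults (conventions for test design; presets are noiseless)
DEFAULT_NOISE_SD_PPM = 0.002
DEFAULT_NOISE_CV = 0.05

PRESET_FILES = {"sp2-paper": "sp2_paper.yaml", "sp3-paper": "sp3_paper.yaml"}


@dataclass(frozen=True)
class MoverSpec:
    """Piecewise two-mode path of one cross-peak (ppm displacements)."""

    atoms: tuple[str, str]
    pre: tuple[float, float]    # displacement accumulated at the break ratio
    post: tuple[float, float]   # additional displacement from break to end


@dataclass
class NMRSimConfig:
    """Configuration of a synthetic NMR titration series.

    Residue keys in ``site1``/``site2``/``movers`` use protein numbering
    (``sequence.numbering_offset`` applies).  ``site1``/``site2`` map residue
    -> (d_f1, d_f2) bound-state shift vectors for equilibrium mode; ``movers``
    holds :class:`MoverSpec` paths for piecewise mode.
    """

    sequence: PeptideSequence
    ratios: list[float]
    spectrum_type: SpectrumType = SpectrumType.TOCSY
    mode: str = "equilibrium"                 # "equilibrium" | "piecewise"
    model: BindingModel | None = None
    p_total: float = 1000.0                   # uM; NMR-scale peptide concentration
    site1: dict[int, tuple[float, float]] = field(default_factory=dict)
    site2: dict[int, tuple[float, float]] = field(default_factory=dict)
    movers: dict[int, MoverSpec] = field(default_factory=dict)
    break_ratio: float = 0.5
    noise_sd: float = DEFAULT_NOISE_SD_PPM
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.spectrum_type = SpectrumType.coerce(self.spectrum_type)
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if 0.0 not in self.ratios:
            raise ValidationError("ratios must include the reference point 0.0")
        if self.mode not in ("equilibrium", "piecewise"):
            raise ValidationError(f"unknown NMR generator mode {self.mode!r}")
        if self.mode == "equilibrium" and self.model is None:
            raise ValidationError("equilibrium mode requires a BindingModel")
        for residues in (self.site1, self.site2, self.movers):
            for protein_idx in residues:
                local = self.sequence.local_index(protein_idx)
                if not 1 <= local <= len(self.sequence):
                    raise ValidationError(
                        f"residue {protein_idx} outside sequence "
                        f"{self.sequence.numbering_offset}.."
                        f"{self.sequence.protein_index(len(self.sequence))}"
                    )

    def two_mode_residues(self) -> list[int]:
        """Protein-numbered residues whose path genuinely turns.

        Piecewise mode: movers with non-parallel pre/post vectors.
        Equilibrium mode: residues with non-parallel site1/site2 vectors.
        """
        out = []
        if self.mode == "piecewise":
            for idx, spec in self.movers.items():
                if _nonparallel(spec.pre, spec.post):
                    out.append(idx)
        else:
            for idx in set(self.site1) & set(self.site2):
                if _nonparallel(self.site1[idx], self.site2[idx]):
                    out.append(idx)
        return sorted(out)


def _nonparallel(u: tuple[float, float], v: tuple[float, float]) -> bool:
    cross = u[0] * v[1] - u[1] * v[0]
    nu, nv = math.hypot(*u), math.hypot(*v)
    return nu > 0 and nv > 0 and abs(cross) / (nu * nv) > 1e-9


def _baseline_positions(
    sequence: PeptideSequence, spectrum_type: SpectrumType
) -> dict[Assignment, tuple[float, float]]:
    """Deterministic free-state peak positions spread over realistic windows."""
    positions: dict[Assignment, tuple[float, float]] = {}
    rc = RandomCoilTable.default() if spectrum_type is SpectrumType.HSQC_CH else None
    for local in range(1, len(sequence) + 1):
        res = sequence.residue_type(local)
        if spectrum_type is SpectrumType.TOCSY:
            a = Assignment(local, res, "H", "HA")
            nh = 7.9 + 0.05 * ((local * 3) % 9)       # 7.9-8.3 ppm amide window
            ha = 4.05 + 0.04 * ((local * 5) % 7)      # 4.05-4.3 ppm alpha window
            positions[a] = (nh, ha)
        else:
            a = Assignment(local, res, "CA", "HA")
            ca = rc[res] + 0.2 * ((local * 3) % 5 - 2)  # near random coil
            ha = 4.05 + 0.04 * ((local * 5) % 7)
            positions[a] = (ca, ha)
    return positions


def _extra_mover_positions(
    config: NMRSimConfig, positions: dict[Assignment, tuple[float, float]]
) -> None:
    """Add cross-peaks movers reference beyond the default H/HA (e.g. H/HG)."""
    for protein_idx, spec in config.movers.items():
        local = config.sequence.local_index(protein_idx)
        res = config.sequence.residue_type(local)
        a = Assignment(local, res, *spec.atoms)
        if a in positions:
            continue
        nh = 8.0 + 0.05 * ((local * 7) % 7)
        side = 0.9 + 0.05 * ((local * 2) % 6)  # side-chain 1H window
        positions[a] = (nh, side)


def generate_nmr_series(config: NMRSimConfig) -> TitrationSeries:
    """Generate a titration series of assigned peak lists under ``config``."""
    rng = np.random.default_rng(config.seed)
    positions = _baseline_positions(config.sequence, config.spectrum_type)
    if config.mode == "piecewise":
        _extra_mover_positions(config, positions)

    displacement: dict[Assignment, dict[float, tuple[float, float]]] = {}
    ratios = sorted(config.ratios)
    if config.mode == "equilibrium":
        states = binding_isotherm(config.model, config.p_total, ratios)
        occupancy = {r: (s.pag / s.p_total, s.pag2 / s.p_total) for r, s in zip(ratios, states)}
        for a in positions:
            protein_idx = config.sequence.protein_index(a.residue_index)
            v1 = config.site1.get(protein_idx, (0.0, 0.0))
            v2 = config.site2.get(protein_idx, (0.0, 0.0))
            displacement[a] = {
                r: (
                    f1 * v1[0] + f2 * v2[0],
                    f1 * v1[1] + f2 * v2[1],
                )
                for r, (f1, f2) in occupancy.items()
            }
    else:
        b, r_max = config.break_ratio, max(ratios)
        for a in positions:
            protein_idx = config.sequence.protein_index(a.residue_index)
            spec = config.movers.get(protein_idx)
            per_ratio: dict[float, tuple[float, float]] = {}
            for r in ratios:
                if spec is None or (spec.atoms != (a.atom_f1, a.atom_f2)):
                    per_ratio[r] = (0.0, 0.0)
                    continue
                if r <= b:
                    t = r / b if b > 0 else 1.0
                    per_ratio[r] = (t * spec.pre[0], t * spec.pre[1])
                else:
                    t = (r - b) / (r_max - b) if r_max > b else 1.0
                    per_ratio[r] = (
                        spec.pre[0] + t * spec.post[0],
                        spec.pre[1] + t * spec.post[1],
                    )
            displacement[a] = per_ratio

    points = []
    for r in ratios:
        peaks = []
        for a, (base1, base2) in positions.items():
            d1, d2 = displacement[a][r]
            n1 = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            n2 = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            peaks.append(Peak2D(a, base1 + d1 + n1, base2 + d2 + n2))
        points.append(PeakList(config.spectrum_type, r, peaks))
    return TitrationSeries(sequence=config.sequence, points=points)


@dataclass
class MSSimConfig:
    """Configuration of a synthetic ESI-MS titration.

    ``dimer_fraction`` of the free-peptide pool appears as apo dimer (two
    peptide equivalents per dimer); ``ag3_fraction`` of the doubly-bound pool
    appears as a gas-phase n=3 adduct.  ``response_factors`` maps species key
    (oligomer_k, n_ag) to a relative response (default 1).
    """

    sequence: PeptideSequence
    model: BindingModel
    p_total: float = 100.0          # uM
    ratios: list[float] = field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0])
    z_range: tuple[int, int] = (2, 3)
    charge_weights: dict[int, float] = field(default_factory=lambda: {2: 0.6, 3: 0.4})
    dimer_fraction: float = 0.35
    ag3_fraction: float = 0.05
    response_factors: dict[tuple[int, int], float] = field(default_factory=dict)
    base_area: float = 1000.0       # area units per uM at unit response
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0.0 <= self.dimer_fraction < 1.0:
            raise ValidationError("dimer_fraction must lie in [0, 1)")
        if not 0.0 <= self.ag3_fraction < 1.0:
            raise ValidationError("ag3_fraction must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")

    def response(self, key: tuple[int, int]) -> float:
        return self.response_factors.get(key, 1.0)


def generate_ms_titration(config: MSSimConfig) -> list[MSSpectrum]:
    """Stick ESI-MS spectra along the titration, one per ratio."""
    rng = np.random.default_rng(config.seed)
    mass_da = peptide_mass(config.sequence)
    states = binding_isotherm(config.model, config.p_total, sorted(config.ratios))
    spectra: list[MSSpectrum] = []
    for state in states:
        # species concentrations (uM); dimer counted as a species of 2 peptides
        mono_apo = (1.0 - config.dimer_fraction) * state.p_free
        dimer = config.dimer_fraction * state.p_free / 2.0
        gamma = config.ag3_fraction if state.ag_total > 0 else 0.0
        conc: dict[tuple[int, int], float] = {
            (1, 0): mono_apo,
            (1, 1): state.pag,
            (1, 2): (1.0 - gamma) * state.pag2,
            (1, 3): gamma * state.pag2,
            (2, 0): dimer,
        }
        peaks: list[tuple[float, float]] = []
        for (k, n), c in conc.items():
            if c <= 0:
                continue
            z_allowed = [z for z in range(config.z_range[0], config.z_range[1] + 1) if z >= n]
            if not z_allowed:
                raise ValidationError(f"no admissible charge state for species k={k}, n={n}")
            weights = np.array([config.charge_weights.get(z, 1.0) for z in z_allowed])
            weights = weights / weights.sum()
            for z, w in zip(z_allowed, weights):
                area = config.base_area * config.response((k, n)) * c * w
                if config.noise_cv > 0:
                    area *= max(0.0, 1.0 + rng.normal(0.0, config.noise_cv))
                peaks.append((theoretical_mz(mass_da, k, n, z), area))
        peaks.sort()
        spectra.append(MSSpectrum(state.p_total, state.ag_total, peaks))
    return spectra


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _load_preset_dict(name: str) -> dict:
    try:
        filename = PRESET_FILES[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; available: {sorted(PRESET_FILES)}")
    ref = resources.files("silbind.data").joinpath(filename)
    return yaml.safe_load(ref.read_text())


def load_preset(name: str, seed: int | None = None) -> NMRSimConfig | MSSimConfig:
    """Load a packaged preset ('sp2-paper' or 'sp3-paper') by name.

    ``seed`` overrides the preset's seed (the presets are noiseless, so the
    seed only matters if noise is switched on afterwards).
    """
    raw = _load_preset_dict(name)
    sequence = PeptideSequence(raw["sequence"], raw.get("numbering_offset", 1))
    if raw["kind"] == "nmr":
        movers = {
            int(idx): MoverSpec(
                atoms=tuple(m["atoms"]), pre=tuple(m["pre"]), post=tuple(m["post"])
            )
            for idx, m in raw.get("movers", {}).items()
        }
        return NMRSimConfig(
            sequence=sequence,
            ratios=list(raw["ratios"]),
            spectrum_type=SpectrumType.coerce(raw["spectrum_type"]),
            mode=raw.get("mode", "piecewise"),
            movers=movers,
            break_ratio=float(raw.get("break_ratio", 0.5)),
            noise_sd=float(raw.get("noise_sd", 0.0)),
            seed=int(seed if seed is not None else raw.get("seed", DEFAULT_SEED)),
        )
    if raw["kind"] == "ms":
        return MSSimConfig(
            sequence=sequence,
            model=BindingModel(float(raw["kd1_um"]), float(raw["kd2_um"])),
            p_total=float(raw["p_total_um"]),
            ratios=list(raw["ratios"]),
            z_range=tuple(raw.get("z_range", (2, 3))),
            charge_weights={int(z): float(w) for z, w in raw.get("charge_weights", {}).items()},
            dimer_fraction=float(raw.get("dimer_fraction", 0.0)),
            ag3_fraction=float(raw.get("ag3_fraction", 0.0)),
            noise_cv=float(raw.get("noise_cv", 0.0)),
            seed=int(seed if seed is not None else raw.get("seed", DEFAULT_SEED)),
        )
    raise ValidationError(f"preset {name!r} has unknown kind {raw['kind']!r}")
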