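"""Model/Results interface for the two-site Ag+ binding fit.

:class:`AgBindingTitration` is built from quantified titration points (or
directly from spectra via :meth:`AgBindingTitration.from_spectra`); its
:meth:`~AgBindingTitration.fit` returns :class:`AgBindingResults`, which
carries the estimated stepwise dissociation constants, their asymptotic
standard errors, fit diagnostics, prediction, plotting, and a text
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MSSpectrum, PeptideSequence, ValidationError
from .equilibrium import BindingModel, solve_species
from .ms_titration import (
    DEFAULT_FIT_START,
    FitResult,
    TitrationQuant,
    assign_species,
    fit_kds,
    quantify,
)


class AgBindingTitration:
    """Sequential two-site Ag+ binding model over an ESI-MS titration.

    Parameters
    ----------
    quants
        Quantified titration points (peptide mole fractions plus totals),
        one per Ag+:peptide ratio.
    """

    def __init__(self, quants: list[TitrationQuant]):
        if len(quants) < 3:
            raise ValidationError("the titration model needs >= 3 points")
        self.quants = sorted(quants, key=lambda q: q.metal_total)
        self.endog = np.asarray([q.fractions for q in self.quants])
        self.exog = np.asarray([(q.peptide_total, q.metal_total) for q in self.quants])

    @classmethod
    def from_spectra(
        cls,
        spectra: list[MSSpectrum],
        peptide: PeptideSequence | str,
        **assign_kwargs,
    ) -> "AgBindingTitration":
        """Annotate and quantify raw spectra, then build the model."""
        quants = [quantify(assign_species(s, peptide, **assign_kwargs)) for s in spectra]
        return cls(quants)

    def predict(self, model: BindingModel) -> pd.DataFrame:
        """Model mole fractions at the observed titration points."""
        rows = []
        for p_total, ag_total in self.exog:
            state = solve_species(model, p_total, ag_total)
            rows.append(
                {
                    "peptide_total": p_total,
                    "metal_total": ag_total,
                    "ratio": ag_total / p_total if p_total else math.nan,
                    "f0": state.fractions[0],
                    "f1": state.fractions[1],
                    "f2": state.fractions[2],
                }
            )
        return pd.DataFrame(rows)

    def fit(self, start: BindingModel = DEFAULT_FIT_START) -> "AgBindingResults":
        """Deterministic least-squares fit from the documented starting point."""
        result = fit_kds(self.quants, init=start)
        return AgBindingResults(self, result)


@dataclass
class AgBindingResults:
    """Results of fitting :class:`AgBindingTitration`."""

    model: AgBindingTitration
    fit_result: FitResult

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"kd1_uM": self.fit_result.kd1_hat, "kd2_uM": self.fit_result.kd2_hat}
        )

    @property
    def binding_model(self) -> BindingModel:
        return BindingModel(self.fit_result.kd1_hat, self.fit_result.kd2_hat)

    @property
    def sse(self) -> float:
        return self.fit_result.sse

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def bse(self) -> pd.Series:
        """Asymptotic standard errors (uM) from the Gauss-Newton curvature.

        Computed on the log10 scale via a finite-difference Jacobian at the
        optimum and propagated back; NaN when the curvature is singular
        (e.g. a constant that the data do not constrain).
        """
        x_hat = np.log10([self.fit_result.kd1_hat, self.fit_result.kd2_hat])
        observed = self.model.endog

        def residuals(x: np.ndarray) -> np.ndarray:
            m = BindingModel(10.0 ** x[0], 10.0 ** x[1])
            rows = [
                solve_species(m, p, a).fractions for p, a in self.model.exog
            ]
            return (np.asarray(rows) - observed).ravel()

        eps = 1e-6
        jac = np.empty((observed.size, 2))
        base = residuals(x_hat)
        for j in range(2):
            step = np.zeros(2)
            step[j] = eps
            jac[:, j] = (residuals(x_hat + step) - base) / eps
        dof = max(observed.size - 2, 1)
        s2 = float(base @ base) / dof
        try:
            cov_log = s2 * np.linalg.inv(jac.T @ jac)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            se_log = np.full(2, np.nan)
        # delta method: d(kd)/d(log10 kd) = kd * ln(10)
        kds = 10.0 ** x_hat
        return pd.Series(
            {"kd1_uM": kds[0] * math.log(10) * se_log[0],
             "kd2_uM": kds[1] * math.log(10) * se_log[1]}
        )

    def fittedvalues(self) -> pd.DataFrame:
        return self.model.predict(self.binding_model)

    def resid(self) -> np.ndarray:
        fitted = self.fittedvalues()[["f0", "f1", "f2"]].to_numpy()
        return self.model.endog - fitted

    def summary(self) -> str:
        """Text summary of the fit in a statsmodels-like layout."""
        se = self.bse()
        lines = [
            "Sequential two-site Ag+ binding fit",
            "=" * 52,
            f"{'titration points':<28}{self.fit_result.n_points:>24}",
            f"{'converged':<28}{str(self.converged):>24}",
            f"{'SSE (mole fractions)':<28}{self.sse:>24.3e}",
            "-" * 52,
            f"{'parameter':<12}{'estimate (uM)':>20}{'std err (uM)':>20}",
            f"{'K_D1':<12}{self.fit_result.kd1_hat:>20.4g}{se['kd1_uM']:>20.3g}",
            f"{'K_D2':<12}{self.fit_result.kd2_hat:>20.4g}{se['kd2_uM']:>20.3g}",
            "-" * 52,
        ]
        if self.fit_result.kd1_is_upper_bound:
            lines.append(
                "note: K_D1 sensitivity below threshold at this peptide\n"
                "concentration; the estimate is an upper bound, not a\n"
                "resolved value."
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs fitted mole fractions against added Ag+ equivalents."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ratios = self.model.exog[:, 1] / self.model.exog[:, 0]
        fitted = self.fittedvalues()
        labels = ["P", "P·Ag", "P·Ag₂"]
        for i, (col, label) in enumerate(zip(["f0", "f1", "f2"], labels)):
            ax.plot(ratios, self.model.endog[:, i], "o", label=f"{label} (obs)")
            ax.plot(ratios, fitted[col], "-", label=f"{label} (fit)")
        ax.set_xlabel("Ag⁺ : peptide (equivalents)")
        ax.set_ylabel("peptide mole fraction")
        ax.legend(fontsize=8)
        return ax
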