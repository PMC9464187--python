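"""Binding affinity and thermodynamic analysis.

Quantities derived from surface plasmon resonance measurements:
affinity windows (K_D wild-type over K_D mutant — the selectivity of a
TCR for the neoantigen), fold changes, Gibbs free energy from K_D,
complex half-life from k_off, and van't Hoff fitting of the temperature
dependence of K_D to extract binding enthalpy and entropy (with an
optional heat-capacity term).

Units: K_D in molar, temperatures in Kelvin, energies in kcal/mol,
entropies in kcal/(mol K). The gas constant R = 1.9872e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3

#: Reference temperature (25 C), the SPR standard.
T_REF_DEFAULT = 298.15

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
                  "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class AffinityRecord:
    """A single K_D measurement (molar) at one temperature.

    ``kd_is_lower_bound`` marks censored entries (">" or no-binding
    rows): the true K_D is at least the stored value, so any window
    using it as numerator is itself a lower bound.
    """

    tcr_id: str
    phla_id: str
    kd: float
    temperature: float = T_REF_DEFAULT
    koff: float | None = None
    kd_is_lower_bound: bool = False

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"K_D must be positive, got {self.kd}")
        if self.koff is not None and not self.koff > 0:
            raise ValueError(f"k_off must be positive, got {self.koff}")
        if not (273.0 < self.temperature < 323.0):
            raise ValueError(
                f"temperature {self.temperature} K outside the plausible "
                "SPR range (273, 323)"
            )


@dataclass(frozen=True)
class ThermoParams:
    """Fitted binding thermodynamics at a reference temperature.

    ``dg = dh - T_ref * ds`` (the heat-capacity correction is folded
    into the reference-temperature values by construction of the fit).
    """

    dh: float          # kcal/mol at T_ref
    ds: float          # kcal/(mol K) at T_ref
    dcp: float         # kcal/(mol K); 0 for the linear model
    t_ref: float
    residual_ss: float
    model: str

    @property
    def tds(self) -> float:
        return self.t_ref * self.ds

    @property
    def dg(self) -> float:
        return self.dh - self.t_ref * self.ds

    def delta_g(self, temperature: float) -> float:
        """Integrated Gibbs-Helmholtz ΔG(T) in kcal/mol."""
        t = temperature
        return (
            self.dh
            + self.dcp * (t - self.t_ref)
            - t * (self.ds + self.dcp * math.log(t / self.t_ref))
        )

    def kd(self, temperature: float) -> float:
        """Model K_D(T) = exp(ΔG(T) / (R T)) in molar."""
        return math.exp(self.delta_g(temperature) / (R_KCAL * temperature))


def affinity_window(kd_wt: float, kd_mut: float) -> float:
    """Selectivity window K_D(wild-type) / K_D(mutant).

    Larger values mean stronger selectivity for the mutant epitope. If
    the wild-type K_D is censored (no measurable binding), the result
    is a lower bound on the true window.
    """
    if not (kd_wt > 0 and kd_mut > 0):
        raise ValueError("K_D values must be positive")
    return kd_wt / kd_mut


def fold_change(kd_variant: float, kd_reference: float) -> float:
    """K_D(reference) / K_D(variant).

    With the reference the unmodified epitope, values below 1 indicate
    a binding loss for the variant (e.g. 0.1 for a 10-fold weaker
    alanine mutant).
    """
    if not (kd_variant > 0 and kd_reference > 0):
        raise ValueError("K_D values must be positive")
    return kd_reference / kd_variant


def delta_g_from_kd(kd: float, temperature: float = T_REF_DEFAULT) -> float:
    """Standard binding free energy ΔG = R T ln K_D, in kcal/mol."""
    if not kd > 0:
        raise ValueError("K_D must be positive")
    return R_KCAL * temperature * math.log(kd)


def half_life_from_koff(koff: float) -> float:
    """Complex half-life t_1/2 = ln 2 / k_off, in hours."""
    if not koff > 0:
        raise ValueError("k_off must be positive")
    return math.log(2.0) / koff / 3600.0


def fit_vant_hoff(
    series: Sequence[tuple[float, float]],
    model: str = "nonlinear",
    t_ref: float = T_REF_DEFAULT,
) -> ThermoParams:
    """Fit ΔH, ΔS (and ΔCp) to a K_D(T) series by van't Hoff analysis.

    Minimises unweighted squared residuals of ln K_D(T) against
    ΔG(T)/(R T) with the integrated Gibbs-Helmholtz form

        ΔG(T) = ΔH + ΔCp (T - T_ref) - T [ΔS + ΔCp ln(T / T_ref)]

    ``model='linear'`` fixes ΔCp = 0 (ln K_D linear in 1/T, solved in
    closed form); ``'nonlinear'`` also fits ΔCp, initialised from the
    linear solution. Requires >= 3 distinct temperatures (linear) or
    >= 4 (nonlinear).
    """
    if model not in ("linear", "nonlinear"):
        raise ValueError("model must be 'linear' or 'nonlinear'")
    temps = np.array([t for t, _ in series], dtype=float)
    kds = np.array([k for _, k in series], dtype=float)
    if np.any(kds <= 0):
        raise ValueError("K_D values must be positive")
    n_distinct = len(set(np.round(temps, 6)))
    needed = 3 if model == "linear" else 4
    if n_distinct < needed:
        raise ValueError(
            f"{model} fit needs >= {needed} distinct temperatures, got {n_distinct}"
        )
    lnk = np.log(kds)

    # linear: ln K_D = (ΔH/R)(1/T) - ΔS/R
    slope, intercept = np.polyfit(1.0 / temps, lnk, 1)
    dh0, ds0 = slope * R_KCAL, -intercept * R_KCAL

    def predict(params: np.ndarray) -> np.ndarray:
        dh, ds, dcp = params
        dg = dh + dcp * (temps - t_ref) - temps * (ds + dcp * np.log(temps / t_ref))
        return dg / (R_KCAL * temps)

    if model == "linear":
        params = np.array([dh0, ds0, 0.0])
        resid = predict(params) - lnk
        return ThermoParams(dh0, ds0, 0.0, t_ref, float(resid @ resid), "linear")

    result = least_squares(
        lambda p: predict(p) - lnk,
        x0=np.array([dh0, ds0, 0.0]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
    )
    if not result.success:
        raise RuntimeError(
            f"van't Hoff fit did not converge (final cost {result.cost:.3g})"
        )
    dh, ds, dcp = result.x
    return ThermoParams(
        float(dh), float(ds), float(dcp), t_ref,
        float(2.0 * result.cost), "nonlinear",
    )


def read_affinity_records(path: str | Path) -> list[AffinityRecord]:
    """Read a K_D table (TSV).

    Columns: ``tcr_id``, ``phla_id``, ``temperature_C``, ``kd``,
    ``kd_units`` (M, mM, uM, nM or pM), optional ``koff`` (1/s). A
    leading ``>`` in ``kd`` or the value ``NB`` marks a censored
    (lower-bound / no-binding) measurement.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"tcr_id", "phla_id", "temperature_C", "kd", "kd_units"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        raw = str(row["kd"]).strip()
        censored = raw.startswith(">") or raw.upper() == "NB"
        if raw.upper() == "NB":
            continue  # no numeric value to carry
        value = float(raw.lstrip(">"))
        unit = str(row["kd_units"]).strip()
        if unit not in _UNIT_TO_MOLAR:
            raise ValueError(f"{path}: unknown K_D unit {unit!r}")
        koff = row.get("koff")
        koff = None if koff is None or (isinstance(koff, float) and math.isnan(koff)) else float(koff)
        records.append(
            AffinityRecord(
                tcr_id=str(row["tcr_id"]),
                phla_id=str(row["phla_id"]),
                kd=value * _UNIT_TO_MOLAR[unit],
                temperature=float(row["temperature_C"]) + 273.15,
                koff=koff,
                kd_is_lower_bound=censored,
            )
        )
    return records
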