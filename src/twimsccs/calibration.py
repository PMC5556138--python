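"""Traveling-wave ion-mobility CCS calibration.

Drift times in a traveling-wave IMS cell relate to collision cross-section
nonlinearly, so CCS is obtained by calibrating against ions of known CCS
measured under identical conditions. The workflow implemented here is the
standard power-law protocol:

1. **EDC correction** — remove the mass-dependent enhanced-duty-cycle delay
   from each measured drift time::

       t'_D = t_D - C_EDC * sqrt(m/z) / 1000

   with ``C_EDC`` an instrument constant (1.57 and 1.41 for the two
   instrument presets shipped here).

2. **Exponent fit** — each calibrant's literature CCS is reduced by charge
   and ion–gas reduced mass, Ω' = Ω·sqrt(μ)/z, and the power law
   Ω' = A·t'_D^X is fitted by ordinary least squares in log–log form::

       ln Ω' = X * ln t'_D + ln A

3. **Linearisation** — a doubly corrected drift time folds the exponent,
   charge and reduced mass back in::

       t''_D = t'_D^X * z * (1/μ)^(1/2)

   which makes the calibrant CCS an exactly linear function of t''_D
   (Ω = A·t''_D on noise-free data). A straight line of published CCS
   against t''_D — with a free intercept by default, to absorb instrument
   offsets — is the final calibration, and unknown ions are read off it.

The log–log form in step 2 is what makes step 3 linear; fitting Ω' itself
against ln t'_D would leave Ω logarithmic in t''_D and the final "linear"
plot systematically curved.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence as Seq

import numpy as np
import pandas as pd
from scipy import stats

from .masses import GAS_MASS_N2, mz_from_mass, reduced_mass

__all__ = [
    "CalibrantIon",
    "CalibrationModel",
    "CcsMeasurement",
    "CalibrationError",
    "edc_correct",
    "reduced_ccs",
    "fit_exponent",
    "doubly_corrected_time",
    "fit_calibration",
    "estimate_ccs",
    "estimate_ccs_table",
    "read_calibrants_csv",
    "read_analytes_csv",
    "C_EDC_PROTEIN",
    "C_EDC_RNA",
]

#: EDC delay coefficients of the two instrument configurations used for
#: protein (Synapt HDMS) and RNA (Synapt G2-S, negative mode) measurements.
C_EDC_PROTEIN = 1.57
C_EDC_RNA = 1.41


class CalibrationError(ValueError):
    """Raised for unusable calibration inputs (too few points, degenerate fit,
    or drift times consumed by the EDC correction)."""


@dataclass(frozen=True)
class CalibrantIon:
    """One calibrant charge state: known CCS plus its measured drift time.

    ``published_ccs`` is the literature value (e.g. from the Bush/Clemmer
    CCS databases) in Å²; ``drift_time`` is the raw measured value in ms.
    """

    label: str
    neutral_mass: float
    z: int
    published_ccs: float
    drift_time: float

    def __post_init__(self) -> None:
        if min(self.neutral_mass, self.z, self.published_ccs, self.drift_time) <= 0:
            raise ValueError(f"calibrant {self.label!r}: all fields must be positive")


@dataclass
class CalibrationModel:
    """A fitted traveling-wave calibration.

    ``slope``/``intercept`` map the doubly corrected drift time t''_D to CCS
    in Å². The calibrant t''_D range is retained so that estimates outside it
    can be flagged as extrapolations.
    """

    c_edc: float
    gas_mass: float
    X: float
    ln_A: float
    slope: float
    intercept: float
    r_squared_loglog: float
    r_squared_linear: float
    n_calibrants: int
    tpp_range: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.X <= 0:
            raise CalibrationError(f"fitted exponent X = {self.X:.4f} must be positive")
        if self.n_calibrants < 2:
            raise CalibrationError("a calibration needs at least 2 calibrant ions")

    def to_json(self, target=None) -> str:
        payload = asdict(self)
        payload["tpp_range"] = list(self.tpp_range)
        text = json.dumps(payload, indent=2)
        if target is not None:
            if hasattr(target, "write"):
                target.write(text)
            else:
                with open(target, "w") as fh:
                    fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        data["tpp_range"] = tuple(data.get("tpp_range", (0.0, math.inf)))
        return cls(**data)


@dataclass(frozen=True)
class CcsMeasurement:
    """An analyte ion with its calibrated CCS estimate (Å²)."""

    label: str
    neutral_mass: float
    z: int
    drift_time: float
    estimated_ccs: float
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.estimated_ccs <= 0:
            raise CalibrationError(
                f"{self.label!r}: calibrated CCS {self.estimated_ccs:.3f} Å² "
                "is non-positive; drift time outside the model's valid range"
            )


def edc_correct(t_d: float, mz: float, c_edc: float) -> float:
    """Remove the enhanced-duty-cycle delay: t'_D = t_D − C_EDC·√(m/z)/1000.

    ``t_d`` in ms, ``mz`` in Th. Raises :class:`CalibrationError` if the
    correction consumes the whole drift time.
    """
    if t_d <= 0 or mz <= 0:
        raise ValueError("t_d and mz must be positive")
    corrected = t_d - c_edc * math.sqrt(mz) / 1000.0
    if corrected <= 0:
        raise CalibrationError(
            f"EDC correction exhausted the drift time ({t_d} ms at m/z {mz})"
        )
    return corrected


def reduced_ccs(ccs: float, z: int, mu: float) -> float:
    """Charge- and reduced-mass-normalised CCS: Ω' = Ω·√μ / z."""
    if ccs <= 0 or z <= 0 or mu <= 0:
        raise ValueError("ccs, z and mu must be positive")
    return ccs * math.sqrt(mu) / z


def _corrected_times_and_omega(
    calibrants: Seq[CalibrantIon], c_edc: float, gas_mass: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    t_prime = np.empty(len(calibrants))
    omega_prime = np.empty(len(calibrants))
    zs = np.empty(len(calibrants))
    mus = np.empty(len(calibrants))
    for i, ion in enumerate(calibrants):
        mz = mz_from_mass(ion.neutral_mass, ion.z)
        t_prime[i] = edc_correct(ion.drift_time, mz, c_edc)
        mus[i] = reduced_mass(ion.neutral_mass, gas_mass)
        zs[i] = ion.z
        omega_prime[i] = reduced_ccs(ion.published_ccs, ion.z, mus[i])
    return t_prime, omega_prime, zs, mus


def fit_exponent(
    calibrants: Seq[CalibrantIon],
    c_edc: float,
    gas_mass: float = GAS_MASS_N2,
) -> tuple[float, float, float]:
    """Fit the traveling-wave power law Ω' = A·t'_D^X.

    Ordinary least squares of ln Ω' on ln t'_D over all calibrant charge
    states. Returns ``(X, ln_A, r_squared)``.

    Raises
    ------
    CalibrationError
        Fewer than two calibrants, or all corrected drift times identical
        (the regression is singular).
    """
    if len(calibrants) < 2:
        raise CalibrationError("need at least 2 calibrant ions to fit the exponent")
    t_prime, omega_prime, _, _ = _corrected_times_and_omega(calibrants, c_edc, gas_mass)
    ln_t = np.log(t_prime)
    if np.ptp(ln_t) == 0:
        raise CalibrationError("all corrected drift times identical; singular fit")
    result = stats.linregress(ln_t, np.log(omega_prime))
    return float(result.slope), float(result.intercept), float(result.rvalue**2)


def doubly_corrected_time(t_prime_d: float, X: float, z: int, mu: float) -> float:
    """Fold exponent, charge and reduced mass into one time axis:
    t''_D = t'_D^X · z · (1/μ)^(1/2)."""
    if t_prime_d <= 0:
        raise ValueError("corrected drift time must be positive")
    return t_prime_d**X * z * mu**-0.5


def fit_calibration(
    calibrants: Seq[CalibrantIon],
    c_edc: float,
    gas_mass: float = GAS_MASS_N2,
    *,
    through_origin: bool = False,
) -> CalibrationModel:
    """Fit the full calibration: exponent, then the linear CCS–t''_D map.

    The final straight line has a free intercept unless ``through_origin``
    is set (on ideal data the intercept is zero and the slope equals A).
    """
    X, ln_A, r2_loglog = fit_exponent(calibrants, c_edc, gas_mass)
    t_prime, _, zs, mus = _corrected_times_and_omega(calibrants, c_edc, gas_mass)
    tpp = t_prime**X * zs / np.sqrt(mus)
    ccs = np.array([ion.published_ccs for ion in calibrants])

    if through_origin:
        slope = float(np.dot(tpp, ccs) / np.dot(tpp, tpp))
        intercept = 0.0
        predicted = slope * tpp
        ss_res = float(np.sum((ccs - predicted) ** 2))
        ss_tot = float(np.sum((ccs - ccs.mean()) ** 2))
        r2_linear = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    else:
        if np.ptp(tpp) == 0:
            raise CalibrationError("degenerate calibrant set: identical t''_D values")
        result = stats.linregress(tpp, ccs)
        slope, intercept = float(result.slope), float(result.intercept)
        r2_linear = float(result.rvalue**2)

    return CalibrationModel(
        c_edc=c_edc,
        gas_mass=gas_mass,
        X=X,
        ln_A=ln_A,
        slope=slope,
        intercept=intercept,
        r_squared_loglog=r2_loglog,
        r_squared_linear=min(r2_linear, 1.0),
        n_calibrants=len(calibrants),
        tpp_range=(float(tpp.min()), float(tpp.max())),
    )


def estimate_ccs(
    label: str,
    neutral_mass: float,
    z: int,
    drift_time: float,
    model: CalibrationModel,
) -> CcsMeasurement:
    """Calibrated CCS of one analyte ion, in Å².

    Applies the EDC correction with the model's C_EDC, the double correction
    with the model's exponent and the analyte's reduced mass, then the linear
    map. The result is flagged as an extrapolation when the analyte's t''_D
    falls outside the calibrant range.
    """
    mz = mz_from_mass(neutral_mass, z)
    t_prime = edc_correct(drift_time, mz, model.c_edc)
    mu = reduced_mass(neutral_mass, model.gas_mass)
    tpp = doubly_corrected_time(t_prime, model.X, z, mu)
    ccs = model.slope * tpp + model.intercept
    lo, hi = model.tpp_range
    return CcsMeasurement(
        label=label,
        neutral_mass=neutral_mass,
        z=z,
        drift_time=drift_time,
        estimated_ccs=float(ccs),
        extrapolated=not (lo <= tpp <= hi),
    )


def estimate_ccs_table(analytes: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    """Vectorised :func:`estimate_ccs` over an analyte table.

    Expects columns ``label, mass_da, charge, drift_ms``; returns the same
    table with ``ccs_A2`` and ``extrapolated`` appended.
    """
    rows = []
    for rec in analytes.itertuples(index=False):
        m = estimate_ccs(str(rec.label), float(rec.mass_da), int(rec.charge),
                         float(rec.drift_ms), model)
        rows.append((m.label, m.neutral_mass, m.z, m.drift_time,
                     m.estimated_ccs, m.extrapolated))
    return pd.DataFrame(
        rows, columns=["label", "mass_da", "charge", "drift_ms", "ccs_A2", "extrapolated"]
    )


def read_calibrants_csv(source) -> list[CalibrantIon]:
    """Read a calibrant table (columns label,mass_da,charge,ccs_A2,drift_ms)."""
    df = pd.read_csv(source, float_precision="round_trip")
    required = {"label", "mass_da", "charge", "ccs_A2", "drift_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibrant CSV missing columns: {sorted(missing)}")
    return [
        CalibrantIon(str(r.label), float(r.mass_da), int(r.charge),
                     float(r.ccs_A2), float(r.drift_ms))
        for r in df.itertuples(index=False)
    ]


def read_analytes_csv(source) -> pd.DataFrame:
    """Read an analyte table (columns label,mass_da,charge,drift_ms)."""
    df = pd.read_csv(source, float_precision="round_trip")
    required = {"label", "mass_da", "charge", "drift_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"analyte CSV missing columns: {sorted(missing)}")
    return df
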