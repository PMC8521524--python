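"""Pressure dependence of chemical shifts.

High pressure perturbs protein chemical shifts; for an amide in a transiently
structured region the perturbation deviates from the random-coil response.  The
shift of one nucleus is modelled as a second-order Taylor expansion around an
ambient reference pressure ``p0``::

    delta(p) = delta0 + B1 * (p - p0)/1000 + B2 * ((p - p0)/1000)**2

with ``p`` in bar, so ``B1`` is in ppm/kbar and ``B2`` in ppm/kbar**2.
Subtracting the coefficients measured on random-coil model peptides isolates
the structure-specific part of the response; the sign of the corrected ``B1``
then classifies the residue as pressure-stabilised, pressure-destabilised or
random-coil-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "ShiftSeries",
    "PressureCoefficients",
    "RandomCoilReference",
    "ResponseClass",
    "IntensityTrend",
    "fit_pressure_coefficients",
    "apply_random_coil_correction",
    "classify_response",
    "fit_intensity_trend",
]

#: nuclei accepted in shift tables (backbone + Arg side-chain probes)
NUCLEI = ("H", "N", "C", "CA", "CB", "HA", "CO", "HE", "NE", "CZ")


@dataclass
class ShiftSeries:
    """Chemical shifts of one (residue, nucleus) across pressure points.

    Parameters
    ----------
    residue_index : int
        1-based position in the sequence.
    residue_name : str
        Three-letter residue code (e.g. ``"ARG"``).
    nucleus : str
        One of :data:`NUCLEI`.
    pressures : array-like of float
        Pressures in bar, strictly increasing, all > 0.
    shifts : array-like of float
        Chemical shifts in ppm, one per pressure.
    intensities : array-like of float, optional
        Peak intensities (arbitrary units, >= 0), one per pressure.
    """

    residue_index: int
    residue_name: str
    nucleus: str
    pressures: np.ndarray
    shifts: np.ndarray
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
        if self.nucleus not in NUCLEI:
            raise InvalidParameterError(
                f"unknown nucleus {self.nucleus!r}; expected one of {NUCLEI}"
            )
        if self.pressures.size < 2:
            raise InsufficientDataError(
                f"need >= 2 pressure points, got {self.pressures.size}"
            )
        if self.pressures.size != self.shifts.size:
            raise InvalidParameterError("pressures and shifts differ in length")
        if np.any(self.pressures <= 0):
            raise InvalidParameterError("all pressures must be > 0 bar")
        if np.any(np.diff(self.pressures) <= 0):
            raise InvalidParameterError("pressures must be strictly increasing")
        if self.intensities is not None:
            if self.intensities.size != self.pressures.size:
                raise InvalidParameterError("intensities and pressures differ in length")
            if np.any(self.intensities < 0):
                raise InvalidParameterError("intensities must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.pressures.size)


@dataclass
class PressureCoefficients:
    """Fitted Taylor coefficients of delta(p) for one (residue, nucleus).

    ``B1`` is in ppm/kbar, ``B2`` in ppm/kbar**2.  ``*_se`` are standard errors
    from the least-squares covariance (NaN when the fit interpolates exactly,
    i.e. zero residual degrees of freedom).  The ``*_corrected`` fields hold
    coefficients after random-coil subtraction and are ``None`` until
    :func:`apply_random_coil_correction` has been applied.
    """

    residue_index: int
    residue_name: str
    nucleus: str
    delta0: float
    B1: float
    B2: float
    delta0_se: float
    B1_se: float
    B2_se: float
    fit_rss: float
    n_points: int
    p0: float = 1.0
    linear_only: bool = False
    B1_corrected: float | None = None
    B2_corrected: float | None = None
    reference_missing: bool = False

    def __post_init__(self) -> None:
        if self.fit_rss < -1e-12:
            raise InvalidParameterError("fit_rss must be >= 0")
        self.fit_rss = max(self.fit_rss, 0.0)


@dataclass
class RandomCoilReference:
    """Pressure coefficients of random-coil model peptides.

    Maps ``(residue_name, nucleus)`` to ``(B1_rc, B2_rc)``.  Pairs absent from
    the table are treated as ``(0, 0)`` and flagged on the corrected record so
    a zero subtraction is never mistaken for a measured reference.  The default
    (empty) table therefore leaves coefficients unchanged but flags every
    residue.
    """

    table: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def zero(cls) -> "RandomCoilReference":
        """An empty table: every lookup returns (0, 0) and is flagged."""
        return cls({})

    @classmethod
    def from_csv(cls, path: str | Path) -> "RandomCoilReference":
        """Load from CSV with columns residue_name,nucleus,B1_rc,B2_rc."""
        df = pd.read_csv(path)
        required = {"residue_name", "nucleus", "B1_rc", "B2_rc"}
        missing = required - set(df.columns)
        if missing:
            from .exceptions import SchemaError

            raise SchemaError(f"random-coil reference CSV missing columns: {sorted(missing)}")
        table = {
            (str(r.residue_name).upper(), str(r.nucleus).upper()): (float(r.B1_rc), float(r.B2_rc))
            for r in df.itertuples()
        }
        return cls(table)

    def lookup(self, residue_name: str, nucleus: str) -> tuple[float, float, bool]:
        """Return ``(B1_rc, B2_rc, missing_flag)`` for a residue/nucleus pair."""
        key = (residue_name.upper(), nucleus.upper())
        if key in self.table:
            b1, b2 = self.table[key]
            return b1, b2, False
        return 0.0, 0.0, True


@dataclass(frozen=True)
class ResponseClass:
    """Sign classification of a corrected B1 coefficient."""

    label: str  # "positive" | "negative" | "near_zero"
    threshold: float

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative", "near_zero"):
            raise InvalidParameterError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class IntensityTrend:
    """Linear trend of peak intensity with pressure."""

    slope_per_kbar: float
    intercept: float
    label: str  # "increasing" | "decreasing" | "flat"


def _collapse_duplicate_pressures(
    p: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(p, return_inverse=True)
    if uniq.size == p.size:
        return p, y
    warnings.warn(
        f"collapsed {p.size - uniq.size} duplicate pressure point(s) by averaging",
        stacklevel=3,
    )
    means = np.bincount(inv, weights=y) / np.bincount(inv)
    return uniq, means


def _polyfit_with_se(
    x: np.ndarray, y: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares polynomial fit returning (coeffs, standard errors, rss).

    Coefficients are ordered constant-first.  Standard errors come from
    ``rss/dof * inv(X'X)``; NaN when dof == 0 (exact interpolation).
    """
    X = np.vander(x, order + 1, increasing=True)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = x.size - (order + 1)
    if dof > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(order + 1, np.nan)
    return beta, se, rss


def fit_pressure_coefficients(
    series: ShiftSeries, p0: float = 1.0, quadratic: bool = True
) -> PressureCoefficients:
    """Fit delta(p) = delta0 + B1*(p-p0)/1000 + B2*((p-p0)/1000)^2.

    Parameters
    ----------
    series : ShiftSeries
        Observations; >= 3 distinct pressures for the quadratic fit, >= 2 in
        linear-only mode (``quadratic=False``, B2 fixed to 0).
    p0 : float
        Expansion point in bar (default ambient, 1 bar).

    Returns
    -------
    PressureCoefficients
        With standard errors and residual sum of squares.  When the number of
        distinct points equals the number of parameters the fit interpolates
        exactly (rss ~ 0, standard errors NaN).

    Raises
    ------
    InsufficientDataError
        If fewer distinct pressures than parameters are available.
    """
    p, y = _collapse_duplicate_pressures(series.pressures, series.shifts)
    n_par = 3 if quadratic else 2
    if p.size < n_par:
        raise InsufficientDataError(
            f"insufficient data: {p.size} distinct pressure(s) for a "
            f"{n_par}-parameter {'quadratic' if quadratic else 'linear'} fit"
        )
    x = (p - p0) / 1000.0  # kbar
    beta, se, rss = _polyfit_with_se(x, y, order=2 if quadratic else 1)
    if not quadratic:
        beta = np.append(beta, 0.0)
        se = np.append(se, 0.0)
    return PressureCoefficients(
        residue_index=series.residue_index,
        residue_name=series.residue_name,
        nucleus=series.nucleus,
        delta0=float(beta[0]),
        B1=float(beta[1]),
        B2=float(beta[2]),
        delta0_se=float(se[0]),
        B1_se=float(se[1]),
        B2_se=float(se[2]),
        fit_rss=rss,
        n_points=int(p.size),
        p0=p0,
        linear_only=not quadratic,
    )


def apply_random_coil_correction(
    coeffs: PressureCoefficients,
    ref: RandomCoilReference,
    residue_name: str | None = None,
    nucleus: str | None = None,
) -> PressureCoefficients:
    """Subtract random-coil reference coefficients.

    ``B1_corrected = B1 - B1_rc`` and likewise for B2.  A missing reference
    pair subtracts zero and sets ``reference_missing``.  Returns a new record;
    the input is not mutated.
    """
    rname = residue_name if residue_name is not None else coeffs.residue_name
    nuc = nucleus if nucleus is not None else coeffs.nucleus
    b1_rc, b2_rc, missing = ref.lookup(rname, nuc)
    return replace(
        coeffs,
        B1_corrected=coeffs.B1 - b1_rc,
        B2_corrected=coeffs.B2 - b2_rc,
        reference_missing=missing,
    )


def classify_response(
    coeffs: PressureCoefficients, threshold: float = 0.2
) -> ResponseClass:
    """Classify corrected B1 as positive / negative / near_zero.

    ``positive`` if B1_corrected > threshold, ``negative`` if < -threshold,
    otherwise ``near_zero`` (pressure response indistinguishable from random
    coil at the chosen threshold, default 0.2 ppm/kbar for 15N).
    """
    if threshold <= 0:
        raise InvalidParameterError(f"threshold must be > 0, got {threshold}")
    if coeffs.B1_corrected is None:
        raise InvalidParameterError(
            "corrected coefficients absent; apply_random_coil_correction first"
        )
    b1 = coeffs.B1_corrected
    if b1 > threshold:
        label = "positive"
    elif b1 < -threshold:
        label = "negative"
    else:
        label = "near_zero"
    return ResponseClass(label=label, threshold=threshold)


def fit_intensity_trend(
    series: ShiftSeries, flat_tolerance: float = 1e-9
) -> IntensityTrend:
    """Least-squares linear slope of peak intensity vs pressure (per kbar).

    The label is ``flat`` when ``|slope| <= flat_tolerance`` (intensity units
    per kbar), else the sign of the slope decides.
    """
    if series.intensities is None or series.intensities.size < 2:
        raise InsufficientDataError("no intensity data (need >= 2 intensity points)")
    p, y = _collapse_duplicate_pressures(series.pressures, series.intensities)
    if p.size < 2:
        raise InsufficientDataError("no intensity data (need >= 2 distinct pressures)")
    x = p / 1000.0
    beta, _, _ = _polyfit_with_se(x, y, order=1)
    slope = float(beta[1])
    if abs(slope) <= flat_tolerance:
        label = "flat"
    elif slope > 0:
        label = "increasing"
    else:
        label = "decreasing"
    return IntensityTrend(slope_per_kbar=slope, intercept=float(beta[0]), label=label)


def fit_shift_table(
    series_list: Iterable[ShiftSeries],
    reference: RandomCoilReference | None = None,
    p0: float = 1.0,
    threshold: float = 0.2,
    quadratic: bool = True,
) -> pd.DataFrame:
    """Fit, correct and classify a whole shift table.

    Convenience wrapper: one row per (residue, nucleus) with raw and corrected
    coefficients, standard errors and the sign class.
    """
    reference = reference if reference is not None else RandomCoilReference.zero()
    rows = []
    for s in series_list:
        c = fit_pressure_coefficients(s, p0=p0, quadratic=quadratic)
        c = apply_random_coil_correction(c, reference)
        cls = classify_response(c, threshold=threshold)
        rows.append(
            {
                "residue_index": c.residue_index,
                "residue_name": c.residue_name,
                "nucleus": c.nucleus,
                "delta0_ppm": c.delta0,
                "B1_ppm_per_kbar": c.B1,
                "B2_ppm_per_kbar2": c.B2,
                "B1_se": c.B1_se,
                "B2_se": c.B2_se,
                "B1_corrected": c.B1_corrected,
                "B2_corrected": c.B2_corrected,
                "reference_missing": c.reference_missing,
                "response_class": cls.label,
                "fit_rss": c.fit_rss,
                "n_points": c.n_points,
            }
        )
    return pd.DataFrame(rows)
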