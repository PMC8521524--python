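"""Two-site symmetric-exchange CEST: simulation, fitting, dip detection.

The arginine guanidinium group rotates around the Czeta-Nepsilon bond, which
exchanges the chemical environments of the two Neta nitrogens.  With equal
populations (an exact symmetry of the rotation) this is a two-site symmetric
exchange with total rate ``k_ex`` (the SUM of the forward and backward rates;
each direction runs at ``k_ex/2``) and a resonance-frequency separation
``delta_omega`` in rad/s.

A saturation field of amplitude ``B1_sat`` (Hz) applied for ``T_sat`` seconds
at an offset is modelled by the Bloch-McConnell equations for the six
magnetization components (x, y, z per site) plus a constant, i.e. a 7x7
evolution matrix including transverse/longitudinal relaxation (R2, R1),
nutation, chemical-shift offsets and exchange, propagated with a matrix
exponential.  The reported intensity is the total z-magnetization normalised
to the no-saturation (T_sat = 0) reference, so a profile starts at ~1 far from
resonance and dips where saturation transfers through exchange.

This longitudinal model is a stand-in for the multiquantum CEST experiment
that motivates it: the coherence pathway of that pulse sequence is not
reproduced, but the two-site symmetric exchange analysis (positions and depths
of the exchange dips, and the (k_ex, delta_omega) round trip) is the same.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import lmfit
from scipy.linalg import expm
from scipy.signal import find_peaks

from .exceptions import (
    FlatProfileError,
    InsufficientDataError,
    InvalidParameterError,
    NoConvergenceError,
    NumericalFailureError,
)

__all__ = [
    "ExchangeModel",
    "CESTProfile",
    "ExchangeFit",
    "Dip",
    "DipSet",
    "simulate_profile",
    "fit_profile",
    "detect_dips",
    "DEFAULT_KEX_STARTS",
    "DEFAULT_DOMEGA_STARTS",
]

#: default multi-start grid for the exchange rate (s^-1)
DEFAULT_KEX_STARTS = (50.0, 200.0, 500.0, 1000.0)
#: default multi-start grid for the shift difference (rad/s)
DEFAULT_DOMEGA_STARTS = (500.0, 1000.0, 2000.0)


@dataclass
class ExchangeModel:
    """Two-site symmetric exchange model with acquisition parameters.

    Parameters
    ----------
    k_ex : float
        Total exchange rate in s^-1 (sum convention: each direction k_ex/2).
    delta_omega : float
        Neta1-Neta2 shift difference in rad/s.
    center_ppm : float
        Mean Neta chemical shift; the two sites sit at center +- half the
        ppm-equivalent of ``delta_omega``.
    r1, r2 : float
        Longitudinal and transverse relaxation rates, s^-1.
    b1_sat_hz : float
        Saturation field amplitude in Hz.
    t_sat : float
        Saturation duration in s.
    freq_mhz : float
        Nitrogen Larmor frequency in MHz (sets the ppm <-> rad/s conversion).
    """

    k_ex: float
    delta_omega: float
    center_ppm: float
    r1: float = 1.5
    r2: float = 30.0
    b1_sat_hz: float = 25.0
    t_sat: float = 0.4
    freq_mhz: float = 81.1

    def __post_init__(self) -> None:
        if self.k_ex < 0:
            raise InvalidParameterError("k_ex must be >= 0")
        if self.r1 <= 0 or self.r2 <= 0:
            raise InvalidParameterError("R1 and R2 must be > 0")
        if self.t_sat <= 0:
            raise InvalidParameterError("T_sat must be > 0")
        if self.freq_mhz <= 0:
            raise InvalidParameterError("spectrometer frequency must be > 0")

    @property
    def populations(self) -> tuple[float, float]:
        """Site populations; fixed at 1/2, 1/2 by the rotational symmetry."""
        return (0.5, 0.5)

    def ppm_to_rad_s(self, ppm: float) -> float:
        return 2.0 * np.pi * self.freq_mhz * ppm

    def rad_s_to_ppm(self, rad_s: float) -> float:
        return rad_s / (2.0 * np.pi * self.freq_mhz)


@dataclass
class CESTProfile:
    """Saturation offset (ppm) vs normalised intensity."""

    offsets_ppm: np.ndarray
    intensities: np.ndarray
    reference: str = "t_sat=0"

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets_ppm.size != self.intensities.size:
            raise InvalidParameterError("offsets and intensities differ in length")
        d = np.diff(self.offsets_ppm)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidParameterError("offsets must be strictly monotone")

    @property
    def n_points(self) -> int:
        return int(self.offsets_ppm.size)


@dataclass
class ExchangeFit:
    """Result of a multi-start (k_ex, delta_omega, center) profile fit."""

    model: ExchangeModel
    k_ex_se: float
    delta_omega_se: float
    center_ppm_se: float
    rss: float
    converged: bool
    n_points: int
    start_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for se in (self.k_ex_se, self.delta_omega_se, self.center_ppm_se):
            if np.isfinite(se) and se < 0:
                raise InvalidParameterError("standard errors must be >= 0")


@dataclass(frozen=True)
class Dip:
    position_ppm: float
    depth: float
    label: str  # "major" | "minor"


@dataclass
class DipSet:
    dips: list[Dip]

    def __len__(self) -> int:
        return len(self.dips)

    @property
    def major(self) -> Dip | None:
        for d in self.dips:
            if d.label == "major":
                return d
        return None

    @property
    def minors(self) -> list[Dip]:
        return [d for d in self.dips if d.label == "minor"]


# ---------------------------------------------------------------------------
# simulation


def _evolution_matrices(model: ExchangeModel, offsets_ppm: np.ndarray) -> np.ndarray:
    """Batched 7x7 Bloch-McConnell generators, one per saturation offset.

    State vector: (Mx_a, My_a, Mz_a, Mx_b, My_b, Mz_b, 1).  The constant
    component carries the R1 recovery toward the equilibrium populations.
    """
    n = offsets_ppm.size
    w1 = 2.0 * np.pi * model.b1_sat_hz
    k = model.k_ex / 2.0  # per-direction rate under symmetry
    # site resonance offsets from the saturation carrier, rad/s
    w_center = 2.0 * np.pi * model.freq_mhz * (model.center_ppm - offsets_ppm)
    wa = w_center + model.delta_omega / 2.0
    wb = w_center - model.delta_omega / 2.0
    pa, pb = model.populations
    L = np.zeros((n, 7, 7))
    for sl, w, p in ((slice(0, 3), wa, pa), (slice(3, 6), wb, pb)):
        i = sl.start
        L[:, i + 0, i + 0] = -model.r2 - k
        L[:, i + 0, i + 1] = -w
        L[:, i + 1, i + 0] = w
        L[:, i + 1, i + 1] = -model.r2 - k
        L[:, i + 1, i + 2] = w1
        L[:, i + 2, i + 1] = -w1
        L[:, i + 2, i + 2] = -model.r1 - k
        L[:, i + 2, 6] = model.r1 * p
    for d in range(3):  # symmetric exchange couples matching components
        L[:, d, 3 + d] += k
        L[:, 3 + d, d] += k
    return L


def simulate_profile(model: ExchangeModel, offsets_ppm: Sequence[float]) -> CESTProfile:
    """Simulate a CEST profile at the given saturation offsets.

    Starting from thermal equilibrium (Mz_a = Mz_b = 1/2), the magnetization
    is propagated for ``T_sat`` under the Bloch-McConnell generator at each
    offset; the intensity is the surviving total Mz, already normalised since
    the T_sat = 0 reference equals 1.  Deterministic.
    """
    offsets = np.asarray(offsets_ppm, dtype=float)
    L = _evolution_matrices(model, offsets)
    P = expm(L * model.t_sat)
    if not np.all(np.isfinite(P)):
        bad = offsets[~np.isfinite(P).all(axis=(1, 2))]
        raise NumericalFailureError(
            f"non-finite matrix exponential at offset(s) {bad[:3]} ppm"
        )
    m0 = np.array([0.0, 0.0, 0.5, 0.0, 0.0, 0.5, 1.0])
    m = P @ m0
    intensities = m[:, 2] + m[:, 5]
    return CESTProfile(offsets_ppm=offsets, intensities=intensities)


# ---------------------------------------------------------------------------
# fitting


def _residuals(params: lmfit.Parameters, model: ExchangeModel, profile: CESTProfile) -> np.ndarray:
    trial = replace(
        model,
        k_ex=float(params["k_ex"].value),
        delta_omega=float(params["delta_omega"].value),
        center_ppm=float(params["center_ppm"].value),
    )
    sim = simulate_profile(trial, profile.offsets_ppm)
    return sim.intensities - profile.intensities


def fit_profile(
    profile: CESTProfile,
    fixed: ExchangeModel | None = None,
    kex_starts: Sequence[float] = DEFAULT_KEX_STARTS,
    domega_starts: Sequence[float] = DEFAULT_DOMEGA_STARTS,
    flat_tolerance: float = 1e-3,
    **fixed_kwargs,
) -> ExchangeFit:
    """Multi-start nonlinear least squares for (k_ex, delta_omega, center_ppm).

    Parameters
    ----------
    profile : CESTProfile
        >= 8 points spanning the dip region.
    fixed : ExchangeModel, optional
        Carries the fixed acquisition parameters (R1, R2, B1_sat, T_sat,
        frequency); its k_ex/delta_omega/center are ignored.  Alternatively
        pass them as keyword arguments (``r1=..., r2=..., ...``).
    kex_starts, domega_starts : sequences
        The multi-start grid; every (k_ex, delta_omega) combination is tried
        and the converged fit with the lowest residual sum of squares wins.

    Returns
    -------
    ExchangeFit
        Best fit with covariance-based standard errors and the full start log.

    Raises
    ------
    FlatProfileError
        If the profile carries no exchange information (flat within
        ``flat_tolerance``).
    NoConvergenceError
        If no start converges.
    """
    if profile.n_points < 8:
        raise InsufficientDataError(f"need >= 8 profile points, got {profile.n_points}")
    span = float(np.max(profile.intensities) - np.min(profile.intensities))
    if span < flat_tolerance:
        raise FlatProfileError(
            f"no exchange information: intensity span {span:.2e} < {flat_tolerance}"
        )
    if fixed is None:
        fixed = ExchangeModel(k_ex=0.0, delta_omega=0.0, center_ppm=0.0, **fixed_kwargs)
    center0 = float(profile.offsets_ppm[np.argmin(profile.intensities)])
    lo, hi = float(np.min(profile.offsets_ppm)), float(np.max(profile.offsets_ppm))

    best = None
    log: list[dict] = []
    for k0 in kex_starts:
        for dw0 in domega_starts:
            params = lmfit.Parameters()
            params.add("k_ex", value=k0, min=0.0)
            params.add("delta_omega", value=dw0, min=0.0)
            params.add("center_ppm", value=center0, min=lo, max=hi)
            try:
                res = lmfit.minimize(
                    _residuals, params, args=(fixed, profile), method="leastsq"
                )
            except Exception as err:  # numerical blow-up on a bad start
                log.append({"k_ex0": k0, "delta_omega0": dw0, "error": str(err)})
                continue
            rss = float(np.sum(np.asarray(res.residual) ** 2))
            log.append(
                {
                    "k_ex0": k0,
                    "delta_omega0": dw0,
                    "success": bool(res.success),
                    "rss": rss,
                    "k_ex": float(res.params["k_ex"].value),
                    "delta_omega": float(res.params["delta_omega"].value),
                }
            )
            if res.success and (best is None or rss < best[0]):
                best = (rss, res)
    if best is None:
        raise NoConvergenceError(
            f"no start of the {len(kex_starts)}x{len(domega_starts)} grid converged; "
            f"log: {log}"
        )
    rss, res = best

    def _se(name: str) -> float:
        err = res.params[name].stderr
        return float(err) if err is not None else float("nan")

    fitted = replace(
        fixed,
        k_ex=float(res.params["k_ex"].value),
        delta_omega=float(res.params["delta_omega"].value),
        center_ppm=float(res.params["center_ppm"].value),
    )
    return ExchangeFit(
        model=fitted,
        k_ex_se=_se("k_ex"),
        delta_omega_se=_se("delta_omega"),
        center_ppm_se=_se("center_ppm"),
        rss=rss,
        converged=True,
        n_points=profile.n_points,
        start_log=log,
    )


# ---------------------------------------------------------------------------
# dip detection


def detect_dips(
    profile: CESTProfile,
    depth_threshold: float = 0.05,
    smooth_window: int = 1,
) -> DipSet:
    """Locate CEST dips as local minima deeper than a prominence threshold.

    The profile is optionally smoothed with a centred moving average of
    ``smooth_window`` points, then minima with prominence above
    ``depth_threshold`` (fraction of the normalised intensity) are returned,
    the deepest labelled ``major`` and the rest ``minor``, ordered by depth.
    """
    if profile.n_points < 5:
        raise InsufficientDataError(f"need >= 5 points, got {profile.n_points}")
    if smooth_window < 1:
        raise InvalidParameterError("smooth_window must be >= 1")
    if smooth_window > profile.n_points:
        raise InvalidParameterError(
            f"smooth_window {smooth_window} exceeds profile length {profile.n_points}"
        )
    order = np.argsort(profile.offsets_ppm)
    x = profile.offsets_ppm[order]
    y = profile.intensities[order]
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    peaks, props = find_peaks(-y, prominence=depth_threshold)
    if peaks.size == 0:
        return DipSet(dips=[])
    depths = props["prominences"]
    rank = np.argsort(depths)[::-1]
    dips = [
        Dip(
            position_ppm=float(x[peaks[i]]),
            depth=float(depths[i]),
            label="major" if pos == 0 else "minor",
        )
        for pos, i in enumerate(rank)
    ]
    return DipSet(dips=dips)
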