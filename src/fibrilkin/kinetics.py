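"""Forward models of amyloid fibril formation kinetics.

The bulk reaction network couples free monomer ``m(t)``, fibril mass
``M(t)`` and fibril number ``P(t)`` (both in monomer-equivalent
concentration units):

    dP/dt = kn * m**nc  +  k2 * m**n2 * M  +  kminus * M
    dM/dt = 2 * kplus * m * P
    m     = m_total - M

i.e. primary nucleation (rate constant ``kn``, reaction order ``nc``),
fibril-catalysed secondary nucleation (``k2``, order ``n2``; ``n2 = 0``
is the saturated limit where monomer attachment to the fibril surface is
not rate limiting), fragmentation (``kminus``) and elongation at both
fibril ends (``kplus``).  Nucleation consumes a mass-negligible amount
of monomer, so monomer is depleted by elongation only.

Two effective rates control the macroscopic curve shape at a given total
monomer concentration ``m0``:

    lambda = sqrt(2 * kplus * kn * m0**nc)         (primary + elongation)
    kappa  = sqrt(2 * kplus * k2 * m0**(n2 + 1))   (secondary + elongation)

Units are hours and micromolar throughout; conversions to per-second
happen only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "FibrilTrajectory",
    "NormalizedTrace",
    "simulate_fibril_mass",
    "closed_form_fibril_mass",
    "half_time",
    "lag_time",
    "scaling_exponent",
]


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rate constants of the fibril-formation network.

    Parameters
    ----------
    kn : float
        Primary nucleation rate constant, conc**(1 - nc) / h.
    nc : float
        Primary nucleation reaction order (>= 1).  Default 1, the
        apparent order of heterogeneous (surface-catalysed) primary
        nucleation.
    kplus : float
        Elongation rate constant, 1 / (conc * h).
    k2 : float
        Secondary nucleation rate constant, conc**(-n2) / h per
        monomer-equivalent of fibril mass.
    n2 : float
        Secondary nucleation reaction order.  Default 0 (saturated).
    kminus : float
        Fragmentation rate constant, 1 / h per monomer-equivalent of
        fibril.
    """

    kn: float = 0.0
    nc: float = 1.0
    kplus: float = 0.0
    k2: float = 0.0
    n2: float = 0.0
    kminus: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kn", "kplus", "k2", "kminus"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {getattr(self, name)}")
        if self.nc < 1:
            raise ValueError(f"primary reaction order nc must be >= 1, got {self.nc}")
        if self.n2 < 0:
            raise ValueError(f"secondary reaction order n2 must be >= 0, got {self.n2}")

    def lam(self, m0: float) -> float:
        """Effective primary-pathway rate lambda = sqrt(2 kplus kn m0**nc), 1/h."""
        return float(np.sqrt(2.0 * self.kplus * self.kn * m0**self.nc))

    def kappa(self, m0: float) -> float:
        """Effective secondary-pathway rate kappa = sqrt(2 kplus k2 m0**(n2+1)), 1/h."""
        return float(np.sqrt(2.0 * self.kplus * self.k2 * m0 ** (self.n2 + 1.0)))

    def kappa_fragmentation(self, m0: float) -> float:
        """Fragmentation analogue of kappa: sqrt(2 kplus kminus m0), 1/h."""
        return float(np.sqrt(2.0 * self.kplus * self.kminus * m0))

    def with_(self, **changes) -> "RateConstants":
        return replace(self, **changes)


@dataclass
class FibrilTrajectory:
    """Deterministic bulk trajectory in monomer-equivalent units (uM, h)."""

    times: np.ndarray
    m: np.ndarray
    M: np.ndarray
    P: np.ndarray
    m_total: float
    M0: float = 0.0
    P0: float = 0.0

    def mean_length(self) -> np.ndarray:
        """Number-average fibril length M/P (monomer units); NaN where P == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.P > 0, self.M / self.P, np.nan)

    def normalized(self) -> "NormalizedTrace":
        seed_fraction = 100.0 * self.M0 / self.m_total
        return NormalizedTrace(
            times=self.times.copy(),
            fraction_aggregated=self.M / self.m_total,
            m_total=self.m_total,
            seed_fraction=seed_fraction,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "m_uM": self.m, "M_uM": self.M, "P_uM": self.P}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class NormalizedTrace:
    """Fraction-aggregated curve M(t)/m_total on [0, 1].

    `anchored` records that the curve was rescaled so that the means of
    its first and last 5% windows sit at exactly 0 and 1 (the raw-signal
    normalization convention); model curves are put through the same
    windowed map before being compared with anchored data.
    """

    times: np.ndarray
    fraction_aggregated: np.ndarray
    m_total: float
    seed_fraction: float = 0.0
    anchored: bool = False


def _validate_grid(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("time grid must be 1-D with at least two points")
    if times[0] < 0:
        raise ValueError("time grid must start at t >= 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return times


def simulate_fibril_mass(
    rates: RateConstants,
    m_total: float,
    M0: float = 0.0,
    P0: float = 0.0,
    times: np.ndarray | None = None,
) -> FibrilTrajectory:
    """Integrate the moment equations for fibril mass and number.

    Uses a stiff-capable adaptive integrator (LSODA) with absolute
    tolerance 1e-9 * m_total.  With all rate constants zero and P0 = 0
    the state is constant.

    Raises
    ------
    ValueError
        On negative inputs, M0 >= m_total, or a non-monotone time grid.
    RuntimeError
        If the integrator fails; the message includes the parameters.
    """
    if m_total <= 0:
        raise ValueError(f"m_total must be > 0, got {m_total}")
    if M0 < 0 or P0 < 0:
        raise ValueError("seed mass M0 and number P0 must be >= 0")
    if M0 >= m_total:
        raise ValueError(f"seed mass M0={M0} must be < m_total={m_total}")
    times = _validate_grid(times)

    kn, nc = rates.kn, rates.nc
    kplus, k2, n2, kminus = rates.kplus, rates.k2, rates.n2, rates.kminus

    def rhs(t, y):
        M, P = y
        m = m_total - M
        if m < 0.0:
            m = 0.0
        dM = 2.0 * kplus * m * P
        dP = kn * m**nc + kminus * M
        if k2 > 0.0:
            dP += k2 * m**n2 * M
        return (dM, dP)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        (M0, P0),
        method="LSODA",
        t_eval=times,
        rtol=1e-8,
        atol=1e-9 * m_total,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed ({sol.message}) for rates={rates}, "
            f"m_total={m_total}, M0={M0}, P0={P0}"
        )
    M = np.clip(sol.y[0], 0.0, m_total)
    P = np.maximum(sol.y[1], 0.0)
    return FibrilTrajectory(
        times=times, m=m_total - M, M=M, P=P, m_total=m_total, M0=M0, P0=P0
    )


# ---------------------------------------------------------------------------
# Closed-form solution via the exact first integral.
#
# With mu = ln(m0 / m) the moment equations collapse to a second-order
# equation mu'' = F(mu) whose right-hand side depends on mu alone
# (monomer is consumed by elongation only, so mu' = 2 kplus P exactly):
#
#   F(mu) = lam**2 exp(-nc mu)
#           + 2 kplus (k2 m**n2 + kminus) (m_total - m),   m = m0 exp(-mu)
#
# Multiplying by mu' and integrating gives an energy-type first integral
#
#   mu'(mu)**2 = (2 kplus P0)**2 + 2 * Integral_0^mu F(u) du
#
# in which the integral is elementary.  Time is then recovered by 1-D
# quadrature, t(mu) = Integral d(mu)/mu'(mu), on a sqrt(mu) grid (the
# substitution removes the integrable singularity of unseeded starts).
# The effective rates kappa and lambda set the scale of mu' exactly as
# in the generalized-logistic approximation, but no linearization is
# involved.
# ---------------------------------------------------------------------------


def _energy_velocity_sq(
    mu: np.ndarray,
    rates: RateConstants,
    m_total: float,
    m0: float,
    P0: float,
) -> np.ndarray:
    """mu'(mu)^2 from the exact first integral (units 1/h^2)."""
    kn, nc = rates.kn, rates.nc
    kplus, k2, n2, kminus = rates.kplus, rates.k2, rates.n2, rates.kminus

    v2 = np.full_like(mu, (2.0 * kplus * P0) ** 2)
    lam2 = 2.0 * kplus * kn * m0**nc
    if lam2 > 0:
        v2 = v2 + (2.0 * lam2 / nc) * (1.0 - np.exp(-nc * mu))
    if k2 > 0:
        pref = 4.0 * kplus * k2 * m0**n2
        if n2 == 0:
            i1 = mu
        else:
            i1 = (1.0 - np.exp(-n2 * mu)) / n2
        i2 = (1.0 - np.exp(-(n2 + 1.0) * mu)) / (n2 + 1.0)
        v2 = v2 + pref * (m_total * i1 - m0 * i2)
    if kminus > 0:
        v2 = v2 + 4.0 * kplus * kminus * (m_total * mu - m0 * (1.0 - np.exp(-mu)))
    return v2


def closed_form_fibril_mass(
    rates: RateConstants,
    m_total: float,
    M0: float = 0.0,
    P0: float = 0.0,
    times: np.ndarray | None = None,
    _n_grid: int = 4000,
) -> NormalizedTrace:
    """Fraction-aggregated curve from the first-integral (energy) solution.

    An independent route to the same dynamics as
    :func:`simulate_fibril_mass`: no ODE stepping, only elementary
    functions and one cumulative quadrature.  Valid whenever some
    aggregation pathway is active; raises if lambda, kappa and the
    seeded elongation flux are all zero (nothing can aggregate).
    """
    if m_total <= 0:
        raise ValueError(f"m_total must be > 0, got {m_total}")
    if M0 < 0 or P0 < 0:
        raise ValueError("seed mass M0 and number P0 must be >= 0")
    if M0 >= m_total:
        raise ValueError(f"seed mass M0={M0} must be < m_total={m_total}")
    times = _validate_grid(times)
    m0 = m_total - M0
    seed_fraction = 100.0 * M0 / m_total

    lam = rates.lam(m0)
    kap = rates.kappa(m0)
    kap_f = rates.kappa_fragmentation(m0)
    seeded_flux = rates.kplus * P0
    active_secondary = (kap > 0 or kap_f > 0) and M0 > 0
    if lam == 0 and kap == 0 and kap_f == 0 and seeded_flux == 0:
        raise ValueError(
            "no active aggregation pathway: lambda and kappa are both zero "
            "and there is no seeded elongation flux"
        )
    if lam == 0 and seeded_flux == 0 and not active_secondary:
        # unseeded with no primary pathway: m = m0 is a fixed point
        frac = np.full_like(times, M0 / m_total)
        return NormalizedTrace(times=times, fraction_aggregated=frac,
                               m_total=m_total, seed_fraction=seed_fraction)

    # sqrt(mu) grid; mu = 30 puts m/m0 below 1e-13
    w_max = np.sqrt(30.0)
    w = np.linspace(0.0, w_max, _n_grid)
    mu = w**2
    v2 = _energy_velocity_sq(mu, rates, m_total, m0, P0)
    v = np.sqrt(np.maximum(v2, 0.0))

    # integrand of t(mu) in the w coordinate: d(mu)/v = 2 w dw / v(w^2)
    g = np.empty_like(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        g[1:] = 2.0 * w[1:] / v[1:]
    if seeded_flux > 0:
        g[0] = 0.0
    elif lam > 0:
        g[0] = np.sqrt(2.0) / lam  # lim 2w/v, v ~ lam*sqrt(2 mu)
    else:
        # seeded mass without seed number: v^2 ~ c * mu, same sqrt form
        eps = 1e-12
        g[0] = 2.0 * np.sqrt(eps) / np.sqrt(
            _energy_velocity_sq(np.array([eps]), rates, m_total, m0, P0)[0]
        )

    t_of_w = np.concatenate(([0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(w))))
    frac_of_w = 1.0 - (m0 / m_total) * np.exp(-mu)

    frac = np.interp(times, t_of_w, frac_of_w, left=frac_of_w[0], right=1.0)
    return NormalizedTrace(
        times=times, fraction_aggregated=frac, m_total=m_total,
        seed_fraction=seed_fraction,
    )


def _crossing_time(trace: NormalizedTrace, level: float) -> float:
    """First time the fraction-aggregated curve crosses `level` (linear interp)."""
    t = np.asarray(trace.times, dtype=float)
    f = np.asarray(trace.fraction_aggregated, dtype=float)
    if f[0] >= level:
        return 0.0
    above = np.nonzero(f >= level)[0]
    if above.size == 0:
        raise ValueError(
            f"trace never reaches fraction {level} (max {f.max():.3f})"
        )
    i = above[0]
    return float(t[i - 1] + (level - f[i - 1]) * (t[i] - t[i - 1]) / (f[i] - f[i - 1]))


def half_time(trace: NormalizedTrace) -> float:
    """Aggregation half-time t_1/2: first 50% crossing, linearly interpolated."""
    return _crossing_time(trace, 0.5)


def lag_time(trace: NormalizedTrace, threshold: float = 0.25) -> float:
    """Lag time: time to reach 25% aggregation (first crossing); 0 if already past."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return _crossing_time(trace, threshold)


def scaling_exponent(half_times, m_totals) -> float:
    """Slope of log10(t_1/2) versus log10(m_total), by ordinary least squares.

    The signature of the dominant fibril-multiplication mechanism: the
    asymptotic slope is -(n2 + 1)/2 for secondary nucleation of order
    n2, -1/2 for fragmentation, and -nc/2 for primary-only kinetics.
    """
    ht = np.asarray(half_times, dtype=float)
    mt = np.asarray(m_totals, dtype=float)
    if ht.shape != mt.shape or ht.ndim != 1:
        raise ValueError("half_times and m_totals must be 1-D arrays of equal length")
    if np.unique(mt).size < 3:
        raise ValueError("need at least 3 distinct monomer concentrations")
    if np.any(ht <= 0) or np.any(mt <= 0):
        raise ValueError("half-times and concentrations must be positive")
    slope, _ = np.polyfit(np.log10(mt), np.log10(ht), 1)
    return float(slope)
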