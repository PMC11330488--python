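"""Oligomer population dynamics during fibril formation.

Oligomers (concentration S) are transient: they form, dissociate back to
monomer, and both steps may or may not be catalysed by fibrils.  Two
coarse-grained linear-in-S rate laws are compared:

primary origin (monomer-only source, first-order decay):

    dS/dt = k_form * m(t)**n_o - k_diss * S

secondary origin (both source and sink catalysed by fibril mass M):

    dS/dt = k_form * m(t)**n_o * M(t) - k_diss * S * M(t)

The bulk trajectory m(t), M(t) comes from the fibril-formation model.
The two mechanisms predict different responses to seeding: a
fibril-catalysed source shifts the oligomer peak together with the
fibril half-time, a monomer-only source does not.  Measured oligomer
concentrations are relative (detection efficiency is unknown and may be
orders of magnitude below 1), so fits determine an effective formation
amplitude = detection_scale * k_form; the reported formation rate is a
lower bound on the true one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import FibrilTrajectory, NormalizedTrace, half_time

__all__ = [
    "OligomerParams",
    "OligomerSeries",
    "OligomerFit",
    "ModelSelection",
    "PeakEstimate",
    "integrate_oligomers",
    "fit_oligomer_series",
    "select_oligomer_model",
    "oligomer_peak_time",
]

MODES = ("primary", "secondary")

#: reference monomer concentration (uM) for reporting formation rates
REFERENCE_M = 100.0


@dataclass(frozen=True)
class OligomerParams:
    """Rate constants of one oligomer rate law.

    mode "primary": k_form in conc**(1-n_o)/h, k_diss in 1/h.
    mode "secondary": both rate constants are additionally per uM of
    fibril mass concentration.
    """

    mode: str
    k_form: float
    k_diss: float
    n_o: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.k_form < 0 or self.k_diss < 0 or self.n_o < 0:
            raise ValueError("oligomer rate constants and order must be >= 0")


@dataclass
class OligomerSeries:
    """Relative oligomer mass concentration vs time.

    `sem` entries are NaN for single-replicate points (no error bar).
    """

    times: np.ndarray
    S: np.ndarray
    sem: np.ndarray | None = None
    n_replicates: np.ndarray | None = None
    condition: str = ""
    t_halfwidth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if np.any(self.S < 0):
            raise ValueError("oligomer concentrations must be >= 0")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if np.any(self.sem[np.isfinite(self.sem)] < 0):
                raise ValueError("sem must be >= 0 where present")


def _interp_bulk(bulk: FibrilTrajectory, times: np.ndarray, refine: int = 4):
    """Fine common grid covering `times`, with m and M interpolated."""
    t_req = np.asarray(times, dtype=float)
    if t_req.min() < bulk.times.min() - 1e-9 or t_req.max() > bulk.times.max() + 1e-9:
        raise ValueError(
            "bulk trajectory does not cover the requested oligomer times "
            f"([{t_req.min()}, {t_req.max()}] vs [{bulk.times.min()}, {bulk.times.max()}])"
        )
    fine = np.unique(np.concatenate([
        np.linspace(bulk.times.min(), t_req.max(), refine * bulk.times.size),
        t_req,
    ]))
    m = np.interp(fine, bulk.times, bulk.m)
    M = np.interp(fine, bulk.times, bulk.M)
    return fine, m, M


def integrate_oligomers(
    params: OligomerParams,
    bulk: FibrilTrajectory,
    S0: float = 0.0,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the selected linear oligomer rate law along a bulk trajectory.

    Exact exponential-integrator recursion on a refined grid:
    S_{i+1} = S_i e^{-dG} + integral of the source over the step, which
    is unconditionally stable even for fast dissociation.  Returns S at
    `times` (default: the bulk grid).
    """
    if S0 < 0:
        raise ValueError("S0 must be >= 0")
    t_out = bulk.times if times is None else np.asarray(times, dtype=float)
    fine, m, M = _interp_bulk(bulk, t_out)
    if params.mode == "primary":
        f = params.k_form * m**params.n_o
        g = np.full_like(fine, params.k_diss)
    else:
        f = params.k_form * m**params.n_o * M
        g = params.k_diss * M

    # second-order exponential time differencing: with g frozen at its step
    # mean and f linear over the step, the update is exact for constant
    # coefficients (steady states are preserved to machine precision) and
    # unconditionally stable for arbitrarily fast dissociation
    dt = np.diff(fine)
    a = 0.5 * (g[1:] + g[:-1]) * dt
    decay = np.exp(-a)
    small = a < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        phi1 = np.where(small, 1.0 - a / 2.0, (1.0 - decay) / a)
        phi2 = np.where(small, 0.5 - a / 6.0, (a - 1.0 + decay) / a**2)
    w0 = dt * (phi1 - phi2)   # weight of f at step start
    w1 = dt * phi2            # weight of f at step end
    S = np.empty_like(fine)
    S[0] = S0
    for i in range(fine.size - 1):
        S[i + 1] = S[i] * decay[i] + w0[i] * f[i] + w1[i] * f[i + 1]
    S = np.maximum(S, 0.0)
    return np.interp(t_out, fine, S)


@dataclass
class OligomerFit:
    """Weighted least-squares fit of one oligomer rate law."""

    mode: str
    k_form: float          # effective amplitude: detection_scale * k_form
    k_diss: float
    n_o: float
    objective: float
    converged: bool
    formation_rate_per_s: float
    formation_rate_ci: tuple = (np.nan, np.nan)
    reference_m: float = REFERENCE_M
    residuals: np.ndarray | None = None
    systematic_misfit: bool = False

    def params(self) -> OligomerParams:
        return OligomerParams(self.mode, self.k_form, self.k_diss, self.n_o)


def _weights(series: OligomerSeries) -> np.ndarray:
    if series.sem is None:
        return np.ones_like(series.S)
    with np.errstate(divide="ignore"):
        w = np.where(np.isfinite(series.sem) & (series.sem > 0), 1.0 / series.sem, np.nan)
    # points without error bars get the median weight of the others
    med = np.nanmedian(w)
    if not np.isfinite(med):
        return np.ones_like(series.S)
    return np.where(np.isfinite(w), w, med)


def fit_oligomer_series(
    series: OligomerSeries | list[OligomerSeries],
    bulk: FibrilTrajectory | list[FibrilTrajectory],
    mode: str = "secondary",
    n_o: float = 1.0,
    reference_m: float = REFERENCE_M,
    seed: int = 0,
    n_starts: int = 4,
    fix_k_diss: float | None = None,
) -> OligomerFit:
    """Fit k_form and k_diss of one rate law to oligomer series.

    Accepts a single (series, bulk) pair or matched lists for a joint
    fit with shared parameters across conditions.  Residuals are
    weighted by 1/sem where available.  Because the data are relative,
    the fitted k_form is the product of detection scale and true
    formation rate constant, i.e. a lower bound; the reported
    formation rate is k_form * reference_m**n_o converted to 1/s
    (for mode "secondary" it is per uM of fibril mass).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    series_list = [series] if isinstance(series, OligomerSeries) else list(series)
    bulk_list = [bulk] if isinstance(bulk, FibrilTrajectory) else list(bulk)
    if len(series_list) != len(bulk_list):
        raise ValueError("need one bulk trajectory per oligomer series")
    for s in series_list:
        if s.times.size < 5:
            raise ValueError("each oligomer series needs >= 5 timepoints")
    if all(np.all(s.S == 0) for s in series_list):
        raise ValueError("all-zero oligomer series cannot be fitted")

    weights = [_weights(s) for s in series_list]

    def model_S(theta, s, b):
        if fix_k_diss is None:
            kf, kd = 10.0 ** theta
        else:
            kf, kd = 10.0 ** theta[0], fix_k_diss
        p = OligomerParams(mode, kf, kd, n_o)
        return integrate_oligomers(p, b, S0=0.0, times=s.times)

    def residuals(theta):
        res = []
        for s, b, w in zip(series_list, bulk_list, weights):
            res.append((model_S(theta, s, b) - s.S) * w)
        return np.concatenate(res)

    # amplitude guess: match the peak of a unit-k_form solution
    s0, b0 = series_list[0], bulk_list[0]
    unit = integrate_oligomers(OligomerParams(mode, 1.0, 0.1, n_o), b0, times=s0.times)
    peak_ratio = np.max(s0.S) / max(np.max(unit), 1e-300)
    x0_base = np.array([np.log10(max(peak_ratio, 1e-12)), -1.0])
    if fix_k_diss is not None:
        x0_base = x0_base[:1]

    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(1, n_starts)):
        x0 = x0_base if i == 0 else x0_base + rng.normal(0, 1.0, x0_base.size)
        try:
            sol = least_squares(residuals, x0, bounds=(-14, 8), method="trf",
                                xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        obj = float(np.sum(sol.fun**2))
        if best is None or obj < best[0]:
            best = (obj, sol)
    if best is None:
        raise RuntimeError("oligomer fit failed to converge from any start")
    obj, sol = best
    if fix_k_diss is None:
        kf, kd = 10.0 ** sol.x
    else:
        kf, kd = 10.0 ** sol.x[0], fix_k_diss

    # systematic residual structure: a long terminal same-sign run means the
    # rate law cannot follow the late-time decay (e.g. dissociation frozen)
    misfit = False
    for s, b in zip(series_list, bulk_list):
        r = model_S(sol.x, s, b) - s.S
        tail = r[-max(3, s.times.size // 3):]
        if np.all(tail > 0) or np.all(tail < 0):
            scale = max(np.max(np.abs(s.S)), 1e-300)
            if np.mean(np.abs(tail)) > 0.05 * scale:
                misfit = True

    # delta-method CI on log10 k_form from the residual Jacobian
    ci = (np.nan, np.nan)
    try:
        J = sol.jac
        dof = max(sol.fun.size - sol.x.size, 1)
        s2 = obj / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        sd_log = np.sqrt(cov[0, 0])
        lo = np.clip(sol.x[0] - 1.96 * sd_log, -300.0, 300.0)
        hi = np.clip(sol.x[0] + 1.96 * sd_log, -300.0, 300.0)
        rate = lambda logkf: 10.0**logkf * reference_m**n_o / 3600.0
        ci = (rate(lo), rate(hi))
    except np.linalg.LinAlgError:
        pass

    return OligomerFit(
        mode=mode, k_form=float(kf), k_diss=float(kd), n_o=n_o,
        objective=obj, converged=bool(sol.status > 0),
        formation_rate_per_s=float(kf * reference_m**n_o / 3600.0),
        formation_rate_ci=ci, reference_m=reference_m,
        residuals=sol.fun, systematic_misfit=misfit,
    )


@dataclass
class ModelSelection:
    """Joint-fit comparison of primary vs secondary oligomer origin."""

    fits: dict
    selected: str
    margin: float
    indeterminate: bool


def select_oligomer_model(
    series_by_condition: dict[str, OligomerSeries],
    bulks_by_condition: dict[str, FibrilTrajectory],
    n_o: float = 1.0,
    margin: float = 0.10,
    **fit_kwargs,
) -> ModelSelection:
    """Fit both rate laws jointly across conditions and pick the better one.

    Conditions (e.g. unseeded and 1%-seeded) share oligomer parameters;
    the mode with the lower weighted objective is selected.  Objectives
    within `margin` (relative) are reported as indeterminate.
    """
    keys = sorted(series_by_condition)
    if set(keys) - set(bulks_by_condition):
        raise ValueError("every oligomer condition needs a matching bulk trajectory")
    series = [series_by_condition[k] for k in keys]
    bulks = [bulks_by_condition[k] for k in keys]
    fits = {
        mode: fit_oligomer_series(series, bulks, mode=mode, n_o=n_o, **fit_kwargs)
        for mode in MODES
    }
    o_p, o_s = fits["primary"].objective, fits["secondary"].objective
    rel = abs(o_p - o_s) / max(min(o_p, o_s), 1e-300)
    # both rate laws fitting essentially perfectly carries no information
    data_scale = sum(float(np.sum(s.S**2)) for s in series)
    if max(o_p, o_s) < 1e-9 * max(data_scale, 1e-300):
        indeterminate = True
    else:
        indeterminate = rel < margin
    selected = "indeterminate" if indeterminate else ("primary" if o_p < o_s else "secondary")
    return ModelSelection(fits=fits, selected=selected, margin=rel,
                          indeterminate=indeterminate)


@dataclass
class PeakEstimate:
    """Location of the oligomer maximum and its ratio to the bulk half-time."""

    peak_time: float
    peak_value: float
    boundary: bool
    ratio_to_half_time: float | None = None


def oligomer_peak_time(
    times: np.ndarray,
    S: np.ndarray,
    bulk: NormalizedTrace | None = None,
) -> PeakEstimate:
    """Peak of an oligomer series by parabolic interpolation.

    A maximum on the first or last sample is flagged as `boundary`
    (monotone series carry no peak information).  When a bulk trace is
    given, the peak_time / half_time ratio is reported; a value below 1
    places the oligomer maximum before the aggregation half-time.
    """
    t = np.asarray(times, dtype=float)
    S = np.asarray(S, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to locate a peak")
    i = int(np.argmax(S))
    if i == 0 or i == t.size - 1:
        est = PeakEstimate(peak_time=float(t[i]), peak_value=float(S[i]), boundary=True)
    else:
        # parabola through the three samples around the discrete max
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = S[i - 1], S[i], S[i + 1]
        denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
        a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
        b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
        tp = -b / (2 * a) if a < 0 else t1
        tp = float(np.clip(tp, t0, t2))
        est = PeakEstimate(peak_time=tp, peak_value=float(S[i]), boundary=False)
    if bulk is not None:
        est.ratio_to_half_time = est.peak_time / half_time(bulk)
    return est
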