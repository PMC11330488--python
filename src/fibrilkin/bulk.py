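"""Normalization of raw kinetic traces and global multi-curve fitting.

Raw plate-reader signals (ThT fluorescence increasing with fibril mass,
or AlexaFluor-488 fluorescence quenched by aggregation and therefore
decreasing) are taken to be affine in the fibril mass concentration.
Traces are normalized to fraction aggregated and fitted globally:
several curves at different monomer and seed concentrations share one
set of rate constants, and only the combinations

    kplus*kn, kplus*k2 (or kplus*kminus), kplus

are identifiable from bulk data, so the fit works on those composite
products in log10 space.  The headline output is the effective
secondary-pathway proliferation rate kappa at a reference monomer
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    NormalizedTrace,
    RateConstants,
    closed_form_fibril_mass,
    half_time,
)

__all__ = [
    "KineticTrace",
    "FitResult",
    "ComparisonReport",
    "normalize_trace",
    "global_fit",
    "compare_primary_vs_secondary",
    "fit_with_fragmentation_fixed",
    "MODELS",
]

MODELS = ("primary_only", "primary_plus_secondary", "primary_plus_fragmentation")

#: default mean seed length in monomer units (~1 um unsonicated fibrils)
DEFAULT_SEED_MEAN_LENGTH = 5000.0

_LOG_BOUNDS = (-14.0, 8.0)


@dataclass
class KineticTrace:
    """Raw kinetic trace: time (h) vs fluorescence (a.u.) for one well."""

    times: np.ndarray
    signal: np.ndarray
    m_total: float
    seed_mass: float = 0.0
    direction: str = "increase"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size < 20:
            raise ValueError(f"kinetic trace needs >= 20 samples, got {self.times.size}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("trace signal contains non-finite values")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"direction must be 'increase' or 'decrease', got {self.direction!r}")
        if self.m_total <= 0 or self.seed_mass < 0 or self.seed_mass >= self.m_total:
            raise ValueError("require m_total > 0 and 0 <= seed_mass < m_total")


@dataclass
class FitResult:
    """Outcome of a global fit of normalized traces."""

    model: str
    params: dict
    per_trace_rss: list
    objective: float
    converged: bool
    seed: int
    kappa: float | None = None
    kappa_reference_m: float | None = None
    message: str = ""

    def rate_constants(self, kplus: float | None = None) -> RateConstants:
        """Materialize RateConstants from fitted composites.

        Bulk data pin only the products kplus*kn and kplus*k2; a value
        of kplus (fitted when seeded traces were present, else supplied)
        splits them into individual constants.
        """
        kp = kplus if kplus is not None else self.params.get("kplus")
        if kp is None or kp <= 0:
            raise ValueError("kplus is not identified; supply a positive value")
        return RateConstants(
            kn=self.params["kplus_kn"] / kp,
            nc=self.params["nc"],
            kplus=kp,
            k2=self.params.get("kplus_k2", 0.0) / kp,
            n2=self.params["n2"],
            kminus=self.params.get("kplus_kminus", 0.0) / kp,
        )


@dataclass
class ComparisonReport:
    """Model comparison between primary-only and secondary-including fits."""

    fit_primary: FitResult
    fit_secondary: FitResult
    objective_ratio: float
    verdict: str
    factor: float
    per_condition_misfit: dict = field(default_factory=dict)


def _estimate_noise_sd(signal: np.ndarray, n_edge: int) -> float:
    """Noise SD from first differences of the baseline and plateau windows."""
    edges = np.concatenate([signal[:n_edge], signal[-n_edge:]])
    d = np.diff(edges)
    if d.size == 0:
        return 0.0
    return float(np.std(d) / np.sqrt(2.0))


def normalize_trace(trace: KineticTrace) -> NormalizedTrace:
    """Map a raw trace onto fraction aggregated in [0, 1].

    Baseline is the mean of the first 5% of points, plateau the mean of
    the last 5%; a decreasing (quench) trace is flipped so aggregation
    always increases.  Raises if the dynamic range is below 5x the
    estimated noise SD (flat trace / plateau not reached).
    """
    n = trace.times.size
    n_edge = max(2, int(np.ceil(0.05 * n)))
    baseline = float(np.mean(trace.signal[:n_edge]))
    plateau = float(np.mean(trace.signal[-n_edge:]))
    span = plateau - baseline
    noise = _estimate_noise_sd(trace.signal, n_edge)
    if abs(span) <= 5.0 * noise or span == 0.0:
        raise ValueError(
            "no transition: trace range is not distinguishable from noise "
            f"(|range|={abs(span):.3g}, noise SD={noise:.3g})"
        )
    frac = (trace.signal - baseline) / span
    if trace.direction == "decrease":
        # quench signal decreases as fibril mass grows; baseline/plateau
        # means already encode that via a negative span, so frac is
        # oriented correctly — nothing more to do.
        pass
    seed_fraction = 100.0 * trace.seed_mass / trace.m_total
    return NormalizedTrace(
        times=trace.times.copy(),
        fraction_aggregated=frac,
        m_total=trace.m_total,
        seed_fraction=seed_fraction,
        anchored=True,
    )


# ---------------------------------------------------------------------------
# global fitting machinery
# ---------------------------------------------------------------------------


def _trace_conditions(traces: list[NormalizedTrace], seed_mean_length: float):
    conds = []
    for tr in traces:
        seed_mass = tr.seed_fraction / 100.0 * tr.m_total
        conds.append(
            dict(
                m_total=tr.m_total,
                M0=seed_mass,
                P0=seed_mass / seed_mean_length,
            )
        )
    return conds


def _anchor(curve: np.ndarray) -> np.ndarray:
    """Apply the windowed [0, 1] normalization convention to a model curve."""
    n_edge = max(2, int(np.ceil(0.05 * curve.size)))
    base = np.mean(curve[:n_edge])
    top = np.mean(curve[-n_edge:])
    span = top - base
    if span <= 0:
        return curve - base
    return (curve - base) / span


def _model_curve(theta: dict, model: str, nc: float, n2: float,
                 cond: dict, times: np.ndarray, anchored: bool = False) -> np.ndarray:
    """Forward fraction-aggregated curve from composite parameters."""
    kplus = theta.get("kplus", 1.0)
    rates = RateConstants(
        kn=theta["kplus_kn"] / kplus,
        nc=nc,
        kplus=kplus,
        k2=theta.get("kplus_k2", 0.0) / kplus,
        n2=n2,
        kminus=theta.get("kplus_kminus", 0.0) / kplus,
    )
    tr = closed_form_fibril_mass(rates, cond["m_total"], cond["M0"], cond["P0"], times)
    if anchored:
        return _anchor(tr.fraction_aggregated)
    return tr.fraction_aggregated


def _free_param_names(model: str, seeded: bool, fixed: dict) -> list[str]:
    names = ["kplus_kn"]
    if model == "primary_plus_secondary":
        names.append("kplus_k2")
    elif model == "primary_plus_fragmentation":
        names.append("kplus_kminus")
    if seeded:
        names.append("kplus")
    return [n for n in names if n not in fixed]


def _initial_guess(traces: list[NormalizedTrace]) -> dict:
    """Curve-feature heuristic: kappa from the maximal slope, lambda from t_1/2.

    For a secondary-dominated sigmoid f = 1 - exp(-C exp(kappa t)) the
    maximum of df/dt is kappa/e, and the unseeded prefactor is
    C = lambda^2 / (2 kappa^2).
    """
    # prefer an unseeded trace for the heuristic
    unseeded = [t for t in traces if t.seed_fraction == 0]
    tr = unseeded[0] if unseeded else traces[0]
    t, f = tr.times, np.clip(tr.fraction_aggregated, 0.0, 1.0)
    df = np.gradient(f, t)
    kappa0 = max(float(np.e * np.nanmax(df)), 1e-3)
    try:
        th = half_time(tr)
    except ValueError:
        th = t[-1] / 2
    C = np.log(2.0) * np.exp(-kappa0 * max(th, 1e-6))
    lam0 = kappa0 * np.sqrt(max(2.0 * C, 1e-12))
    m0 = tr.m_total
    guess = {
        "kplus_kn": lam0**2 / (2.0 * m0),        # nc=1 scale; starts are perturbed anyway
        "kplus_k2": kappa0**2 / (2.0 * m0),
        "kplus_kminus": kappa0**2 / (2.0 * m0),
        "kplus": 10.0,
    }
    return guess


def global_fit(
    traces: list[NormalizedTrace],
    model: str = "primary_plus_secondary",
    fixed: dict | None = None,
    nc: float = 1.0,
    n2: float = 0.0,
    seed_mean_length: float = DEFAULT_SEED_MEAN_LENGTH,
    n_starts: int = 5,
    seed: int = 0,
    kappa_reference_m: float | None = None,
) -> FitResult:
    """Globally fit shared composite rate constants to a set of curves.

    Minimizes the summed squared residuals between the normalized data
    and the model curves over log10 of the composite parameters
    (kplus*kn, and kplus*k2 or kplus*kminus depending on the model;
    kplus itself joins the fit when seeded traces are present because
    the seed number enters through kplus*P0).  Multi-start local least
    squares with a seeded RNG; best objective wins, ties broken by the
    smaller parameter norm.

    `fixed` maps composite names to frozen values.  Reports kappa (or
    its fragmentation analogue) at `kappa_reference_m` (default: the
    largest m_total present).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    fixed = dict(fixed or {})
    if len(traces) == 0:
        raise ValueError("no traces to fit")
    conditions = _trace_conditions(traces, seed_mean_length)
    seeded = any(c["P0"] > 0 for c in conditions)
    distinct = {(t.m_total, t.seed_fraction) for t in traces}
    free = _free_param_names(model, seeded, fixed)
    if free and (len(traces) < 2 or len(distinct) < 2):
        raise ValueError(
            "non-identifiable configuration: global fitting needs >= 2 traces "
            "spanning >= 2 distinct monomer or seed conditions"
        )

    def unpack(x: np.ndarray) -> dict:
        theta = dict(fixed)
        for name, xi in zip(free, x):
            theta[name] = 10.0**xi
        return theta

    def residuals(x: np.ndarray) -> np.ndarray:
        theta = unpack(x)
        res = []
        for tr, cond in zip(traces, conditions):
            try:
                curve = _model_curve(theta, model, nc, n2, cond, tr.times,
                                     anchored=getattr(tr, 'anchored', False))
            except (ValueError, FloatingPointError):
                curve = np.zeros_like(tr.times)
            res.append(curve - tr.fraction_aggregated)
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    guess = _initial_guess(traces)
    x0_base = np.array([np.log10(max(guess.get(n, 1e-6), 1e-12)) for n in free])

    best = None
    for i in range(max(1, n_starts)):
        x0 = x0_base if i == 0 else x0_base + rng.normal(0.0, 1.0, size=x0_base.size)
        x0 = np.clip(x0, _LOG_BOUNDS[0] + 1, _LOG_BOUNDS[1] - 1)
        try:
            sol = least_squares(
                residuals, x0, bounds=_LOG_BOUNDS, method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        obj = float(np.sum(sol.fun**2))
        norm = float(np.linalg.norm(sol.x))
        key = (obj, norm)
        if best is None or key < (best[0], best[1]):
            best = (obj, norm, sol)
    if best is None and free:
        raise RuntimeError("optimizer failed to converge from any start")

    if free:
        obj, _, sol = best
        theta = unpack(sol.x)
        converged = bool(sol.status > 0)
    else:  # zero-dimensional fit: evaluate residuals at the fixed point
        r = residuals(np.empty(0))
        obj, theta, converged = float(np.sum(r**2)), dict(fixed), True

    per_trace_rss = []
    for tr, cond in zip(traces, conditions):
        curve = _model_curve(theta, model, nc, n2, cond, tr.times,
                             anchored=getattr(tr, 'anchored', False))
        per_trace_rss.append(float(np.sum((curve - tr.fraction_aggregated) ** 2)))

    m_ref = kappa_reference_m or max(t.m_total for t in traces)
    if model == "primary_plus_secondary":
        kappa = float(np.sqrt(2.0 * theta["kplus_k2"] * m_ref ** (n2 + 1.0)))
    elif model == "primary_plus_fragmentation":
        kappa = float(np.sqrt(2.0 * theta["kplus_kminus"] * m_ref))
    else:
        kappa = None

    params = dict(theta)
    params["nc"] = nc
    params["n2"] = n2
    params["lambda"] = float(np.sqrt(2.0 * theta["kplus_kn"] * m_ref**nc))
    return FitResult(
        model=model,
        params=params,
        per_trace_rss=per_trace_rss,
        objective=float(np.sum(per_trace_rss)),
        converged=converged,
        seed=seed,
        kappa=kappa,
        kappa_reference_m=m_ref,
    )


def compare_primary_vs_secondary(
    traces: list[NormalizedTrace],
    factor: float = 5.0,
    **fit_kwargs,
) -> ComparisonReport:
    """Fit with and without secondary processes and compare objectives.

    Secondary processes are declared required when the primary-only
    objective exceeds the secondary-model objective by `factor`; a ratio
    between 1 and `factor` is reported as indeterminate.
    """
    fit_p = global_fit(traces, model="primary_only", **fit_kwargs)
    fit_s = global_fit(traces, model="primary_plus_secondary", **fit_kwargs)
    ratio = fit_p.objective / fit_s.objective if fit_s.objective > 0 else np.inf
    if ratio >= factor:
        verdict = "secondary required"
    elif ratio <= 1.0:
        verdict = "primary sufficient"
    else:
        verdict = "indeterminate"
    misfit = {
        (tr.m_total, tr.seed_fraction): dict(primary=rp, secondary=rs)
        for tr, rp, rs in zip(traces, fit_p.per_trace_rss, fit_s.per_trace_rss)
    }
    return ComparisonReport(
        fit_primary=fit_p,
        fit_secondary=fit_s,
        objective_ratio=float(ratio),
        verdict=verdict,
        factor=factor,
        per_condition_misfit=misfit,
    )


def fit_with_fragmentation_fixed(
    traces: list[NormalizedTrace],
    kappa_frag: float,
    m_ref: float | None = None,
    **fit_kwargs,
) -> FitResult:
    """Primary + fragmentation fit with the proliferation rate pinned.

    The fragmentation proliferation rate sqrt(2 kplus kminus m_ref) is
    fixed to `kappa_frag` (e.g. the bound from plateau-phase fibril
    length analysis), and the remaining parameters are fitted.  The
    resulting objective quantifies how badly a fragmentation-only
    multiplication mechanism accounts for the data.
    """
    if kappa_frag <= 0:
        raise ValueError(f"kappa_frag must be > 0, got {kappa_frag}")
    if m_ref is None:
        m_vals = {t.m_total for t in traces}
        if len(m_vals) != 1:
            raise ValueError(
                "traces span several m_total values; pass m_ref explicitly"
            )
        m_ref = m_vals.pop()
    fixed = dict(fit_kwargs.pop("fixed", {}) or {})
    fixed["kplus_kminus"] = kappa_frag**2 / (2.0 * m_ref)
    return global_fit(
        traces, model="primary_plus_fragmentation", fixed=fixed,
        kappa_reference_m=m_ref, **fit_kwargs,
    )
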