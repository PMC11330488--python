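"""Plateau-phase fibril length analysis.

Once monomer is depleted the fibril mass concentration is constant
(M = M_inf) but fragmentation keeps cutting fibrils, so the number
concentration grows linearly,

    dP/dt = kminus * M_inf      =>   P(t) = kminus * M_inf * t + P_plateau,

and the mean length decays hyperbolically,

    L(t) = M_inf / P(t) = 1 / (kminus * t + 1 / L_plateau),

with t measured from plateau onset.  Fitting L(t) to mean lengths
measured (e.g. by TEM) at several plateau timepoints yields kminus and
L_plateau, whose product is the proliferation rate that fragmentation
alone could sustain:

    kappa_frag = L_plateau * kminus     [1/h]

Lengths are carried in monomer equivalents so that this product has
units of 1/h directly; the product is invariant to a rescaling of the
length unit (L scales up, the fitted kminus scales down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LengthSample",
    "FragmentationFit",
    "mean_length_model",
    "fit_length_series",
    "proliferation_ratio",
    "ProliferationVerdict",
]


@dataclass
class LengthSample:
    """Fibril lengths at one plateau timepoint.

    Either individual `lengths` or a precomputed (`mean_length`,
    `n_measured`) summary.  `t` is hours since plateau onset.
    """

    t: float
    lengths: np.ndarray | None = None
    mean_length: float | None = None
    n_measured: int | None = None
    sem: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("plateau time must be >= 0")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=float)
            if self.lengths.size < 1 or np.any(self.lengths <= 0):
                raise ValueError("lengths must be positive and non-empty")
            self.n_measured = int(self.lengths.size)
            self.mean_length = float(np.mean(self.lengths))
            if self.n_measured > 1:
                self.sem = float(np.std(self.lengths, ddof=1) / np.sqrt(self.n_measured))
        if self.mean_length is None or self.mean_length <= 0:
            raise ValueError("need positive individual lengths or a positive mean_length")
        if self.n_measured is None or self.n_measured < 1:
            raise ValueError("n_measured must be >= 1")


def mean_length_model(t, kminus: float, L_plateau: float):
    """Mean fibril length L(t) = 1 / (kminus*t + 1/L_plateau) in the plateau."""
    if L_plateau <= 0:
        raise ValueError(f"L_plateau must be > 0, got {L_plateau}")
    if kminus < 0:
        raise ValueError(f"kminus must be >= 0, got {kminus}")
    t = np.asarray(t, dtype=float)
    out = 1.0 / (kminus * t + 1.0 / L_plateau)
    return float(out) if out.ndim == 0 else out


@dataclass
class FragmentationFit:
    """Fitted fragmentation rate, plateau length, and their product."""

    kminus: float
    L_plateau: float
    ci: dict = field(default_factory=dict)
    converged: bool = True
    note: str = ""

    @property
    def kappa_frag(self) -> float:
        """Fragmentation-only proliferation rate L_plateau * kminus, 1/h."""
        return self.L_plateau * self.kminus


def _fit_means(t: np.ndarray, means: np.ndarray, sems: np.ndarray | None):
    """Weighted least squares of the hyperbolic decay to timepoint means."""
    # linear fit of 1/L vs t initializes (exact for noise-free data)
    slope, intercept = np.polyfit(t, 1.0 / means, 1)
    k0 = max(slope, 1e-12)
    L0 = 1.0 / max(intercept, 1.0 / (10.0 * means.max()))
    popt, pcov = curve_fit(
        lambda tt, k, L: 1.0 / (k * tt + 1.0 / L),
        t,
        means,
        p0=(k0, L0),
        sigma=sems,
        absolute_sigma=sems is not None,
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    return popt, pcov


def fit_length_series(
    samples: list[LengthSample],
    n_bootstrap: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> FragmentationFit:
    """Fit the plateau length-decay model to a series of length samples.

    Timepoint means are fitted by least squares, weighted by 1/SEM^2
    where individual lengths (or SEMs) are available.  Bootstrap
    confidence intervals resample individual lengths within each
    timepoint when given, otherwise resample mean-level residuals.
    kappa_frag = L_plateau * kminus is an upper-bound estimate of the
    fragmentation-driven proliferation rate.
    """
    if len(samples) < 3:
        raise ValueError("need >= 3 plateau timepoints")
    t = np.array([s.t for s in samples], dtype=float)
    means = np.array([s.mean_length for s in samples], dtype=float)
    sems = np.array([s.sem if s.sem else np.nan for s in samples], dtype=float)
    use_sems = np.all(np.isfinite(sems)) and np.all(sems > 0)
    (kminus, L_plateau), _ = _fit_means(t, means, sems if use_sems else None)

    note = ""
    if kminus < 1e-10:
        note = "kminus pinned at 0 (no decay resolved); kappa_frag <= resolution"

    rng = np.random.default_rng(seed)
    boots = []
    have_lengths = all(s.lengths is not None for s in samples)
    fitted = mean_length_model(t, kminus, L_plateau)
    resid = means - fitted
    for _ in range(n_bootstrap):
        if have_lengths:
            bmeans = np.array(
                [np.mean(rng.choice(s.lengths, size=s.lengths.size, replace=True))
                 for s in samples]
            )
        else:
            bmeans = fitted + rng.choice(resid, size=resid.size, replace=True)
            bmeans = np.maximum(bmeans, 1e-9)
        try:
            (bk, bL), _ = _fit_means(t, bmeans, sems if use_sems else None)
            boots.append((bk, bL, bk * bL))
        except RuntimeError:
            continue
    ci = {}
    if boots:
        arr = np.array(boots)
        lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
        for j, name in enumerate(("kminus", "L_plateau", "kappa_frag")):
            ci[name] = tuple(np.percentile(arr[:, j], [lo, hi]))
    return FragmentationFit(
        kminus=float(kminus), L_plateau=float(L_plateau), ci=ci, note=note
    )


@dataclass
class ProliferationVerdict:
    """Comparison of kinetic and fragmentation-only proliferation rates."""

    ratio: float
    verdict: str
    factor: float


def proliferation_ratio(
    kappa_kinetic: float, kappa_frag: float, factor: float = 5.0
) -> ProliferationVerdict:
    """Fold difference between the kinetic proliferation rate and the
    fragmentation bound, with a verdict.

    ratio > `factor` means fibrils multiply faster than fragmentation
    could account for ("fragmentation insufficient").
    """
    if kappa_kinetic <= 0 or kappa_frag <= 0:
        raise ValueError("both rates must be > 0")
    ratio = kappa_kinetic / kappa_frag
    verdict = "fragmentation insufficient" if ratio > factor else "consistent with fragmentation"
    return ProliferationVerdict(ratio=float(ratio), verdict=verdict, factor=factor)
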