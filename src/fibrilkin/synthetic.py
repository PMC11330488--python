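"""Synthetic data generators for every input the pipeline consumes.

The defaults emulate alpha-synuclein aggregation at neutral pH under
mild agitation: 100 uM monomer, unsonicated fibrillar seeds at 0-1%
mass, a secondary-nucleation-dominated bulk reaction with effective
proliferation rate kappa = 0.4 1/h at 100 uM (saturated secondary
nucleation, reaction order 0), a weak primary pathway
(lambda/kappa = 0.01, giving an unseeded half-time near 24 h), a
plateau-phase fragmentation bound L_plateau * kminus = 0.01 1/h, and
fibril-catalysed oligomer formation at 4e-5 1/s per uM fibril mass at
100 uM monomer with fast dissociation.

Every generator is deterministic under a fixed seed and returns the
ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .bulk import KineticTrace
from .bursts import PhotonTrace
from .kinetics import RateConstants, FibrilTrajectory, simulate_fibril_mass, half_time
from .lengths import LengthSample, mean_length_model
from .oligomers import OligomerParams, OligomerSeries, integrate_oligomers

__all__ = [
    "GeneratorConfig",
    "default_rates",
    "gen_kinetic_traces",
    "gen_length_samples",
    "gen_oligomer_series",
    "gen_photon_traces",
]


def default_rates() -> RateConstants:
    """Study-condition rate constants: kappa = 0.4 1/h and lambda = 0.004 1/h
    at 100 uM monomer (saturated secondary nucleation, n2 = 0, nc = 1)."""
    m_ref = 100.0
    kplus = 20.0                       # 1/(uM h), amyloid-typical elongation
    kappa, lam = 0.4, 0.004            # 1/h at m_ref
    k2 = kappa**2 / (2.0 * kplus * m_ref)
    kn = lam**2 / (2.0 * kplus * m_ref)
    return RateConstants(kn=kn, nc=1.0, kplus=kplus, k2=k2, n2=0.0, kminus=0.0)


@dataclass
class GeneratorConfig:
    """Condition grid, ground-truth parameters and noise levels."""

    seed: int = 0
    m_totals: tuple = (100.0,)
    seed_pcts: tuple = (0.0, 0.25, 1.0)
    rates: RateConstants = field(default_factory=default_rates)
    seed_mean_length: float = 5000.0           # monomers; ~1 um unsonicated fibrils
    direction: str = "decrease"                # AF488 quench readout
    t_max: float = 60.0                        # h
    dt: float = 0.25                           # h, plate-reader cycle
    noise_bulk: float = 0.01                   # additive, fraction of range
    signal_base: float = 100.0                 # a.u.
    signal_amp: float = 100.0                  # a.u.

    # plateau length series
    kminus: float = 5e-6                       # 1/h per monomer
    L_plateau: float = 2000.0                  # monomers; product = 0.01 1/h
    length_times: tuple = (0.0, 25.0, 50.0, 75.0, 100.0)
    n_fibrils: int = 700                       # >= the 650-per-timepoint floor

    # oligomer series
    oligomer: OligomerParams = field(
        default_factory=lambda: OligomerParams(
            mode="secondary",
            k_form=4e-5 * 3600.0 / 100.0,      # 1/(uM_M h): 4e-5 1/s at 100 uM
            k_diss=0.1,                        # 1/(uM_M h): fast dissociation
            n_o=1.0,
        )
    )
    noise_oligomer: float = 0.10               # multiplicative log-normal
    n_replicates: int = 8
    n_oligomer_timepoints: int = 15

    # photon timetraces
    bin_width_ms: float = 1.0
    duration_s: float = 60.0
    background_rate: float = 20.0              # mean counts per bin
    burst_rate_hz: float = 2.0                 # oligomer arrivals per second
    burst_median_photons: float = 150.0
    burst_sigma_ln: float = 1.0
    detection_efficiency_spread: bool = False  # per-burst uniform [0,1] factor
    n_positions: int = 5

    def __post_init__(self) -> None:
        for name in ("noise_bulk", "noise_oligomer", "background_rate", "burst_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng((int(self.seed) + 1_000_003 * stream) % 2**31)


def _conditions(config: GeneratorConfig):
    for m_total in config.m_totals:
        for pct in config.seed_pcts:
            M0 = pct / 100.0 * m_total
            yield m_total, pct, M0, M0 / config.seed_mean_length


def gen_kinetic_traces(config: GeneratorConfig) -> tuple[list[KineticTrace], dict]:
    """Plate-reader-like sigmoidal traces over the condition grid.

    ODE fraction curves are mapped to raw signal through a
    direction-aware affine map plus additive Gaussian noise.  Returns
    the traces and a ground-truth sidecar dict.
    """
    rng = config.rng(1)
    traces = []
    truth_conditions = []
    times = np.arange(0.0, config.t_max + config.dt / 2, config.dt)
    for m_total, pct, M0, P0 in _conditions(config):
        traj = simulate_fibril_mass(config.rates, m_total, M0, P0, times)
        frac = traj.M / m_total
        if config.direction == "decrease":
            clean = config.signal_base + config.signal_amp * (1.0 - frac)
        else:
            clean = config.signal_base + config.signal_amp * frac
        noise = rng.normal(0.0, config.noise_bulk * config.signal_amp, frac.size)
        traces.append(
            KineticTrace(
                times=times.copy(),
                signal=clean + noise,
                m_total=m_total,
                seed_mass=M0,
                direction=config.direction,
            )
        )
        truth_conditions.append(
            dict(m_total=m_total, seed_pct=pct, M0=M0, P0=P0,
                 kappa=config.rates.kappa(m_total - M0),
                 lam=config.rates.lam(m_total - M0))
        )
    truth = dict(
        seed=config.seed,
        rates=asdict(config.rates),
        seed_mean_length=config.seed_mean_length,
        noise_bulk=config.noise_bulk,
        conditions=truth_conditions,
    )
    return traces, truth


def gen_length_samples(config: GeneratorConfig) -> tuple[list[LengthSample], dict]:
    """Plateau-phase fibril length samples.

    Individual lengths are exponentially distributed (the plateau length
    distribution is broad and roughly exponential) with mean following
    the hyperbolic decay L(t) = 1/(kminus t + 1/L_plateau).
    """
    if len(config.length_times) < 3:
        raise ValueError("need >= 3 plateau timepoints")
    if config.n_fibrils < 100:
        raise ValueError("need >= 100 fibrils per timepoint")
    rng = config.rng(2)
    samples = []
    for t in config.length_times:
        mean = mean_length_model(t, config.kminus, config.L_plateau)
        lengths = rng.exponential(mean, size=config.n_fibrils)
        samples.append(LengthSample(t=float(t), lengths=lengths))
    truth = dict(
        seed=config.seed, kminus=config.kminus, L_plateau=config.L_plateau,
        kappa_frag=config.kminus * config.L_plateau, n_fibrils=config.n_fibrils,
    )
    return samples, truth


def gen_oligomer_series(
    config: GeneratorConfig,
    bulks: dict[str, FibrilTrajectory] | None = None,
) -> tuple[dict[str, OligomerSeries], dict[str, FibrilTrajectory], dict]:
    """Replicate-averaged oligomer time series per condition.

    Bulk trajectories (default: noise-free simulations of the config
    grid at the first m_total, unseeded and each seeded level) drive the
    oligomer rate law; replicates get multiplicative log-normal noise.
    Points keep SEMs except when a single replicate is drawn, mirroring
    sparse single-sample measurements.
    """
    rng = config.rng(3)
    m_total = config.m_totals[0]
    times = np.arange(0.0, config.t_max + config.dt / 2, config.dt)
    if bulks is None:
        bulks = {}
        for pct in config.seed_pcts:
            M0 = pct / 100.0 * m_total
            P0 = M0 / config.seed_mean_length
            label = f"seed_{pct:g}pct"
            bulks[label] = simulate_fibril_mass(config.rates, m_total, M0, P0, times)

    series = {}
    for label, bulk in bulks.items():
        th = half_time(bulk.normalized())
        t_obs = np.linspace(0.0, min(2.5 * th, bulk.times[-1]),
                            config.n_oligomer_timepoints)
        S_true = integrate_oligomers(config.oligomer, bulk, S0=0.0, times=t_obs)
        S_mean = np.empty_like(S_true)
        sem = np.full_like(S_true, np.nan)
        n_rep = np.empty(S_true.size, dtype=int)
        sigma_ln = np.sqrt(np.log1p(config.noise_oligomer**2))
        for i, s in enumerate(S_true):
            # occasional single-sample points, as in sparse experiments
            n = 1 if (config.n_replicates > 1 and rng.random() < 0.2) else config.n_replicates
            if config.noise_oligomer > 0:
                reps = s * rng.lognormal(-sigma_ln**2 / 2.0, sigma_ln, size=n)
            else:
                reps = np.full(n, s)
            S_mean[i] = reps.mean()
            n_rep[i] = n
            if n > 1:
                sem[i] = reps.std(ddof=1) / np.sqrt(n)
        series[label] = OligomerSeries(
            times=t_obs, S=S_mean, sem=sem, n_replicates=n_rep, condition=label
        )
    truth = dict(
        seed=config.seed,
        oligomer=asdict(config.oligomer),
        noise_oligomer=config.noise_oligomer,
        formation_rate_per_s_at_100uM=config.oligomer.k_form * 100.0**config.oligomer.n_o / 3600.0,
    )
    return series, bulks, truth


def gen_photon_traces(
    config: GeneratorConfig,
    relative_concentration: float = 1.0,
) -> tuple[list[PhotonTrace], dict]:
    """Confocal timetraces: Poisson background plus rare log-normal bursts.

    Burst arrivals are Poisson with rate proportional to
    `relative_concentration`; each burst deposits a log-normal photon
    count spread over up to three adjacent bins (transit through the
    focal volume).  With `detection_efficiency_spread`, each burst is
    additionally attenuated by a uniform [0, 1] factor emulating the
    non-uniform confocal intensity profile.
    """
    if relative_concentration < 0:
        raise ValueError("relative_concentration must be >= 0")
    rng = config.rng(4)
    n_bins = int(round(config.duration_s * 1000.0 / config.bin_width_ms))
    traces = []
    total_bursts = 0
    for pos in range(config.n_positions):
        lam = np.full(n_bins, config.background_rate, dtype=float)
        n_bursts = rng.poisson(
            config.burst_rate_hz * relative_concentration * config.duration_s
        )
        total_bursts += int(n_bursts)
        if n_bursts > 0:
            centers = rng.integers(1, n_bins - 1, size=n_bursts)
            sizes = rng.lognormal(np.log(config.burst_median_photons),
                                  config.burst_sigma_ln, size=n_bursts)
            if config.detection_efficiency_spread:
                sizes = sizes * rng.uniform(0.0, 1.0, size=n_bursts)
            for c, s in zip(centers, sizes):
                # triangular transit profile over 3 bins
                lam[c - 1] += 0.25 * s
                lam[c] += 0.5 * s
                lam[c + 1] += 0.25 * s
        counts = rng.poisson(lam)
        traces.append(PhotonTrace(bin_width_ms=config.bin_width_ms,
                                  counts=counts, position=pos))
    truth = dict(
        seed=config.seed,
        relative_concentration=relative_concentration,
        burst_rate_hz=config.burst_rate_hz * relative_concentration,
        background_rate=config.background_rate,
        n_bursts_total=total_bursts,
    )
    return traces, truth
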