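"""Simulate fibril-formation kinetics and read off curve descriptors.

Builds unseeded and seeded trajectories at 100 uM monomer with the
default study rates (secondary-nucleation dominated, kappa = 0.4 1/h),
then scans monomer concentration to measure the half-time scaling
exponent that fingerprints the multiplication mechanism.
"""

import numpy as np

import fibrilkin as fk

rates = fk.default_rates()
times = np.arange(0.0, 60.25, 0.25)

print("condition        t_half (h)   lag (h)")
for label, seed_pct in [("unseeded", 0.0), ("1% seeds", 1.0)]:
    M0 = seed_pct  # 1% of 100 uM
    traj = fk.simulate_fibril_mass(rates, 100.0, M0, M0 / 5000.0, times)
    trace = traj.normalized()
    print(f"{label:<15}  {fk.half_time(trace):9.2f}   {fk.lag_time(trace):6.2f}")

m_totals = [25.0, 50.0, 100.0, 200.0]
half_times = []
for m in m_totals:
    t = np.linspace(0, 600, 4000)
    half_times.append(fk.half_time(fk.simulate_fibril_mass(rates, m, 0, 0, t).normalized()))
gamma = fk.scaling_exponent(half_times, m_totals)
print(f"\nscaling exponent over 25-200 uM: {gamma:.3f}")
print("(-0.5 is the signature of saturated secondary nucleation or fragmentation;")
print(" seeding shortens both lag and half-time because fibrils self-catalyse)")
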