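"""Simulate 13C label incorporation in an SBR enrichment.

An SBR at SRT 7.55 d replaces 1/SRT of its biomass per day, so after 8
days of labeled feed a metabolically inert polymer reaches ~65%
labeling. Pools that also turn over intrinsically (degradation balanced
by resynthesis) label faster; storage compartments and amino-acid
recycling delay labeling without changing the endpoint.
"""

from sipturnover import PoolSpec, SBRConfig, simulate_storage_delay, simulate_washout, theoretical_lr

cfg = SBRConfig()  # SRT 7.55 d, 6-h cycles, 32 cycles, 99 atom % substrate
print(f"wash-out alone predicts LR(8 d) = {theoretical_lr(8, 1, 1 / cfg.srt_days):.3f}")

pools = [
    PoolSpec(name="inert polymer"),
    PoolSpec(name="decaying polymer", k_turnover=0.048),
    PoolSpec(name="glycogen-like", k_turnover=0.194),
    PoolSpec(name="protein w/ recycling", k_turnover=0.06,
             recycling_fraction=0.5, precursor_exchange=0.25),
]
print("\nfinal labeling ratio after 32 cycles:")
for pool in pools:
    series = simulate_washout(cfg, pool)
    day2 = series.lr[7]
    print(f"  {pool.name:22s} LR(2 d) = {day2:.3f}   LR(8 d) = {series.lr[-1]:.3f}")

# Storage polymers (PHA/glycogen) on the substrate path delay labeling
# by a few hours at most when they are fully cycled every SBR cycle.
stored = PoolSpec(name="behind storage", n_storage_pools=2, storage_exchange=1.0)
delay = simulate_storage_delay(cfg, stored)
print(f"\ndelay from two fully-cycled storage pools: {delay * 24:.1f} h (<= 12 h)")
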