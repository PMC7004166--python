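"""Daily movement statistics and the musth signal they carry.

For one simulated bull, compute the three per-day statistics -- mean
speed (km/h), 95% minimum-convex-polygon range (km^2), and Benhamou
sinuosity -- and compare musth against non-musth days using the
generator's ground truth.
"""

from musthtrack import SimConfig, simulate_tracks
from musthtrack.pipeline import daily_table

cfg = SimConfig(ages={"B08": 42}, n_days=120, seed=6)
tracks, truth = simulate_tracks(cfg)
daily = daily_table(tracks).merge(truth, on=["individual_id", "date"])

for state, g in daily.groupby("state"):
    print(f"{state:10s} n={len(g):3d}  "
          f"speed {g['mean_speed_kmh'].median():.3f} km/h  "
          f"95% MCP {g['mcp95_km2'].median():.2f} km^2  "
          f"sinuosity {g['sinuosity'].median():.2f}")

ratio = (daily.loc[daily.state == "musth", "mean_speed_kmh"].mean()
         / daily.loc[daily.state == "non_musth", "mean_speed_kmh"].mean())
print(f"\nmusth / non-musth mean-speed ratio: {ratio:.2f}")
print("Musth days are roughly twice as fast and range over a much larger "
      "daily area -- the contrast the detector exploits.")
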