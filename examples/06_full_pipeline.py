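"""Full pipeline: simulate -> preprocess -> metrics -> detect -> score.

Three over-35 bulls are simulated for 300 days with missing fixes and
sparse sightings; musth bouts are detected from the movement data alone
and scored against the expanded observation labels.
"""

from musthtrack import (SCALED_CONFIG, SimConfig, label_observations,
                        simulate_observations, simulate_tracks)
from musthtrack.pipeline import daily_table, detect_musth

cfg = SimConfig(ages={"B06": 38, "B08": 42, "B09": 47}, n_days=300, seed=5,
                missing_rate=0.02, sighting_rate=0.08)
tracks, truth = simulate_tracks(cfg)
obs = label_observations(
    simulate_observations(truth, cfg.sighting_rate, seed=5,
                          one_signal_fraction=0.05))
daily = daily_table(tracks)
print(f"{len(daily)} QC-passing individual-days, {len(obs)} sightings "
      f"({(obs['label'] == 'excluded').sum()} single-signal, excluded)")

res = detect_musth(daily, obs, config=SCALED_CONFIG)
for ind, dec in res.decodes.items():
    g = truth[(truth.individual_id == ind) & (truth.state == "musth")]
    print(f"{ind}: decoded {dec.interval[0]} .. {dec.interval[1]}, "
          f"true bout {g.date.min()} .. {g.date.max()}")
c = res.confusion
print(f"\nconfusion on observation days: TP={c.tp} FP={c.fp} "
      f"TN={c.tn} FN={c.fn}")
print(f"mean per-individual sensitivity {c.mean_sensitivity:.2f}, "
      f"specificity {c.mean_specificity:.2f}")
print("\nFor bulls over 35 the long, well-separated bout makes detection "
      "from tracking data alone nearly perfect; short-bout young bulls "
      "degrade markedly (see the detection-quality acceptance check).")
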