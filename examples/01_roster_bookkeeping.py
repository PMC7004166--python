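"""Tally the packaged study roster.

The package ships a transcription of the 25-bull sample table: per bull,
the age range during the study and the number of non-musth/musth
observation days and analysed tracking days. Totals are always computed,
never stored.
"""

from musthtrack import load_roster, tally_roster

roster = load_roster()
t = tally_roster(roster)

print(f"individuals:                {t.n_individuals}")
print(f"age range (years):          {t.min_age}-{t.max_age}")
print(f"observation days (non-musth/musth): {t.obs_days_nonmusth} / {t.obs_days_musth}")
print(f"tracking days analysed (non-musth/musth): {t.total_days_nonmusth} / {t.total_days_musth}")
print()
print("The tracking-day totals are the analysis set of the mixed-effects "
      "models: each observation labels the day before, of, and after the "
      "sighting, so tracking days outnumber observation days ~3:1.")
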