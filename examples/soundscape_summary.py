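"""Stratified percentile statistics of a synthetic four-site campaign.

Generates the standard monitoring scenario (four sites, two 14-day
campaigns at 5-minute cadence, 6 % dropout) and summarises the background
third-octave levels by site, with day/night and winter/summer tallies.
"""

from shoalsound import StratumKey, default_scene, summarize, synth_campaign, tally

frame, truth = synth_campaign(default_scene(seed=7))
print(f"campaign table: {len(frame)} samples "
      f"({truth['slots_per_period']} slots per site-period before dropout)")

counts = tally(frame, ["diel"])
print("\nday/night counts (sum to total):")
print(counts.to_string(index=False))

print("\nper-site median and 95th-percentile TOL at 1 kHz (dB re 1 uPa rms):")
for site in ("Tidy", "BayouHammock", "Hillview", "PCM"):
    summary = summarize(frame, StratumKey(site_id=site), [50.0, 95.0])
    p50 = summary.levels.loc[50.0, "TOL_1000"]
    p95 = summary.levels.loc[95.0, "TOL_1000"]
    print(f"  {site:14s} n={summary.n:5d}  p50={p50:6.1f}  p95={p95:6.1f}")
print()
print("Medians recover the configured stratum targets; p95 sits a few dB up,")
print("set by the generator's dB-domain jitter. Quiet sites stay quiet in rank.")
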