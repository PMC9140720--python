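"""Generate a small DHS-like female survey with known ground truth.

Builds two synthetic survey waves, prints the table's shape and a few
rows, and shows the exact child-mortality probabilities the generator
used -- the values any downstream estimate can be checked against.
"""

from icebrass import SyntheticConfig, generate_gps, generate_population, ground_truth

config = SyntheticConfig(
    n_per_wave={2000: 2000, 2015: 2500},
    n_clusters=60,
    true_mortality_level=13.0,
    seed=42,
)

table = generate_population(config)
gps = generate_gps(config)

print(f"generated {len(table)} female records over waves {config.wave_years}")
print(table[["wave_year", "age_years", "residence", "wealth_quintile",
             "bmi", "ceb", "sons_dead", "daughters_dead"]].head())
print(f"\n{len(gps)} GPS cluster rows; join closure:",
      table.merge(gps, on=["cluster_id", "wave_year"])["longitude"].notna().all())

print("\nground truth (q_true = probability a child dies by age x, for")
print("children of mothers in each age group, at the generating level):")
print(ground_truth(config).round(4).to_string(index=False))
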