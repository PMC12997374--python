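"""Generate a CKD-like synthetic cohort and inspect its structure.

The generator emulates the public screening table: 400 records, 11
numeric + 14 nominal attributes, prevalence 0.625, 7 planted informative
features, 5% MCAR missingness.  The planted set is the ground truth that
the feature-selection examples try to recover.
"""

from spiralselect import SyntheticSpec, generate_dataset

spec = SyntheticSpec(seed=1)
ds = generate_dataset(spec)

print(f"cohort: {ds.n_samples} records x {ds.n_features} attributes")
print(f"numeric: {len(ds.numeric_columns())}, "
      f"nominal: {len(ds.nominal_columns())}")
print(f"CKD-positive: {int(ds.y.sum())} "
      f"({ds.y.mean():.3f} prevalence; target {spec.class_ratio})")
print(f"missing cells: {ds.missing_mask().to_numpy().mean():.3f} "
      f"(target {spec.missing_rate})")
print(f"planted informative features: {sorted(ds.informative_idx)}")

ds.to_csv("scratch_cohort.csv")
print("wrote scratch_cohort.csv in the UCI dialect ('?' = missing)")
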