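"""Standardize a raw haul-level survey table.

Generates a small synthetic survey (heterogeneous effort fields, one
identification-protocol change), runs the full standardization pipeline —
quality filters, taxonomic harmonization, fish-class filter, per-taxon-haul
aggregation, swept-area derivation/imputation, CPUE/CPUA — and prints what
came out.
"""

import trawlkit as tk

cfg = tk.SimConfig(seed=1, n_years=12, core_cells=6, transient_cells=3,
                   missing_area_fraction=0.2)
raw, truth = tk.generate_survey(cfg)
print(f"raw survey: {raw.n_hauls} hauls, {raw.n_catches} catch records")

backbone = tk.default_backbone()
std, report = tk.standardize(raw, backbone)

print(f"after standardization: {std.n_hauls} hauls, {std.n_catches} records")
print(f"unmatched taxon names: {len(report.unmatched_names)}")
print(f"hauls with swept area: {std.hauls['area_swept'].notna().sum()} "
      f"(20% were generated missing, then model-imputed)")

example = std.catches.dropna(subset=["num_cpue"]).iloc[0]
print(f"\nexample standardized record ({example['accepted_name']}):")
print(f"  num = {example['num']:.1f} individuals")
print(f"  num_cpue = {example['num_cpue']:.1f} individuals per hour towed")
print(f"  num_cpua = {example['num_cpua']:.1f} individuals per km^2 swept")
# CPUE/CPUA make catches comparable across hauls of different duration/area.
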