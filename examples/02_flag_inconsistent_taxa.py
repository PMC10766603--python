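"""Detect a taxon whose identification protocol changed mid-series.

The generated survey records 'Argentina sphyraena' until the midpoint year
and the genus 'Argentina' afterwards — the classic naming-convention switch.
The temporal flag rule (present in < 95% of sampled years AND fewer than 4
presence transitions) marks both names for curation.
"""

import trawlkit as tk

ds, truth = tk.generate_survey(tk.SimConfig(seed=2))
std, _ = tk.standardize(ds, tk.default_backbone())

flags = tk.flag_taxa(tk.build_presence_series(std))
print(flags.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

orig, repl, year = truth.relabel_pairs[0]
print(f"\nplanted protocol change: {orig!r} -> {repl!r} at {year}")
flagged = set(flags.loc[flags["flag_taxon"], "accepted_name"])
print(f"flag rule caught both names: {orig in flagged and repl in flagged}")
# Low presence fraction with few transitions = one contiguous presence span,
# the signature of a renaming; patchy species switch often and escape.
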