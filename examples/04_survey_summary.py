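"""Produce the per-survey quality-control summary.

Hauls per year, per-year distributions of sampling variables, trends of the
six most abundant taxa, and the share of hauls/taxa each flag family would
remove — the overview a user should inspect before analysing a survey.
"""

import trawlkit as tk

ds, _ = tk.generate_survey(tk.SimConfig(seed=4))
std, _ = tk.standardize(ds, tk.default_backbone())

footprint = tk.combine_flags(std)
taxa = tk.flag_taxa(tk.build_presence_series(std))
summary = tk.summarize(std, footprint_flags=footprint, taxon_flags=taxa)

print(summary.to_text())

# summary.write("summaries/") would emit the same content as CSV + text
# files, one set per survey unit.
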