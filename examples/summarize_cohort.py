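"""Cohort summary table: samples, breakpoints and per-genome averages.

The per-genome average is floor(n_breakpoints / n_samples), and the Total
row repeats the arithmetic on the grand sums.
"""
from brehot import summarize_counts

counts = {
    "GBM": (27, 55_874),
    "BRC": (15, 22_077),
    "LUAD": (17, 36_086),
    "OV": (23, 56_435),
    "HN": (17, 22_154),
}
table = summarize_counts(counts)
print(table.to_string(index=False))
# Total row: 99 samples, 192,626 breakpoints, 1945 breakpoints per genome.
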