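"""Recompute the published derived statistics from the bundled printed
summary tables: SNP-type distribution, Ts/Tv ratios, genic shares,
reference-line missingness, and marker-validation rates.
"""

from bessnp import datasets
from bessnp.screenreport import iteration_success, packaged_table, screening_rates, simple_rate
from bessnp.stats import callstats_percent, tstv_summary
from bessnp.subgenome import genic_percent

tstv = tstv_summary(datasets.snp_type_counts())
print(tstv[["total", "transitions", "transversions", "transition_pct", "tstv_ratio"]])
print()

genic = datasets.genic_annotation()
for _, row in genic.iterrows():
    total = int(row.genic_n + row.nongenic_n)
    print(f"{row.tier:<11} genic {genic_percent(int(row.genic_n), total):5.2f}% of {total}")
print()

calls = datasets.final_callstats()
tm1 = calls[calls["sample"] == "TM-1"].iloc[0]
total = int(tstv.loc["overall", "total"])
print(f"reference line missingness: {callstats_percent(int(tm1.missing_n), total)}% "
      f"({int(tm1.missing_n)} of {total})")
print()

records = packaged_table()
rates = screening_rates(records)
it2 = iteration_success(records, 2)
print(f"KASP screening: {rates['good_n']}/{rates['n']} good = {rates['good_pct']}%")
print(f"  transcriptome-associated among good: {rates['good_transcriptome_pct']}%")
print(f"  post-filter success, mapping iteration 2: {it2['success_pct']}%")
print(f"  intraspecific panel: {simple_rate(40, 48)}%   diploid panel: {simple_rate(31, 32)}%")
# The Ts/Tv ratio near 2 and a transition excess are the expected
# signature of genuine SNPs; the validation rates measure how many
# in-silico markers survive wet-lab assay screening.
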