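"""Across-repeat summary of the bundled published per-repeat kinetic fits.

Loads the bundled table of per-repeat Method-1 fits (sigma, lambda, To(0))
for the 14 high-confidence BMP target genes and prints the gene-wise mean
and n-1 sample SD — the package's reproduction of the study's summary
table.
"""

from bmpdiversity import summarize_repeats
from bmpdiversity.reference import method1_repeat_fits_as_method1

summary = summarize_repeats(method1_repeat_fits_as_method1())
print(f"{'gene':>8}  {'sigma mean':>10} {'sd':>8}  {'lambda mean':>11} {'sd':>8}")
for row in summary.itertuples():
    print(f"{row.gene:>8}  {row.sigma_mean:10.5f} {row.sigma_sd:8.5f}  "
          f"{row.lambda_mean:11.5f} {row.lambda_sd:8.5f}")
print("\nRates are per second; e.g. bambia's mean sigma of 0.00047/s makes it")
print("one of the fastest-induced BMP targets, while its lambda of 0.00083/s")
print("implies a transcript half-life of ~14 min after the pulse.")
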