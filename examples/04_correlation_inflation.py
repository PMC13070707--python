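"""Sparsity-induced correlation inflation in co-expression networks.

Two independent Poisson expression profiles are padded with shared zeros to
mimic increasing dropout; the Pearson and Spearman correlations between
them grow with the shared-zero fraction even though the profiles carry no
common signal.  This is why naive co-expression networks over sparse
scRNA-seq data overestimate similarity, and why the hypergraph keeps the
raw expression levels instead.
"""

import hyperwalk as hw

df = hw.inflation_experiment(base_length=50,
                             zero_fractions=(0.0, 0.2, 0.4, 0.6, 0.8, 0.9),
                             n_reps=100, seed=0)
for stat in ("pearson", "spearman"):
    sub = df[df.statistic == stat]
    print(f"{stat}:")
    for _, row in sub.iterrows():
        print(f"  zero fraction {row.fraction:.1f}: mean r = {row.mean_corr:+.3f} "
              f"[{row.ci_low:+.3f}, {row.ci_high:+.3f}]")
print("-> the f=0 row is the baseline for independent profiles (CI covers 0); "
      "correlation rises towards 1 purely through shared zeros.")
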