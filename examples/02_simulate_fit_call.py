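"""Simulate a dataset with known truth, fit the sampler, call isoforms.

Generates 20 genes (2-3 isoforms each, 10 vs 10 samples, half the isoforms
differential at 0-5 dB), runs a short chain, and scores the calls at the
0.75 posterior-probability threshold against the generative truth.
"""

import isodex as ix
from isodex.analysis import call_differential, evaluate_detection

dataset = ix.simulate_dataset(ix.SimulationConfig(n_genes=20, seed=7))
truth = dataset.truth_table()
print(f"simulated {len(truth)} isoforms, "
      f"{int(truth.d_true.sum())} truly differential")

summary = ix.run_mcmc(dataset.gene_data(), dataset.design,
                      ix.MCMCConfig(n_iter=1500, burn_in=750, seed=8))
table = summary.to_table()
print("\nper-isoform results (head):")
print(table.head(6).to_string(index=False,
                              float_format=lambda v: f"{v:.3f}"))

ev = evaluate_detection(call_differential(summary, threshold=0.75), truth)
print(f"\nat P(d=1) > 0.75: precision {ev.precision:.3f}, "
      f"recall {ev.recall:.3f}, F {ev.f_score:.3f}")
print("recall by true-SNR band:",
      {k: round(v, 3) for k, v in ev.band_recall.items()})
print("\nprob_differential is the posterior probability the two phenotype")
print("groups draw this isoform's abundance from different Gamma rates;")
print("snr_db summarizes the estimated effect size on the decibel scale.")
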