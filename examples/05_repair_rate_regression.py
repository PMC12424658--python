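"""Repair rates along the genome and the hyperbolic mutation-count law.

Per-window lesion time courses give exponential-decay repair rates rNER(w).
The kinetic model predicts window mutation counts y = A/(rNER - r*) + B:
a hyperbolic translesion-synthesis part that blows up as repair approaches
the overwhelmed point r*, plus a rate-independent repair-error baseline B.
The fit decomposes each window's mutations into the two channels.
"""

import numpy as np

from funnelsig.repairmap import (
    bin_by_rate, decompose_contributions, estimate_ner_rates, fit_hyperbolic,
)
from funnelsig.synthetic_data import gen_repair_timecourse, gen_window_counts

tc, truth = gen_repair_timecourse(n_windows=400, L0=1e4, seed=3)
rates = estimate_ner_rates(tc)
true_rates = truth.derived["rates"]
err = np.mean([
    abs(row.rate - true_rates[row.window_id]) / true_rates[row.window_id]
    for row in rates.itertuples()
])
print(f"estimated rNER for {len(rates)} windows; "
      f"mean relative error vs truth {100 * err:.1f}%")

counts, _ = gen_window_counts(rates.rate.to_numpy(), A=8.0, r_star=0.1, B=20.0,
                              seed=4)
binned = bin_by_rate(counts, n_bins=50)
fit = fit_hyperbolic(binned.rate, binned["count"] / binned.n_windows)
print(f"hyperbolic fit: A = {fit.A:.2f} (true 8), r* = {fit.r_star:.3f} "
      f"(true 0.1), B = {fit.B:.2f} (true 20), R^2 = {fit.r_squared:.3f}")

decomp = decompose_contributions(fit, binned.rate, binned["count"])
print(f"aggregate TLS share {decomp.attrs['aggregate_tls_share']:.2f}, "
      f"repair-error share {decomp.attrs['aggregate_repair_error_share']:.2f}")
print("Slowly repaired windows are TLS-dominated; fast windows approach the "
      "flat repair-error baseline — the signature of two mutation sources.")
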