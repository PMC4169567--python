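"""The RNA-polymerase pausing model of TSSaRNA biogenesis.

Polymerases start every dtau time units and stall dt units at pause sites;
a polymerase blocked one bp behind a stalled one releases its partial
transcript — the modelled TSSaRNA.  Truncated transcripts therefore pile up
one bp behind each pause, and the split between truncated and full-length
output is set entirely by (dtau, dt).
"""

import math

from tssarna import (
    PolSimConfig, length_histogram, modal_lengths, run_cell, simulate,
    steady_state_rates,
)

# --- multi-band pattern: pauses with increasing retention times ------------
cfg = PolSimConfig(
    L=2000, dtau=4, pauses=((27, 50), (63, 150), (91, 400), (107, 1000)),
    T=60_000, burn_in=14_000,
)
hist = length_histogram(simulate(cfg))
print("Truncated-length bands:", modal_lengths(hist))
print("Band counts:", {k: hist[k] for k in sorted(hist)})
print("One band one bp behind each pause (27/63/91/107 -> 26/62/90/106 nt), "
      "matching a multi-band small-RNA blot; counts fall with depth because "
      "each pause throttles the flux reaching the next.\n")

# --- fold-differences from the two parameters ------------------------------
fast = run_cell(4, 250)    # frequent initiation, long stall
slow = run_cell(84, 250)   # sparse initiation, same stall
fold = fast.truncated_rate / slow.truncated_rate
print(f"dt=250, dtau=4 vs dtau=84: full-length rates {fast.full_length_rate:.6f} "
      f"vs {slow.full_length_rate:.6f} (equal), truncated fold {fold:.1f} "
      f"(~2^{round(math.log2(fold))}): TSSaRNA output varies ~32-fold while "
      "the cognate gene is constant.")

a = run_cell(12, 46)
b = run_cell(8, 14)
print(f"dt=46, dtau=12 vs dt=14, dtau=8: cognate fold "
      f"{b.full_length_rate / a.full_length_rate:.2f} with truncated rates "
      f"{a.truncated_rate:.4f} vs {b.truncated_rate:.4f}: the cognate gene "
      "varies ~3-fold while TSSaRNA output is constant.\n")

# --- exact steady state -----------------------------------------------------
full, trunc = steady_state_rates(4, [(36, 250)])
print(f"Closed form (dtau=4, dt=250): full-length rate {full:.6f}, truncated "
      f"{sum(trunc.values()):.6f} — pause entries lock to the initiation "
      "grid, cycle = dtau*ceil(dt/dtau).")
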