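"""Ultra-low-coverage read-count simulation and its extreme missingness.

At 0.01-0.05x coverage most cell-site entries receive no reads at all, and
an entry with reads but zero variant-supporting reads is indistinguishable
from lack of coverage, so the observed matrix contains only 1s and missing
entries (3).  This example uses a reduced size (800 x 1000) so it runs in
about a second; the benchmark-scale run is 4000 cells x 5000 mutations.
"""

import numpy as np

import scclonesim as s

for coverage in (0.01, 0.03, 0.05):
    ds = s.simulate_lowcov_dataset(
        n_cells=800, n_mutations=1000, n_clusters=8, coverage=coverage, seed=11
    )
    t = ds.reads.t
    print(
        f"coverage {coverage}: P(t=1)={np.mean(t == 1):.4f} (expect {coverage - coverage**2:.4f}), "
        f"P(t=2)={np.mean(t == 2):.4f} (expect {coverage**2:.4f}), "
        f"missing {100 * ds.missing_fraction:.2f}%"
    )
# Depth follows the two-threshold uniform rule; the missing percentage
# drops as coverage rises but stays above 99% throughout this regime.
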