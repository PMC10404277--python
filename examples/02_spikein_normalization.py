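"""Spike-in size-factor recovery from planted library scale factors.

Four libraries are simulated with known scale factors {1, 1.5, 2, 3} and
Poisson counting noise on 92 ERCC-like spike-in species; median-of-ratios
against the known input amounts should recover the factors (up to the
geometric-mean anchoring) within a few percent.
"""

import numpy as np
import pandas as pd

from polyte import (
    SimulationDesign,
    compute_size_factors,
    generate_fraction_counts,
    make_spikein_reference,
)

planted = {
    "control_total_rep1": 1.0,
    "control_total_rep2": 1.5,
    "mutant_total_rep1": 2.0,
    "mutant_total_rep2": 3.0,
}
ref = make_spikein_reference(n_species=92, span_log2=8.0, total_amount=1e4)
design = SimulationDesign(
    fractions=("total",), mean_depth=100.0, dispersion=0.0,
    library_scale_factors=planted, noise="poisson", seed=4,
)
counts, _ = generate_fraction_counts(["g1"], design, ref)

factors = compute_size_factors(counts, ref)
expected = pd.Series(planted)
expected /= np.exp(np.log(expected).mean())  # geometric mean -> 1

report = pd.DataFrame(
    {"planted": expected, "recovered": factors,
     "rel_error_pct": 100 * (factors / expected - 1).abs()}
)
print(report.round(4).to_string())
print(
    "\nEvery factor within a few percent: spike-ins anchor the absolute "
    "between-library scale that makes polysome/monosome ratios comparable."
)
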