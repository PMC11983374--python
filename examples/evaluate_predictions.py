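"""Score quantification results the way the method is validated.

Builds a toy set of 'certified' compositions, perturbs them into mock
predictions, and produces the deviation report: relative deviations for
concentrations (stratified at the 0.1% mass-fraction boundary) and
density, absolute deviations for the surface position, and the summed
concentration predicted for elements that are certified absent.
"""

import numpy as np

from cmxrf import evaluation, samples
from cmxrf.model import QuantPrediction
from cmxrf.samples import TARGET_ELEMENTS

rng = np.random.default_rng(7)
truths, preds, x0s = [], [], []
for _ in range(25):
    truth = samples.draw_composition(samples.default_occurrence_table(), rng)
    conc = truth.as_vector() * rng.lognormal(0.0, 0.15, size=53)  # ~15% scatter
    conc[rng.integers(0, 53)] += 1e-4  # an occasional spurious trace prediction
    x0 = float(rng.uniform(25, 125))
    truths.append(truth)
    x0s.append(x0)
    preds.append(
        QuantPrediction(conc, truth.density * rng.normal(1.0, 0.1), x0 + rng.normal(0, 4))
    )

report = evaluation.build_report(preds, truths, x0_true=x0s)
print(report.to_json())
print(
    "\nmedian relative deviation (elements >= 0.1%):",
    f"{report.summary['median_conc_rel_dev_over_0.1%']:.3f}",
)
print(
    "fraction of trace elements within one order of magnitude:",
    f"{report.summary['frac_under_0.1%_within_order_of_magnitude']:.2f}",
)
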