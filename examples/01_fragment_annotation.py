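"""Annotate a spectrum with theoretical b/y ions and normalize intensities.

Builds a modified peptidoform, computes its singly charged b/y fragment
m/z values, simulates a spectrum from the package's closed-form intensity
law, and extracts TIC-normalized log2 intensities.
"""

import numpy as np

from imrescore import (
    annotate_spectrum,
    normalize_log_intensities,
    parse_peptidoform,
    theoretical_fragment_mz,
)
from imrescore.synthetic import simulate_spectrum

pep = parse_peptidoform("AC[+57.02146]DEFGHK/2")
b_mz, y_mz = theoretical_fragment_mz(pep)
print(f"peptidoform: {pep}")
print(f"b ions (m/z): {np.round(b_mz, 4)}")
print(f"y ions (m/z): {np.round(y_mz, 4)}")

spectrum = simulate_spectrum(pep, noise_sigma=0.2, n_noise_peaks=5, seed=7)
table = annotate_spectrum(spectrum, pep, tolerance=10.0, unit="ppm")
print(f"matched ions: {table.n_matched} of {2 * table.n_sites}")

norm = normalize_log_intensities(table)
print(f"normalized log2 y intensities: {np.round(norm.y_obs, 2)}")
# Values near log2(0.001) = -10 are unmatched ions; larger values are the
# fraction of the spectrum's total ion current carried by each fragment.
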