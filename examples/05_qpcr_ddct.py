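"""Comparative-Ct (ddCt) quantification of a qPCR validation run.

Ct values for a target gene and the reference gene (e.g. ACT) in three
ripening samples; the earliest stage serves as the calibrator.
"""

import pandas as pd

from flavornet.qpcr import ddct_table

records = pd.DataFrame(
    {
        "gene_id": ["SUS1"] * 3 + ["CCD1"] * 3,
        "sample_id": ["50DPA", "73DPA", "91DPA"] * 2,
        "ct_target": [24.0, 21.5, 20.0, 26.0, 24.8, 23.1],
        "ct_reference": [15.0, 15.2, 14.9, 15.0, 15.2, 14.9],
        "is_calibrator": [True, False, False, True, False, False],
    }
)

table = ddct_table(records)
print(table.round(2))
# Each row is one gene, each column one sample, values are 2^(-ddCt):
# fold expression relative to the calibrator (50 DPA = 1.0) after
# normalising to the reference gene.  SUS1 rises ~15-fold by full
# ripeness; a ddCt of -1 would mean exactly one extra doubling.
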