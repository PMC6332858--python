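"""Ripening-profile groups and the FPKM colour scales.

Genes significant in the S1->S2 and/or S2->S3 screens are classified by
the signs of their changes: I monotone up, II up-then-down, III monotone
down, IV down-then-up; genes changing more than 32-fold are excluded.
"""

import pandas as pd

from flavornet.profiles import bin_expression, classify_profiles

idx = pd.Index(["sugar_up", "peak_mid", "acid_down", "dip_mid", "wild"], name="gene_id")
de12 = pd.DataFrame(
    {"log2ratio": [1.8, 2.2, -1.5, -2.0, 6.2],
     "is_deg": [True, True, True, True, True]},
    index=idx,
)
de23 = pd.DataFrame(
    {"log2ratio": [1.2, -1.9, -2.1, 1.7, 1.0],
     "is_deg": [True, True, True, True, True]},
    index=idx,
)

out = classify_profiles(de12, de23)
print(out)
# sugar_up rises at both intervals -> group I; peak_mid peaks at
# commercial maturation -> II; acid_down falls throughout -> III;
# dip_mid dips -> IV; "wild" changed 2^6.2 = 73-fold and is excluded
# by the 32-fold cap.

for fpkm in [0.05, 3.0, 500.0]:
    print(f"FPKM {fpkm:>7}: 9-bin colour {bin_expression(fpkm, 'fig3')}, "
          f"12-bin colour {bin_expression(fpkm, 'fig56')}")
# Bin indices are the 1-based colour codes of the two printed scales.
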