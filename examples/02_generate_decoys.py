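"""Generate a balanced starting set of peptide decoys from a native pose.

Half the decoys are 'salvageable' (whole-peptide LRMSD < 5.5 A, or a
contiguous stretch of at least half the peptide under 4.0 A) and half are
not; move magnitudes adapt after every draw to hover around that boundary.
"""

import numpy as np

from pepscore import assemble_balanced_set, make_fixture_complex

native = make_fixture_complex(seed=0)
records = assemble_balanced_set(native, n=20, rng=np.random.default_rng(0))

print("lrmsd (A)  target  salvageable")
for rec in records:
    print(f"{rec.lrmsd_to_native:8.2f}  {rec.target:.3f}  {rec.salvageable}")

n_salv = sum(r.salvageable for r in records)
print(f"\n{n_salv}/{len(records)} salvageable (exactly half by construction);")
print("'target' is the normalized LRMSD the score network is trained to predict.")
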