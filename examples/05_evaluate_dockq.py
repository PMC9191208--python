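"""Score a model against its native structure with DockQ.

DockQ averages the fraction of preserved native contacts (Fnat), a scaled
interface RMSD and a scaled ligand RMSD into one number in [0, 1], with
quality classes Incorrect / Acceptable / Medium / High at 0.23 / 0.49 /
0.80.
"""

import numpy as np

from pepscore import dockq, make_fixture_complex
from pepscore.decoys import PerturbationParams, perturb_native

native = make_fixture_complex(seed=0)
model = perturb_native(
    native,
    PerturbationParams(translation_scale=2.0, rotation_scale=10.0, internal_scale=3.0),
    np.random.default_rng(4),
).complex

report = dockq(model, native)
for key, value in report.as_dict().items():
    print(f"{key:12s} {value if isinstance(value, str) else round(value, 3)}")
print("\nfnat: preserved native contacts; irmsd/lrmsd in Angstrom; "
      "dockq in [0,1] with its CAPRI-style class above.")
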