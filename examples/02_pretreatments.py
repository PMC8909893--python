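"""Apply the canonical spectral pre-treatments to one spectra matrix.

Shows the eight treatment variants side by side and verifies the two
scatter-correction identities: SNV ignores per-spectrum affine distortion,
and MSC inverts it against the training-set reference.
"""

import numpy as np

import gingerspec as gs
from gingerspec.preprocessing import CANONICAL_TREATMENTS, make_treatment

dataset = gs.extract_dataset(gs.generate_dataset(
    gs.SyntheticConfig(n_samples=12, cube_rows=16, cube_cols=16, seed=1)))
sm = dataset.spectra
print(f"spectra matrix: {sm.n_samples} samples x {sm.n_bands} bands")

for tag in CANONICAL_TREATMENTS:
    out = make_treatment(tag).fit_transform(sm)
    print(f"  {tag:5s} -> range [{out.X.min():+.3f}, {out.X.max():+.3f}]  "
          f"(tag {out.treatment_tag!r})")

# SNV removes any per-spectrum affine distortion exactly
distorted = 1.3 * sm.X + 0.2
print("SNV(1.3x + 0.2) == SNV(x):",
      np.allclose(gs.snv(distorted), gs.snv(sm.X), atol=1e-10))

# MSC inverts an affine distortion of the reference spectrum
ref = gs.msc_fit(sm.X)
twisted = 1.8 * ref.reference_spectrum + 0.05
restored = gs.msc_apply(twisted[None, :], ref)[0]
print("MSC inverts 1.8*ref + 0.05:",
      np.allclose(restored, ref.reference_spectrum, atol=1e-10))
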