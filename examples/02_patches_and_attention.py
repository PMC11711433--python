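"""Patchification and scaled dot-product attention on toy tensors.

A 224 x 224 x 3 image splits into N = HW/P^2 = 256 non-overlapping 14 x 14
patches, each flattened to 588 values - the token sequence a vision
transformer attends over.  The attention demo shows that each output row is
a convex mixture of the value rows, weighted by softmax(QK^T/sqrt(dK)).
"""

import numpy as np

from tokenmixer import (compute_num_patches, extract_patches,
                        reassemble_patches, scaled_dot_attention)
from tokenmixer.synthetic import make_toy_tensors

img = make_toy_tensors((1, 224, 224, 3), seed=0)[0]
print("patch count for 224x224, P=14:", compute_num_patches(224, 224, 14))
grid = extract_patches(img, 14)
print("patch matrix:", grid.patches.shape, "(N patches x P*P*C values)")
print("roundtrip exact:", bool((reassemble_patches(grid) == img).all()))

Q = np.array([[1.0, 0.0]])
K = np.array([[1.0, 0.0], [0.0, 1.0]])
V = np.array([[1.0, 0.0], [0.0, 1.0]])
out = scaled_dot_attention(Q, K, V, d_k=2)
print("attention output:", np.round(out, 4))
# The query aligns with the first key, so the first value gets weight
# softmax(1/sqrt(2), 0) ~ 0.67 and the output is ~ [0.67, 0.33]:
# a convex combination of V's rows, never outside their hull.
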