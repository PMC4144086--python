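"""Feature-wise min-max normalization to [0, 1].

The statistics are computed over every sample passed in — in the
transductive pipeline that is the union of training and test samples,
so that a single similarity graph can be built over all of them.
"""

from __future__ import annotations

import numpy as np

from nimclass.dataio import ExpressionDataset


def minmax_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Map every feature to [0, 1] by (x - min) / (max - min).

    Constant features map to 0 rather than being dropped, keeping
    feature indices stable. Idempotent on non-constant features, and
    order-preserving within each feature.
    """
    if dataset.n_samples == 0:
        raise ValueError("cannot normalize an empty dataset")
    x = dataset.values
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    out = (x - lo) / safe_span
    out[:, constant] = 0.0
    return dataset.with_values(out)
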