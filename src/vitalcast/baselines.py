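"""Reference predictors for comparison tests.

The persistence (last-observation-carried-forward) baseline is the
canonical naive forecaster for vitals: hold the most recent real
observation flat across the horizon.  It is strong over short horizons and
weak for sparsely observed channels, which is exactly the regime where a
joint model that borrows strength across correlated channels should win.
"""

from __future__ import annotations

import numpy as np

from .prep import WindowSet

__all__ = ["persistence_forecast"]


def persistence_forecast(ws: WindowSet) -> np.ndarray:
    """(n_windows, horizon, n_targets) clinical-scale flat forecasts.

    Each target holds its last mask-1 past observation; windows with no
    real past observation for a target fall back to the training mean
    (the normalization center).
    """
    targets = list(ws.schema.targets)
    past_names = list(ws.schema.past_timeseries)
    N, L, _ = ws.past.shape
    H = ws.future_truth.shape[1]
    out = np.empty((N, H, len(targets)))
    for j, tgt in enumerate(targets):
        mu, sd = ws.normalization[tgt]
        col = past_names.index(tgt)
        z = ws.past[:, :, col]  # z-scored past values (filled)
        mask = ws.past_masks[:, :, j] > 0
        for i in range(N):
            real = np.nonzero(mask[i])[0]
            last = z[i, real[-1]] * sd + mu if real.size else mu
            out[i, :, j] = last
    return out
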