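"""Shared output container for the two context encoders."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EncoderOutputs:
    """Per-layer context matrices from a two-layer encoder.

    ``Y`` is the first-layer output and ``Z`` the second-layer output,
    both ``T x D``; rows at masked-off positions are zero so downstream
    pooling can rely on the mask alone.
    """

    Y: np.ndarray
    Z: np.ndarray
    mask: np.ndarray

    @property
    def D(self) -> int:
        return self.Y.shape[-1]
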