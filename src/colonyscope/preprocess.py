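"""Per-frame brightness normalization.

Bright-field acquisitions vary in illumination between wells and days; the
texture classifier should see intensity-normalized input.  The operation here
is a percentile-clipped linear contrast stretch ("autolevels"): pixels at or
below the low percentile map to the output minimum, pixels at or above the
high percentile map to the output maximum, linear in between.  It is exactly
invariant to positive affine intensity changes a*x + b, which is the point:
after normalization, frames differing only in lamp brightness/offset are
identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Frame


@dataclass
class AutolevelsParams:
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    output_range: tuple[float, float] = (0.0, 65535.0)

    def __post_init__(self) -> None:
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValueError(
                "require 0 <= low_percentile < high_percentile <= 100, got "
                f"({self.low_percentile}, {self.high_percentile})"
            )


def autolevels(image: Frame | np.ndarray, params: AutolevelsParams | None = None):
    """Percentile-clipped linear stretch of one frame.

    Parameters
    ----------
    image
        A :class:`~colonyscope.frames.Frame` or a bare 2-D array.
    params
        Percentiles and output range; defaults stretch the 1st..99th
        percentile onto the full 16-bit range.

    Returns
    -------
    Same type as the input (Frame in, Frame out), with the same dtype as the
    input pixels.  A constant (degenerate) image maps to a constant mid-range
    image rather than raising.
    """
    params = params or AutolevelsParams()
    is_frame = isinstance(image, Frame)
    px = image.pixels if is_frame else image
    px = np.asarray(px)
    if px.size == 0:
        raise ValueError("empty image")

    lo = np.percentile(px, params.low_percentile)
    hi = np.percentile(px, params.high_percentile)
    out_lo, out_hi = params.output_range
    if hi <= lo:
        out = np.full(px.shape, 0.5 * (out_lo + out_hi))
    else:
        out = (px.astype(np.float64) - lo) * ((out_hi - out_lo) / (hi - lo)) + out_lo
        np.clip(out, out_lo, out_hi, out=out)
    if np.issubdtype(px.dtype, np.integer):
        out = np.rint(out)
    out = out.astype(px.dtype)
    if is_frame:
        return Frame(pixels=out, well=image.well, day=image.day)
    return out
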