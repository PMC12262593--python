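"""Z-anisotropy correction by slide interpolation.

3D-SIM reconstructions are acquired with a much coarser pitch along Z
(0.15 um) than in-plane (0.06 um). To balance the voxel dimensions, two
equidistant slides are inserted between every adjacent pair of real
Z-slides. Each interpolated slide is the distance-weighted average of its
two neighbouring real slides,

    I_hat = (2/3) I_s0 + (1/3) I_s1,

where I_s0 is the nearer and I_s1 the farther real slide. The weights are
exact linear interpolation at the inserted positions (0.05 and 0.10 um of
the 0.15 um gap), so each original gap becomes a run of four slides (two
real, two interpolated) at a uniform 0.05 um pitch. Real slides are passed
through unmodified; interpolated values are kept in floating point.
"""

from __future__ import annotations

import numpy as np

from .stack import INTERP, REAL, MultiChannelStack

#: interpolation weights toward the nearer / farther real slide
W_NEAR = 2.0 / 3.0
W_FAR = 1.0 / 3.0


def interpolate_z(stack: MultiChannelStack) -> MultiChannelStack:
    """Insert two interpolated slides between each adjacent real pair.

    All channels are interpolated identically. For N real slides the output
    has ``3 N - 2`` slides flagged ``real, interp, interp, real, ...`` and a
    Z-spacing one third of the input's.

    Raises
    ------
    ValueError
        If the stack has fewer than two slides, or has already been
        enhanced (re-interpolation is refused, never silently applied).
    """
    if stack.is_enhanced:
        raise ValueError("stack is already enhanced; refusing to re-interpolate")
    n = stack.n_slides
    if n < 2:
        raise ValueError("interpolation needs at least 2 real slides")

    n_out = 3 * n - 2
    out_channels: dict[str, np.ndarray] = {}
    for name, raw in stack.channels.items():
        # weighted averages are taken in float64; integer-count channels are
        # stored as float32 (exact for camera counts, and rounding to
        # nearest cannot push a convex combination past either endpoint)
        store = np.float32 if np.asarray(raw).dtype.kind in "iub" else np.float64
        ch = np.asarray(raw, dtype=np.float64)
        out = np.empty((n_out,) + ch.shape[1:], dtype=store)
        out[::3] = ch
        a, b = ch[:-1], ch[1:]  # nearer/farther real slides per gap
        out[1::3] = W_NEAR * a + W_FAR * b
        out[2::3] = W_NEAR * b + W_FAR * a
        out_channels[name] = out

    flags = [REAL if i % 3 == 0 else INTERP for i in range(n_out)]
    return MultiChannelStack(
        channels=out_channels,
        spacing_xy=stack.spacing_xy,
        spacing_z=stack.spacing_z / 3.0,
        slide_flags=flags,
    )
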