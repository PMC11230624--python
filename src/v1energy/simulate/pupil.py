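"""Synthetic eye-camera frames: a dark elliptical pupil on a brighter iris."""

from __future__ import annotations

import numpy as np

from v1energy.pupil import PupilEllipse


def simulate_pupil_video(
    semi_axes: tuple[float, float],
    center: tuple[float, float] | None = None,
    angle_deg: float = 0.0,
    frame_shape: tuple[int, int] = (200, 200),
    frame_count: int = 1,
    noise: float = 0.0,
    seed: int = 0,
    pupil_value: float = 40.0,
    iris_value: float = 200.0,
    supersample: int = 4,
) -> tuple[np.ndarray, PupilEllipse]:
    """Grayscale frame stack containing one dark elliptical pupil.

    The ellipse has the given semi-axes (pixels), center (row, col;
    defaults to the frame center) and orientation; edges are rendered
    with ``supersample``-fold area sampling so partial pixels carry
    intermediate intensity.  ``noise`` is the per-pixel Gaussian SD in
    intensity units (frames are clipped to [0, 255]).  Returns the
    ``(frame_count, h, w)`` float stack and the ground-truth ellipse.

    Raises
    ------
    ValueError
        If the geometric-mean diameter is under 4 px or the ellipse
        (with a 2-px margin) does not fit inside the frame.
    """
    a, b = float(max(semi_axes)), float(min(semi_axes))
    if b <= 0:
        raise ValueError("semi-axes must be positive")
    if 2.0 * np.sqrt(a * b) < 4.0:
        raise ValueError("pupil diameter must be >= 4 px")
    h, w = frame_shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cr, cc = center
    margin = 2.0
    if cr - a < margin or cr + a > h - 1 - margin or cc - a < margin or cc + a > w - 1 - margin:
        raise ValueError("pupil exceeds the frame bounds (2-px margin required)")

    # area-sampled ellipse interior on a supersampled grid
    s = supersample
    rr = (np.arange(h * s) + 0.5) / s - 0.5
    cc_ax = (np.arange(w * s) + 0.5) / s - 0.5
    r_grid, c_grid = np.meshgrid(rr - cr, cc_ax - cc, indexing="ij")
    phi = np.deg2rad(angle_deg)
    u = r_grid * np.cos(phi) + c_grid * np.sin(phi)
    v = -r_grid * np.sin(phi) + c_grid * np.cos(phi)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    coverage = inside.reshape(h, s, w, s).mean(axis=(1, 3))
    base = iris_value + (pupil_value - iris_value) * coverage

    rng = np.random.default_rng(seed)
    stack = np.repeat(base[None], frame_count, axis=0)
    if noise > 0:
        stack = stack + rng.normal(0.0, noise, size=stack.shape)
    stack = np.clip(stack, 0.0, 255.0)
    truth = PupilEllipse(semi_major=a, semi_minor=b, center_rc=(cr, cc))
    return stack, truth
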