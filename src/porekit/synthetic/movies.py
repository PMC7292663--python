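"""Render a simulated trace cohort into a single-channel movie.

Cells become Gaussian blobs at their static positions whose amplitude
follows the cell's simulated indicator intensity, giving the spot
detector/linker a realistic-but-known input.
"""

from __future__ import annotations

import numpy as np

from ..traces import CellTrack

__all__ = ["render_cohort_movie"]


def render_cohort_movie(
    tracks: list[CellTrack],
    shape: tuple[int, int] = (256, 256),
    channel: str = "gcamp6f",
    blob_sigma: float = 3.0,
    background: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """(frames, h, w) float movie of Gaussian blobs driven by track intensities."""
    if not tracks:
        raise ValueError("no tracks to render")
    n_frames = tracks[0].n_frames
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    movie = np.full((n_frames, h, w), float(background))
    for tr in tracks:
        if tr.position is None:
            raise ValueError(f"track {tr.cell_id} has no position")
        r, c = tr.position
        if not (0 <= r < h and 0 <= c < w):
            continue
        kernel = np.exp(-(((yy - r) ** 2 + (xx - c) ** 2) / (2 * blob_sigma ** 2)))
        vals = tr.channels[channel]
        movie += vals[:, None, None] * kernel[None, :, :] / 100.0 * 20.0
    if noise_sd > 0:
        movie += rng.normal(0.0, noise_sd, size=movie.shape)
    return np.clip(movie, 0.0, None)
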