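"""Simplified spot detection and frame-to-frame linking for cell movies.

A Laplacian-of-Gaussian blob detector per frame plus greedy
mutual-nearest-neighbour linking under a displacement gate.  This is a
deliberately small detector/linker for synthetic movies; it produces
per-cell intensity tracks compatible with the trace-analysis module.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import blob_log

from .traces import CellTrack

__all__ = ["detect_spots", "link_tracks", "tracks_from_movie"]


def detect_spots(
    image: np.ndarray,
    min_sigma: float = 2.0,
    max_sigma: float = 6.0,
    threshold: float = 0.02,
) -> np.ndarray:
    """(n, 2) array of (row, col) blob centers in one frame."""
    img = np.asarray(image, dtype=float)
    rng = np.ptp(img)
    if rng == 0:
        return np.empty((0, 2))
    norm = (img - img.min()) / rng
    blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma,
                     threshold=threshold)
    return blobs[:, :2] if blobs.size else np.empty((0, 2))


def _mutual_nearest(a: np.ndarray, b: np.ndarray, max_disp: float) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbour pairs within ``max_disp``."""
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    pairs = []
    for i in range(len(a)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= max_disp and int(np.argmin(d[:, j])) == i:
            pairs.append((i, j))
    return pairs


def link_tracks(
    spot_lists: list[np.ndarray],
    max_displacement: float = 10.0,
) -> list[list[tuple[int, float, float]]]:
    """Link per-frame spot lists into tracks of (frame, row, col) triples.

    Spots left unlinked at any frame start new tracks; tracks simply end when
    no mutual nearest neighbour lies within ``max_displacement``.
    """
    tracks: list[list[tuple[int, float, float]]] = []
    active: dict[int, int] = {}  # spot index in previous frame -> track index
    prev: np.ndarray | None = None
    for f, spots in enumerate(spot_lists):
        spots = np.asarray(spots, dtype=float).reshape(-1, 2)
        new_active: dict[int, int] = {}
        if prev is not None:
            for i, j in _mutual_nearest(prev, spots, max_displacement):
                if i in active:
                    tracks[active[i]].append((f, spots[j, 0], spots[j, 1]))
                    new_active[j] = active[i]
        for j in range(len(spots)):
            if j not in new_active:
                tracks.append([(f, spots[j, 0], spots[j, 1])])
                new_active[j] = len(tracks) - 1
        active = new_active
        prev = spots
    return tracks


def tracks_from_movie(
    movie: np.ndarray,
    time_min: np.ndarray,
    condition: str = "",
    channel_name: str = "gcamp6f",
    read_radius: int = 3,
    max_displacement: float = 10.0,
    **spot_params,
) -> list[CellTrack]:
    """Detect, link, and read out mean intensity to build CellTracks.

    Only tracks spanning every frame are returned (partial tracks cannot be
    baselined consistently).  Intensity is the mean over a small square
    window around the linked position in each frame.
    """
    movie = np.asarray(movie, dtype=float)
    spot_lists = [detect_spots(frame, **spot_params) for frame in movie]
    raw_tracks = link_tracks(spot_lists, max_displacement=max_displacement)

    out: list[CellTrack] = []
    n_frames, h, w = movie.shape
    for k, tr in enumerate(raw_tracks):
        if len(tr) != n_frames:
            continue
        vals = []
        for f, r, c in tr:
            r0, r1 = max(0, int(r) - read_radius), min(h, int(r) + read_radius + 1)
            c0, c1 = max(0, int(c) - read_radius), min(w, int(c) + read_radius + 1)
            vals.append(float(movie[f, r0:r1, c0:c1].mean()))
        out.append(
            CellTrack(
                cell_id=f"track_{k:04d}",
                field_id="movie0",
                condition=condition,
                time_min=np.asarray(time_min, dtype=float),
                channels={channel_name: np.asarray(vals)},
                position=(tr[0][1], tr[0][2]),
            )
        )
    return out
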