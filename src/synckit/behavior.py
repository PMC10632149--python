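"""Face-video behaviour features.

Motion-energy SVD in temporal segments, the whisking L2 norm, pupil ellipse
area from four tracked keypoints with confidence/blink masking, and
event-locked baseline normalization of behaviour traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PupilTrace", "motion_energy_svd", "segmented_svd", "whisking_trace",
           "pupil_area", "blink_detect", "normalize_to_baseline"]


@dataclass
class PupilTrace:
    """Per-frame pupil ellipse area with an undefined-frame mask."""

    area: np.ndarray            # pixel^2; NaN where undefined
    undefined_mask: np.ndarray  # True where blink / low confidence / degenerate

    def defined(self) -> np.ndarray:
        return self.area[~self.undefined_mask]


def segmented_svd(X: np.ndarray, n_components: int,
                  segment_length: int = 1000) -> np.ndarray:
    """Spatial basis from per-segment SVDs merged by a second SVD.

    ``X`` is pixels x time.  Each temporal segment is decomposed separately;
    the per-segment singular-vector bases (weighted by their singular
    values) are stacked and reduced by one more SVD, giving an orthonormal
    pixels x n_components basis.  This is how face-movie matrices too large
    for a direct decomposition are handled.
    """
    n_pix, T = X.shape
    n_components = min(n_components, n_pix, T)
    bases = []
    for s in range(0, T, segment_length):
        seg = X[:, s:s + segment_length]
        k = min(n_components, *seg.shape)
        U, sv, _ = np.linalg.svd(seg, full_matrices=False)
        bases.append(U[:, :k] * sv[:k])
    stacked = np.concatenate(bases, axis=1)
    U, _, _ = np.linalg.svd(stacked, full_matrices=False)
    return U[:, :n_components]


def motion_energy_svd(movie: np.ndarray, n_components: int = 250,
                      segment_length: int = 1000
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Project a movie and its absolute motion energy onto SVD bases.

    ``movie`` is pixels x time on a fixed pixel grid.  Motion energy at
    frame t is |frame_t - frame_{t-1}| (first frame set to 0).  Returns
    ``(X_movie, X_motion)``, each n_components x time.
    """
    n_pix, T = movie.shape
    if T < 2:
        raise ValueError("need at least two frames")
    if n_components > min(n_pix, T):
        warnings.warn(f"n_components clipped to {min(n_pix, T)}")
        n_components = min(n_pix, T)
    energy = np.zeros_like(movie)
    energy[:, 1:] = np.abs(np.diff(movie, axis=1))
    U_movie = segmented_svd(movie, n_components, segment_length)
    U_motion = segmented_svd(energy, n_components, segment_length)
    return U_movie.T @ movie, U_motion.T @ energy


def whisking_trace(whisker_motion_svd: np.ndarray, n_components: int = 10) -> np.ndarray:
    """Whisking = per-frame L2 norm of the top motion-SVD components."""
    X = np.asarray(whisker_motion_svd, dtype=float)
    if X.shape[0] < n_components:
        warnings.warn(f"only {X.shape[0]} whisker components available; using all")
        n_components = X.shape[0]
    return np.linalg.norm(X[:n_components], axis=0)


def _median_filter_time(x: np.ndarray, window: int) -> np.ndarray:
    """Odd-window median filter along the last axis with edge replication."""
    if window <= 1:
        return x
    if window % 2 == 0:
        window += 1
    size = (1,) * (x.ndim - 1) + (window,)
    return ndimage.median_filter(x, size=size, mode="nearest")


def pupil_area(keypoints: np.ndarray, confidences: np.ndarray,
               blink_mask: np.ndarray | None = None,
               median_window: int = 5, conf_threshold: float = 0.75) -> PupilTrace:
    """Ellipse area from 4 pupil keypoints (top, bottom, left, right).

    Coordinates are median filtered over 5 frames; the vertical axis is
    |top - bottom|, horizontal |left - right|, and area = pi (a/2)(b/2).
    Frames with any keypoint confidence below 0.75, a blink, or a
    degenerate (zero-length) axis are undefined.
    """
    kp = np.asarray(keypoints, dtype=float)
    if kp.shape[0] != 4 or kp.shape[1] != 2:
        raise ValueError("keypoints must be (4 points, 2 coords, T frames)")
    T = kp.shape[2]
    filt = _median_filter_time(kp.reshape(8, T), median_window).reshape(4, 2, T)
    top, bottom, left, right = filt
    a = np.linalg.norm(top - bottom, axis=0)       # vertical axis length
    b = np.linalg.norm(left - right, axis=0)       # horizontal axis length
    area = np.pi * (a / 2) * (b / 2)

    mask = np.any(np.asarray(confidences, dtype=float) < conf_threshold, axis=0)
    if blink_mask is not None:
        mask = mask | np.asarray(blink_mask, dtype=bool)
    degenerate = (a <= 0) | (b <= 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} frames with degenerate pupil axis")
    mask = mask | degenerate
    area = area.copy()
    area[mask] = np.nan
    return PupilTrace(area=area, undefined_mask=mask)


def blink_detect(eye_dark_pixel_count: np.ndarray, area_threshold: float) -> np.ndarray:
    """Blink frames: eye dark-pixel count strictly below the area threshold."""
    return np.asarray(eye_dark_pixel_count, dtype=float) < area_threshold


def normalize_to_baseline(trace: np.ndarray, sample_rate: float,
                          event_onsets: np.ndarray,
                          baseline_window: tuple[float, float] = (-30.0, 0.0),
                          summary_window: tuple[float, float] = (0.0, 5.0),
                          t0: float = 0.0):
    """Divide a trace by its event-specific baseline mean; summarize post-event.

    For each event onset, the baseline is the NaN-aware mean over
    ``baseline_window`` (relative seconds); the whole trace divided by it is
    returned together with the mean over ``summary_window``.  Events with a
    zero or undefined baseline are skipped with a warning.

    Returns a list of ``(normalized_trace, summary_mean)`` per event.
    """
    x = np.asarray(trace, dtype=float)
    out = []
    for onset in np.atleast_1d(event_onsets):
        onset = onset.onset if hasattr(onset, "onset") else float(onset)
        i0 = int(round((onset + baseline_window[0] - t0) * sample_rate))
        i1 = int(round((onset + baseline_window[1] - t0) * sample_rate))
        if i0 < 0 or i1 > x.size or i1 <= i0:
            warnings.warn(f"baseline window outside trace for event at {onset:.2f} s; skipped")
            out.append((None, None))
            continue
        base = np.nanmean(x[i0:i1])
        if not np.isfinite(base) or base == 0:
            warnings.warn(f"zero/undefined baseline for event at {onset:.2f} s; skipped")
            out.append((None, None))
            continue
        norm = x / base
        j0 = int(round((onset + summary_window[0] - t0) * sample_rate))
        j1 = int(round((onset + summary_window[1] - t0) * sample_rate))
        j0, j1 = max(j0, 0), min(j1, x.size)
        summary = float(np.nanmean(norm[j0:j1])) if j1 > j0 else None
        out.append((norm, summary))
    return out
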