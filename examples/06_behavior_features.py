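"""Behaviour features: motion-energy SVD, whisking norm, pupil area.

A tiny moving-blob movie demonstrates the segmented SVD of raw frames and
absolute motion energy; the whisking trace is the L2 norm of the top-10
whisker motion components; pupil area comes from a four-keypoint ellipse
with confidence and blink masking.
"""

import numpy as np

from synckit import behavior
from synckit.synth import GeneratorConfig, generate_session

rng = np.random.default_rng(0)

# 8x8-pixel movie of a blob drifting across the frame
T, side = 300, 8
xs = np.linspace(1, side - 2, T)
frames = np.exp(-0.5 * ((np.arange(side)[:, None, None] - 4) ** 2
                        + (np.arange(side)[None, :, None] - xs[None, None]) ** 2))
movie = frames.reshape(side * side, T) + 0.01 * rng.standard_normal((side * side, T))
x_movie, x_motion = behavior.motion_energy_svd(movie, n_components=5,
                                               segment_length=100)
print(f"movie SVD components: {x_movie.shape[0]} x {x_movie.shape[1]} frames; "
      f"motion energy of the static background ~0, of the moving blob > 0")
print(f"mean |motion component 1| = {np.abs(x_motion[0]).mean():.2f}")

session, truth = generate_session(GeneratorConfig(
    duration=120.0, seed=2, laser_plan=((20, 60.0, 30.0),),
    regions={"SSp": 2}, n_components=6, latent_dim=2))
b = session.behavior

whisk = behavior.whisking_trace(b.whisker_motion_svd)
print(f"whisking norm: baseline {whisk[:1500].mean():.2f}, "
      f"first 5 s after laser {whisk[1800:1950].mean():.2f} (onset burst)")

blinks = behavior.blink_detect(b.eye_dark_pixel_count, area_threshold=50.0)
pupil = behavior.pupil_area(b.keypoints, b.confidence, blink_mask=blinks)
out = behavior.normalize_to_baseline(pupil.area, b.sample_rate,
                                     [session.lasers[0].onset],
                                     summary_window=(5.0, 25.0))
_, summary = out[0]
print(f"{int(blinks.sum())} blink frames masked; "
      f"pupil area during stimulation = {summary:.2f}x baseline "
      f"(programmed dilation {truth.pupil_gain}x radius = "
      f"{truth.pupil_gain**2:.2f}x area)")
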