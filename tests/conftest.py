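"""Shared fixtures.

The rendered-video batch is expensive (rendering plus magnification of 20
desk-scale segments), so it is built once per session and shared by every
test that needs magnified synthetic video.  Only derived artifacts are
retained (patch series means, tensor profile summary, windowed eigenvalue
sample); the frame stacks themselves would not fit in memory twenty times
over.
"""

from __future__ import annotations

import numpy as np
import pytest

from rubeoscan.evm import MagnifierConfig, magnify
from rubeoscan.profiles import extract_patches, tensor_profile
from rubeoscan.spectra import windowed_lambda_max
from rubeoscan.synthgen import SceneLayout, SegmentSchedule, render_video

# Desk-scale video conditions: 2,500-frame (50 s) segments in the compact
# layout; windows of ~2 pulse periods resolve the beat-scale burst
# structure that the control group's heavy tail lives in.
VIDEO_T = 2500
VIDEO_WINDOW = 70
VIDEO_STRIDE = 8
VIDEO_THRESHOLD_Q = 0.5
N_PER_GROUP = 10


@pytest.fixture(scope="session")
def video_batch():
    """20 processed desk-scale segments (10 C, 10 DM).

    Each entry holds: group, seed, manifest, patch roles, per-frame patch
    means of the magnified red channel, mean |raw patch difference|, and
    the windowed largest-eigenvalue sample.
    """
    schedule = SegmentSchedule(segment_lengths=[VIDEO_T])
    batch = []
    for seed in range(N_PER_GROUP):
        for group in ("C", "DM"):
            layout = SceneLayout.compact()
            stacks, manifest = render_video(layout, schedule, group=group, seed=seed)
            magnified = magnify(stacks[0], MagnifierConfig(fps=50), channels=(0,))
            del stacks
            series = extract_patches(magnified, manifest)
            del magnified
            profile = tensor_profile(series)
            eigen = windowed_lambda_max(
                profile, window_length=VIDEO_WINDOW, stride=VIDEO_STRIDE
            )
            batch.append(
                {
                    "group": group,
                    "seed": seed,
                    "manifest": manifest,
                    "roles": series.roles,
                    "patch_means": series.means,
                    "mean_abs_raw": float(np.mean(np.abs(profile.raw))),
                    "eigen": eigen,
                }
            )
    return batch


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
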