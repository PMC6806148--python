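from dataclasses import replace

import numpy as np
import pytest

from adlfusion.evaluation import deoverlap_subsample
from adlfusion.pipeline import SessionData, extract_session_instances
from adlfusion.synthetic import (
    default_config,
    generate_session,
    make_confusable_design,
)


def noise_free(config):
    return replace(config, accel_noise_sd=0.0, miss_prob=0.0, fp_rate=0.0,
                   box_jitter_px=0.0)


def confusable_config(seed, **overrides):
    cfg = make_confusable_design(default_config(seed))
    return replace(cfg, **overrides) if overrides else cfg


def cohort_sessions(cfg):
    return [
        SessionData(*generate_session(cfg, si, se))
        for si in range(cfg.subjects)
        for se in range(cfg.sessions_per_subject)
    ]


def fused_deoverlapped(cfg):
    instances = []
    for s in cohort_sessions(cfg):
        inst = extract_session_instances(s, cfg.catalog)
        instances.extend(deoverlap_subsample(inst, "vision_or_fused"))
    return instances


@pytest.fixture(scope="session")
def noise_free_confusable_instances():
    """Noise-free 4-class confusable cohort (2 subjects x 6 sessions),
    fused + de-overlapped — the separable end-to-end reference dataset."""
    cfg = noise_free(confusable_config(11))
    return fused_deoverlapped(cfg), cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251002)
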