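"""Shared fixtures: phantoms and precomputed pipeline runs.

The heavyweight 20-phantom suite (enhancement -> localization -> all
segmentation backends, enhanced and raw input) is computed once per session
and shared between the property tests and the acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from kneeus.enhancement import enhance_cartilage
from kneeus.bonefeatures import compute_phase_features
from kneeus.phantom import PhantomSpec, generate_phantom, phantom_suite
from kneeus.pipeline import PipelineConfig, run_pipeline
from kneeus.shadow import compute_shadow_set
from kneeus.thickness import overlap_metrics

SUITE_SEED = 1
SUITE_N = 20


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom with the default (artifact-bearing) appearance."""
    return generate_phantom(PhantomSpec(rng_seed=3))


@pytest.fixture(scope="session")
def clean_phantom():
    """Speckled phantom without interface echo, layers or misalignment."""
    spec = PhantomSpec(
        rng_seed=3, interface_brightness=0.0, n_tissue_layers=0, align_min=1.0
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Deterministic piecewise-constant phantom (no speckle, no PSF, no artifacts)."""
    spec = PhantomSpec(
        rng_seed=3,
        speckle_scale=0.0,
        psf_sigma_px=0.0,
        interface_brightness=0.0,
        n_tissue_layers=0,
        align_min=1.0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_features(default_phantom):
    """Enhancement + phase features + shadow set for the default phantom."""
    img, truth = default_phantom
    enhanced = enhance_cartilage(img)
    features = compute_phase_features(enhanced)
    shadow = compute_shadow_set(features.lp)
    return {
        "image": img,
        "truth": truth,
        "enhanced": enhanced,
        "features": features,
        "shadow": shadow,
    }


@pytest.fixture(scope="session")
def suite_results():
    """Per-phantom pipeline outputs for the 20-phantom suite.

    For each phantom: results for the three backends on the enhanced input
    plus the random-walker run on the raw B-mode input, with DSC against
    the ground-truth cartilage mask.
    """
    out = []
    for img, truth in phantom_suite(SUITE_N, rng_seed=SUITE_SEED):
        entry = {"image": img, "truth": truth}
        for backend in ("rw", "watershed", "graphcut"):
            res = run_pipeline(img, PipelineConfig(backend=backend))
            entry[backend] = res
            entry[f"dsc_{backend}"] = overlap_metrics(
                res.segmentation.mask, truth.cartilage_mask
            ).dsc
        raw = run_pipeline(img, PipelineConfig(), use_enhanced_input=False)
        entry["rw_raw"] = raw
        entry["dsc_rw_raw"] = overlap_metrics(
            raw.segmentation.mask, truth.cartilage_mask
        ).dsc
        out.append(entry)
    return out
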