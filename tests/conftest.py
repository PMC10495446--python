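"""Shared fixtures: small synthetic recordings with ground-truth manifests.

Everything is generated at test time; session scope keeps the expensive
simulations and the preprocessing chain to one run each.
"""

import numpy as np
import pytest

from resteeg import preprocess as pp
from resteeg import simulate as sim
from resteeg.model_io import ParamSet


@pytest.fixture(scope="session")
def clean_sim():
    """60 s clean recording: occipital alpha + frontal theta, no artifacts."""
    cfg = sim.SimulationConfig(duration_s=60.0, seed=7)
    rec, manifest = sim.simulate_recording(cfg)
    return rec, manifest, cfg


@pytest.fixture(scope="session")
def artifact_sim():
    """120 s recording with one flat channel, one noisy channel, blinks,
    line noise and a 1 s high-amplitude burst."""
    cfg = sim.SimulationConfig(
        duration_s=120.0, seed=2,
        artifacts=sim.ArtifactSpec(
            flat_spans=[(3, 10.0, 16.5)],
            noisy_channels=[7],
            blink_times_s=[5.0, 20.0, 35.0, 50.0],
            line_amp_uv=5.0,
            burst_spans_s=[(40.0, 41.0)]))
    rec, manifest = sim.simulate_recording(cfg)
    rec, manifest = sim.inject_artifacts(rec, cfg, manifest)
    return rec, manifest, cfg


@pytest.fixture(scope="session")
def artifact_chain(artifact_sim):
    """Stages 1-6 run once on the artifact fixture (2 ICA repetitions)."""
    rec, manifest, cfg = artifact_sim
    params = ParamSet(n_ica_repetitions=2, seed=3)
    raw = rec
    r = pp.highpass(pp.remove_line_noise(rec), params)
    report = pp.detect_bad_channels(r, params, raw=raw)
    r = pp.rereference_average(pp.drop_bad_channels(r, report))
    cleaned, mask, diag = pp.stabilize_and_clean(r, params, report)
    return {"raw": rec, "manifest": manifest, "cfg": cfg, "params": params,
            "report": report, "cleaned": cleaned, "mask": mask, "diag": diag}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
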