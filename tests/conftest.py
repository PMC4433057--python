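import numpy as np
import pytest

from romexam import load_catalog
from romexam.anatomy import process_recording
from romexam.kinesim import (
    MotionScript,
    NoiseModel,
    Recording,
    apply_mounting,
    simulate_segment_kinematics,
    synthesize_imu,
)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def run_examination(catalog):
    """Simulate one repetition of one examination and push it through the
    full measurement chain; returns the reported RoM (degrees)."""

    def _run(angle_id, peak, noise=None, start_offset=0.0, mounts=None, script_kwargs=None):
        exam = catalog.lookup(angle_id)
        noise = NoiseModel.zero() if noise is None else noise
        script = MotionScript(
            angle_id=angle_id,
            rep_peaks=[peak],
            n_repetitions=1,
            start_offset_deg=start_offset,
            **(script_kwargs or {}),
        )
        kin = simulate_segment_kinematics(script, exam, catalog)
        rng = np.random.default_rng(noise.seed)
        streams = {}
        for site, trace in kin.repetitions[0].items():
            if mounts and site in mounts:
                trace = apply_mounting(trace, mounts[site])
            streams[site] = synthesize_imu(trace, noise, site_id=site, rng=rng)
        rec = Recording(
            subject=0, rater=0, angle_id=angle_id, rep=0,
            streams=streams, executed_rom_deg=peak, mounts=mounts,
        )
        return process_recording(rec, catalog)

    return _run
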