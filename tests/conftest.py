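import pytest

import wellflux as wf
from wellflux import analysis


@pytest.fixture(scope="session")
def tube():
    return wf.TubeSpec()


@pytest.fixture(scope="session")
def flow():
    return wf.FlowSpec()


@pytest.fixture(scope="session")
def staining_timeline():
    pm = wf.staining_plate_map()
    return wf.compile_protocol(pm, wf.staining_steps(), wf.FlowSpec())


@pytest.fixture(scope="session")
def carryover_scan():
    """Default 96-well alternating scan, seed 0."""
    pm, order = wf.carryover_scenario()
    return wf.gen_carryover_scan(pm, order, wf.CarryoverPreset(), seed=0)


@pytest.fixture(scope="session")
def dose_response_peaks():
    """Full-size dose-response experiment (18 animals, 4 pulses, seed 0),
    reduced to per-trace peaks."""
    traces = wf.gen_dose_response(seed=0)
    return analysis.extract_peaks(traces)


@pytest.fixture(scope="session")
def screen_experiment():
    """Full-size solvent screen (20 animals, 57 wells, seed 0)."""
    preset = wf.ScreenPreset()
    pm, seq = wf.screen_scenario(preset)
    traces = wf.gen_screen(preset, n_animals=20, plate_map=pm, sequence=seq, seed=0)
    peaks = analysis.extract_peaks(traces)
    return preset, pm, seq, peaks
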