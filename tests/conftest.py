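import numpy as np
import pytest

import wingbeam as wb

FS = 30_517.0
V0 = 3.0


@pytest.fixture(scope="session")
def geometry():
    return wb.BeamGeometry()


def make_transit(fw=500.0, duration=0.1, body=0.3, ratio=None, wing=None,
                 n_harmonics=4):
    """TransitParams with wing depth set either directly or via a target
    true wing-to-body ratio."""
    if wing is None:
        wing = (wb.wing_depth_for_ratio(ratio, body, duration, fw,
                                        n_harmonics=n_harmonics)
                if ratio is not None else 0.0)
    return wb.TransitParams(0.0, duration, fw if wing > 0 else fw, body, wing,
                            n_harmonics=n_harmonics)


def single_event_stream(params, stream_duration=0.5, noise_sd=0.005, seed=0,
                        start=0.2):
    from dataclasses import replace

    ev = replace(params, start_time=start)
    scenario = wb.StreamScenario(
        duration=stream_duration, noise_sd=noise_sd, events=(ev,),
        overlap_probability=0.0, seed=seed,
    )
    return wb.simulate_stream(scenario)
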