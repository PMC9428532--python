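"""Shared fixtures.

The five reference-room impulse responses are expensive enough to be
worth computing once per session; several modules' tests and the
acceptance suite all consume them.
"""

import pytest

from revspeech import room as rm

#: Simulation length per room: long enough for the -35 dB Schroeder point.
RIR_DURATIONS = {0.15: 0.35, 0.5: 0.7, 0.8: 0.95, 1.1: 1.2, 1.5: 1.5}


@pytest.fixture(scope="session")
def reference_rirs():
    """Unnormalized RIRs for the five tabulated rooms, keyed by RT label."""
    return {
        rt: rm.simulate_rir(rm.reference_room(rt), duration=dur, rng_seed=0)
        for rt, dur in RIR_DURATIONS.items()
    }
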