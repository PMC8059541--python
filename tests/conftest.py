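import warnings

import pandas as pd
import pytest

from icepulse import dive_processing as dp
from icepulse.synthetic import SeasonScenario, generate_tdr


@pytest.fixture(scope="session")
def small_waveforms():
    """Three seals, ten days of full 6-s waveforms with per-dive truth."""
    scn = SeasonScenario(n_seals=3, days=10, seed=2)
    records, truth = generate_tdr(scn)
    truth = truth.sort_values(["seal_id", "start_time"]).reset_index(drop=True)
    return scn, records, truth


@pytest.fixture(scope="session")
def processed_dives(small_waveforms):
    """The waveform fixture pushed through the full dive-processing chain."""
    _, records, truth = small_waveforms
    frames = [dp.process_record(dp.zero_offset_correct(rec), seal)
              for seal, rec in sorted(records.items())]
    dives = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dives = dp.classify_dives(dives)
    dives = dives.sort_values(["seal_id", "start_time"]).reset_index(drop=True)
    return dives, truth
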