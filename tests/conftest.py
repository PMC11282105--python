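import numpy as np
import pandas as pd
import pytest


def build_session(n_hit=0, n_miss=0, n_fa=0, n_cr=0, go_level="G5",
                  nogo_level="G0", laser="none", extra_rows=None):
    """Construct a trial table with given outcome counts on the trained pair."""
    rows = []
    for outcome, n in (("hit", n_hit), ("miss", n_miss), ("FA", n_fa), ("CR", n_cr)):
        level = go_level if outcome in ("hit", "miss") else nogo_level
        licked = outcome in ("hit", "FA")
        for _ in range(n):
            rows.append({"stimulus_level": level, "is_go": outcome in ("hit", "miss"),
                         "laser": laser, "licked": licked, "outcome": outcome,
                         "bias_correction": False, "aborted": False})
    rows.extend(extra_rows or [])
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
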