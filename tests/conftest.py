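import numpy as np
import pandas as pd
import pytest

from itasense.observer import TrialTable


def make_search_table(rows):
    return TrialTable(pd.DataFrame(rows), task="search")


@pytest.fixture
def separated_table():
    """One participant whose repeated RTs all lie below the new RTs."""
    rows = []
    for rt in (300, 310, 320, 330):
        rows.append({"participant": "p1", "epoch": 1, "block": 1, "condition": "repeated", "rt_ms": rt})
    for rt in (400, 410, 420, 430):
        rows.append({"participant": "p1", "epoch": 1, "block": 1, "condition": "new", "rt_ms": rt})
    return make_search_table(rows)


@pytest.fixture
def six_epoch_table():
    """2 participants x 6 epochs x 2 conditions x 4 trials, with errors."""
    rng = np.random.default_rng(42)
    rows = []
    for pid in ("p1", "p2"):
        for epoch in range(1, 7):
            for cond in ("repeated", "new"):
                for _ in range(4):
                    rows.append(
                        {
                            "participant": pid,
                            "epoch": epoch,
                            "block": epoch,
                            "condition": cond,
                            "rt_ms": float(rng.uniform(400, 1200)),
                            "correct": int(rng.random() > 0.05),
                        }
                    )
    return make_search_table(rows)


@pytest.fixture
def recognition_table():
    """2 participants with 12+12 recognition trials each; p1 all correct,
    p2 responses independent of condition."""
    rows = []
    for i in range(12):
        rows.append({"participant": "p1", "condition": "repeated", "response": "old"})
        rows.append({"participant": "p1", "condition": "new", "response": "new"})
        rows.append({"participant": "p2", "condition": "repeated", "response": "old" if i % 2 else "new"})
        rows.append({"participant": "p2", "condition": "new", "response": "old" if i % 2 else "new"})
    return TrialTable(pd.DataFrame(rows), task="recognition")
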