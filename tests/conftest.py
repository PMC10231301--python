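import numpy as np
import pandas as pd
import pytest

from maskddm import task_design


@pytest.fixture(scope="session")
def demo_design():
    return task_design.generate_blocks(6, seed=11)


@pytest.fixture(scope="session")
def demo_schedule():
    return task_design.schedule_rounds([f"p{i}" for i in range(4)], seed=7)


@pytest.fixture(scope="session")
def clustered_binary():
    """Deterministic clustered yes/no data with a known mask effect."""
    rng = np.random.default_rng(42)
    rows = []
    u = rng.normal(0, 0.6, 15)
    for j in range(15):
        for mask, b in (("none", 1.0), ("lower", 0.3), ("upper", 0.6)):
            ys = rng.random(20) < 1 / (1 + np.exp(-(b + u[j])))
            for yy in ys:
                rows.append({"participant_id": j, "mask": mask, "y": int(yy)})
    return pd.DataFrame(rows)
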