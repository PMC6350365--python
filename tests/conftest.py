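import numpy as np
import pandas as pd
import pytest

from pdxtrial import TrialDataset, SimConfig, simulate_trial


def make_trial(arm_curves: dict[str, list[list[float]]], days: list[float],
               tumor: str = "T1", control: str | None = "Vehicle") -> TrialDataset:
    """Build a trial from explicit per-animal volume curves.

    ``arm_curves`` maps arm name -> list of animals, each a volume list
    aligned with ``days``.
    """
    rows = []
    for arm, animals in arm_curves.items():
        for i, vols in enumerate(animals):
            for d, v in zip(days, vols):
                rows.append((tumor, arm, f"{arm}-m{i + 1}", float(d), float(v)))
    df = pd.DataFrame(rows, columns=["tumor_id", "arm", "animal_id", "day", "volume"])
    ctrl = control if control in arm_curves else None
    return TrialDataset(df, control_arm=ctrl)


@pytest.fixture
def worked_trajectory_curves():
    """The hand-computed reference animal: V=[100,120,80,60] at days 0,7,14,21."""
    return [100.0, 120.0, 80.0, 60.0], [0.0, 7.0, 14.0, 21.0]


@pytest.fixture
def separated_3v3():
    """3 vs 3 animals with the treatment strictly below control every day."""
    days = [0, 3, 6, 9]
    control = [[100 * np.exp(0.10 * d) * (1 + 0.02 * i) for d in days] for i in range(3)]
    treated = [[90 * np.exp(0.01 * d) * (1 + 0.02 * i) for d in days] for i in range(3)]
    return make_trial({"Vehicle": control, "Drug": treated}, days)


@pytest.fixture
def sim_1an():
    """Default single-tumor six-arm simulated trial (seeded)."""
    return simulate_trial(SimConfig(seed=11))
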