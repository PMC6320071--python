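import numpy as np
import pytest

from tweezefold.dumbbell import separation_for_force
from tweezefold.hmm import dwell_statistics, idealize_two_state
from tweezefold.simulate import simulate_constant_separation, wt_template_scenario

#: folded-state forces of the standard scan through the WT transition (pN)
SCAN_FORCES = np.linspace(4.0, 6.5, 8)


@pytest.fixture(scope="session")
def wt_scenario():
    """Calibrated wild-type template-complex scenario (session-cached)."""
    return wt_template_scenario()


@pytest.fixture(scope="session")
def wt_separations(wt_scenario):
    return [
        separation_for_force(
            wt_scenario.traps, wt_scenario.folded, wt_scenario.handle, f
        )
        for f in SCAN_FORCES
    ]


def run_force_scan(scenario, separations, duration_s, seed0):
    """Simulate + idealize one record per separation; returns (stats, trajs)."""
    stats, trajs = [], []
    for i, d in enumerate(separations):
        traj = simulate_constant_separation(scenario, d, duration_s, seed0 + i)
        ideal = idealize_two_state(traj)
        stats.append(dwell_statistics(ideal, traj))
        trajs.append(traj)
    return stats, trajs


@pytest.fixture(scope="session")
def wt_scan(wt_scenario, wt_separations):
    """One 100 s-per-force scan of the WT transition (seed 11)."""
    return run_force_scan(wt_scenario, wt_separations, 100.0, seed0=1100)
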