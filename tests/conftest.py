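import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the atrial thin-wall warning fires legitimately late in remodeling runs
warnings.filterwarnings("ignore", message=".*thin-wall Laplace formula.*")


@pytest.fixture(scope="session")
def baseline():
    """Calibrated non-pregnant baseline (shared across the whole run)."""
    from gravicor import study

    return study.calibrate_baseline()


@pytest.fixture(scope="session")
def term_cra(baseline):
    """Controlled remodeling at the end of pregnancy."""
    from gravicor import study

    return study.run_stage("Term", "CRA", baseline)


@pytest.fixture(scope="session")
def term_ncra(baseline):
    """Uncontrolled (blood-volume-only) run at the end of pregnancy."""
    from gravicor import study

    return study.run_stage("Term", "NCRA", baseline)


@pytest.fixture(scope="session")
def t1_cra(baseline):
    """Controlled remodeling at the first trimester (cheaper stage used by
    the factor-independence suite)."""
    from gravicor import study

    return study.run_stage("T1", "CRA", baseline)


@pytest.fixture(scope="session")
def t1_cra_halved_factors(baseline):
    """T1 controlled run with all rate factors halved (same fixed point)."""
    from gravicor import parameterize, remodeling

    stage = baseline.stages["T1"]
    net = parameterize.build_stage_network(stage, baseline.net)
    targets = baseline.targets_for("T1")
    return remodeling.run_remodeling(
        net, baseline.state, targets, mode="CRA", max_iter=4000,
        fact_co=0.005, fact_sigma_f=0.0025, fact_sigma_wss=500.0,
    )


@pytest.fixture(scope="session")
def term_target_scan(baseline):
    """Stress-target scan (0.8x / 1.2x) at Term.

    Term is the right stage for the scan: the pregnant heart must grow in
    both directions of the scan, so the dilation rule never needs to drive
    an unstressed volume below zero.
    """
    from gravicor import parameterize, remodeling

    stage = baseline.stages["Term"]
    net = parameterize.build_stage_network(stage, baseline.net)
    targets = baseline.targets_for("Term")
    # the wall-growth factor is accelerated 4x: the fixed point is
    # independent of the rate factors (tested), and the 0.8x leg otherwise
    # needs many thousands of beats of slow wall growth
    return remodeling.stress_target_scan(
        net, baseline.state, targets, scales=(0.8, 1.2), max_iter=4000,
        fact_sigma_f=0.02,
    )
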