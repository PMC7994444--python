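import numpy as np
import pytest

import beetox as bt
from beetox.io import aggregate_mortality


def make_record(
    bee_id="b0",
    species="osmia",
    arm="SUL",
    sul_dose=11.0,
    flu_dose=0.0,
    last_time=24.0,
    event=1,
):
    return bt.BeeRecord(
        bee_id=bee_id,
        species=species,
        arm=arm,
        sul_dose=sul_dose,
        flu_dose=flu_dose,
        last_time=last_time,
        event=event,
    )


def make_group(times_events, arm="SUL", sul_dose=11.0, flu_dose=0.0, species="osmia"):
    """Build a record group from a list of (last_time, event) pairs."""
    return [
        make_record(
            bee_id=f"{arm}_{i}",
            species=species,
            arm=arm,
            sul_dose=sul_dose,
            flu_dose=flu_dose,
            last_time=t,
            event=e,
        )
        for i, (t, e) in enumerate(times_events)
    ]


def fit_sul_arm(records, design, time):
    """Probit fit of the SUL arm at one assessment time, solvent control."""
    agg = aggregate_mortality(records, time, design)
    rows = agg[agg["arm"] == "SUL"]
    table = list(
        rows[["sul_dose_ng", "n_exposed", "n_dead"]].itertuples(
            index=False, name=None
        )
    )
    ctl = agg[agg["arm"] == "SOLVENT"]
    control = None
    if len(ctl):
        control = (int(ctl["n_exposed"].sum()), int(ctl["n_dead"].sum()))
    return bt.fit_probit(table, control=control)


def arm_records(records, arm, sul_dose=None):
    out = [r for r in records if r.arm == arm]
    if sul_dose is not None:
        out = [r for r in out if r.sul_dose == sul_dose]
    return out


@pytest.fixture(scope="session")
def osmia_dataset():
    """One simulated osmia-like bioassay (fixed seed), full design."""
    scenario = bt.reference_scenario("osmia", seed=2024)
    return scenario, bt.simulate_bioassay(scenario)
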