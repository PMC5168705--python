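import numpy as np
import pytest

from cfmethyl import ddmsp, features, synthetic
from cfmethyl.panel import DEFAULT_PANEL


@pytest.fixture(scope="session")
def planted_array():
    """β matrix with 20+20+50+50 disjoint planted probes and its manifest."""
    return synthetic.gen_array_dataset(synthetic.ArraySimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (30 HV / 30 BC, 2000 droplets/well) with droplet data."""
    cfg = synthetic.small_cohort_config(seed=5)
    roster = synthetic.gen_roster(cfg)
    wells, truth = synthetic.gen_droplet_dataset(roster, DEFAULT_PANEL, cfg)
    labels = {s: int(c == "BC") for s, c in zip(roster["sample_id"], roster["class"])}
    return {"cfg": cfg, "roster": roster, "wells": wells, "truth": truth, "labels": labels}


@pytest.fixture(scope="session")
def quantified_cohort(small_cohort):
    """Fitted thresholds/cutoffs, quantification table and 15-variable features."""
    state = ddmsp.fit_quantification(small_cohort["wells"], small_cohort["labels"])
    quants = ddmsp.quantify_cohort(small_cohort["wells"], state)
    table = features.build_feature_table(quants)
    y = np.array([small_cohort["labels"][s] for s in table.index])
    return {"state": state, "quants": quants, "features": table, "y": y, **small_cohort}
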