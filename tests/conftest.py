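import numpy as np
import pandas as pd
import pytest

from metaevol.containers import PeakTable


def make_meta(rows):
    """Build a sample-metadata frame from (sample_id, species, tissue, ...)
    dicts, filling covariate defaults."""
    defaults = dict(sex="F", age=10.0, rin=8.0, condition="standard",
                    postmortem_delay=0.25, is_pooled=False, individual_id=None)
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        if d["individual_id"] is None and not d["is_pooled"]:
            d["individual_id"] = "i_" + d["sample_id"]
        out.append(d)
    return pd.DataFrame(out).set_index("sample_id")


def make_table(values, sample_ids, peak_ids=None, meta_cols=None, log_scale=False):
    values = np.asarray(values, dtype=float)
    if peak_ids is None:
        peak_ids = [f"p{i:03d}" for i in range(values.shape[0])]
    intens = pd.DataFrame(values, index=peak_ids, columns=sample_ids)
    pm = pd.DataFrame(index=intens.index)
    pm["mz"] = np.nan
    pm["mass"] = np.nan
    pm["rt"] = 1.0
    pm["dataset"] = "posLC"
    if meta_cols:
        for k, v in meta_cols.items():
            pm[k] = v
    return PeakTable(intens, pm, log_scale=log_scale)


@pytest.fixture(scope="session")
def small_sim():
    """A small but full-design synthetic dataset shared across tests."""
    from metaevol.synthio import SimConfig, simulate_metabolome

    cfg = SimConfig(n_peaks=300, seed=42, detection_limit=1000.0)
    table, meta, truth = simulate_metabolome(cfg)
    return cfg, table, meta, truth
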