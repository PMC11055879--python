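import numpy as np
import pandas as pd
import pytest


def make_fc_table(rows):
    """Build a fold-change table from (construct_id, targets, cls, replicate LFCs)."""
    ids, targets, classes, reps = [], [], [], []
    n_reps = max(len(r[3]) for r in rows)
    data = {f"lfc_T18_{i+1}": [] for i in range(n_reps)}
    for cid, tgt, cls, lfcs in rows:
        ids.append(cid)
        targets.append(tgt)
        classes.append(cls)
        for i in range(n_reps):
            data[f"lfc_T18_{i+1}"].append(lfcs[i] if i < len(lfcs) else np.nan)
    df = pd.DataFrame({"targets": targets, "class": classes, **data}, index=pd.Index(ids, name="construct_id"))
    df["mean_lfc"] = df[[c for c in df.columns if c.startswith("lfc_")]].mean(axis=1)
    return df


@pytest.fixture(scope="session")
def simulated_screen():
    """One default-condition screen with 12 planted synthetic lethals."""
    from crisparray.synthetic_data import ScreenSimConfig, simulate_screen

    planted = tuple(((f"G{i:03d}", f"G{i + 50:03d}"), -2.0) for i in range(50, 62))
    cfg = ScreenSimConfig(sl_pairs=planted, seed=11)
    counts, truth = simulate_screen(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def scored_screen(simulated_screen):
    from crisparray.gi_scoring import score_screen
    from crisparray.normalization import NormalizationConfig, counts_to_fold_changes

    cfg, counts, truth = simulated_screen
    fc, offsets = counts_to_fold_changes(counts, NormalizationConfig())
    records, unassayed = score_screen(fc, control_labels={"CTRL"})
    return truth, fc, records, unassayed
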