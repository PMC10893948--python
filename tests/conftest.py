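import numpy as np
import pandas as pd
import pytest

from radpanel import cnvcall, dosage
from radpanel import simpanel as sp


def gene_lengths(pair_map: pd.DataFrame) -> pd.Series:
    return pd.concat([
        pd.Series(pair_map.len_A_bp.values, index=pair_map.gene_A),
        pd.Series(pair_map.len_C_bp.values, index=pair_map.gene_C),
    ])


def dosage_pipeline(pair_map, events, samples, noise, config):
    """counts -> RPKM -> control baseline -> copy estimates -> pair profile."""
    counts = sp.simulate_counts(pair_map, events, samples, noise, config)
    rpkm = dosage.rpkm_normalize(counts, gene_lengths(pair_map))
    controls = list(samples.sample_id[samples.role == "control"])
    baseline = dosage.control_baseline(rpkm, controls)
    k = dosage.estimate_copies(rpkm, baseline)
    return k, dosage.pair_profile(k, pair_map)


def interval_jaccard(a0, a1, b0, b1):
    inter = max(0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union if union else 0.0


def truth_recovered(truth_ev, calls, min_jaccard=0.5):
    """True when some same-direction call overlaps the truth interval."""
    direction = {"segmental_deletion": -1, "chromosome_loss": -1,
                 "segmental_duplication": 1, "chromosome_gain": 1}
    want = direction[truth_ev.event_class]
    sel = calls[(calls.sample_id == truth_ev.sample_id)
                & (calls.subgenome == truth_ev.subgenome)
                & (calls.chrom == truth_ev.chrom)]
    return any(
        direction.get(c.event_class) == want
        and interval_jaccard(truth_ev.start_idx, truth_ev.end_idx,
                             c.start_idx, c.end_idx) >= min_jaccard
        for c in sel.itertuples())


@pytest.fixture(scope="session")
def small_config():
    """8 gamma-2000 M1 families x 2 sibs + 16 controls, 120 pairs/chromosome."""
    return sp.PanelConfig(
        n_pairs_per_chrom=120, seed=101,
        doses=(sp.DoseGroup("gamma", 2000, 8, 2),),
        n_controls=16, recip_prob=0.3, he_prob_control=0.0)


@pytest.fixture(scope="session")
def small_panel(small_config):
    pm = sp.make_pair_map(small_config)
    samples = sp.build_sample_sheet(small_config)
    events = sp.simulate_lesions(small_config, pm, samples)
    k, profile = dosage_pipeline(pm, events, samples, sp.NoiseModel(), small_config)
    return {"config": small_config, "pair_map": pm, "samples": samples,
            "events": events, "k": k, "profile": profile}


@pytest.fixture(scope="session")
def small_calls(small_panel):
    return cnvcall.call_panel(small_panel["profile"], small_panel["pair_map"])
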