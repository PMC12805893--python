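"""PSI, group tests, FDR, event filtering, gel/qPCR/DE quantification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asoscan.quant import (
    EventFilterThresholds,
    SpliceEvent,
    analyze_event_table,
    bh_adjust,
    ddct_relative_expression,
    delta_psi_test,
    filter_events,
    gel_percent_inclusion,
    psi_from_junctions,
    summarize_de_table,
)
from asoscan.simulate import simulate_qpcr_table


# ---------------------------------------------------------------- PSI


@pytest.mark.parametrize(
    "ijc,sjc,li,ls,expected",
    [
        (50, 50, 3, 3, 0.5),
        (0, 30, 2, 2, 0.0),
        (30, 0, 2, 2, 1.0),
        (30, 10, 2, 1, 0.6),  # (30/2) / (30/2 + 10/1)
    ],
)
def test_psi_from_junctions(ijc, sjc, li, ls, expected):
    assert psi_from_junctions(ijc, sjc, li, ls) == pytest.approx(expected)


def test_psi_edge_cases():
    assert math.isnan(psi_from_junctions(0, 0))
    with pytest.raises(ValueError, match="non-negative"):
        psi_from_junctions(-1, 5)
    with pytest.raises(ValueError, match="positive"):
        psi_from_junctions(1, 5, 0, 1)


# ---------------------------------------------------------------- BH


def test_bh_adjust_step_up():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
@settings(max_examples=60, derandomize=True)
def test_bh_adjust_permutation_invariant(ps):
    perm = list(reversed(ps))
    direct = sorted(bh_adjust(ps))
    permuted = sorted(bh_adjust(perm))
    assert np.allclose(direct, permuted)
    assert np.all(bh_adjust(ps) >= np.asarray(ps) - 1e-12)


# ---------------------------------------------------------------- LR test


def _event(groups, ijc, sjc, **kw):
    return SpliceEvent(
        "e", "g", tuple(groups), tuple(f"s{i}" for i in range(len(groups))),
        np.array(ijc), np.array(sjc), **kw
    )


def test_identical_groups_give_p_one():
    ev = _event(["c", "c", "t", "t"], [30, 30, 30, 30], [70, 70, 70, 70])
    assert delta_psi_test(ev) == pytest.approx(1.0)


def test_total_separation_gives_tiny_p():
    ev = _event(["c", "c", "t", "t"], [100, 100, 0, 0], [0, 0, 100, 100])
    assert delta_psi_test(ev) < 1e-6


def test_group_without_reads_gives_missing_p():
    ev = _event(["c", "c", "t", "t"], [0, 0, 10, 10], [0, 0, 10, 10])
    assert math.isnan(delta_psi_test(ev))


def test_type_one_error_near_nominal_on_null_simulations():
    """Empirical size of the pooled-binomial LR test at alpha = 0.05 lies
    within 3-sigma binomial error of nominal on 2000 null data sets."""
    rng = np.random.default_rng(11)
    n = 2000
    rej = 0
    for k in range(n):
        p0 = rng.uniform(0.15, 0.85)
        ijc = rng.binomial(100, p0, size=6)
        ev = _event(["c"] * 3 + ["t"] * 3, ijc, 100 - ijc)
        if delta_psi_test(ev) < 0.05:
            rej += 1
    band = 3 * math.sqrt(0.05 * 0.95 / n)
    assert abs(rej / n - 0.05) <= band


# ---------------------------------------------------------------- filter


def _table(rows):
    return pd.DataFrame(rows, columns=["event_id", "gene", "group", "sample", "ijc", "sjc", "len_inc", "len_skip"])


def _toy_table():
    rows = []
    # ev_big: clear skipping shift, deep counts -> survives
    # ev_small: tiny shift -> fails the delta-PSI rule
    # ev_shallow: clear shift but only ~6 reads/sample -> fails support
    spec = {
        "ev_big": (0.8, 0.3, 100),
        "ev_small": (0.52, 0.50, 100),
        "ev_shallow": (0.8, 0.2, 8),
    }
    for eid, (pc, pt, depth) in spec.items():
        for g, p in (("control", pc), ("treated", pt)):
            for r in range(3):
                i = round(depth * p)
                rows.append([eid, eid.upper(), g, f"{g}{r}", i, depth - i, 1, 1])
    return _table(rows)


def test_filter_applies_all_three_rules():
    events = analyze_event_table(_toy_table(), control_group="control")
    survivors = filter_events(events)
    assert [e.event_id for e in survivors] == ["ev_big"]
    assert survivors[0].direction == "skipping"
    assert survivors[0].delta_psi == pytest.approx(-0.5)


def test_filter_rejects_good_effect_with_bad_fdr():
    events = analyze_event_table(_toy_table(), control_group="control")
    for ev in events:
        ev.fdr = 0.2  # override: significance rule alone must reject
    assert filter_events(events) == []


def test_event_with_zero_reads_dropped_with_reason():
    rows = []
    for g in ("control", "treated"):
        for r in range(2):
            rows.append(["ev0", "G", g, f"{g}{r}", 0, 0, 1, 1])
    events = analyze_event_table(_table(rows), control_group="control")
    log = []
    assert filter_events(events, log=log) == []
    assert log and "dropped" in log[0]


# ---------------------------------------------------------------- gel, ddct, DE


def test_gel_percent_inclusion():
    out = gel_percent_inclusion({"FL": 75.0, "dE7": 25.0})
    assert out == {"FL": 75.0, "dE7": 25.0}
    assert gel_percent_inclusion({"only": 12.0}) == {"only": 100.0}
    three = gel_percent_inclusion({"a": 10, "b": 30, "c": 60})
    assert (three["a"], three["b"], three["c"]) == (10.0, 30.0, 60.0)
    with pytest.raises(ValueError, match="zero total"):
        gel_percent_inclusion({"a": 0.0})


def test_ddct_cycle_arithmetic():
    df = pd.DataFrame(
        {
            "sample": ["c1", "c2", "t1", "t2", "u1", "u2"],
            "condition": ["ctl", "ctl", "up1", "up1", "dn2", "dn2"],
            "target_ct": [24.0, 24.0, 25.0, 25.0, 22.0, 22.0],
            "normalizer_ct": [18.0, 18.0, 18.0, 18.0, 18.0, 18.0],
        }
    )
    out = ddct_relative_expression(df, "ctl").set_index("condition")["rq"]
    assert out["ctl"] == pytest.approx(1.0)  # control vs itself is exactly 1
    assert out["up1"] == pytest.approx(0.5)  # one cycle higher -> halved
    assert out["dn2"] == pytest.approx(4.0)  # two cycles lower -> 4-fold


def test_ddct_excludes_samples_missing_normalizer():
    df = pd.DataFrame(
        {
            "sample": ["c1", "c2", "t1", "t2"],
            "condition": ["ctl", "ctl", "trt", "trt"],
            "target_ct": [24.0, 24.0, 23.0, 23.0],
            "normalizer_ct": [18.0, 18.0, math.nan, 18.0],
        }
    )
    log = []
    out = ddct_relative_expression(df, "ctl", log=log).set_index("condition")["rq"]
    assert out["trt"] == pytest.approx(2.0)
    assert log == ["t1: excluded (missing Ct)"]


def test_ddct_recovers_planted_fold_change_within_three_se():
    """Parameter recovery: planted log2 fold change f, Gaussian Ct noise
    sigma = 0.1 -> recovered log2 RQ within 3 standard errors of f."""
    f, reps, sd = 1.5, 6, 0.1
    q = simulate_qpcr_table({"treated": f}, n_replicates=reps, seed=2024, noise_sd=sd)
    out = ddct_relative_expression(q, "control").set_index("condition")
    se = sd * math.sqrt(2) * math.sqrt(2 / reps)  # two Cts, two condition means
    assert abs(math.log2(out.loc["treated", "rq"]) - f) <= 3 * se


def test_de_summary_counts():
    assert summarize_de_table(pd.DataFrame()) == {"significant": 0, "fc_gt2": 0, "up": 0, "down": 0}
    one = pd.DataFrame({"gene": ["g"], "log2fc": [-1.5], "padj": [0.01]})
    assert summarize_de_table(one) == {"significant": 1, "fc_gt2": 1, "up": 0, "down": 1}


def test_de_summary_matches_planted_truth():
    rng = np.random.default_rng(33)
    n, n_sig = 1000, 100
    sig = np.zeros(n, dtype=bool)
    sig[:n_sig] = True
    padj = np.where(sig, rng.uniform(0, 0.049, n), rng.uniform(0.051, 1, n))
    log2fc = np.where(sig, rng.choice([-2.0, 2.0, 0.5], n), rng.normal(0, 0.2, n))
    df = pd.DataFrame({"gene": [f"g{i}" for i in range(n)], "log2fc": log2fc, "padj": padj})
    out = summarize_de_table(df)
    assert out["significant"] == n_sig
    assert out["fc_gt2"] == int((sig & (np.abs(log2fc) > 1)).sum())
    assert out["up"] + out["down"] == n_sig
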