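"""Duplex alignment engine: DP vs brute force, scanning, feature counting."""

import numpy as np
import pytest

from asoscan.duplex import (
    Column,
    DuplexAlignment,
    ScanParams,
    align_duplex,
    feature_summary,
    oracle_align,
    render_duplex,
    scan_mismatch_only,
    scan_sequence,
)
from asoscan.oligo import PairClass, SugarMod, antisense_of, uniform
from asoscan.simulate import Edit, EditKind, PlantSpec, plant_target_site


def _random_aso(rng, n=10, name="rnd"):
    return uniform(name, "".join(rng.choice(list("ACGT"), size=n)), SugarMod.MOE)


def test_perfect_footprint_gives_all_canonical_columns(f18moe):
    aln = align_duplex(f18moe, f18moe.perfect_target())
    f = aln.features
    assert (f.n_canonical, f.n_noncanonical) == (18, 0)
    assert f.max_canonical_run == 18
    assert aln.score == 36.0


def test_polr2h_like_site_features(catalogue, f18moe):
    """The strongest validated off-target duplex: 14 canonical pairs, two
    mismatches opposing the ASO 3' end, two wobbles mid-duplex."""
    site = catalogue["targets"]["POLR2H"].site_seq
    aln = align_duplex(f18moe, site)
    f = aln.features
    assert (f.n_canonical, f.n_mismatch, f.n_wobble, f.n_bulge) == (14, 2, 2, 0)
    assert f.n_noncanonical == 4
    mism_aso_pos = sorted(c.aso_pos for c in aln.columns if c.pair is PairClass.MISMATCH)
    wob_aso_pos = sorted(c.aso_pos for c in aln.columns if c.pair is PairClass.WOBBLE)
    assert mism_aso_pos == [16, 18]  # toward the ASO 3' end
    assert wob_aso_pos == [6, 10]  # mid-duplex


def test_feature_summary_run_arithmetic():
    cols = tuple(
        Column(5 - i, i + 1, pc)
        for i, pc in enumerate(
            [
                PairClass.CANONICAL,
                PairClass.CANONICAL,
                PairClass.MISMATCH,
                PairClass.WOBBLE,
                PairClass.CANONICAL,
            ]
        )
    )
    aln = DuplexAlignment("x", "t", (1, 5), "+", cols, 0.0)
    f = feature_summary(aln)
    assert f.max_noncanonical_run == 2
    assert f.max_canonical_run == 2
    assert (f.n_canonical, f.n_wobble, f.n_mismatch) == (3, 1, 1)


def test_window_shorter_than_precondition_is_an_error(f18moe):
    with pytest.raises(ValueError, match="cannot accommodate"):
        align_duplex(f18moe, "ACGTACGTACGTACG")  # 15 < 18 - 2


def test_scan_finds_exact_antisense_at_planted_position(f18moe):
    rng = np.random.default_rng(5)
    flank = "".join(rng.choice(list("ACGT"), size=80))
    p = 41  # 1-based plant position
    seq = flank[: p - 1] + f18moe.perfect_target() + flank[p - 1 :]
    hits = scan_sequence(f18moe, "t", seq)
    assert hits[0].target_span == (p, p + 17)
    assert hits[0].features.n_canonical == 18


def test_scan_recovers_planted_degraded_site():
    rng = np.random.default_rng(0)
    aso = _random_aso(rng, 18, "probe18")
    # wobble edits need a G or T ASO base at the opposed footprint position
    wobble_ok = [
        p for p in range(4, 16) if aso.base_at(len(aso) - p + 1) in "GT"
    ]
    spec = PlantSpec(
        aso,
        edits=(
            Edit(2, EditKind.MISMATCH),
            Edit(17, EditKind.MISMATCH),
            Edit(wobble_ok[0], EditKind.WOBBLE_SWAP),
            Edit(wobble_ok[-1], EditKind.WOBBLE_SWAP),
        ),
        flank5=240,
        flank3=240,
        seed=42,
    )
    planted = plant_target_site(spec)
    hits = scan_sequence(aso, planted.target_id, planted.sequence)
    assert hits, "planted site not recovered"
    assert hits[0].target_span == planted.site_span
    f = hits[0].features
    assert f.n_noncanonical == planted.n_mismatch + planted.n_wobble + planted.n_bulge


def test_scan_on_reverse_complement_finds_mirrored_site(f18moe):
    rng = np.random.default_rng(9)
    flank = "".join(rng.choice(list("ACGT"), size=60))
    seq = flank + f18moe.perfect_target() + flank
    mirrored = antisense_of(seq)
    fwd = scan_sequence(f18moe, "t", seq)[0]
    rev = scan_sequence(f18moe, "t", mirrored, both_strands=True)
    minus = [h for h in rev if h.strand == "-"]
    assert minus and minus[0].target_span == (
        len(seq) - fwd.target_span[1] + 1,
        len(seq) - fwd.target_span[0] + 1,
    )


def test_empty_target_is_an_error(f18moe):
    with pytest.raises(ValueError, match="empty"):
        scan_sequence(f18moe, "t", "")


def test_mismatch_only_scan(catalogue, f18moe):
    rng = np.random.default_rng(3)
    flank = "".join(rng.choice(list("ACGT"), size=50))
    seq = flank + f18moe.perfect_target() + flank
    exact = scan_mismatch_only(f18moe, "t", seq, max_mismatches=0)
    assert len(exact) == 1 and exact[0].start == 51

    # the POLR2H-like site carries 4 strict non-canonical positions
    site_rec = catalogue["targets"]["POLR2H"]
    at2 = scan_mismatch_only(f18moe, "t", site_rec.sequence, max_mismatches=2)
    at4 = scan_mismatch_only(f18moe, "t", site_rec.sequence, max_mismatches=4)
    spans2 = {(h.start, h.end) for h in at2}
    spans4 = {(h.start, h.end) for h in at4}
    assert site_rec.site_span not in spans2
    assert site_rec.site_span in spans4


def test_oracle_equivalence_on_random_small_instances():
    """DP agrees with exhaustive enumeration on score, span and pair-class
    composition (co-optimal alignments may differ in column arrangement)."""
    rng = np.random.default_rng(7)
    for i in range(60):
        aso = _random_aso(rng, 10, f"r{i}")
        window = "".join(rng.choice(list("ACGT"), size=14))
        d = align_duplex(aso, window)
        o = oracle_align(aso, window)
        fd, fo = d.features, o.features
        assert d.score == o.score
        assert d.target_span == o.target_span
        assert (fd.n_canonical, fd.n_wobble, fd.n_mismatch, fd.n_bulge) == (
            fo.n_canonical,
            fo.n_wobble,
            fo.n_mismatch,
            fo.n_bulge,
        )


def test_oracle_rejects_large_instances(f18moe):
    with pytest.raises(ValueError, match="limited"):
        oracle_align(f18moe, "A" * 18)


def test_zero_bulge_budget_reduces_to_best_gapless_offset():
    from asoscan.oligo import pair_class

    rng = np.random.default_rng(21)
    params = ScanParams(max_bulged_nt=0)
    for i in range(20):
        aso = _random_aso(rng, 9, f"g{i}")
        window = "".join(rng.choice(list("ACGT"), size=15))
        rev = aso.bases[::-1]
        best_gapless = max(
            sum(
                params.pair_score(pair_class(a, t))
                for a, t in zip(rev, window[off : off + 9])
            )
            for off in range(len(window) - 9 + 1)
        )
        aln = align_duplex(aso, window, params)
        assert aln.score == best_gapless
        assert all(c.pair not in (PairClass.ASO_BULGE, PairClass.TARGET_BULGE) for c in aln.columns)


def test_leftmost_start_wins_on_exact_tie():
    aso = uniform("tie", "ACGTACGT", SugarMod.MOE)
    fp = aso.perfect_target()
    window_seq = fp + "TTTT" + fp  # two identical perfect sites
    hits = scan_sequence(aso, "t", window_seq, ScanParams(min_score=16))
    aln = align_duplex(aso, window_seq)
    assert aln.target_span == (1, 8)  # leftmost of the two optima
    assert len(hits) == 2  # scan reports both loci


def test_monotonicity_fixing_a_mismatch_never_decreases_score(catalogue, f18moe):
    wt = catalogue["targets"]["POLR2H"].site_seq
    base = align_duplex(f18moe, wt)
    # restore each mismatch column to the canonical complement, one at a time
    from asoscan.oligo import complement_base

    for col in base.columns:
        if col.pair is PairClass.MISMATCH:
            fixed = list(wt)
            fixed[col.target_pos - 1] = complement_base(f18moe.base_at(col.aso_pos))
            better = align_duplex(f18moe, "".join(fixed))
            assert better.score >= base.score
            assert better.features.n_canonical >= base.features.n_canonical


def test_render_duplex_marks(f18moe, catalogue):
    site = catalogue["targets"]["POLR2H"].site_seq
    aln = align_duplex(f18moe, site)
    text = render_duplex(f18moe, aln, site)
    lines = text.splitlines()
    assert lines[1].count("|") == 14 and lines[1].count("o") == 2
    assert "mC" in lines[2]  # display retains methylcytosine
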