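import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastpop import (
    AlignedSet,
    detect_ssrs,
    profile_bins,
    rank_hotspots,
    screen_polymorphic_ssrs,
    simulate_population_alignment,
    spearman_rho,
    trim_alignment,
)
from plastpop.scan import BinProfile, gap_run_events, map_ssrs_to_alignment
from tests.conftest import two_deme_demography


# ---------------------------------------------------------------------------
# trimming

def test_trim_removes_ambiguous_columns():
    aln = AlignedSet([("a", "ACNGT"), ("b", "ACAGT")])
    trimmed, kept = trim_alignment(aln)
    assert trimmed.length == 4
    assert kept == [1, 2, 4, 5]
    assert trimmed.sequence("a") == "ACGT"


def test_trim_is_identity_without_ambiguity(tiny_alignment):
    trimmed, kept = trim_alignment(tiny_alignment)
    assert trimmed.records == tiny_alignment.records
    assert kept == [1, 2, 3]


@given(st.lists(st.sampled_from("ACGTN-RY"), min_size=4, max_size=40), st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_trim_report_reconstructs_trimmed_set(template, seed):
    # applying the retained-column report to the original reproduces the output
    rng = np.random.default_rng(seed)
    rows = []
    for sid in ("a", "b", "c"):
        chars = [c if rng.random() < 0.8 else rng.choice(list("ACGTN-")) for c in template]
        rows.append((sid, "".join(chars)))
    aln = AlignedSet(rows)
    try:
        trimmed, kept = trim_alignment(aln)
    except Exception:
        return  # all columns ambiguous: nothing to reconstruct
    rebuilt = aln.with_columns([c - 1 for c in kept])
    assert rebuilt.records == trimmed.records


# ---------------------------------------------------------------------------
# bin profiling

def test_profile_bins_hand_oracle():
    # 3 x 20 alignment: SNP columns 12 and 18, one 3-column gap run (cols 3-5)
    aln = AlignedSet(
        [
            ("a", "AC---TGGACTAGACTGTAC"),
            ("b", "ACGTATGGACTCGACTGGAC"),
            ("c", "ACGTATGGACTCGACTGGAC"),
        ]
    )
    bins = profile_bins(aln, bin_length=20)
    assert len(bins) == 1
    assert bins[0].snp_count == 2
    assert bins[0].indel_count == 1


def test_profile_bins_tiling_and_final_short_bin():
    aln = AlignedSet([("a", "ACGT" * 25), ("b", "ACGT" * 25)])  # L=100
    bins = profile_bins(aln, bin_length=30)
    assert [(b.start, b.end) for b in bins] == [(1, 30), (31, 60), (61, 90), (91, 100)]
    assert all(b.snp_count == 0 and b.indel_count == 0 for b in bins)


def test_bin_counts_zero_for_identical_sequences(simulated_study):
    aln = simulated_study["trimmed"]
    first = aln.sample_ids[0]
    dup = AlignedSet([("x", aln.sequence(first)), ("y", aln.sequence(first))])
    bins = profile_bins(dup, bin_length=400)
    assert all(b.snp_count == 0 and b.indel_count == 0 for b in bins)


def test_snp_and_indel_conservation(simulated_study):
    """Per-bin counts must partition the alignment-wide totals exactly."""
    trimmed = simulated_study["trimmed"]
    bins = profile_bins(trimmed, bin_length=400)
    mat = trimmed.to_matrix()
    seg_total = 0
    for c in range(mat.shape[1]):
        bases = {b for b in mat[:, c].tolist() if b != ord("-")}
        if len(bases) >= 2:
            seg_total += 1
    assert sum(b.snp_count for b in bins) == seg_total
    assert sum(b.indel_count for b in bins) == len(gap_run_events(trimmed))


def test_bin_count_matches_ceiling_formula(simulated_study):
    trimmed = simulated_study["trimmed"]
    bins = profile_bins(trimmed, bin_length=400)
    assert len(bins) == -(-trimmed.length // 400)


# ---------------------------------------------------------------------------
# SSR detection

def _brute_force_ssrs(seq, min_mono=8, min_multi=5, max_motif=6):
    """Independent oracle: every maximal primitive tandem repeat via substring scan."""
    found = []
    n = len(seq)
    for m in range(1, max_motif + 1):
        for i in range(n - m):
            motif = seq[i : i + m]
            # primitive motif, maximal start
            if any(m % p == 0 and motif == motif[:p] * (m // p) for p in range(1, m)):
                continue
            if i >= m and seq[i - m : i] == motif:
                continue  # not leftmost
            units = 1
            while seq[i + units * m : i + (units + 1) * m] == motif:
                units += 1
            # extend partial periodicity for maximal-stretch unit counting
            extra = 0
            j = i + units * m
            while j + extra < n and seq[j + extra] == seq[j + extra - m]:
                extra += 1
            units = (units * m + extra) // m
            if units >= (min_mono if m == 1 else min_multi):
                found.append((i + 1, units * m, motif))
    return found


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAAAAAAA", [("A", 8, 1, 8)]),  # mono at threshold
        ("AAAAAAA", []),  # below mono threshold
        ("GATATATATATC", [("AT", 5, 2, 11)]),  # dimer, units 5, length 10
        ("ATATATAT", []),  # 4 units < multi threshold
        ("CGCGCGCGCG", [("CG", 5, 1, 10)]),
    ],
)
def test_detect_ssrs_threshold_examples(seq, expected):
    loci = detect_ssrs(seq)
    got = [(l.motif, l.units, l.start, l.end) for l in loci]
    assert got == expected
    for l in loci:
        assert l.length == l.units * len(l.motif)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_detect_ssrs_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    pieces = []
    for _ in range(4):
        pieces.append("".join(rng.choice(list("ACGT"), rng.integers(3, 15))))
        motif = "".join(rng.choice(list("ACGT"), rng.integers(1, 4)))
        pieces.append(motif * rng.integers(2, 12))
    seq = "".join(pieces)
    got = {(l.start, l.length) for l in detect_ssrs(seq)}
    oracle = _brute_force_ssrs(seq)
    # every detected locus is a genuine maximal repeat found by the oracle
    oracle_spans = {(s, ln) for s, ln, _ in oracle}
    assert got <= oracle_spans
    # every oracle locus is detected unless it overlaps an earlier (leftmost-longest) one
    for s, ln, motif in sorted(oracle):
        if (s, ln) in got:
            continue
        assert any(gs <= s + ln - 1 and s <= gs + gl - 1 for gs, gl in got), (
            f"missed non-overlapping locus at {s} len {ln} motif {motif}"
        )


def test_detect_ssrs_reversal_invariance():
    seq = "GGATATATATATCCAAAAAAAAAG"
    fwd = detect_ssrs(seq)
    rev = detect_ssrs(seq[::-1])
    n = len(seq)
    fwd_spans = sorted((l.start, l.end) for l in fwd)
    rev_spans = sorted((n - l.end + 1, n - l.start + 1) for l in rev)
    assert fwd_spans == rev_spans


def test_detect_ssrs_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        detect_ssrs("ACGTN")


# ---------------------------------------------------------------------------
# Spearman

def test_spearman_monotone_and_reverse():
    assert spearman_rho([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)


def test_spearman_tie_correction_matches_rank_pearson():
    # independent oracle: Pearson correlation of average ranks
    x, y = [1, 2, 2, 4], [1, 3, 2, 4]
    rx, ry = [1.0, 2.5, 2.5, 4.0], [1.0, 3.0, 2.0, 4.0]
    expected = np.corrcoef(rx, ry)[0, 1]
    rho, p = spearman_rho(x, y)
    assert rho == pytest.approx(expected, abs=1e-12)
    assert 0 < p <= 1


def test_spearman_constant_vector_is_undefined_not_zero():
    rho, p = spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])
    assert np.isnan(rho) and np.isnan(p)


# ---------------------------------------------------------------------------
# hotspot ranking

def _bin(i, snp, indel, width=400):
    s = (i - 1) * width + 1
    return BinProfile(i, s, s + width - 1, 0.3, snp, indel, 0)


def test_rank_hotspots_single_variable_bin():
    profiles = [_bin(1, 0, 0), _bin(2, 3, 1), _bin(3, 0, 0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regions = rank_hotspots(profiles, k=27)
    assert len(regions) == 1
    assert (regions[0].snp_total, regions[0].indel_total) == (3, 1)


def test_rank_hotspots_tie_broken_by_coordinate():
    profiles = [_bin(1, 2, 0), _bin(2, 0, 0), _bin(3, 2, 0), _bin(4, 0, 0), _bin(5, 2, 0)]
    regions = rank_hotspots(profiles, k=2)
    assert sorted(r.start for r in regions) == [1, 801]  # bins 1 and 3


def test_rank_hotspots_merges_adjacent_bins():
    profiles = [_bin(1, 5, 0), _bin(2, 4, 1), _bin(3, 0, 0), _bin(4, 1, 0)]
    regions = rank_hotspots(profiles, k=2)
    merged = regions[0]
    assert (merged.start, merged.end) == (1, 800)
    assert merged.snp_total == 9 and merged.indel_total == 1


def test_rank_hotspots_recovers_true_hotspots(snp_hotspot_plastome):
    """Monte-Carlo: selected regions overlap the true hotspot intervals."""
    spec, ref, ann = snp_hotspot_plastome
    hits = total = 0
    for seed in range(20):
        demo = two_deme_demography(seed)
        aln, _, _ = simulate_population_alignment(ref, demo, spec, ann)
        trimmed, _ = trim_alignment(aln)
        regions = rank_hotspots(profile_bins(trimmed, bin_length=400), k=4)
        for r in regions:
            total += 1
            hits += any(not (r.end < s or r.start > e) for s, e in ann["hotspots"])
    assert hits / total >= 0.8


# ---------------------------------------------------------------------------
# polymorphic cpSSR screening

def test_polymorphic_mono_run_two_alleles():
    # homologous A-run: 9 units vs 11 units (alignment pads the shorter)
    aln = AlignedSet(
        [
            ("a", "GGC" + "A" * 9 + "--" + "CGGTT"),
            ("b", "GGC" + "A" * 11 + "CGGTT"),
        ]
    )
    clusters = screen_polymorphic_ssrs(aln)
    assert len(clusters) == 1
    assert clusters[0].motif == "A"
    assert sorted(clusters[0].alleles.values()) == [9, 11]


def test_identical_sequences_have_no_polymorphic_ssrs():
    seq = "GGC" + "A" * 10 + "CG" + "AT" * 6 + "GTT"
    aln = AlignedSet([("a", seq), ("b", seq)])
    assert screen_polymorphic_ssrs(aln) == []


def test_seeded_ssr_loci_recovered_as_polymorphic(demo_plastome):
    spec, ref, ann = demo_plastome
    from plastpop.simulate import default_demo_spec

    _, demo = default_demo_spec()
    demo.seed = 1
    aln, _, _ = simulate_population_alignment(ref, demo, spec, ann)
    trimmed, _ = trim_alignment(aln)
    clusters = screen_polymorphic_ssrs(trimmed)
    assert len(clusters) == len(ann["ssr_loci"]) == 6
    for c in clusters:
        assert len(set(c.alleles.values())) >= 2


def test_map_ssrs_to_alignment_coordinates():
    aligned = "A--CGAAAAAAAAT"
    loci = detect_ssrs(aligned.replace("-", ""))
    mapped = map_ssrs_to_alignment(aligned, loci)
    assert len(mapped) == 1
    assert (mapped[0].start, mapped[0].end) == (6, 13)
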