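"""Guide grouping, ranking, non-overlapping selection, coverage DP,
dropout taxonomy and retention."""

import itertools
import random

import pytest

from ampdesign.config import DesignConfig
from ampdesign.primers import AmpliconCandidate
from ampdesign.selection import (
    DropoutReason,
    GeneDesign,
    choose_guide_subset,
    compute_retention,
    dropout_reason,
    group_guides,
    guide_overlap_pairs,
    rank_amplicons,
    rank_key,
    select_coverage,
    select_top,
)
from .test_guides import mk_guide


def mk_amp(fwd, rev, gene="g1", aid=None, penalty=0.0):
    """Amplicon with primer intervals fwd=[s,e) and rev=[s,e)."""
    return AmpliconCandidate(
        amplicon_id=aid or f"{gene}_a{fwd[0]}",
        gene_id=gene,
        fwd_seq="A" * (fwd[1] - fwd[0]),
        rev_seq="A" * (rev[1] - rev[0]),
        fwd_interval=tuple(fwd),
        rev_interval=tuple(rev),
        tm_fwd=60.0, tm_rev=60.0, gc_fwd=0.5, gc_rev=0.5,
        penalty=penalty,
    )


class TestGrouping:
    def test_distance_exactly_min_qualifies(self):
        amp = mk_amp((80, 100), (170, 190))
        g = mk_guide(start=115)  # protospacer [115,135); 100+15=115, 135<=170-15
        grouped = group_guides([amp], [g], min_distance=15)
        assert grouped[amp.amplicon_id] == [g]

    def test_one_bp_too_close_is_excluded(self):
        amp = mk_amp((80, 100), (170, 190))
        g = mk_guide(start=114)
        assert group_guides([amp], [g], 15)[amp.amplicon_id] == []

    def test_guide_under_primer_not_grouped(self):
        amp = mk_amp((80, 100), (200, 220))
        g = mk_guide(start=90)
        assert group_guides([amp], [g], 15)[amp.amplicon_id] == []

    def test_matches_containment_oracle_on_random_layouts(self):
        rnd = random.Random(42)
        amps = [
            mk_amp((s, s + 20), (s + 110, s + 130), aid=f"a{i}")
            for i, s in enumerate(rnd.sample(range(0, 600), 20))
        ]
        guides = [mk_guide(start=rnd.randrange(0, 700), gid=str(i)) for i in range(60)]
        grouped = group_guides(amps, guides, 15)
        for a in amps:
            lo, hi = a.fwd_interval[1] + 15, a.rev_interval[0] - 15
            expect = {
                g.guide_id
                for g in guides
                if g.target_interval[0] >= lo and g.target_interval[1] <= hi
            }
            assert {g.guide_id for g in grouped[a.amplicon_id]} == expect


class TestOverlapCount:
    def test_disjoint_and_overlapping_pairs(self):
        a, b = mk_guide(start=0), mk_guide(start=50)
        assert guide_overlap_pairs([a, b]) == 0
        c = mk_guide(start=10)  # overlaps a ([0,20) vs [10,30))
        assert guide_overlap_pairs([a, c]) == 1

    def test_matches_all_pairs_oracle(self):
        rnd = random.Random(7)
        for _ in range(30):
            guides = [
                mk_guide(start=rnd.randrange(0, 120), gid=str(i))
                for i in range(rnd.randrange(0, 12))
            ]
            expect = sum(
                1
                for g1, g2 in itertools.combinations(guides, 2)
                if g1.target_interval[0] < g2.target_interval[1]
                and g2.target_interval[0] < g1.target_interval[1]
            )
            assert guide_overlap_pairs(guides) == expect


class TestGuideSubset:
    def test_overlap_minimisation_forced(self):
        a = mk_guide(start=0, gid="a", spec=50)
        b = mk_guide(start=10, gid="b", spec=99)  # overlaps a
        c = mk_guide(start=100, gid="c", spec=10)
        chosen = choose_guide_subset([a, b, c], 2)
        assert {g.guide_id for g in chosen} in ({"a", "c"}, {"b", "c"})
        # the non-overlapping pair with higher mean specificity wins
        assert {g.guide_id for g in chosen} == {"b", "c"}

    def test_specificity_breaks_ties(self):
        guides = [
            mk_guide(start=s, gid=str(s), spec=sp)
            for s, sp in ((0, 90.0), (50, 70.0), (100, 80.0))
        ]
        chosen = choose_guide_subset(guides, 2)
        assert {g.guide_id for g in chosen} == {"0", "100"}

    def test_never_worse_than_exhaustive_on_first_criterion(self):
        rnd = random.Random(13)
        for _ in range(40):
            n = rnd.randrange(3, 7)
            guides = [
                mk_guide(
                    start=rnd.randrange(0, 80), gid=str(i),
                    spec=float(rnd.randrange(0, 101)),
                )
                for i in range(n)
            ]
            k = rnd.randrange(1, n)
            chosen = choose_guide_subset(guides, k)
            best = min(
                guide_overlap_pairs(list(sub))
                for sub in itertools.combinations(guides, k)
            )
            assert guide_overlap_pairs(chosen) == best


class TestRanking:
    def test_paper_order_count_then_overlap(self):
        A = (mk_amp((0, 20), (130, 150), aid="A"),
             [mk_guide(start=40, gid="a1"), mk_guide(start=80, gid="a2")])
        B = (mk_amp((200, 220), (330, 350), aid="B"),
             [mk_guide(start=240, gid="b1"), mk_guide(start=250, gid="b2")])
        C = (mk_amp((400, 420), (530, 550), aid="C"), [mk_guide(start=440)])
        ranked = rank_amplicons([C, B, A])
        assert [x[0].amplicon_id for x in ranked] == ["A", "B", "C"]

    def test_mean_specificity_breaks_ties(self):
        A = (mk_amp((0, 20), (130, 150), aid="A"),
             [mk_guide(start=40, spec=90.0)])
        B = (mk_amp((200, 220), (330, 350), aid="B"),
             [mk_guide(start=240, spec=70.0)])
        ranked = rank_amplicons([B, A])
        assert ranked[0][0].amplicon_id == "A"

    def test_full_tie_leftmost_first(self):
        A = (mk_amp((100, 120), (230, 250), aid="A"), [])
        B = (mk_amp((0, 20), (130, 150), aid="B"), [])
        ranked = rank_amplicons([A, B])
        assert ranked[0][0].amplicon_id == "B"

    def test_strict_total_order_stable_under_shuffle(self):
        rnd = random.Random(3)
        items = []
        for i in range(15):
            s = rnd.randrange(0, 2000)
            gs = [
                mk_guide(start=s + 25 + rnd.randrange(0, 60), gid=f"{i}_{j}",
                         spec=float(rnd.randrange(0, 101)))
                for j in range(rnd.randrange(0, 4))
            ]
            items.append((mk_amp((s, s + 20), (s + 130, s + 150), aid=f"x{i}"), gs))
        once = rank_amplicons(items)
        shuffled = items[:]
        rnd.shuffle(shuffled)
        assert [a.amplicon_id for a, _ in rank_amplicons(shuffled)] == [
            a.amplicon_id for a, _ in once
        ]
        assert [a.amplicon_id for a, _ in rank_amplicons(once)] == [
            a.amplicon_id for a, _ in once
        ]


def _independent_select_top(ranked, max_amplicons):
    """Spec fixpoint re-implemented independently: scan in rank order,
    keep amplicons disjoint from all kept ones, stop at the cap."""
    kept = []
    for amp, gs in ranked:
        if max_amplicons is not None and len(kept) == max_amplicons:
            break
        s, e = amp.product_interval
        if all(
            e <= k.product_interval[0] or s >= k.product_interval[1]
            for k, _ in kept
        ):
            kept.append((amp, gs))
    return kept


class TestSelectTop:
    def test_overlapping_pair_keeps_higher_rank(self):
        A = (mk_amp((0, 20), (130, 150), aid="A"), [mk_guide(start=40)])
        B = (mk_amp((100, 120), (230, 250), aid="B"), [mk_guide(start=140)])
        ranked = rank_amplicons([A, B])
        sel = select_top(ranked, 2)
        assert len(sel) == 1
        assert sel[0][0].amplicon_id == ranked[0][0].amplicon_id

    def test_three_disjoint_top_two(self):
        items = [
            (mk_amp((i * 200, i * 200 + 20), (i * 200 + 130, i * 200 + 150),
                    aid=f"d{i}"),
             [mk_guide(start=i * 200 + 40, gid=f"g{i}", spec=float(90 - i))])
            for i in range(3)
        ]
        ranked = rank_amplicons(items)
        sel = select_top(ranked, 2)
        assert [a.amplicon_id for a, _ in sel] == [
            a.amplicon_id for a, _ in ranked[:2]
        ]

    def test_matches_independent_reimplementation(self):
        rnd = random.Random(99)
        for _ in range(50):
            items = []
            for i in range(rnd.randrange(1, 13)):
                s = rnd.randrange(0, 800)
                gs = [
                    mk_guide(start=s + 25 + rnd.randrange(0, 60),
                             gid=f"{i}_{j}", spec=float(rnd.randrange(101)))
                    for j in range(rnd.randrange(0, 3))
                ]
                items.append(
                    (mk_amp((s, s + 20), (s + 110 + rnd.randrange(0, 30),
                                          s + 140 + rnd.randrange(0, 30)),
                            aid=f"r{i}"), gs)
                )
            ranked = rank_amplicons(items)
            cap = rnd.choice([1, 2, 3, None])
            got = select_top(ranked, cap)
            want = _independent_select_top(ranked, cap)
            assert [a.amplicon_id for a, _ in got] == [
                a.amplicon_id for a, _ in want
            ]

    def test_monotone_in_max_amplicons(self):
        items = [
            (mk_amp((i * 160, i * 160 + 20), (i * 160 + 130, i * 160 + 150),
                    aid=f"m{i}"), [mk_guide(start=i * 160 + 40, gid=f"g{i}")])
            for i in range(5)
        ]
        ranked = rank_amplicons(items)
        counts = [len(select_top(ranked, k)) for k in range(1, 6)]
        assert counts == sorted(counts)


class TestCoverage:
    def test_forced_disjoint_choice(self):
        c = [
            mk_amp((0, 20), (130, 150), aid="a"),
            mk_amp((140, 160), (270, 290), aid="b"),
            mk_amp((300, 320), (430, 450), aid="c"),
        ]
        sel = select_coverage(c, None)
        ids = {a.amplicon_id for a in sel}
        # a and b overlap ([0,150) vs [140,290)); optimum keeps two disjoint
        assert len(sel) == 2 and "c" in ids
        covered = sum(a.product_size for a in sel)
        assert covered == 300

    def test_single_candidate(self):
        c = [mk_amp((0, 20), (130, 150), aid="solo")]
        assert [a.amplicon_id for a in select_coverage(c, None)] == ["solo"]

    def test_dp_equals_exhaustive_enumeration(self):
        rnd = random.Random(5)
        for _ in range(40):
            n = rnd.randrange(1, 13)
            cands = []
            for i in range(n):
                s = rnd.randrange(0, 500)
                size = rnd.randrange(120, 151)
                cands.append(
                    mk_amp((s, s + 20), (s + size - 20, s + size), aid=f"e{i}")
                )
            cap = rnd.choice([None, 1, 2, 3])
            got = select_coverage(cands, cap)
            got_cov = sum(a.product_size for a in got)

            best = 0
            for r in range(0, (len(cands) if cap is None else cap) + 1):
                for sub in itertools.combinations(cands, r):
                    ivs = sorted(a.product_interval for a in sub)
                    if any(b[0] < a[1] for a, b in zip(ivs, ivs[1:])):
                        continue
                    best = max(best, sum(a.product_size for a in sub))
            assert got_cov == best
            # result itself is disjoint
            ivs = sorted(a.product_interval for a in got)
            assert all(b[0] >= a[1] for a, b in zip(ivs, ivs[1:]))

    def test_beats_greedy_by_length(self):
        rnd = random.Random(17)
        for _ in range(20):
            cands = []
            for i in range(12):
                s = rnd.randrange(0, 400)
                size = rnd.randrange(120, 151)
                cands.append(
                    mk_amp((s, s + 20), (s + size - 20, s + size), aid=f"h{i}")
                )
            dp_cov = sum(a.product_size for a in select_coverage(cands, None))
            greedy, taken = 0, []
            for c in sorted(cands, key=lambda c: -c.product_size):
                s, e = c.product_interval
                if all(e <= t[0] or s >= t[1] for t in taken):
                    taken.append((s, e))
                    greedy += e - s
            assert dp_cov >= greedy


class TestDropout:
    def test_crispr_precedence(self):
        kw = dict(mode="CRISPR", sequence_long_enough=True, had_selection=False)
        assert dropout_reason(
            n_guides_input=0, n_guides_filtered=0, n_specific_amplicons=5,
            n_grouped_amplicons=0, **kw
        ) is DropoutReason.NO_GRNAS_DESIGNED
        assert dropout_reason(
            n_guides_input=3, n_guides_filtered=0, n_specific_amplicons=5,
            n_grouped_amplicons=0, **kw
        ) is DropoutReason.NO_GRNAS_PASSED_FILTERS
        assert dropout_reason(
            n_guides_input=3, n_guides_filtered=2, n_specific_amplicons=0,
            n_grouped_amplicons=0, **kw
        ) is DropoutReason.NO_SPECIFIC_AMPLICONS
        assert dropout_reason(
            n_guides_input=3, n_guides_filtered=2, n_specific_amplicons=4,
            n_grouped_amplicons=0, **kw
        ) is DropoutReason.NO_GRNA_AMPLICON_OVERLAP

    def test_natvar_reasons(self):
        assert dropout_reason(
            mode="NatVar", sequence_long_enough=False, n_guides_input=0,
            n_guides_filtered=0, n_specific_amplicons=0,
            n_grouped_amplicons=0, had_selection=False,
        ) is DropoutReason.SEQUENCE_TOO_SHORT

    def test_called_with_selection_is_error(self):
        with pytest.raises(ValueError):
            dropout_reason(
                mode="CRISPR", sequence_long_enough=True, n_guides_input=1,
                n_guides_filtered=1, n_specific_amplicons=1,
                n_grouped_amplicons=1, had_selection=True,
            )


def _design(gene, fam, pairs=None, reason=None):
    return GeneDesign(
        gene_id=gene, family_id=fam,
        selected=pairs or [], dropout_reason=reason,
    )


def _amp_with_guides(n_guides, offset=0, aid="a"):
    amp = mk_amp((offset, offset + 20), (offset + 130, offset + 150), aid=aid)
    gs = [mk_guide(start=offset + 30 + 25 * j, gid=f"{aid}{j}") for j in range(n_guides)]
    return (amp, gs)


class TestRetention:
    def test_three_of_four(self):
        ds = [
            _design(f"g{i}", "fam", [_amp_with_guides(2, aid=f"a{i}")])
            for i in range(3)
        ] + [_design("g3", "fam", reason=DropoutReason.NO_GRNAS_DESIGNED)]
        assert compute_retention(ds)["fam"] == 75.0

    def test_single_guide_amplicon_not_retained_at_min_two(self):
        ds = [_design("g0", "fam", [_amp_with_guides(1)])]
        assert compute_retention(ds, min_guides=2)["fam"] == 0.0
        assert compute_retention(ds, min_guides=1)["fam"] == 100.0

    def test_matches_recount_oracle(self):
        rnd = random.Random(23)
        ds = []
        for i in range(40):
            fam = f"f{i % 5}"
            if rnd.random() < 0.3:
                ds.append(_design(f"g{i}", fam,
                                  reason=DropoutReason.NO_GRNAS_DESIGNED))
            else:
                pairs = [
                    _amp_with_guides(rnd.randrange(0, 3), offset=200 * j,
                                     aid=f"g{i}a{j}")
                    for j in range(rnd.randrange(1, 3))
                ]
                pairs = [p for p in pairs if True]
                ds.append(_design(f"g{i}", fam, pairs))
        for min_guides in (1, 2):
            got = compute_retention(ds, min_guides=min_guides)
            byfam = {}
            for d in ds:
                byfam.setdefault(d.family_id, []).append(d)
            for fam, members in byfam.items():
                n_ok = sum(
                    1 for d in members
                    if any(len(gs) >= min_guides for _, gs in d.selected)
                )
                assert got[fam] == pytest.approx(100.0 * n_ok / len(members))

    def test_raising_min_guides_never_increases_retention(self):
        rnd = random.Random(31)
        ds = []
        for i in range(30):
            pairs = [
                _amp_with_guides(rnd.randrange(0, 4), offset=200 * j,
                                 aid=f"g{i}b{j}")
                for j in range(rnd.randrange(1, 3))
            ]
            ds.append(_design(f"g{i}", f"f{i % 4}", pairs))
        r1 = compute_retention(ds, min_guides=1)
        r2 = compute_retention(ds, min_guides=2)
        for fam in r1:
            assert r2[fam] <= r1[fam]

    def test_design_invariant_disjoint_amplicons(self):
        overlapping = [
            _amp_with_guides(1, offset=0, aid="o1"),
            _amp_with_guides(1, offset=50, aid="o2"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            _design("g", "f", overlapping)
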