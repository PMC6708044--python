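"""Recombinant screening, breakpoint classes and interval deduction."""

import numpy as np
import pandas as pd
import pytest

from hifmap import finemap as fm
from hifmap import simulate as sim
from hifmap import wheat7al as w
from hifmap.genetics import GenomicInterval, GenotypeMatrix, Marker
from hifmap.simulate import CrossDesign


def _region_markers(n=10, start=1_000_000, step=1_000_000, chrom="7A"):
    return [Marker(f"R{j}", chrom, start + j * step) for j in range(n)]


def _gm(markers, rows, ids=None):
    ids = ids or [f"L{i}" for i in range(len(rows))]
    return GenotypeMatrix.from_codes(ids, markers,
                                     np.array(rows, dtype=np.int8))


class TestFindRecombinants:
    def test_flank_patterns(self):
        markers = [Marker("L", "7A", 100), Marker("R", "7A", 200)]
        gm = _gm(markers, [[0, 0], [0, 1], [1, 2], [0, 2], [2, 2], [-1, 0]])
        res = fm.find_recombinants(gm, "L", "R")
        assert res.recombinant_ids == ["L1", "L2", "L3"]
        assert res.excluded_missing_ids == ["L5"]
        assert res.n_screened == 6

    def test_swapped_flanks_warn_and_correct(self):
        markers = [Marker("L", "7A", 100), Marker("R", "7A", 200)]
        gm = _gm(markers, [[0, 1]])
        with pytest.warns(UserWarning, match="swapped"):
            res = fm.find_recombinants(gm, "R", "L")
        assert res.recombinant_ids == ["L0"]

    def test_simulated_f2_fraction_matches_closed_form(self):
        """Screen fraction matches the exact F2 two-flank expectation from
        the calibrated map."""
        gmap = sim.region_map_7al(include_locus=False)
        pop = sim.simulate_population(CrossDesign("F2", 3000, gmap, rng_seed=5))
        res = fm.find_recombinants(pop.genotypes, "IWB713", "IWB53096")
        d_cm = (gmap.positions_cM("7A")[-1] - gmap.positions_cM("7A")[0])
        from hifmap.genetics import haldane_from_cM

        p = sim.expected_f2_screen_fraction(haldane_from_cM(d_cm))
        se = np.sqrt(p * (1 - p) / 3000)
        assert abs(res.recombinant_fraction - p) < 4 * se


class TestBreakpointClasses:
    def test_identical_and_missing_tolerant_grouping(self):
        markers = _region_markers(4)
        gm = _gm(markers, [
            [0, 0, 1, 1],
            [0, 0, 1, 1],     # identical to L0
            [0, -1, 1, 1],    # compatible with L0 at observed sites
            [1, 1, 0, 0],     # different class
        ])
        res = fm.group_by_breakpoint(gm, gm.line_ids)
        assert res.n_classes == 2
        assert sorted(map(sorted, res.classes)) == [["L0", "L1", "L2"], ["L3"]]

    def test_mostly_missing_line_unclassifiable(self):
        markers = _region_markers(4)
        gm = _gm(markers, [[0, 0, 1, 1], [-1, -1, -1, 0]])
        res = fm.group_by_breakpoint(gm, gm.line_ids)
        assert res.unclassifiable == ["L1"]

    def test_class_keys_name_transition_interval(self):
        markers = _region_markers(4)
        gm = _gm(markers, [[0, 0, 1, 1]])
        res = fm.group_by_breakpoint(gm, gm.line_ids)
        assert res.class_keys == ["R1..R2"]

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        """Class count equals connected components of the brute-force
        pairwise comparison graph, on random recombinant vectors."""
        markers = _region_markers(6)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            rows = rng.integers(-1, 3, size=(n, 6))
            gm = _gm(markers, rows)
            res = fm.group_by_breakpoint(gm, gm.line_ids)

            # independent oracle: adjacency + BFS over usable lines
            usable = [i for i in range(n) if (rows[i] < 0).mean() <= 0.5]
            seen, comps = set(), 0
            for s in usable:
                if s in seen:
                    continue
                comps += 1
                stack = [s]
                while stack:
                    u = stack.pop()
                    if u in seen:
                        continue
                    seen.add(u)
                    for v in usable:
                        both = (rows[u] >= 0) & (rows[v] >= 0)
                        if v not in seen and np.all(rows[u][both] == rows[v][both]):
                            stack.append(v)
            assert res.n_classes == comps


class TestProgenyTest:
    def test_equal_means_classified_homozygous(self, rng):
        d = sim.simulate_progeny_test_phenotypes(heterozygous=False,
                                                 n_per_class=40, rng=rng)
        res = fm.progeny_test_classify("F1", d)
        assert res.classification == "homozygous"

    def test_one_class_absent_is_an_error(self):
        d = pd.DataFrame({"sister_class": ["A"] * 6, "experiment": ["GH1"] * 6,
                          "value": np.arange(6.0)})
        with pytest.raises(ValueError, match="incomplete"):
            fm.progeny_test_classify("F1", d)

    def test_anova_matches_normal_equations(self, rng):
        """F/P equal a direct dummy-coded least-squares computation."""
        from scipy import stats

        d = sim.simulate_progeny_test_phenotypes(rng=rng, n_per_class=12)
        res = fm.progeny_test_classify("F1", d)
        y = d["value"].to_numpy()
        X = np.column_stack([
            np.ones(len(d)),
            (d["sister_class"] == "B").astype(float),
            (d["experiment"] == "GH2").astype(float),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss1 = float(((y - X @ beta) ** 2).sum())
        X0 = X[:, [0, 2]]
        b0 = np.linalg.solve(X0.T @ X0, X0.T @ y)
        rss0 = float(((y - X0 @ b0) ** 2).sum())
        dfd = len(d) - 3
        f = (rss0 - rss1) / (rss1 / dfd)
        assert res.f_value == pytest.approx(f, rel=1e-9)
        assert res.p_value == pytest.approx(stats.f.sf(f, 1, dfd), rel=1e-9)

    def test_power_at_published_gap(self):
        """With the 2.1-SNS homozygote gap and HIF-level noise, 25 plants
        per class in 2 experiments detect segregation in >=95% of trials
        (50 seeded trials here; the full 500-trial rate is computed by the
        acceptance checks)."""
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(50):
            d = sim.simulate_progeny_test_phenotypes(rng=rng)
            if fm.progeny_test_classify("F", d).classification == "heterozygous":
                hits += 1
        assert hits >= 48


class TestFamilySegments:
    def test_segments_from_calls(self):
        markers = _region_markers(6)
        region = GenomicInterval("7A", 1_000_000, 6_000_000)
        calls = pd.Series(["A", "A", "H", "H", "B", "B"],
                          index=[m.name for m in markers])
        fam = fm.RecombinantFamily.from_genotypes("F", calls, markers, region)
        assert (fam.het_segment_min.start_bp, fam.het_segment_min.end_bp) == (
            3_000_000, 4_000_000)
        assert (fam.het_segment_max.start_bp, fam.het_segment_max.end_bp) == (
            2_000_000, 5_000_000)
        assert fam.het_segment_max.contains(fam.het_segment_min)

    def test_no_het_calls_gives_empty_segments(self):
        markers = _region_markers(3)
        region = GenomicInterval("7A", 1_000_000, 3_000_000)
        calls = pd.Series(["A", "A", "B"], index=[m.name for m in markers])
        fam = fm.RecombinantFamily.from_genotypes("F", calls, markers, region)
        assert fam.het_segment_max is None and fam.het_segment_min is None

    def test_het_run_touching_region_edge_extends_to_region(self):
        markers = _region_markers(3)
        region = GenomicInterval("7A", 500_000, 3_500_000)
        calls = pd.Series(["H", "H", "B"], index=[m.name for m in markers])
        fam = fm.RecombinantFamily.from_genotypes("F", calls, markers, region)
        assert fam.het_segment_max.start_bp == 500_000


def _oracle_deduction(families, markers, region):
    """Brute force: test every between-marker gap against every constraint,
    then take the widest contiguous viable run."""
    pos = sorted(m.pos_bp for m in markers
                 if region.start_bp <= m.pos_bp <= region.end_bp)
    gaps = list(zip(pos, pos[1:]))
    viable = []
    for lo, hi in gaps:
        ok = True
        for fam, label in families:
            if label == "heterozygous":
                seg = fam.het_segment_max
                if not (seg.start_bp <= lo and hi <= seg.end_bp):
                    ok = False
            else:
                seg = fam.het_segment_min
                if seg is not None and seg.start_bp < hi and seg.end_bp > lo:
                    ok = False
        viable.append(ok)
    best = None
    i = 0
    while i < len(gaps):
        if viable[i]:
            j = i
            while j + 1 < len(gaps) and viable[j + 1]:
                j += 1
            if best is None or gaps[j][1] - gaps[i][0] > best[1] - best[0]:
                best = (gaps[i][0], gaps[j][1])
            i = j + 1
        else:
            i += 1
    return best


class TestDeduceLocusInterval:
    def test_single_het_family_gives_its_max_segment(self):
        markers = _region_markers(6)
        region = GenomicInterval("7A", 1_000_000, 6_000_000)
        calls = pd.Series(["A", "A", "H", "H", "B", "B"],
                          index=[m.name for m in markers])
        fam = fm.RecombinantFamily.from_genotypes("F", calls, markers, region)
        ded = fm.deduce_locus_interval([(fam, "heterozygous")], markers, region)
        assert (ded.candidate_interval.start_bp,
                ded.candidate_interval.end_bp) == (2_000_000, 5_000_000)

    def test_reconstructed_two_phase_narrowing(self):
        """Three heterozygous families whose maximal segments all contain
        the 87-kb interval, plus two homozygous families tiling the flanks,
        bound the locus exactly by the published flanking markers."""
        names = ["IWB7435", "AX-109397893", "AX-111159341", "AX-109360122",
                 "IWA5913", "IWA5167"]
        markers = [w.marker(n) for n in names]
        region = w.NXC_INITIAL_WINDOW
        patterns = {
            # het families: H across the candidate gap
            "T13": ["A", "A", "H", "H", "H", "B"],
            "T19": ["B", "H", "H", "H", "A", "A"],
            "T27": ["A", "H", "H", "H", "H", "B"],
            # hom families: het segment ends before/after the candidate gap
            "T18": ["H", "H", "H", "A", "A", "A"],   # min seg spans left flank
            "T28": ["B", "B", "B", "H", "H", "H"],   # min seg spans right flank
        }
        labels = {"T13": "heterozygous", "T19": "heterozygous",
                  "T27": "heterozygous", "T18": "homozygous",
                  "T28": "homozygous"}
        fams = []
        for fid, pat in patterns.items():
            calls = pd.Series(pat, index=names)
            fams.append(
                (fm.RecombinantFamily.from_genotypes(fid, calls, markers, region),
                 labels[fid])
            )
        ded = fm.deduce_locus_interval(fams, markers, region)
        assert ded.left_marker == "AX-111159341"
        assert ded.right_marker == "AX-109360122"
        assert ded.candidate_interval.start_bp == 674_019_191
        assert ded.candidate_interval.end_bp == 674_106_327
        assert ded.candidate_interval.width_bp("between_markers") == 87_136
        assert ded.conflicts == []

    def test_requires_a_heterozygous_family(self):
        markers = _region_markers(3)
        region = GenomicInterval("7A", 1_000_000, 3_000_000)
        calls = pd.Series(["H", "A", "A"], index=[m.name for m in markers])
        fam = fm.RecombinantFamily.from_genotypes("F", calls, markers, region)
        with pytest.raises(ValueError, match="heterozygous"):
            fm.deduce_locus_interval([(fam, "homozygous")], markers, region)

    def test_random_consistent_constraints_match_oracle(self, rng):
        """Deduction equals the exhaustive per-gap check on randomly
        generated consistent constraint sets."""
        markers = _region_markers(8)
        region = GenomicInterval("7A", 1_000_000, 8_000_000)
        n_ok = 0
        for _ in range(200):
            locus_gap = int(rng.integers(0, 7))  # true locus inside this gap
            fams = []
            for f in range(int(rng.integers(1, 5))):
                # heterozygous family: H run covering the locus gap
                lo = int(rng.integers(0, locus_gap + 1))
                hi = int(rng.integers(locus_gap + 1, 8))
                pat = ["A"] * lo + ["H"] * (hi - lo) + ["B"] * (8 - hi)
                calls = pd.Series(pat, index=[m.name for m in markers])
                fams.append(
                    (fm.RecombinantFamily.from_genotypes(f"het{f}", calls,
                                                         markers, region),
                     "heterozygous")
                )
            for f in range(int(rng.integers(0, 4))):
                # homozygous family: H run avoiding the locus gap
                side = rng.random() < 0.5
                if side and locus_gap > 0:
                    lo, hi = 0, int(rng.integers(1, locus_gap + 1))
                elif locus_gap < 7:
                    lo = int(rng.integers(locus_gap + 1, 8))
                    hi = int(rng.integers(lo, 8))
                else:
                    continue
                if hi <= lo:
                    hi = lo + 1
                pat = ["A"] * lo + ["H"] * (hi - lo) + ["A"] * (8 - hi)
                calls = pd.Series(pat, index=[m.name for m in markers])
                fam = fm.RecombinantFamily.from_genotypes(f"hom{f}", calls,
                                                          markers, region)
                if fam.het_segment_min is not None:
                    fams.append((fam, "homozygous"))
            oracle = _oracle_deduction(fams, markers, region)
            if oracle is None:
                continue
            ded = fm.deduce_locus_interval(fams, markers, region)
            assert ded.conflicts == []
            assert (ded.candidate_interval.start_bp,
                    ded.candidate_interval.end_bp) == oracle
            # the true locus gap must lie inside the deduced interval
            lo_bp = 1_000_000 + locus_gap * 1_000_000
            assert ded.candidate_interval.start_bp <= lo_bp
            assert ded.candidate_interval.end_bp >= lo_bp + 1_000_000
            n_ok += 1
        assert n_ok >= 150

    def test_interior_hom_segment_splits_region_into_reported_pieces(self):
        """A homozygous family whose heterozygous run sits inside the
        heterozygous-family intersection splits the viable region; both
        pieces are reported (widest as candidate, rest as alternatives)."""
        markers = _region_markers(8)
        region = GenomicInterval("7A", 1_000_000, 8_000_000)
        names = [m.name for m in markers]
        het = fm.RecombinantFamily.from_genotypes(
            "het", pd.Series(["A", "H", "H", "H", "H", "H", "H", "B"],
                             index=names), markers, region)
        hom = fm.RecombinantFamily.from_genotypes(
            "hom", pd.Series(["A", "A", "A", "H", "H", "A", "A", "A"],
                             index=names), markers, region)
        ded = fm.deduce_locus_interval(
            [(het, "heterozygous"), (hom, "homozygous")], markers, region)
        assert ded.ambiguous
        pieces = sorted(
            (iv.start_bp, iv.end_bp) for iv in ded.viable_intervals()
        )
        # left piece ends at the hom family's first H marker (R3), right
        # piece starts at its last H marker (R4)
        assert pieces == [(1_000_000, 4_000_000), (5_000_000, 8_000_000)]
        # candidate is the wider piece (tie broken toward smaller bp here)
        assert (ded.candidate_interval.start_bp,
                ded.candidate_interval.end_bp) == (1_000_000, 4_000_000)

    def test_interval_monotone_as_families_added(self):
        markers = _region_markers(8)
        region = GenomicInterval("7A", 1_000_000, 8_000_000)
        pats = [
            ["A", "H", "H", "H", "H", "H", "H", "B"],
            ["A", "A", "H", "H", "H", "H", "B", "B"],
            ["A", "A", "A", "H", "H", "B", "B", "B"],
        ]
        fams = [
            (fm.RecombinantFamily.from_genotypes(f"F{i}",
                                                 pd.Series(p, index=[m.name for m in markers]),
                                                 markers, region),
             "heterozygous")
            for i, p in enumerate(pats)
        ]
        widths = []
        for k in (1, 2, 3):
            ded = fm.deduce_locus_interval(fams[:k], markers, region)
            widths.append(ded.candidate_interval.width_bp("between_markers"))
        assert widths[0] >= widths[1] >= widths[2]

    def test_flipped_label_detected_as_conflict_or_consistent_widening(self):
        """Mislabeling a family either surfaces as a reported conflict or
        yields an interval still satisfying all remaining constraints —
        never a silently inconsistent interval."""
        markers = _region_markers(8)
        region = GenomicInterval("7A", 1_000_000, 8_000_000)
        names = [m.name for m in markers]
        fams = [
            (fm.RecombinantFamily.from_genotypes(
                "h1", pd.Series(["A", "A", "H", "H", "H", "B", "B", "B"],
                                index=names), markers, region), "heterozygous"),
            (fm.RecombinantFamily.from_genotypes(
                "h2", pd.Series(["A", "A", "A", "H", "H", "H", "B", "B"],
                                index=names), markers, region), "heterozygous"),
            # hom family whose min segment covers gaps 3..4: conflicts with
            # the het intersection when flipped in
            (fm.RecombinantFamily.from_genotypes(
                "flip", pd.Series(["A", "A", "A", "H", "H", "A", "A", "A"],
                                  index=names), markers, region), "homozygous"),
        ]
        ded = fm.deduce_locus_interval(fams, markers, region)
        if not ded.conflicts:
            # the result must satisfy every kept constraint
            iv = ded.candidate_interval
            for fam, label in fams:
                if label == "heterozygous":
                    assert fam.het_segment_max.contains(iv)
                else:
                    seg = fam.het_segment_min
                    assert not (seg.start_bp < iv.end_bp and seg.end_bp > iv.start_bp)
        else:
            assert "flip" in ded.conflicts or len(ded.conflicts) >= 1


class TestPlanRescreen:
    def test_arithmetic(self):
        iv = GenomicInterval("7A", 0 + 1, 10_000_001)
        # choose calibration so expected fraction is ~0.01, then N = target/p
        plan = fm.plan_rescreen(iv, cm_per_mb=0.0505, target_new_recombinants=5)
        assert plan.n_plants == int(np.ceil(5 / plan.expected_fraction))

    def test_doubling_target_doubles_n(self):
        iv = GenomicInterval("7A", 1, 5_000_001)
        p1 = fm.plan_rescreen(iv, 0.7, 5)
        p2 = fm.plan_rescreen(iv, 0.7, 10)
        assert abs(p2.n_plants - 2 * p1.n_plants) <= 1

    def test_zero_probability_over_published_rescreen(self):
        """P(zero recombinants among 1208 plants) for the 87-kb interval
        under the calibrated map is a valid probability."""
        plan = fm.plan_rescreen(
            w.CANDIDATE_87KB, sim.default_cm_per_mb(), 1,
            n_planned=w.BXR_PHASE2_SCREENED,
        )
        assert 0.0 < plan.p_zero_recombinants < 1.0
        assert plan.p_zero_recombinants == pytest.approx(
            (1 - plan.expected_fraction) ** 1208
        )

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            fm.plan_rescreen(w.CANDIDATE_87KB, 0.7, 0)
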