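"""PWM scanning exactness, DP threshold calibration, GC-matched enrichment."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiprime.intervals import GenomicInterval, PeakSet
from epiprime.motifs import (
    PWM,
    calibrate_threshold,
    gc_matched_background,
    motif_enrichment,
    motif_set_comparison,
    nominate_tfs,
    read_pwms,
    region_gc,
    scan,
    scan_regions,
    write_pwms,
)


def sharp_pwm(consensus, p=0.97, motif_id="m"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m[j, idx[b]] = p
    return PWM(motif_id=motif_id, matrix=m)


def revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestCalibrateThreshold:
    def test_matches_exhaustive_enumeration_width4(self):
        pwm = sharp_pwm("ACGT")
        lod = pwm.log_odds()
        scores = sorted(
            (
                sum(lod[j, b] for j, b in enumerate(word))
                for word in itertools.product(range(4), repeat=4)
            ),
            reverse=True,
        )
        n = len(scores)
        for pvalue in (0.25, 0.05, 1 / 256 + 1e-9):
            thr = calibrate_threshold(pwm, pvalue, bin_width=0.001)
            tail = sum(s >= thr for s in scores) / n
            assert tail <= pvalue
            # the threshold is not needlessly strict: one grid step lower
            # would exceed the requested tail probability
            looser = sum(s >= thr - 0.01 for s in scores) / n
            assert looser > pvalue or math.isclose(looser, tail)

    def test_uniform_pwm_yields_unreachable_threshold(self):
        pwm = PWM(motif_id="u", matrix=np.full((5, 4), 0.25))
        thr = calibrate_threshold(pwm, 0.5)
        assert thr > 0.0
        assert scan(pwm, "ACGTACGTACGT", thr) == []

    def test_dp_tail_matches_monte_carlo(self, rng):
        from epiprime.motifs import null_tail_probability

        pwm = sharp_pwm("ACGTAC", p=0.8, motif_id="w6")
        pvalue = 1e-3
        thr = calibrate_threshold(pwm, pvalue)
        dp_tail = null_tail_probability(pwm, thr)
        assert dp_tail <= pvalue
        lod = pwm.log_odds()
        draws = rng.integers(0, 4, size=(1_000_000, 6))
        scores = lod[np.arange(6)[None, :], draws].sum(axis=1)
        mc = float((scores >= thr).mean())
        se = math.sqrt(max(dp_tail, 1e-9) * (1 - dp_tail) / 1_000_000)
        assert abs(mc - dp_tail) <= 3 * se

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(sharp_pwm("ACGT"), 0.0)


class TestScan:
    def test_planted_consensus_found_with_strand(self, rng):
        pwm = sharp_pwm("ACGTACGTAC")
        thr = calibrate_threshold(pwm, 1e-4)
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, 200))
        seq = seq[:50] + "ACGTACGTAC" + seq[60:]
        hits = [h for h in scan(pwm, seq, thr) if h.position == 50]
        assert hits and hits[0].strand == "+"

    def test_strand_symmetry(self, rng):
        pwm = sharp_pwm("AACCGGTTAA", p=0.9)
        thr = calibrate_threshold(pwm, 1e-3)
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, 300))
        seq = seq[:100] + "AACCGGTTAA" + seq[110:]
        fwd = len(scan(pwm, seq, thr)) > 0
        rev = len(scan(pwm, revcomp(seq), thr)) > 0
        assert fwd and rev  # region-level hit survives reverse complementation

    def test_scores_match_naive_window_sum(self, rng):
        pwm = sharp_pwm("ACGTA", p=0.7)
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, 100))
        lod = pwm.log_odds()
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        hits = scan(pwm, seq, threshold=-1e9)
        by_pos = {h.position: h for h in hits}
        for i in range(len(seq) - 5 + 1):
            window = seq[i : i + 5]
            f = sum(lod[j, idx[b]] for j, b in enumerate(window))
            r = sum(lod[j, idx[b]] for j, b in enumerate(revcomp(window)))
            assert by_pos[i].score == pytest.approx(max(f, r), abs=1e-9)

    def test_n_windows_skipped(self):
        pwm = sharp_pwm("ACGT")
        assert scan(pwm, "ACNT" * 3, threshold=-100) == [] or all(
            "N" not in "ACNT"[h.position : h.position + 4] for h in scan(pwm, "ACNT" * 3, -100)
        )

    def test_short_sequence_no_hits(self):
        pwm = sharp_pwm("ACGTACGT")
        assert scan(pwm, "ACG", threshold=-100) == []


class TestGCMatchedBackground:
    def _genome(self, rng, length=200_000):
        # GC gradient along the chromosome
        seq = []
        for i in range(length):
            gc = 0.2 + 0.6 * i / length
            seq.append(rng.choice(list("GC")) if rng.random() < gc else rng.choice(list("AT")))
        return {"chr1": "".join(seq)}

    def test_counts_and_determinism(self, rng):
        genome = self._genome(rng)
        targets = PeakSet(
            [GenomicInterval("chr1", 1000 * i, 1000 * i + 200, name=f"t{i}") for i in range(100)]
        )
        pool = PeakSet(
            [
                GenomicInterval("chr1", 1000 * i + off, 1000 * i + off + 200, name=f"p{i}_{off}")
                for i in range(199)
                for off in (300, 550)
            ]
        )
        bg1 = gc_matched_background(targets, pool, genome, ratio=1, bins=5, seed=3)
        bg2 = gc_matched_background(targets, pool, genome, ratio=1, bins=5, seed=3)
        assert len(bg1) == 100
        assert bg1 == bg2

    def test_gc_distribution_matched(self, rng):
        genome = self._genome(rng)
        # targets concentrated in the GC-rich half
        targets = PeakSet(
            [GenomicInterval("chr1", 100_000 + 800 * i, 100_000 + 800 * i + 200) for i in range(100)]
        )
        pool = PeakSet(
            [GenomicInterval("chr1", 211 * i, 211 * i + 200) for i in range(900)]
        )
        bg = gc_matched_background(targets, pool, genome, ratio=2, bins=5, seed=7)
        t_gc = region_gc(targets, genome)
        b_gc = region_gc(bg, genome)
        assert abs(np.mean(b_gc) - np.mean(t_gc)) < 0.04

    def test_empty_targets_rejected(self, rng):
        genome = self._genome(rng, 10_000)
        with pytest.raises(ValueError):
            gc_matched_background(PeakSet([]), PeakSet([]), genome)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


class TestMotifEnrichment:
    def _fixture(self, rng, n_target=10, n_bg=15, target_hit=5, bg_hit=3):
        pwm = sharp_pwm("ACGTACGTAC", motif_id="planted")
        genome = {"chr1": "".join(rng.choice(np.array(list("ACGT")), 50_000))}
        ivs = []
        for i in range(n_target + n_bg):
            s = 1000 * i
            ivs.append(GenomicInterval("chr1", s, s + 200, name=f"r{i}"))
        hits = list(range(target_hit)) + [n_target + j for j in range(bg_hit)]
        g = list(genome["chr1"])
        for i in hits:
            g[1000 * i + 90 : 1000 * i + 100] = "ACGTACGTAC"
        genome["chr1"] = "".join(g)
        targets = PeakSet(ivs[:n_target], label="t")
        background = PeakSet(ivs[n_target:], label="b")
        # a strict threshold keeps accidental near-consensus matches out so
        # the planted hit counts are exact
        thresholds = {"planted": calibrate_threshold(pwm, 1e-6)}
        return pwm, genome, targets, background, thresholds

    def test_p_matches_exhaustive_enumeration(self, rng):
        pwm, genome, targets, background, thr = self._fixture(rng)
        table = motif_enrichment(targets, background, genome, [pwm], thresholds=thr)
        k, N = 5, 25
        K, n = 5 + 3, 10
        want = hypergeom_tail_oracle(k, N, K, n)
        assert table.loc["planted", "p"] == pytest.approx(want, rel=1e-9)
        assert table.loc["planted", "n_target_hit"] == 5
        assert table.loc["planted", "n_bg_hit"] == 3

    def test_equal_fractions_not_enriched(self, rng):
        pwm, genome, targets, background, thr = self._fixture(
            rng, n_target=10, n_bg=10, target_hit=4, bg_hit=4
        )
        table = motif_enrichment(targets, background, genome, [pwm], thresholds=thr)
        assert table.loc["planted", "odds_ratio"] == pytest.approx(1.0)
        assert not table.loc["planted", "enriched"]

    def test_extreme_tail_is_minimal_p(self, rng):
        pwm, genome, targets, background, thr = self._fixture(
            rng, n_target=8, n_bg=20, target_hit=8, bg_hit=0
        )
        table = motif_enrichment(targets, background, genome, [pwm], thresholds=thr)
        want = hypergeom_tail_oracle(8, 28, 8, 8)
        assert table.loc["planted", "p"] == pytest.approx(want, rel=1e-9)

    def test_empty_targets_rejected(self, rng):
        pwm, genome, _, background, thr = self._fixture(rng)
        with pytest.raises(ValueError):
            motif_enrichment(PeakSet([]), background, genome, [pwm], thresholds=thr)


class TestMotifSetComparison:
    def test_identical_sets(self):
        part = motif_set_comparison({"a", "b"}, {"a", "b"})
        assert part == {"unique_a": set(), "unique_b": set(), "common": {"a", "b"}}

    def test_disjoint_sets(self):
        part = motif_set_comparison({"a"}, {"b"})
        assert part["common"] == set()

    def test_random_sets_match_membership_oracle(self, rng):
        universe = [f"m{i}" for i in range(50)]
        a = {m for m in universe if rng.random() < 0.4}
        b = {m for m in universe if rng.random() < 0.4}
        part = motif_set_comparison(a, b)
        for m in universe:
            assert (m in part["common"]) == (m in a and m in b)
            assert (m in part["unique_a"]) == (m in a and m not in b)
            assert (m in part["unique_b"]) == (m in b and m not in a)
        counts = sum(len(v) for v in part.values())
        assert counts == len(a | b)


class TestNominateTFs:
    def _tables(self):
        astro = pd.DataFrame(
            {
                "p": [1e-8, 1e-6, 0.5],
                "enriched": [True, True, False],
            },
            index=["m_unique", "m_common", "m_dull"],
        )
        neuro = pd.DataFrame(
            {"p": [0.9, 1e-5, 0.8], "enriched": [False, True, False]},
            index=astro.index,
        )
        return astro, neuro

    def test_unique_ranked_before_common(self):
        astro, neuro = self._tables()
        expr = pd.DataFrame({"eA": [5.0, 5.0]}, index=["tfU", "tfC"])
        nom = nominate_tfs(
            astro, neuro, expr, "eA", {"m_unique": "tfU", "m_common": "tfC"}
        )
        assert list(nom["motif_id"]) == ["m_unique", "m_common"]
        assert list(nom["category"]) == ["unique", "common"]

    def test_unexpressed_tf_filtered(self):
        astro, neuro = self._tables()
        expr = pd.DataFrame({"eA": [0.0]}, index=["tfU"])
        nom = nominate_tfs(astro, neuro, expr, "eA", {"m_unique": "tfU"})
        assert "m_unique" not in list(nom["motif_id"])

    def test_unmappable_motif_retained_and_flagged(self):
        astro, neuro = self._tables()
        expr = pd.DataFrame({"eA": []})
        nom = nominate_tfs(astro, neuro, expr, "eA", {})
        row = nom[nom["motif_id"] == "m_unique"].iloc[0]
        assert not row["mappable"]


def test_pwm_file_round_trip(tmp_path, dataset):
    path = tmp_path / "pwms.txt"
    write_pwms(dataset.pwm_library, path)
    back = read_pwms(path)
    assert len(back) == len(dataset.pwm_library)
    for a, b in zip(back, dataset.pwm_library):
        assert a.motif_id == b.motif_id and a.tf_name == b.tf_name
        assert np.allclose(a.matrix, b.matrix, atol=1e-6)


def test_planted_instances_score_above_threshold(dataset):
    """Every planted motif instance rescans above its calibrated threshold."""
    truth = dataset.truth
    pwms = {p.motif_id: p for p in dataset.pwm_library}
    for motif_id, cls in (("M_EA1", "eA_unique"), ("M_LA1", "lA_unique")):
        pwm = pwms[motif_id]
        thr = calibrate_threshold(pwm, 1e-4)
        carriers = truth.enhancers[
            truth.enhancers["motifs"].str.contains(motif_id)
        ]
        regions = PeakSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end), name=i)
                for i, r in carriers.iterrows()
            ]
        )
        hit = scan_regions(pwm, regions, dataset.genome, thr)
        assert hit.all()
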