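"""Tests of QC, homozygosity-deficit statistics and the window scan."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lethalscan.scan import (
    QCThresholds,
    WindowSpec,
    deficit_test,
    enumerate_window_haplotypes,
    expected_homozygotes_freq,
    expected_homozygotes_trio,
    finemap_recombinants,
    hwe_exact_test,
    qc_filter,
    scan,
)
from lethalscan.synthetic_data import SimConfig, plant_lethal, simulate_founders
from lethalscan.types import CandidateHaplotype, Pedigree, PhasedGenotypes


def brute_force_hwe(n_hom_ref, n_het, n_hom_alt):
    """Independent oracle: full enumeration of the conditional distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het  # allele-1 count
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom1 = (n_a - het) // 2
        hom2 = n - het - hom1
        if hom1 < 0 or hom2 < 0:
            continue
        logp = (math.lgamma(n + 1) - math.lgamma(hom1 + 1) - math.lgamma(het + 1)
                - math.lgamma(hom2 + 1) + het * math.log(2)
                + math.lgamma(n_a + 1) + math.lgamma(2 * n - n_a + 1)
                - math.lgamma(2 * n + 1))
        probs[het] = math.exp(logp)
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWEExact:
    def test_perfect_proportions_give_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_total_heterozygote_deficit_is_extreme(self):
        p = hwe_exact_test(50, 0, 50)
        assert p < 1e-20
        assert p == pytest.approx(brute_force_hwe(50, 0, 50), rel=1e-9)

    def test_monomorphic_marker_returns_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(12, 30, 9), (3, 2, 40), (0, 11, 4),
                                        (7, 0, 7), (100, 180, 95)])
    def test_matches_full_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            brute_force_hwe(*counts), rel=1e-9)


class TestExpectedHomozygotes:
    @pytest.mark.parametrize("c, n, expected", [
        (3763, 28085, 126.0),   # largest Landrace haplotype
        (2358, 28085, 49.5),
        (1319, 28085, 15.5),
        (1271, 28085, 14.4),
        (1084, 11255, 26.1),    # the Duroc haplotype
    ])
    def test_frequency_based_expectations(self, c, n, expected):
        assert expected_homozygotes_freq(c, n) == pytest.approx(expected, abs=0.05)

    def test_zero_carriers(self):
        assert expected_homozygotes_freq(0, 1000) == 0.0

    def test_homozygote_carriers_add_two_alleles(self):
        # f = (C + 2*hom) / 2N before squaring
        assert expected_homozygotes_freq(10, 100, n_hom=5) == pytest.approx(
            100 * (20 / 200) ** 2)

    @given(st.integers(0, 5000), st.integers(1, 50000))
    @settings(max_examples=50, deadline=None)
    def test_algebraic_identity(self, c, n):
        if c > n:
            c = n
        f = c / (2 * n)
        assert expected_homozygotes_freq(c, n) == pytest.approx(n * f * f, rel=1e-12)


def trio_pedigree(n_offspring, carrier_parents=True):
    base = pd.Timestamp("2012-01-01")
    rows = [{"animal": "S", "sire": None, "dam": None, "sex": "M", "birthdate": base},
            {"animal": "D", "sire": None, "dam": None, "sex": "F", "birthdate": base}]
    for i in range(n_offspring):
        rows.append({"animal": f"O{i}", "sire": "S", "dam": "D", "sex": "F",
                     "birthdate": base + pd.DateOffset(years=1)})
    ped = Pedigree(pd.DataFrame(rows))
    status = {"S": 1 if carrier_parents else 0, "D": 1 if carrier_parents else 0}
    status.update({f"O{i}": 1 for i in range(n_offspring)})
    return ped, status


class TestTrioExpectation:
    @pytest.mark.parametrize("n_off, expected", [(208, 52.0), (73, 18.25),
                                                 (24, 6.0), (28, 7.0)])
    def test_quarter_per_cxc_offspring(self, n_off, expected):
        ped, status = trio_pedigree(n_off)
        e, n_cxc = expected_homozygotes_trio(
            ped, status, {f"O{i}" for i in range(n_off)})
        assert e == pytest.approx(expected)
        assert n_cxc == n_off

    def test_noncarrier_parents_contribute_zero(self):
        ped, status = trio_pedigree(10, carrier_parents=False)
        e, n_cxc = expected_homozygotes_trio(ped, status, {f"O{i}" for i in range(10)})
        assert e == 0.0 and n_cxc == 0

    def test_empty_offspring(self):
        ped, status = trio_pedigree(5)
        assert expected_homozygotes_trio(ped, status, set()) == (0.0, 0)

    def test_extended_mode_uses_hap_freq_for_unknown_parent(self):
        ped, status = trio_pedigree(4)
        del status["D"]
        e, n_cxc = expected_homozygotes_trio(
            ped, status, {f"O{i}" for i in range(4)}, hap_freq=0.1)
        assert e == pytest.approx(4 * 0.5 * 0.1)
        assert n_cxc == 0


class TestDeficitTest:
    def test_zero_observed_closed_form(self):
        assert deficit_test(0, 38, 0.25) == pytest.approx(0.75 ** 38, rel=1e-12)

    def test_observed_equals_n(self):
        assert deficit_test(20, 20, 0.25) == 1.0

    def test_matches_brute_force_pmf_sum(self):
        expected = sum(math.comb(20, k) * 0.25 ** k * 0.75 ** (20 - k)
                       for k in range(3))
        assert deficit_test(2, 20, 0.25) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(2, 2000), st.floats(1e-4, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_no_homozygote_closed_form(self, n, p):
        assert deficit_test(0, n, p) == pytest.approx((1 - p) ** n, rel=1e-9)

    def test_monotone_in_carriers_at_zero_observed(self):
        n = 5000
        ps = [deficit_test(0, n, (c / (2 * n)) ** 2) for c in (200, 400, 800, 1600)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


def toy_genotypes(alleles, positions=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m, _ = alleles.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 100_000
    mm = pd.DataFrame({"chrom": chrom, "pos": positions, "ref": "A", "alt": "B"})
    ids = np.array([f"a{i}" for i in range(n)])
    return PhasedGenotypes(ids, mm, alleles)


class TestQCFilter:
    def test_low_maf_marker_removed(self):
        rng = np.random.default_rng(0)
        a = (rng.random((200, 5, 2)) < 0.3).astype(np.int8)
        a[:, 2, :] = 0
        a[0, 2, :] = 1  # MAF 0.005
        g = toy_genotypes(a)
        g2, report = qc_filter(g)
        assert report["markers_removed_maf"] == 1
        assert g2.n_markers == 4

    def test_clean_panel_unchanged(self):
        rng = np.random.default_rng(1)
        a = (rng.random((300, 8, 2)) < 0.4).astype(np.int8)
        g = toy_genotypes(a)
        g2, report = qc_filter(g)
        assert g2.n_markers == 8 and g2.n_animals == 300

    def test_low_callrate_animal_removed_first(self):
        rng = np.random.default_rng(2)
        a = (rng.random((50, 10, 2)) < 0.4).astype(np.int8)
        a[0, :6, :] = -1  # 40% call rate
        g = toy_genotypes(a)
        g2, report = qc_filter(g)
        assert report["animals_removed_callrate"] == 1
        assert g2.n_animals == 49

    def test_lethal_tagging_marker_survives_liberal_but_not_under_strict_alpha(self):
        # a marker in complete LD with a 13.4%-carrier lethal: het excess,
        # zero minor homozygotes. HWE p sits between 1e-30 and 1e-5, so the
        # liberal 1e-5 filter removes it and the strict 1e-30 re-scan keeps it
        n, carriers = 5000, 670
        p = hwe_exact_test(n - carriers, carriers, 0)
        assert 1e-30 < p < 1e-5
        a = np.zeros((n, 3, 2), dtype=np.int8)
        rng = np.random.default_rng(3)
        a[:, 0, :] = rng.random((n, 2)) < 0.4
        a[:, 2, :] = rng.random((n, 2)) < 0.4
        a[:carriers, 1, 0] = 1  # tag marker: heterozygous in carriers only
        g = toy_genotypes(a)
        _, liberal = qc_filter(g, QCThresholds())
        assert liberal["markers_removed_hwe"] == 1
        g2, strict = qc_filter(g, QCThresholds(hwe_alpha=1e-30))
        assert strict["markers_removed_hwe"] == 0
        assert g2.n_markers == 3

    def test_all_markers_removed_raises(self):
        a = np.zeros((100, 2, 2), dtype=np.int8)  # monomorphic: MAF 0
        with pytest.raises(ValueError):
            qc_filter(toy_genotypes(a))


class TestEnumerateWindows:
    def test_hand_enumeration(self):
        # animal 0 carries A/B, animal 1 carries A/A where A=(0,1), B=(1,0)
        a = np.array([[[0, 1], [1, 0]],
                      [[0, 0], [1, 1]]], dtype=np.int8)
        g = toy_genotypes(a)
        wh = enumerate_window_haplotypes(g, "1", 1, 10_000_000)
        table = wh.as_map()
        assert table[(0, 1)][0] == 3 and table[(0, 1)][1] == 1
        assert table[(1, 0)][0] == 1 and table[(1, 0)][1] == 0
        assert wh.n_genotyped == 2

    def test_missing_call_excludes_animal(self):
        a = np.array([[[0, 0], [1, 1]],
                      [[-1, -1], [1, 1]]], dtype=np.int8)
        g = toy_genotypes(a)
        wh = enumerate_window_haplotypes(g, "1", 1, 10_000_000)
        assert wh.n_genotyped == 1

    def test_all_missing_window_is_empty(self):
        a = np.full((3, 2, 2), -1, dtype=np.int8)
        g = toy_genotypes(a)
        wh = enumerate_window_haplotypes(g, "1", 1, 10_000_000)
        assert wh.n_genotyped == 0 and len(wh.counts) == 0

    def test_single_marker_window_skipped(self):
        a = np.zeros((3, 2, 2), dtype=np.int8)
        g = toy_genotypes(a, positions=[100, 5_000_000])
        with pytest.warns(UserWarning, match="skipped"):
            assert enumerate_window_haplotypes(g, "1", 1, 200) is None


class TestScan:
    def test_planted_lethal_recovered(self, small_planted):
        cfg, genotypes, lethal = small_planted
        candidates = scan(genotypes)
        overlapping = [c for c in candidates
                       if c.merged_start_bp < lethal.window_end_bp
                       and c.merged_end_bp > lethal.window_start_bp]
        assert len(overlapping) == 1
        cand = overlapping[0]
        assert cand.homozygotes_observed == 0
        assert cand.p_deficit < 5e-3
        assert cand.carriers == lethal.carrier_count

    def test_unphased_input_rejected(self, small_planted, rng):
        _, genotypes, _ = small_planted
        scrambled = genotypes.scramble_phase(rng)
        with pytest.raises(ValueError, match="phased"):
            scan(scrambled)

    def test_underpowered_low_frequency_not_detected(self):
        # at 2% carriers in 1000 animals the expected homozygote count is
        # ~0.1, so the binomial test cannot reach the threshold
        cfg = SimConfig(n_boars=30, n_sows=970, n_markers=120,
                        chrom_length_bp=6_000_000, lethal_position_bp=3_000_000,
                        target_carrier_freq=0.02, seed=77)
        rng = cfg.rng()
        g, lethal = plant_lethal(simulate_founders(cfg, rng), cfg, rng)
        candidates = scan(g)
        overlapping = [c for c in candidates
                       if c.merged_start_bp < lethal.window_end_bp
                       and c.merged_end_bp > lethal.window_start_bp
                       and c.carriers > 0.5 * lethal.carrier_count]
        assert not overlapping

    def test_null_false_positive_rate_bounded(self):
        spec = WindowSpec(sizes_bp=(500_000, 1_000_000, 2_000_000))
        total_candidates = 0
        total_tests = 0
        for seed in range(10):
            cfg = SimConfig(n_boars=20, n_sows=380, n_markers=100,
                            chrom_length_bp=5_000_000, lethal_position_bp=2_500_000,
                            target_carrier_freq=0.0, seed=400 + seed)
            g = simulate_founders(cfg)
            total_candidates += len(scan(g, windows=spec))
            # oracle count of (window, haplotype) tests actually performed
            from lethalscan.scan import _iter_windows
            for chrom, s, e in _iter_windows(g.marker_map, spec):
                wh = enumerate_window_haplotypes(g, chrom, s, e)
                if wh is not None and wh.n_genotyped:
                    f = wh.counts / (2 * wh.n_genotyped)
                    total_tests += int((f >= spec.min_hap_freq).sum())
        assert total_candidates <= spec.alpha * total_tests

    def test_permutation_invariance(self, small_planted):
        _, genotypes, _ = small_planted
        perm = np.random.default_rng(5).permutation(genotypes.n_animals)
        shuffled = genotypes.take_animals(perm)
        a = scan(genotypes)
        b = scan(shuffled)
        key = lambda c: (c.start_bp, c.end_bp, c.carriers,
                         c.homozygotes_observed, round(c.p_deficit, 12))
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_trio_statistics_attached_with_pedigree(self, small_planted):
        cfg, genotypes, lethal = small_planted
        # synthesize CxC offspring: both parents carriers, offspring het
        base = pd.Timestamp("2012-01-01")
        carriers = np.flatnonzero(lethal.hap_carriage.sum(axis=1) == 1)
        rows = [{"animal": a, "sire": None, "dam": None, "sex": "M",
                 "birthdate": base} for a in genotypes.animal_ids]
        ids = genotypes.animal_ids
        for k in range(20):
            child = ids[carriers[2 * k]]
            rows = [r if r["animal"] != child else
                    {"animal": child, "sire": ids[carriers[40 + k]],
                     "dam": ids[carriers[60 + k]], "sex": "F",
                     "birthdate": base + pd.DateOffset(years=1)}
                    for r in rows]
        ped = Pedigree(pd.DataFrame(rows))
        candidates = scan(genotypes, pedigree=ped)
        cand = [c for c in candidates
                if c.merged_start_bp < lethal.window_end_bp
                and c.merged_end_bp > lethal.window_start_bp][0]
        assert cand.cxc_progeny == 20
        assert cand.expected_trio == pytest.approx(0.25 * 20)
        assert cand.cxc_het_progeny == 20  # children were picked among carriers
        assert cand.p_trio == pytest.approx(0.75 ** 20, rel=1e-9)


class TestScanPower:
    def test_detection_monotone_in_frequency_and_sample_size(self):
        spec = WindowSpec(sizes_bp=(500_000, 1_000_000, 2_000_000))
        freqs = (0.05, 0.13)
        sizes = (600, 2000)
        detections = {}
        for cf in freqs:
            for n in sizes:
                hit = 0
                for rep in range(6):
                    cfg = SimConfig(n_boars=max(10, n // 40), n_sows=n - max(10, n // 40),
                                    n_markers=120, chrom_length_bp=6_000_000,
                                    lethal_position_bp=3_000_000,
                                    target_carrier_freq=cf, seed=1000 + rep)
                    rng = cfg.rng()
                    g, lethal = plant_lethal(simulate_founders(cfg, rng), cfg, rng)
                    cands = scan(g, windows=spec)
                    hit += any(c.merged_start_bp < lethal.window_end_bp
                               and c.merged_end_bp > lethal.window_start_bp
                               and c.carriers > 0.5 * lethal.carrier_count
                               for c in cands)
                detections[(cf, n)] = hit
        assert detections[(0.13, 2000)] >= detections[(0.05, 2000)]
        assert detections[(0.13, 2000)] >= detections[(0.13, 600)]
        assert detections[(0.13, 2000)] == 6  # full power at the study design


class TestFinemap:
    def _candidate(self, n_markers=50, span=5_000_000):
        positions = (np.arange(n_markers) + 1) * (span // n_markers)
        hap = np.ones(n_markers, dtype=np.int8)
        return positions, hap

    def build(self, carriers_hom_tail):
        """20 animals; 10 carriers; optionally homozygous for the tail 2 Mb."""
        n_markers, span = 50, 5_000_000
        positions, hap = self._candidate(n_markers, span)
        rng = np.random.default_rng(8)
        a = (rng.random((20, n_markers, 2)) < 0.3).astype(np.int8)
        tail = positions >= 3_000_000
        for i in range(10):
            a[i, :, 0] = hap
            a[i, :, 1] = 0
            if carriers_hom_tail and i < 2:
                a[i, tail, 1] = 1  # homozygous for the last two sub-haplotypes
        g = toy_genotypes(a, positions=positions)
        cand = CandidateHaplotype(
            name="X", chrom="1", start_bp=1, end_bp=span + 1, hap_alleles=hap,
            marker_idx=np.arange(n_markers), n_genotyped=20, carriers=10,
            homozygotes_observed=0, hap_freq=0.25, expected_freq=1.25,
            p_deficit=1e-4, carrier_animals=np.arange(10))
        return g, cand

    def test_homozygous_tail_excluded(self):
        g, cand = self.build(carriers_hom_tail=True)
        refined = finemap_recombinants(cand, g, 1_000_000)
        assert refined == (1, 3_000_001)  # first 3 Mb survive

    def test_no_recombinants_leaves_interval_unchanged(self):
        g, cand = self.build(carriers_hom_tail=False)
        refined = finemap_recombinants(cand, g, 1_000_000)
        assert refined == (1, 5_000_001)

    def test_all_homozygous_flagged_empty(self):
        g, cand = self.build(carriers_hom_tail=False)
        g.alleles[:10, :, 1] = 1  # every carrier homozygous everywhere
        with pytest.warns(UserWarning, match="empty"):
            assert finemap_recombinants(cand, g, 1_000_000) is None

    def test_short_span_rejected(self):
        g, cand = self.build(carriers_hom_tail=False)
        with pytest.raises(ValueError):
            finemap_recombinants(cand, g, 4_000_000)
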