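"""Sliding-window scan for haplotypes with missing or deficit homozygosity.

A recessive lethal allele riding a haplotype removes its homozygotes
before birth, so among genotyped animals the haplotype shows fewer
homozygotes than Hardy-Weinberg (or Mendelian trio transmission)
predicts. The scan enumerates window haplotypes by exact allele-vector
match over overlapping windows of 0.5-5 Mb, computes the expected
homozygote count two ways — from haplotype frequency (N·f²) and from
carrier-by-carrier trio transmission (0.25 per genotyped CxC offspring) —
and applies a one-sided lower-tail exact binomial test to the observed
count. Significant windows tagging the same carrier set are merged into
candidates; recombinant carriers then refine the causal interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import MISSING, CandidateHaplotype, Pedigree, PhasedGenotypes

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Marker/animal quality-control thresholds.

    Markers failing minor-allele frequency, call rate, or the
    Hardy-Weinberg exact test (p < hwe_alpha) are dropped after animals
    below the animal call-rate floor are removed. ``hwe_alpha`` at the
    default 1e-5 is deliberately liberal; a strict re-scan mode (1e-30)
    retains even markers with extreme homozygote deficits, which is what
    a lethal-tagging marker in near-complete LD would show.
    """

    maf_min: float = 0.01
    marker_callrate_min: float = 0.85
    animal_callrate_min: float = 0.7
    hwe_alpha: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_callrate_min", "animal_callrate_min",
                     "hwe_alpha"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class WindowSpec:
    """Sliding-window layout and significance settings for the scan."""

    sizes_bp: tuple[int, ...] = (500_000, 1_000_000, 2_000_000, 5_000_000)
    step_fraction: float = 0.5
    min_hap_freq: float = 0.005
    alpha: float = 5e-3
    refine: bool = True   # consensus-extend merged candidates to the full
                          # shared haplotype before reporting

    def __post_init__(self) -> None:
        if not all(500_000 <= s <= 5_000_000 for s in self.sizes_bp):
            raise ValueError("window sizes must lie within [0.5, 5] Mb")
        if not (0 < self.step_fraction <= 1):
            raise ValueError("step_fraction must lie in (0, 1]")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic marker.

    Two-sided conditional exact formulation: given the allele counts, sum
    the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count. Monomorphic
    markers return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # conditional pmf over heterozygote counts with matching parity,
    # built by the standard recurrence from the mode
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    mode = int(round(n_rare * (2 * n - n_rare) / (2 * n - 1)))
    if mode % 2 != n_rare % 2:
        mode += 1
    mode = int(np.clip(mode, het_values[0], het_values[-1]))
    probs = {mode: 1.0}
    h = mode
    while h - 2 >= het_values[0]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mode
    while h + 2 <= het_values[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 1) * (h + 2))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def expected_homozygotes_freq(carriers: int, n_genotyped: int,
                              n_hom: int = 0) -> float:
    """Hardy-Weinberg expected homozygote count from carrier counts.

    With all carriers heterozygous this is C²/(4N), i.e. N·f² with
    f = C/(2N). Observed homozygote carriers, if supplied, contribute two
    alleles each to the haplotype frequency before squaring.
    """
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    if not (0 <= carriers <= n_genotyped):
        raise ValueError("carrier count must lie in [0, N]")
    f = (carriers + 2 * n_hom) / (2 * n_genotyped)
    return n_genotyped * f * f


def expected_homozygotes_trio(pedigree: Pedigree, carrier_status: dict,
                              genotyped_offspring: set,
                              hap_freq: float | None = None) -> tuple[float, int]:
    """Trio-based expected homozygote count.

    Sums, over genotyped offspring, the product of the parental
    transmission probabilities: 1/2 for a heterozygous-carrier parent, 0
    for a known non-carrier. In the default mode (``hap_freq`` None) only
    offspring of two carrier parents count, 0.25 each. The extended mode
    substitutes the population haplotype frequency for parents of unknown
    status. Returns (expected count, number of CxC genotyped offspring).
    """
    parents = pedigree.parents_of()
    expected = 0.0
    n_cxc = 0
    for child in genotyped_offspring:
        if child not in parents.index:
            continue
        sire, dam = parents.loc[child, "sire"], parents.loc[child, "dam"]
        if pd.isna(sire) or pd.isna(dam):
            continue
        pr = 1.0
        cxc = True
        for parent in (sire, dam):
            status = carrier_status.get(parent)
            if status is None:
                cxc = False
                if hap_freq is None:
                    pr = 0.0
                else:
                    pr *= hap_freq
            elif status == 1:
                pr *= 0.5
            elif status == 2:  # homozygous carrier transmits with certainty
                pr *= 1.0
            else:
                pr = 0.0
                cxc = False
        expected += pr
        if cxc and carrier_status.get(sire) == 1 and carrier_status.get(dam) == 1:
            n_cxc += 1
    return expected, n_cxc


def deficit_test(observed: int, n: int, p: float) -> float:
    """One-sided lower-tail exact binomial P(X <= observed | n, p)."""
    if not (0 <= observed <= n):
        raise ValueError("observed must lie in [0, n]")
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    return float(stats.binom.cdf(observed, n, p))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(genotypes: PhasedGenotypes, thresholds: QCThresholds | None = None
              ) -> tuple[PhasedGenotypes, dict]:
    """Apply animal and marker quality control.

    Animals below the animal call-rate floor go first; then markers
    failing MAF, marker call rate, or the Hardy-Weinberg exact test.
    Returns the filtered genotypes and a report of removals per criterion.
    """
    thr = thresholds or QCThresholds()
    if genotypes.n_animals == 0 or genotypes.n_markers == 0:
        raise ValueError("empty genotype set")
    called = genotypes.alleles[:, :, 0] != MISSING

    animal_cr = called.mean(axis=1)
    keep_animals = animal_cr >= thr.animal_callrate_min
    g = genotypes.take_animals(np.flatnonzero(keep_animals))
    called = g.alleles[:, :, 0] != MISSING

    dos = g.alleles.sum(axis=2).astype(float)
    dos[~called] = np.nan
    n_called = called.sum(axis=0)
    marker_cr = n_called / g.n_animals
    with np.errstate(invalid="ignore"):
        af = np.nansum(dos, axis=0) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(af, 1 - af)

    fail_cr = marker_cr < thr.marker_callrate_min
    fail_maf = (~fail_cr) & (maf < thr.maf_min)
    fail_hwe = np.zeros(g.n_markers, dtype=bool)
    for j in np.flatnonzero(~(fail_cr | fail_maf)):
        d = dos[called[:, j], j]
        n_hom_ref = int((d == 0).sum())
        n_het = int((d == 1).sum())
        n_hom_alt = int((d == 2).sum())
        if hwe_exact_test(n_hom_ref, n_het, n_hom_alt) < thr.hwe_alpha:
            fail_hwe[j] = True

    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("all markers removed by QC")
    report = {
        "animals_removed_callrate": int((~keep_animals).sum()),
        "markers_removed_callrate": int(fail_cr.sum()),
        "markers_removed_maf": int(fail_maf.sum()),
        "markers_removed_hwe": int(fail_hwe.sum()),
        "animals_kept": int(keep_animals.sum()),
        "markers_kept": int(keep.sum()),
    }
    return g.take_markers(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# window haplotype enumeration
# ---------------------------------------------------------------------------

@dataclass
class WindowHaplotypes:
    """Haplotype table for one window: rows are distinct allele vectors."""

    chrom: object
    start_bp: int
    end_bp: int
    marker_idx: np.ndarray
    haplotypes: np.ndarray        # (n_hap, n_markers) int8
    counts: np.ndarray            # copies among complete animals
    hom_counts: np.ndarray        # animals carrying two copies
    pair: np.ndarray              # (n_complete, 2) haplotype index per haploid
    animals: np.ndarray           # genotype-array indices of complete animals
    n_genotyped: int              # animals fully called in the window

    def het_carriers(self, h: int) -> np.ndarray:
        """Animal indices carrying exactly one copy of haplotype ``h``."""
        one = (self.pair == h).sum(axis=1) == 1
        return self.animals[one]

    def hom_animals(self, h: int) -> np.ndarray:
        """Animal indices carrying two copies of haplotype ``h``."""
        return self.animals[(self.pair == h).all(axis=1)]

    def as_map(self) -> dict:
        """haplotype tuple -> (copy count, homozygote count, carrier set)."""
        return {
            tuple(self.haplotypes[h]): (int(self.counts[h]),
                                        int(self.hom_counts[h]),
                                        set(self.het_carriers(h).tolist()))
            for h in range(len(self.counts))
        }


def enumerate_window_haplotypes(genotypes: PhasedGenotypes, chrom,
                                start_bp: int, end_bp: int,
                                marker_idx: np.ndarray | None = None
                                ) -> WindowHaplotypes | None:
    """Count exact-match haplotypes over one window.

    Haplotype identity is the full allele vector over the window's
    markers; an animal missing any call in the window is excluded from
    the counts. Windows with fewer than two markers are skipped (None).
    """
    if marker_idx is None:
        marker_idx = genotypes.marker_indices(chrom, start_bp, end_bp)
    if len(marker_idx) < 2:
        warnings.warn(f"window {chrom}:{start_bp}-{end_bp} has <2 markers; skipped")
        return None
    window = genotypes.alleles[:, marker_idx, :]
    complete = ~np.any(window == MISSING, axis=(1, 2))
    animals = np.flatnonzero(complete)
    if len(animals) == 0:
        return WindowHaplotypes(chrom, start_bp, end_bp, marker_idx,
                                np.empty((0, len(marker_idx)), np.int8),
                                np.array([], int), np.array([], int),
                                np.empty((0, 2), int), animals, 0)
    haps = np.swapaxes(window[complete], 1, 2).reshape(-1, len(marker_idx))
    uniq, inverse, counts = np.unique(haps, axis=0, return_inverse=True,
                                      return_counts=True)
    pair = inverse.reshape(-1, 2)
    hom = pair[:, 0] == pair[:, 1]
    hom_counts = np.bincount(pair[hom, 0], minlength=len(uniq))
    return WindowHaplotypes(chrom, start_bp, end_bp, marker_idx, uniq, counts,
                            hom_counts, pair, animals, int(len(animals)))


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

@dataclass
class _Hit:
    chrom: object
    start_bp: int
    end_bp: int
    hap: np.ndarray
    marker_idx: np.ndarray
    n: int
    carriers: int
    observed: int
    freq: float
    expected: float
    p: float
    carrier_set: frozenset
    carrier_animals: np.ndarray


def _iter_windows(marker_map: pd.DataFrame, windows: WindowSpec):
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        lo = int(grp["pos"].iloc[0])
        hi = int(grp["pos"].iloc[-1])
        for size in windows.sizes_bp:
            step = max(1, int(size * windows.step_fraction))
            start = lo
            while start <= hi:
                yield chrom, start, start + size
                start += step


def scan(genotypes: PhasedGenotypes, pedigree: Pedigree | None = None,
         windows: WindowSpec | None = None) -> list[CandidateHaplotype]:
    """Genome scan for deficit-of-homozygosity haplotypes.

    Every haplotype above ``min_hap_freq`` in every window is tested with
    the exact binomial deficit test at (n = N, p = f²). Significant
    windows are merged into one candidate when their spans intersect and
    their carrier sets overlap with Jaccard >= 0.8; the reported statistics
    come from the merged group's smallest-p window. When a pedigree is
    supplied, trio-based expectations over carrier-by-carrier progeny are
    added, with the binomial test at (n = CxC progeny, p = 0.25).
    """
    if not genotypes.phased:
        raise ValueError("scan requires phased genotypes")
    spec = windows or WindowSpec()
    hits: list[_Hit] = []
    n_tests = 0
    for chrom, start, end in _iter_windows(genotypes.marker_map, spec):
        wh = enumerate_window_haplotypes(genotypes, chrom, start, end)
        if wh is None or wh.n_genotyped == 0:
            continue
        two_n = 2 * wh.n_genotyped
        for h in range(len(wh.counts)):
            f = wh.counts[h] / two_n
            if f < spec.min_hap_freq:
                continue
            n_tests += 1
            observed = int(wh.hom_counts[h])
            expected = wh.n_genotyped * f * f
            p = deficit_test(observed, wh.n_genotyped, f * f)
            logger.debug("window %s:%d-%d hap %d f=%.4f O=%d E=%.2f p=%.3g",
                         chrom, start, end, h, f, observed, expected, p)
            if p < spec.alpha:
                carriers = wh.het_carriers(h)
                hits.append(_Hit(chrom, start, end, wh.haplotypes[h],
                                 wh.marker_idx, wh.n_genotyped, len(carriers),
                                 observed, f, expected, p,
                                 frozenset(carriers.tolist()), carriers))

    candidates = _merge_hits(hits, genotypes, n_tests, spec)
    if pedigree is not None:
        for cand in candidates:
            _attach_trio_stats(cand, genotypes, pedigree)
    return candidates


def _merge_hits(hits: list[_Hit], genotypes: PhasedGenotypes, n_tests: int,
                spec: WindowSpec) -> list[CandidateHaplotype]:
    """Union-find merge of significant windows tagging the same carriers.

    Windows whose spans intersect are merged when their carrier sets
    overlap by >= 80% of the smaller set. The containment form (rather
    than strict Jaccard) is used because sub-haplotypes of one lethal
    haplotype produce *nested* carrier sets: a window sticking one marker
    past the shared region splits the carriers by their flanking allele,
    and every such fragment is the same discovery.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = hits[i], hits[j]
            if a.chrom != b.chrom:
                continue
            if a.end_bp <= b.start_bp or b.end_bp <= a.start_bp:
                continue
            inter = len(a.carrier_set & b.carrier_set)
            smaller = min(len(a.carrier_set), len(b.carrier_set))
            if smaller and inter / smaller >= 0.8:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[_Hit]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])

    candidates = []
    for k, (_, grp) in enumerate(sorted(groups.items(),
                                        key=lambda kv: min(h.p for h in kv[1]))):
        best = min(grp, key=lambda h: (h.p, -h.expected, -(h.end_bp - h.start_bp)))
        if spec.refine:
            cand = _refined_candidate(best, genotypes)
        else:
            cand = _hit_to_candidate(best, genotypes)
        cand.name = f"CAND{k + 1}"
        cand.n_windows_merged = len(grp)
        cand.merged_start_bp = min([h.start_bp for h in grp] + [cand.start_bp])
        cand.merged_end_bp = max([h.end_bp for h in grp] + [cand.end_bp])
        cand.bonferroni_significant = bool(cand.p_deficit < spec.alpha / max(n_tests, 1))
        candidates.append(cand)
    return candidates


def _candidate_from_markers(genotypes: PhasedGenotypes, chrom,
                            marker_idx: np.ndarray, hap: np.ndarray
                            ) -> CandidateHaplotype:
    """Recompute all candidate statistics for a given haplotype vector."""
    window = genotypes.alleles[:, marker_idx, :]
    complete = ~np.any(window == MISSING, axis=(1, 2))
    match = np.all(window == hap[None, :, None], axis=1)
    match &= complete[:, None]
    copies = match.sum(axis=1)
    n = int(complete.sum())
    carriers = np.flatnonzero(copies == 1)
    o = int((copies == 2).sum())
    f = (len(carriers) + 2 * o) / (2 * n) if n else 0.0
    pos = genotypes.marker_map["pos"].to_numpy()
    return CandidateHaplotype(
        name="", chrom=chrom,
        start_bp=int(pos[marker_idx[0]]),
        end_bp=int(pos[marker_idx[-1]]) + 1,
        hap_alleles=hap, marker_idx=marker_idx,
        n_genotyped=n, carriers=len(carriers), homozygotes_observed=o,
        hap_freq=f, expected_freq=n * f * f,
        p_deficit=deficit_test(o, n, f * f) if n else 1.0,
        carrier_animals=carriers,
    )


def _hit_to_candidate(hit: _Hit, genotypes: PhasedGenotypes) -> CandidateHaplotype:
    return _candidate_from_markers(genotypes, hit.chrom, hit.marker_idx, hit.hap)


def _refined_candidate(hit: _Hit, genotypes: PhasedGenotypes,
                       share_floor: float = 0.9, z: float = 4.0,
                       max_iter: int = 5) -> CandidateHaplotype:
    """Consensus-extend a significant window to the full shared haplotype.

    The carrier haploids of the seed window are extended marker by marker
    in both directions: a flanking marker is adopted when the carriers'
    modal allele is shared by at least ``share_floor`` of them AND the
    sharing significantly (``z`` standard errors) exceeds that allele's
    population frequency — on a lethal-bearing haplotype the carriers are
    identical by descent, whereas past its boundary their alleles are
    ordinary population draws. Haploids that diverge from the consensus
    (chance exact matches of the short seed window) are shed along the
    way, so the refined candidate's carriers are the haplotype's true
    carriers and its span approaches the full shared segment.
    """
    mm = genotypes.marker_map
    chrom_all = np.flatnonzero((mm["chrom"] == hit.chrom).to_numpy())
    A = genotypes.alleles
    called = A[:, :, 0] != MISSING
    # population frequency of the alternate allele per marker (called haploids)
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(called.sum(axis=0) > 0,
                            (A.sum(axis=2) * called).sum(axis=0)
                            / (2 * np.maximum(called.sum(axis=0), 1)), 0.5)

    marker_idx = hit.marker_idx.copy()
    hap = hit.hap.copy()
    pos_of = {g: i for i, g in enumerate(chrom_all)}

    for _ in range(max_iter):
        window = A[:, marker_idx, :]
        complete = ~np.any(window == MISSING, axis=(1, 2))
        match = np.all(window == hap[None, :, None], axis=1)
        match &= complete[:, None]
        anim, hapl = np.nonzero(match)
        if len(anim) == 0:
            break
        lo = pos_of[marker_idx[0]]
        hi = pos_of[marker_idx[-1]]
        left_adopt, right_adopt = [], []
        for direction, rng_iter in ((-1, range(lo - 1, -1, -1)),
                                    (+1, range(hi + 1, len(chrom_all)))):
            active = np.ones(len(anim), dtype=bool)
            adopted = left_adopt if direction < 0 else right_adopt
            for ci in rng_iter:
                g = chrom_all[ci]
                alle = A[anim[active], g, hapl[active]]
                valid = alle != MISSING
                if valid.sum() == 0:
                    break
                n1 = int((alle[valid] == 1).sum())
                n0 = int(valid.sum()) - n1
                modal, n_modal = (1, n1) if n1 > n0 else (0, n0)
                share = n_modal / valid.sum()
                popf = alt_freq[g] if modal == 1 else 1 - alt_freq[g]
                se = np.sqrt(max(popf * (1 - popf), 1e-12) / valid.sum())
                if share < share_floor or share < popf + z * se:
                    break
                adopted.append((g, modal))
                keep = np.zeros(len(anim), dtype=bool)
                keep[active] = (alle == modal)
                active = keep
        if not left_adopt and not right_adopt:
            break
        new_idx = ([g for g, _ in reversed(left_adopt)] + list(marker_idx)
                   + [g for g, _ in right_adopt])
        new_hap = ([a for _, a in reversed(left_adopt)] + list(hap)
                   + [a for _, a in right_adopt])
        marker_idx = np.array(new_idx)
        hap = np.array(new_hap, dtype=hit.hap.dtype)

    return _candidate_from_markers(genotypes, hit.chrom, marker_idx, hap)


def haplotype_carrier_status(candidate: CandidateHaplotype,
                             genotypes: PhasedGenotypes) -> dict:
    """Map animal id -> copies of the candidate haplotype (0/1/2; missing
    window calls excluded)."""
    window = genotypes.alleles[:, candidate.marker_idx, :]
    complete = ~np.any(window == MISSING, axis=(1, 2))
    match = np.all(window == candidate.hap_alleles[None, :, None], axis=1)
    dosage = match.sum(axis=1)
    return {aid: int(d) for aid, d, ok in
            zip(genotypes.animal_ids, dosage, complete) if ok}


def _attach_trio_stats(cand: CandidateHaplotype, genotypes: PhasedGenotypes,
                       pedigree: Pedigree) -> None:
    status = haplotype_carrier_status(cand, genotypes)
    genotyped = set(status)
    expected, n_cxc = expected_homozygotes_trio(pedigree, status, genotyped)
    parents = pedigree.parents_of()
    o_hom = 0
    n_het = 0
    for child in genotyped:
        if child not in parents.index:
            continue
        sire, dam = parents.loc[child, "sire"], parents.loc[child, "dam"]
        if pd.isna(sire) or pd.isna(dam):
            continue
        if status.get(sire) == 1 and status.get(dam) == 1:
            if status[child] == 2:
                o_hom += 1
            elif status[child] == 1:
                n_het += 1
    cand.expected_trio = expected
    cand.cxc_progeny = n_cxc
    cand.cxc_het_progeny = n_het
    cand.p_trio = deficit_test(o_hom, n_cxc, 0.25) if n_cxc > 0 else None


# ---------------------------------------------------------------------------
# fine mapping
# ---------------------------------------------------------------------------

def finemap_recombinants(candidate: CandidateHaplotype,
                         genotypes: PhasedGenotypes,
                         sub_length_bp: int = 1_000_000
                         ) -> tuple[int, int] | None:
    """Refine the causal interval using recombinant carriers.

    The candidate span is divided into consecutive sub-haplotypes; a
    sub-haplotype observed homozygous in any carrier cannot harbour the
    lethal and is excluded. Returns the maximal remaining contiguous
    interval as (start_bp, end_bp), or None with a warning when every
    sub-haplotype is excluded (a contradiction with recessive lethality).
    """
    span = candidate.end_bp - candidate.start_bp
    if span < 2 * sub_length_bp:
        raise ValueError("candidate span must cover at least two sub-haplotypes")
    if len(candidate.carrier_animals) == 0:
        raise ValueError("candidate has no carriers")
    carriers = np.asarray(candidate.carrier_animals)
    mm = genotypes.marker_map
    pos = mm["pos"].to_numpy()

    n_sub = int(np.ceil(span / sub_length_bp))
    keep = []
    bounds = []
    for s in range(n_sub):
        lo = candidate.start_bp + s * sub_length_bp
        hi = min(candidate.end_bp, lo + sub_length_bp)
        sel = (pos[candidate.marker_idx] >= lo) & (pos[candidate.marker_idx] < hi)
        sub_idx = candidate.marker_idx[sel]
        bounds.append((lo, hi))
        if len(sub_idx) == 0:
            keep.append(True)  # no markers: cannot exclude
            continue
        sub_hap = candidate.hap_alleles[sel]
        window = genotypes.alleles[np.ix_(carriers, sub_idx)]
        hom = np.all(window == sub_hap[None, :, None], axis=(1, 2))
        keep.append(not bool(hom.any()))

    best = None
    run_start = None
    best_len = 0
    for s, k in enumerate(keep + [False]):
        if k and run_start is None:
            run_start = s
        elif not k and run_start is not None:
            length = s - run_start
            if length > best_len:
                best_len = length
                best = (run_start, s - 1)
            run_start = None
    if best is None:
        warnings.warn("all sub-haplotypes observed homozygous: empty interval")
        return None
    return bounds[best[0]][0], bounds[best[1]][1]


def candidates_to_frame(candidates: list[CandidateHaplotype]) -> pd.DataFrame:
    if not candidates:
        return pd.DataFrame()
    return pd.DataFrame([c.to_row() for c in candidates])
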