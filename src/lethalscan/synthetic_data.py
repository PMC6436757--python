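"""Synthetic two-tier breeding population with a planted recessive lethal.

Emulates the statistical structure of a commercial pig breeding nucleus:
few boars and many sows, phased biallelic chip markers at realistic MAF,
a recessive embryonic-lethal allele riding one founder haplotype at a
configurable carrier frequency, litters in which lethal homozygotes die
pre-implantation (optionally buffered by uterine capacity), and a local
sequence-variant panel with graded LD to the lethal haplotype. Everything
downstream of phasing and variant annotation can be exercised against
these populations without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CONSEQUENCE_CLASSES,
    MISSING,
    LitterRecord,
    Pedigree,
    PhasedGenotypes,
    VariantRecord,
)

_GENOTYPE_LABELS = ("wt/wt", "wt/mut", "mut/mut")


@dataclass
class SimConfig:
    """Parameters of the simulated breeding population.

    Defaults reflect the nucleus structure of the populations the
    pipeline targets: 50 boars and 2000 sows, ~50K-chip marker density
    (one marker per ~50 kb), a recessive lethal planted at 13.4% carrier
    frequency on a 2 Mb founder haplotype, mean litter size 14.18 piglets
    and ~50% replacement per generation. Ovulation mean (22 ova) and
    uterine capacity (infinite unless set) control the compensation
    regime: with finite capacity the loss of homozygous embryos is
    partially offset by supernumerary ova.
    """

    n_boars: int = 50
    n_sows: int = 2000
    n_generations: int = 5
    n_markers: int = 400
    chrom_length_bp: int = 20_000_000
    maf_low: float = 0.1
    maf_high: float = 0.5
    recomb_rate: float = 0.01  # expected crossovers per Mb per meiosis (1 cM/Mb)
    lethal_position_bp: int = 10_000_000
    target_carrier_freq: float = 0.134
    ovulation_mean: float = 22.0
    uterine_capacity: float | None = None  # None = unlimited (no compensation)
    litter_mean: float = 14.18
    seed: int = 0
    # secondary knobs
    lethal_hap_length_bp: int = 2_000_000
    nsb_rate: float = 0.07   # background stillborn fraction of TNB
    mum_rate: float = 0.01   # background mummified piglets per TNB
    replacement_rate: float = 0.5
    chrom: str = "1"
    base_date: str = "2012-01-01"

    def __post_init__(self) -> None:
        if min(self.n_boars, self.n_sows, self.n_markers) <= 0:
            raise ValueError("population and marker counts must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if not (0 <= self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
        if not (0 <= self.target_carrier_freq <= 0.5):
            raise ValueError("target_carrier_freq must lie in [0, 0.5]")
        if not (0 < self.lethal_position_bp < self.chrom_length_bp):
            raise ValueError("lethal_position_bp must lie inside the chromosome")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        cap = math.inf if self.uterine_capacity is None else self.uterine_capacity
        if cap < 1:
            raise ValueError("uterine_capacity must be >= 1 (or None)")
        if self.litter_survival_scale() > 1.0 + 1e-9:
            raise ValueError(
                "litter_mean unreachable: expected carried embryos fall below it"
            )

    @property
    def n_animals(self) -> int:
        return self.n_boars + self.n_sows

    def expected_carried(self, mendelian_survival: float = 1.0) -> float:
        """E[min(X, capacity)] with X ~ Poisson(ovulation_mean * survival)."""
        lam = self.ovulation_mean * mendelian_survival
        cap = self.uterine_capacity
        if cap is None or math.isinf(cap):
            return lam
        c = int(cap)
        k = np.arange(0, c)
        pmf = stats.poisson.pmf(k, lam)
        return float((k * pmf).sum() + c * stats.poisson.sf(c - 1, lam))

    def litter_survival_scale(self) -> float:
        """Per-embryo birth probability calibrating NCxNC mean TNB to litter_mean."""
        return self.litter_mean / self.expected_carried(1.0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedLethal:
    """Bookkeeping for a planted lethal allele and its host haplotype."""

    variant: VariantRecord
    hap_carriage: np.ndarray        # (n_animals, 2) int8: lethal on that haploid
    host_alleles: np.ndarray        # allele vector of the host haplotype
    marker_idx: np.ndarray          # marker indices spanned by the host window
    window_start_bp: int
    window_end_bp: int

    @property
    def carrier_count(self) -> int:
        return int((self.hap_carriage.sum(axis=1) == 1).sum())


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None) -> PhasedGenotypes:
    """Draw founder phased genotypes.

    Marker positions are evenly spread over the chromosome with small
    jitter; founder haploid alleles are independent Bernoulli draws per
    marker at frequencies uniform in [maf_low, maf_high].
    """
    rng = config.rng() if rng is None else rng
    n, m = config.n_animals, config.n_markers
    spacing = config.chrom_length_bp / (m + 1)
    jitter = rng.uniform(-0.3, 0.3, size=m) * spacing
    pos = np.sort((np.arange(1, m + 1) * spacing + jitter).astype(np.int64))
    pos = np.maximum(pos, 1)
    pos = np.unique(pos)
    while len(pos) < m:  # collisions are essentially impossible at chip density
        extra = rng.integers(1, config.chrom_length_bp, size=m - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    freqs = rng.uniform(config.maf_low, config.maf_high, size=m)
    alleles = (rng.random((n, m, 2)) < freqs[None, :, None]).astype(np.int8)
    ids = np.array(
        [f"G0_B{i:05d}" for i in range(config.n_boars)]
        + [f"G0_S{i:05d}" for i in range(config.n_sows)]
    )
    marker_map = pd.DataFrame({
        "chrom": config.chrom,
        "pos": pos,
        "ref": "A",
        "alt": "B",
    })
    return PhasedGenotypes(ids, marker_map, alleles, phased=True)


def plant_lethal(genotypes: PhasedGenotypes, config: SimConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[PhasedGenotypes, PlantedLethal]:
    """Place a recessive lethal allele on copies of one founder haplotype.

    The host haplotype is a window of ``lethal_hap_length_bp`` centred on
    the lethal position, copied from one founder haploid onto one haploid
    of each selected carrier, so that the window haplotype is in complete
    LD with the lethal allele and no animal is homozygous for it.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = genotypes.n_animals
    half = config.lethal_hap_length_bp // 2
    start = max(1, config.lethal_position_bp - half)
    end = min(config.chrom_length_bp, config.lethal_position_bp + half)
    midx = genotypes.marker_indices(config.chrom, start, end)
    if len(midx) < 2:
        raise ValueError("lethal host window spans fewer than 2 markers")

    hap_carriage = np.zeros((n, 2), dtype=np.int8)
    n_target = int(round(config.target_carrier_freq * n))
    if n_target == 0:
        variant = VariantRecord(config.chrom, config.lethal_position_bp, "G", "A",
                                "splice_donor", np.zeros(n), vid="lethal")
        lethal = PlantedLethal(variant, hap_carriage,
                               genotypes.alleles[0, midx, 0].copy(), midx, start, end)
        return genotypes, lethal

    donor = int(rng.integers(n))
    donor_hap = int(rng.integers(2))
    host = genotypes.alleles[donor, midx, donor_hap].copy()

    window = genotypes.alleles[:, midx, :]
    matches = np.all(window == host[None, :, None], axis=1)  # (n, 2)
    match_animals = np.flatnonzero(matches.any(axis=1))

    # every pre-existing copy of the host vector receives the lethal (one
    # haploid per animal) so LD with the lethal stays complete
    alleles = genotypes.alleles.copy()
    for a in match_animals:
        h = int(np.flatnonzero(matches[a])[0])
        hap_carriage[a, h] = 1

    n_extra = n_target - len(match_animals)
    if n_extra < 0:
        n_extra = 0
    pool = np.setdiff1d(np.arange(n), match_animals)
    if n_extra > len(pool):
        raise ValueError("target carrier frequency unreachable")
    chosen = rng.choice(pool, size=n_extra, replace=False)
    haps = rng.integers(2, size=n_extra)
    for a, h in zip(chosen, haps):
        alleles[a, midx, h] = host
        hap_carriage[a, h] = 1

    realized = (hap_carriage.sum(axis=1) == 1).mean()
    if config.target_carrier_freq > 0 and not (
        0.9 * config.target_carrier_freq <= realized <= 1.1 * config.target_carrier_freq
    ):
        raise ValueError(
            f"realized carrier frequency {realized:.4f} outside +-10% of target"
        )

    dosages = hap_carriage.sum(axis=1).astype(float)
    variant = VariantRecord(config.chrom, config.lethal_position_bp, "G", "A",
                            "splice_donor", dosages, vid="lethal")
    out = PhasedGenotypes(genotypes.animal_ids, genotypes.marker_map, alleles,
                          genotypes.phased)
    return out, PlantedLethal(variant, hap_carriage, host, midx, start, end)


# ---------------------------------------------------------------------------
# litter model
# ---------------------------------------------------------------------------

def _simulate_litters(p_sire: np.ndarray, p_dam: np.ndarray, config: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Vectorised litter outcomes for matings with given lethal-allele
    transmission probabilities (dosage/2) per parent.

    Zygotes are Poisson(ovulation_mean); genotypes Mendelian; mut/mut
    zygotes die pre-implantation; survivors are truncated at uterine
    capacity and thinned so NCxNC litters average ``litter_mean``.
    """
    k = len(p_sire)
    n_ov = rng.poisson(config.ovulation_mean, size=k)
    pr_mm = p_sire * p_dam
    pr_het = p_sire * (1 - p_dam) + p_dam * (1 - p_sire)
    n_mm = rng.binomial(n_ov, pr_mm)
    rest = n_ov - n_mm
    with np.errstate(invalid="ignore"):
        p_het_given_rest = np.where(pr_mm < 1.0, pr_het / np.maximum(1 - pr_mm, 1e-300), 0.0)
    n_het = rng.binomial(rest, p_het_given_rest)
    n_wt = rest - n_het

    survivors = n_wt + n_het
    cap = config.uterine_capacity
    if cap is not None and not math.isinf(cap):
        c = int(cap)
        kept = np.minimum(survivors, c)
        # hypergeometric split of the kept embryos between genotype classes
        excess = survivors > c
        n_het_kept = n_het.copy()
        if excess.any():
            n_het_kept[excess] = rng.hypergeometric(
                n_het[excess], n_wt[excess], c)
        n_wt_kept = kept - n_het_kept
    else:
        n_het_kept, n_wt_kept = n_het, n_wt

    s = config.litter_survival_scale()
    born_het = rng.binomial(n_het_kept, s)
    born_wt = rng.binomial(n_wt_kept, s)
    tnb = born_het + born_wt
    nsb = rng.binomial(tnb, config.nsb_rate)
    mum = rng.poisson(config.mum_rate * tnb)
    return pd.DataFrame({
        "TNB": tnb, "NBA": tnb - nsb, "NSB": nsb, "MUM": mum,
        "n_wtwt": born_wt, "n_wtmut": born_het, "n_mutmut": 0,
        "n_died_mutmut": n_mm,
    })


def litter_model(sire_gt: int, dam_gt: int, config: SimConfig,
                 rng: np.random.Generator,
                 sire: str = "sire", dam: str = "dam",
                 mating_date="2012-01-01") -> LitterRecord:
    """Simulate one litter given parent lethal-locus dosages (0/1/2).

    Homozygous lethal zygotes die before implantation; with unlimited
    uterine capacity a carrier-by-carrier mating therefore loses 25% of
    expected total born, while with limited capacity supernumerary ova
    compensate and the realised loss is smaller.
    """
    df = _simulate_litters(np.array([sire_gt / 2.0]), np.array([dam_gt / 2.0]),
                           config, rng)
    r = df.iloc[0]
    return LitterRecord(
        sire=sire, dam=dam, mating_date=mating_date,
        tnb=int(r["TNB"]), nba=int(r["NBA"]), nsb=int(r["NSB"]), mum=int(r["MUM"]),
        piglet_genotypes={"wt/wt": int(r["n_wtwt"]), "wt/mut": int(r["n_wtmut"]),
                          "mut/mut": 0},
    )


# ---------------------------------------------------------------------------
# multi-generation simulation
# ---------------------------------------------------------------------------

def _gamete(parent_alleles: np.ndarray, parent_lethal: np.ndarray,
            positions: np.ndarray, lethal_pos: int, length_mb: float,
            recomb_rate: float, rng: np.random.Generator,
            require: int | None = None) -> tuple[np.ndarray, int]:
    """One meiosis: returns (haploid allele vector, transmitted lethal 0/1).

    Crossovers are Poisson(recomb_rate * length_mb) at uniform positions.
    ``require`` conditions on the transmitted lethal state by rejection
    sampling (exact conditioning; acceptance 1/2 for a carrier parent).
    """
    while True:
        k = rng.poisson(recomb_rate * length_mb)
        start = int(rng.integers(2))
        if k == 0:
            strands = np.full(len(positions), start)
            lethal_strand = start
        else:
            xpos = np.sort(rng.uniform(0, length_mb * 1e6, size=k))
            strands = (start + np.searchsorted(xpos, positions)) % 2
            lethal_strand = (start + int(np.searchsorted(xpos, lethal_pos))) % 2
        transmitted = int(parent_lethal[lethal_strand])
        if require is None or transmitted == require:
            return parent_alleles[np.arange(len(positions)), strands], transmitted


def simulate_generations(founders: PhasedGenotypes, config: SimConfig,
                         rng: np.random.Generator,
                         lethal: PlantedLethal | None = None
                         ) -> tuple[PhasedGenotypes, Pedigree, list[LitterRecord],
                                    PlantedLethal | None]:
    """Run the breeding program forward.

    Each generation every sow is mated to a uniformly chosen boar; litters
    follow :func:`litter_model`; ~``replacement_rate`` of boars and sows
    are replaced by piglets sampled uniformly among survivors (whose full
    genomes are then formed by recombinant meiosis, phase known by
    construction). Returns genotypes and pedigree of every animal that
    entered the breeding population, all litter records, and the lethal
    bookkeeping extended to the new animals.
    """
    nb, ns = config.n_boars, config.n_sows
    if founders.n_animals != nb + ns:
        raise ValueError("founders must contain n_boars + n_sows animals")
    positions = founders.marker_map["pos"].to_numpy()
    length_mb = config.chrom_length_bp / 1e6
    base = pd.Timestamp(config.base_date)

    if lethal is None:
        lethal_carr = np.zeros((founders.n_animals, 2), dtype=np.int8)
    else:
        lethal_carr = lethal.hap_carriage.copy()

    all_ids = list(founders.animal_ids)
    all_alleles = [founders.alleles]
    all_lethal = [lethal_carr]
    ped_rows = [
        {"animal": aid, "sire": None, "dam": None,
         "sex": "M" if i < nb else "F", "birthdate": base}
        for i, aid in enumerate(founders.animal_ids)
    ]
    # current population: indices into the accumulated arrays
    boars = list(range(nb))
    sows = list(range(nb, nb + ns))
    litters: list[LitterRecord] = []

    def flat_alleles() -> np.ndarray:
        return np.concatenate(all_alleles, axis=0)

    def flat_lethal() -> np.ndarray:
        return np.concatenate(all_lethal, axis=0)

    for g in range(1, config.n_generations + 1):
        A = flat_alleles()
        L = flat_lethal()
        bdate = base + pd.DateOffset(years=g)
        sire_pick = rng.choice(boars, size=len(sows))
        p_s = L[sire_pick].sum(axis=1) / 2.0
        p_d = L[sows].sum(axis=1) / 2.0
        lit = _simulate_litters(p_s, p_d, config, rng)
        date = bdate.date().isoformat()
        for j, (b_i, s_i) in enumerate(zip(sire_pick, sows)):
            r = lit.iloc[j]
            litters.append(LitterRecord(
                sire=all_ids[b_i], dam=all_ids[s_i], mating_date=date,
                tnb=int(r["TNB"]), nba=int(r["NBA"]), nsb=int(r["NSB"]),
                mum=int(r["MUM"]),
                piglet_genotypes={"wt/wt": int(r["n_wtwt"]),
                                  "wt/mut": int(r["n_wtmut"]), "mut/mut": 0}))

        total = int(lit["TNB"].sum())
        if total == 0:
            raise RuntimeError(f"population extinct at generation {g}: no offspring")

        # piglet slots: litter index and genotype category per slot
        slot_litter = np.repeat(np.arange(len(sows)),
                                lit["TNB"].to_numpy())
        cat = np.concatenate([
            np.repeat([0, 1], [int(r["n_wtwt"]), int(r["n_wtmut"])])
            for _, r in lit.iterrows()
        ])
        n_rep_b = int(round(config.replacement_rate * nb))
        n_rep_s = int(round(config.replacement_rate * ns))
        n_rep = min(n_rep_b + n_rep_s, total)
        picked = rng.choice(total, size=n_rep, replace=False)
        n_rep_b = min(n_rep_b, n_rep)

        new_alleles = np.empty((n_rep, founders.n_markers, 2), dtype=np.int8)
        new_lethal = np.zeros((n_rep, 2), dtype=np.int8)
        new_rows = []
        next_idx = len(all_ids)
        for r_i, slot in enumerate(picked):
            li = int(slot_litter[slot])
            het = int(cat[slot]) == 1
            b_i, s_i = int(sire_pick[li]), int(sows[li])
            ls, ld = L[b_i], L[s_i]
            if het:
                pr_s = (ls.sum() / 2.0) * (1 - ld.sum() / 2.0)
                pr_d = (ld.sum() / 2.0) * (1 - ls.sum() / 2.0)
                both = (ls.sum() / 2.0) * (ld.sum() / 2.0)  # excluded: mut/mut dies
                from_sire = rng.random() < pr_s / (pr_s + pr_d) if (pr_s + pr_d) > 0 else False
                req_s, req_d = (1, 0) if from_sire else (0, 1)
                del both
            else:
                req_s = req_d = 0
            # non-carrier parents need no conditioning
            gs, ts = _gamete(A[b_i], ls, positions, config.lethal_position_bp,
                             length_mb, config.recomb_rate, rng,
                             require=req_s if ls.any() else None)
            gd, td = _gamete(A[s_i], ld, positions, config.lethal_position_bp,
                             length_mb, config.recomb_rate, rng,
                             require=req_d if ld.any() else None)
            new_alleles[r_i, :, 0] = gs
            new_alleles[r_i, :, 1] = gd
            new_lethal[r_i, 0] = ts
            new_lethal[r_i, 1] = td
            sex = "M" if r_i < n_rep_b else "F"
            aid = f"G{g}_{'B' if sex == 'M' else 'S'}{next_idx + r_i:05d}"
            new_rows.append({"animal": aid, "sire": all_ids[b_i],
                             "dam": all_ids[s_i], "sex": sex, "birthdate": bdate})
        assert not np.any(new_lethal.sum(axis=1) == 2), "lethal homozygote survived"

        all_alleles.append(new_alleles)
        all_lethal.append(new_lethal)
        ped_rows.extend(new_rows)
        new_ids = [r["animal"] for r in new_rows]
        all_ids.extend(new_ids)

        new_boar_idx = list(range(next_idx, next_idx + n_rep_b))
        new_sow_idx = list(range(next_idx + n_rep_b, next_idx + n_rep))
        keep_b = list(rng.choice(boars, size=nb - len(new_boar_idx), replace=False))
        keep_s = list(rng.choice(sows, size=ns - len(new_sow_idx), replace=False))
        boars = keep_b + new_boar_idx
        sows = keep_s + new_sow_idx

    genotypes = PhasedGenotypes(np.array(all_ids), founders.marker_map,
                                flat_alleles(), phased=True)
    pedigree = Pedigree(pd.DataFrame(ped_rows))
    out_lethal = None
    if lethal is not None:
        carr = flat_lethal()
        out_lethal = replace(
            lethal,
            variant=VariantRecord(lethal.variant.chrom, lethal.variant.pos,
                                  lethal.variant.ref, lethal.variant.alt,
                                  lethal.variant.consequence_class,
                                  carr.sum(axis=1).astype(float),
                                  deleterious=lethal.variant.deleterious,
                                  vid=lethal.variant.vid),
            hap_carriage=carr)
    return genotypes, pedigree, litters, out_lethal


# ---------------------------------------------------------------------------
# variant panel
# ---------------------------------------------------------------------------

_BACKGROUND_CLASSES = ("synonymous", "intergenic", "missense", "inframe_indel")


def simulate_variant_panel(genotypes: PhasedGenotypes, lethal: PlantedLethal,
                           n_variants: int, ld_profile: tuple[float, ...],
                           rng: np.random.Generator,
                           causal_class: str = "splice_donor") -> list[VariantRecord]:
    """Emit the causal variant plus background variants with graded LD.

    The causal variant sits at the lethal position in complete LD with
    the host haplotype (high-impact class, no homozygotes). Background
    variants are generated at haploid level so their dosage r² to the
    host-haplotype dosage follows ``ld_profile``; positions fall both
    inside and beyond the 5 Mb flank of the host window.
    """
    n = genotypes.n_animals
    carr = lethal.hap_carriage.astype(bool)
    q = carr.sum() / (2 * n)
    chrom = lethal.variant.chrom
    chrom_len = int(genotypes.marker_map["pos"].iloc[-1] * 1.05)

    panel = [VariantRecord(chrom, lethal.variant.pos, "G", "A", causal_class,
                           carr.sum(axis=1).astype(float), vid="causal")]

    targets = list(ld_profile)
    while len(targets) < n_variants - 1:
        targets.append(float(rng.uniform(0.0, 0.5)))
    targets = targets[: n_variants - 1]

    for i, t in enumerate(targets):
        inside = i % 3 != 2  # two thirds inside the 5 Mb flank, rest beyond
        if inside:
            lo = max(1, lethal.window_start_bp - 5_000_000)
            hi = min(chrom_len, lethal.window_end_bp + 5_000_000)
        else:
            lo, hi = lethal.window_end_bp + 5_000_001, lethal.window_end_bp + 12_000_000
        pos = int(rng.integers(lo, hi))
        if t >= 0.999:
            v_hap = carr.copy()
        else:
            # variant on every host haploid, plus background haploids at rate
            # beta chosen so dosage r^2 hits the target:
            # p_v = q / (q + t(1-q)); beta = (p_v - q)/(1-q)
            p_v = q / (q + t * (1 - q)) if (q + t * (1 - q)) > 0 else 1.0
            beta = min(max((p_v - q) / (1 - q), 0.0), 1.0)
            v_hap = carr | (rng.random((n, 2)) < beta)
            if t == 0.0:
                v_hap = rng.random((n, 2)) < max(q, 0.05)
        cls = _BACKGROUND_CLASSES[i % len(_BACKGROUND_CLASSES)]
        panel.append(VariantRecord(chrom, pos, "C", "T", cls,
                                   v_hap.sum(axis=1).astype(float),
                                   deleterious=False, vid=f"bg{i:03d}"))
    return panel
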