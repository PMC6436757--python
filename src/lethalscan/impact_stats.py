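"""Fertility impact of recessive lethal haplotypes.

Carrier-by-carrier (CxC) matings of a recessive embryonic lethal lose a
quarter of their embryos, so comparing total-number-born (TNB) between
CxC and carrier-by-noncarrier (CxNC) litters measures the lethal's
penetrance and timing. Scaling the per-litter reduction by the fraction
of litters that are CxC (the squared carrier frequency under random
mating) gives the population-level embryo mortality and average litter
shrinkage, and relating that shrinkage to the purebred-crossbred litter
difference quantifies how much of the heterosis for litter size recessive
lethals explain. Litter genotype ratios (1:2:1 expectation against the
observed 1:2 survivor ratio) validate candidate causal mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImpactRow:
    """One haplotype's fertility-impact accounting.

    Identities: reduction = (TNB_CxNC - TNB_CxC)/TNB_CxNC;
    pct_death = affected_litters x reduction;
    population_reduction = mean population TNB x pct_death.
    All stored as fractions (not percent).
    """

    haplotype: str
    n_cxc: int
    n_cxnc: int
    tnb_cxc: float
    tnb_cxnc: float
    carrier_freq: float | None = None
    affected_litters: float = field(default=None)  # fraction of litters CxC

    def __post_init__(self) -> None:
        if self.affected_litters is None:
            if self.carrier_freq is None:
                raise ValueError("need carrier_freq or affected_litters")
            self.affected_litters = affected_litters(self.carrier_freq)

    @property
    def reduction(self) -> float:
        return tnb_reduction(self.tnb_cxc, self.tnb_cxnc)

    @property
    def piglet_loss(self) -> float:
        return piglet_loss(self.n_cxc, self.tnb_cxc, self.tnb_cxnc)

    @property
    def pct_death(self) -> float:
        return self.affected_litters * self.reduction


def welch_t(values_a, values_b) -> tuple[float, float]:
    """Two-sample unequal-variance t-test (Welch-Satterthwaite df),
    two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both groups degenerate with distinct means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def tnb_reduction(tnb_cxc: float, tnb_cxnc: float) -> float:
    """Relative litter-size reduction of CxC versus CxNC matings."""
    if tnb_cxnc <= 0:
        raise ValueError("tnb_cxnc must be positive")
    return (tnb_cxnc - tnb_cxc) / tnb_cxnc


def affected_litters(carrier_freq: float) -> float:
    """Fraction of litters from two carrier parents under random mating:
    the squared carrier frequency."""
    if not (0 <= carrier_freq <= 1):
        raise ValueError("carrier_freq must lie in [0, 1]")
    return carrier_freq * carrier_freq


def piglet_loss(n_cxc: int, tnb_cxc: float, tnb_cxnc: float) -> float:
    """Piglets lost across the observed CxC litters."""
    if n_cxc < 0:
        raise ValueError("n_cxc must be >= 0")
    return n_cxc * (tnb_cxnc - tnb_cxc)


def population_impact(rows: list[ImpactRow], mean_tnb: float
                      ) -> tuple[float, float]:
    """Population totals: (total embryo-death fraction, total TNB
    reduction per litter).

    Per row, the death fraction is affected_litters x reduction and the
    per-litter TNB reduction is the population mean TNB x that fraction;
    totals are the sums over haplotypes.
    """
    total_death = sum(r.pct_death for r in rows)
    return total_death, mean_tnb * total_death


def impact_table(rows: list[ImpactRow], mean_tnb: float) -> pd.DataFrame:
    """Fertility-impact table with one row per haplotype plus a SUM row."""
    recs = []
    for r in rows:
        recs.append({
            "haplotype": r.haplotype, "n_cxc": r.n_cxc, "n_cxnc": r.n_cxnc,
            "tnb_cxc": r.tnb_cxc, "tnb_cxnc": r.tnb_cxnc,
            "reduction": r.reduction,
            "affected_litters": r.affected_litters,
            "piglet_loss": r.piglet_loss,
            "pct_death": r.pct_death,
            "population_reduction": mean_tnb * r.pct_death,
        })
    total_death, total_red = population_impact(rows, mean_tnb)
    recs.append({
        "haplotype": "SUM",
        "n_cxc": sum(r.n_cxc for r in rows),
        "n_cxnc": sum(r.n_cxnc for r in rows),
        "tnb_cxc": np.nan, "tnb_cxnc": np.nan, "reduction": np.nan,
        "affected_litters": sum(r.affected_litters for r in rows),
        "piglet_loss": sum(r.piglet_loss for r in rows),
        "pct_death": total_death,
        "population_reduction": total_red,
    })
    return pd.DataFrame(recs)


@dataclass
class LitterGenotypeCounts:
    """Genotyped progeny of carrier-by-carrier litters."""

    n_wt: int
    n_het: int
    n_hom: int
    liveborn: int | None = None
    stillborn: int | None = None

    @property
    def n_total(self) -> int:
        return self.n_wt + self.n_het + self.n_hom


def genotype_ratio_test(counts: LitterGenotypeCounts) -> tuple[float, float]:
    """Test genotyped litter counts against the Mendelian 1:2:1 ratio.

    Returns (Pearson chi-square p at df=2, no continuity correction;
    lower-tail exact binomial p for the homozygote count under p=1/4).
    """
    n = counts.n_total
    if n <= 0:
        raise ValueError("no genotyped progeny")
    observed = [counts.n_wt, counts.n_het, counts.n_hom]
    expected = [n / 4, n / 2, n / 4]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_chi = float(stats.chi2.sf(chi2, df=2))
    p_binom = float(stats.binom.cdf(counts.n_hom, n, 0.25))
    return p_chi, p_binom


def heterosis_attribution(tnb_purebred: float, tnb_crossbred: float,
                          total_population_reduction: float) -> float:
    """Fraction of the purebred-crossbred litter-size gap attributable to
    recessive embryonic lethals (which are masked in crossbreds)."""
    diff = tnb_crossbred - tnb_purebred
    if diff <= 0:
        raise ValueError("crossbred litters must exceed purebred litters")
    frac = total_population_reduction / diff
    if frac > 1:
        import warnings
        warnings.warn("attribution exceeds 1; clipped")
    return float(np.clip(frac, 0.0, 1.0))


def population_burden(n_lethals: float, mean_allele_freq: float
                      ) -> tuple[float, float]:
    """Population-level burden of a class of recessive lethals.

    At low frequency q, each of n loci is carried heterozygously by
    ~2q of individuals, so individuals carry 2nq lethals on average and
    nq² of embryos die homozygous.
    """
    if n_lethals < 0 or mean_allele_freq < 0:
        raise ValueError("inputs must be >= 0")
    carried = 2 * n_lethals * mean_allele_freq
    death = n_lethals * mean_allele_freq ** 2
    return carried, death


def carrier_frequency_timeseries(pedigree, carrier_status: dict,
                                 start: str = "2012-01-01",
                                 bin_months: int = 6,
                                 lifespan_years: float = 3.0,
                                 n_bins: int | None = None) -> pd.DataFrame:
    """Carrier fraction among live animals per half-year bin.

    An animal is alive in a bin if it was born on or before the bin end
    and within ``lifespan_years`` of the bin start (the pedigree carries
    no cull dates). Bins with no live genotyped animals report NaN.
    """
    df = pedigree.records
    born = pd.to_datetime(df["birthdate"])
    status = df["animal"].map(carrier_status)
    known = status.notna()
    t0 = pd.Timestamp(start)
    end = born.max()
    bins = []
    b = 0
    while True:
        lo = t0 + pd.DateOffset(months=bin_months * b)
        hi = t0 + pd.DateOffset(months=bin_months * (b + 1))
        if n_bins is None and lo > end:
            break
        if n_bins is not None and b >= n_bins:
            break
        alive = known & (born <= hi) & (born > lo - pd.DateOffset(
            months=int(12 * lifespan_years)))
        n_alive = int(alive.sum())
        carriers = int((status[alive] >= 1).sum())
        bins.append({
            "bin_start": lo, "bin_end": hi, "n_alive": n_alive,
            "n_carriers": carriers,
            "carrier_freq": carriers / n_alive if n_alive else np.nan,
        })
        b += 1
    return pd.DataFrame(bins)


def fertility_comparison(litters: pd.DataFrame, carrier_status: dict
                         ) -> pd.DataFrame:
    """Classify litters by parental carrier status and compare TNB.

    ``litters`` needs columns sire, dam, TNB; returns per-class means and
    the Welch test of CxC against CxNC (order of CxNC parents ignored).
    """
    sire_c = litters["sire"].map(carrier_status)
    dam_c = litters["dam"].map(carrier_status)
    known = sire_c.notna() & dam_c.notna()
    sc = (sire_c >= 1) & known
    dc = (dam_c >= 1) & known
    cls = pd.Series("unknown", index=litters.index)
    cls[known & sc & dc] = "CxC"
    cls[known & (sc ^ dc)] = "CxNC"
    cls[known & ~sc & ~dc] = "NCxNC"
    out = []
    for name, grp in litters.groupby(cls):
        out.append({"class": name, "n": len(grp),
                    "tnb_mean": grp["TNB"].mean()})
    res = pd.DataFrame(out).set_index("class")
    if "CxC" in res.index and "CxNC" in res.index and \
            res.loc["CxC", "n"] >= 2 and res.loc["CxNC", "n"] >= 2:
        t, p = welch_t(litters.loc[cls == "CxC", "TNB"],
                       litters.loc[cls == "CxNC", "TNB"])
        res.attrs["welch_t"] = t
        res.attrs["welch_p"] = p
        res.attrs["reduction"] = tnb_reduction(res.loc["CxC", "tnb_mean"],
                                               res.loc["CxNC", "tnb_mean"])
    return res
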