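"""Candidate causal-variant selection for a lethal haplotype.

Given an annotated sequence-variant panel and a candidate haplotype, a
causal recessive-lethal variant must (1) lie within a flanking distance
of the haplotype boundaries, (2) have at most one homozygous-alternate
animal (one false genotype assignment tolerated), (3) co-segregate with
the haplotype — heterozygous in carriers, absent from non-carriers, again
tolerating one discordant animal — and (4) be in high LD (dosage r²) with
the haplotype. Survivors are ranked high-impact first (loss-of-function
classes, then deleterious missense), then by r².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import haplotype_carrier_status
from .types import CandidateHaplotype, PhasedGenotypes, VariantRecord


@dataclass
class FilterCriteria:
    """Co-segregation and LD criteria for candidate causal variants."""

    flank_bp: int = 5_000_000
    r2_min: float = 0.8      # 0.7 also defensible; both thresholds in use upstream
    max_hom: int = 1
    require_class: frozenset | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min must lie in [0, 1]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


def haplotype_dosage(candidate: CandidateHaplotype,
                     genotypes: PhasedGenotypes) -> np.ndarray:
    """Per-animal copies (0/1/2) of the candidate haplotype; NaN when any
    window marker is missing."""
    status = haplotype_carrier_status(candidate, genotypes)
    return np.array([float(status[a]) if a in status else np.nan
                     for a in genotypes.animal_ids])


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs.

    This is the genotype-dosage r² convention of standard association
    toolkits; it is invariant to allele relabelling (y -> 2 - y). Returns
    NaN with a warning when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete dosage pairs")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        warnings.warn("constant dosage vector: r^2 undefined")
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def candidate_variants(panel: list[VariantRecord],
                       candidate: CandidateHaplotype,
                       genotypes: PhasedGenotypes,
                       criteria: FilterCriteria | None = None) -> pd.DataFrame:
    """Filter and rank candidate causal variants for one haplotype.

    Returns a table sorted by rank with one row per passing variant and
    the measured r², heterozygous-carrier count, homozygote count and
    impact flag. An empty result is a valid outcome (not every lethal
    haplotype tags a coding causal variant).
    """
    crit = criteria or FilterCriteria()
    hap_dos = haplotype_dosage(candidate, genotypes)
    lo = candidate.start_bp - crit.flank_bp
    hi = candidate.end_bp + crit.flank_bp

    rows = []
    for v in panel:
        if v.chrom != candidate.chrom or not (lo <= v.pos <= hi):
            continue
        if crit.require_class is not None and v.consequence_class not in crit.require_class:
            continue
        d = v.dosages
        ok = ~(np.isnan(d) | np.isnan(hap_dos))
        n_hom = int(np.nansum(d == 2))
        if n_hom > crit.max_hom:
            continue
        carrier = ok & (hap_dos >= 1)
        noncarrier = ok & (hap_dos == 0)
        mismatch = int((d[carrier] == 0).sum()) + int((d[noncarrier] >= 1).sum())
        if mismatch > 1:
            continue
        try:
            r2 = ld_r2(d, hap_dos)
        except ValueError:
            continue
        if not np.isfinite(r2) or r2 < crit.r2_min:
            continue
        rows.append({
            "id": v.vid, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
            "alt": v.alt, "class": v.consequence_class, "r2": r2,
            "n_het_carriers": int(np.nansum(d[carrier] == 1)),
            "n_hom": n_hom, "n_mismatch": mismatch,
            "high_impact": v.is_high_impact,
            "impact_rank": 0 if v.is_lof else
                           (1 if (v.consequence_class == "missense" and v.deleterious)
                            else 2),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["impact_rank", "r2"], ascending=[True, False],
                        kind="mergesort").reset_index(drop=True)
    df.attrs["no_high_impact_candidate"] = not bool(df["high_impact"].any())
    return df
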