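"""Core in-memory containers shared across the pipeline.

The substrate of every analysis here is a set of *phased* diploid SNP
genotypes: for each animal two haploid allele sequences over a common
marker map, so that haplotype identity can be established by exact
allele-vector match over a window. Pedigree and litter records carry the
parent-offspring structure and per-litter fertility counts used by the
trio-based homozygosity expectation and the fertility-impact statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing haploid allele call
MISSING = -1

#: closed vocabulary of variant consequence classes
CONSEQUENCE_CLASSES = (
    "splice_acceptor",
    "splice_donor",
    "frameshift",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "inframe_indel",
    "missense",
    "synonymous",
    "intergenic",
)

#: classes treated as putative loss-of-function (high impact)
LOF_CLASSES = frozenset(
    {"splice_acceptor", "splice_donor", "frameshift", "stop_gained",
     "stop_lost", "start_lost"}
)


@dataclass
class PhasedGenotypes:
    """Phased diploid genotypes: animals x markers x 2 haploid calls.

    Parameters
    ----------
    animal_ids
        One identifier per animal.
    marker_map
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``ref``,
        ``alt``; positions strictly increasing within a chromosome.
    alleles
        int8 array of shape ``(n_animals, n_markers, 2)`` holding 0/1
        allele calls, :data:`MISSING` for no-calls. A missing call
        occupies both haploids of a site or neither.
    phased
        Whether haploid sequences represent true parental phase.
    """

    animal_ids: np.ndarray
    marker_map: pd.DataFrame
    alleles: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_animals, n_markers, 2)")
        if self.alleles.shape[0] != len(self.animal_ids):
            raise ValueError("animal_ids length does not match alleles")
        if self.alleles.shape[1] != len(self.marker_map):
            raise ValueError("marker_map length does not match alleles")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        miss = self.alleles == MISSING
        if np.any(miss[:, :, 0] != miss[:, :, 1]):
            raise ValueError("missing calls must affect both haploids of a site")

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def dosages(self) -> np.ndarray:
        """Per-animal alternate-allele dosage (float, NaN for missing)."""
        d = self.alleles.sum(axis=2).astype(float)
        d[self.alleles[:, :, 0] == MISSING] = np.nan
        return d

    def marker_indices(self, chrom, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of markers on ``chrom`` with start_bp <= pos < end_bp."""
        mm = self.marker_map
        sel = (mm["chrom"] == chrom) & (mm["pos"] >= start_bp) & (mm["pos"] < end_bp)
        return np.flatnonzero(sel.to_numpy())

    def take_animals(self, idx: np.ndarray) -> "PhasedGenotypes":
        return PhasedGenotypes(self.animal_ids[idx], self.marker_map,
                               self.alleles[idx], self.phased)

    def take_markers(self, idx: np.ndarray) -> "PhasedGenotypes":
        return PhasedGenotypes(self.animal_ids,
                               self.marker_map.iloc[idx].reset_index(drop=True),
                               self.alleles[:, idx], self.phased)

    def scramble_phase(self, rng: np.random.Generator) -> "PhasedGenotypes":
        """Randomly swap haploids per animal-site; marks output unphased."""
        a = self.alleles.copy()
        swap = rng.random(a.shape[:2]) < 0.5
        a[swap] = a[swap][:, ::-1]
        return PhasedGenotypes(self.animal_ids, self.marker_map, a, phased=False)


PEDIGREE_COLUMNS = ["animal", "sire", "dam", "sex", "birthdate"]


@dataclass
class Pedigree:
    """Parent-offspring links; founders have null (NaN/empty) parents.

    ``records`` is a DataFrame with columns animal, sire, dam, sex
    ('M'/'F'), birthdate (datetime-like). Invariant: acyclic, every
    non-founder's parents exist in the pedigree and predate it.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing_cols = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"pedigree missing columns: {missing_cols}")
        df["birthdate"] = pd.to_datetime(df["birthdate"])
        if df["animal"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        self.records = df
        self.validate()

    def validate(self) -> None:
        df = self.records
        born = dict(zip(df["animal"], df["birthdate"]))
        for parent_col in ("sire", "dam"):
            par = df[parent_col]
            known = par.notna() & (par != "")
            for child, parent, bd in zip(df.loc[known, "animal"],
                                         par[known],
                                         df.loc[known, "birthdate"]):
                if parent not in born:
                    raise ValueError(f"{parent_col} {parent!r} of {child!r} not in pedigree")
                if born[parent] >= bd:
                    raise ValueError(
                        f"{parent_col} {parent!r} does not predate offspring {child!r}"
                    )

    def parents_of(self) -> pd.DataFrame:
        """animal-indexed frame of sire and dam (NaN for founders)."""
        return self.records.set_index("animal")[["sire", "dam"]]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LitterRecord:
    """One farrowing record with fertility counts.

    TNB = total number born, NBA = number born alive, NSB = stillborn,
    MUM = mummified. Invariant NBA + NSB = TNB. ``piglet_genotypes``
    optionally counts surviving piglets by lethal-locus genotype.
    """

    sire: str
    dam: str
    mating_date: object
    tnb: int
    nba: int
    nsb: int
    mum: int
    piglet_genotypes: dict | None = None  # {'wt/wt': n, 'wt/mut': n, 'mut/mut': n}

    def __post_init__(self) -> None:
        if self.nba + self.nsb != self.tnb:
            raise ValueError("NBA + NSB must equal TNB")
        if min(self.tnb, self.nba, self.nsb, self.mum) < 0:
            raise ValueError("litter counts must be non-negative")


def litters_to_frame(litters: list[LitterRecord]) -> pd.DataFrame:
    rows = []
    for lit in litters:
        row = {"sire": lit.sire, "dam": lit.dam, "date": lit.mating_date,
               "TNB": lit.tnb, "NBA": lit.nba, "NSB": lit.nsb, "MUM": lit.mum}
        if lit.piglet_genotypes is not None:
            row["n_wtwt"] = lit.piglet_genotypes.get("wt/wt", 0)
            row["n_wtmut"] = lit.piglet_genotypes.get("wt/mut", 0)
            row["n_mutmut"] = lit.piglet_genotypes.get("mut/mut", 0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class VariantRecord:
    """A sequence variant with consequence annotation and dosages."""

    chrom: object
    pos: int
    ref: str
    alt: str
    consequence_class: str
    dosages: np.ndarray  # per-animal 0/1/2, NaN missing
    deleterious: bool = False
    vid: str | None = None

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence_class!r}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @property
    def is_lof(self) -> bool:
        return self.consequence_class in LOF_CLASSES

    @property
    def is_high_impact(self) -> bool:
        """LoF class, or missense predicted deleterious."""
        return self.is_lof or (self.consequence_class == "missense" and self.deleterious)


@dataclass
class CandidateHaplotype:
    """A haplotype with a homozygosity deficit: one candidate-table row.

    ``n_genotyped`` (N) counts animals fully called in the window,
    ``carriers`` (C) heterozygous carriers, ``homozygotes_observed`` (O)
    animals carrying two copies. ``hap_freq`` f = copies/(2N);
    ``expected_freq`` = N·f² under Hardy-Weinberg; ``expected_trio`` =
    0.25 per genotyped offspring of two carrier parents. ``p_deficit``
    is the one-sided lower-tail exact binomial P(X <= O | N, f²).
    """

    name: str
    chrom: object
    start_bp: int
    end_bp: int
    hap_alleles: np.ndarray
    marker_idx: np.ndarray
    n_genotyped: int
    carriers: int
    homozygotes_observed: int
    hap_freq: float
    expected_freq: float
    p_deficit: float
    carrier_animals: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    expected_trio: float | None = None
    p_trio: float | None = None
    cxc_progeny: int | None = None
    cxc_het_progeny: int | None = None
    n_windows_merged: int = 1
    merged_start_bp: int | None = None
    merged_end_bp: int | None = None
    bonferroni_significant: bool | None = None

    @property
    def carrier_freq(self) -> float:
        return self.carriers / self.n_genotyped

    @property
    def cxc_het_fraction(self) -> float | None:
        if not self.cxc_progeny:
            return None
        return self.cxc_het_progeny / self.cxc_progeny

    def to_row(self) -> dict:
        """One row shaped like the published candidate table."""
        return {
            "Hap": self.name,
            "chrom": self.chrom,
            "start_bp": self.start_bp,
            "end_bp": self.end_bp,
            "start_Mb": round(self.start_bp / 1e6, 1),
            "end_Mb": round(self.end_bp / 1e6, 1),
            "n_carriers": self.carriers,
            "carrier_freq": self.carrier_freq,
            "expected_trio": self.expected_trio,
            "expected_freq": self.expected_freq,
            "observed": self.homozygotes_observed,
            "p_deficit": self.p_deficit,
            "p_trio": self.p_trio,
            "n_cxc_progeny": self.cxc_progeny,
            "n_het_progeny": self.cxc_het_progeny,
            "het_progeny_fraction": self.cxc_het_fraction,
            "bonferroni_significant": self.bonferroni_significant,
        }
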