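"""Shared constants, domain types and pipeline configuration.

The analysis revolves around three modifier SNPs near *C9orf72*:

=============  =====  =====  ==============================
SNP            ref    alt    role
=============  =====  =====  ==============================
rs2492816      G      A      intron-3 eQTL/sQTL, alt raises expression
rs13691        G      A      3'UTR eQTL, alt lowers expression
rs113860022    C      G      rare promoter variant, alt strongly lowers
=============  =====  =====  ==============================

Population variation at the three SNPs is explained by four founder
haplotypes, one of which — rs2492816-A together with rs13691-A — is absent.
The hexanucleotide repeat expansion (HRE) travels exclusively on the
rs2492816-A / rs13691-G / rs113860022-C background, so in an expansion
carrier the residual, wild-type allele (WTA) can be read off the unphased
genotypes.  WTA haplotypes are ordinally coded by increasing *C9orf72*
expression: 0 = super-low, 1 = low, 2 = medium, 3 = high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

SNP_IDS = ("rs2492816", "rs13691", "rs113860022")

#: ref/alt alleles per SNP, in SNP_IDS order
SNP_ALLELES = {
    "rs2492816": ("G", "A"),
    "rs13691": ("G", "A"),
    "rs113860022": ("C", "G"),
}

#: haplotype carried by the repeat-expansion (mutant) allele
HRE_HAPLOTYPE = ("A", "G", "C")

#: founder WTA haplotype -> ordinal subgroup code (increasing expression)
FOUNDER_CODES = {
    ("G", "A", "G"): 0,  # C9-super-low
    ("G", "A", "C"): 1,  # C9-low
    ("G", "G", "C"): 2,  # C9-medium
    ("A", "G", "C"): 3,  # C9-high
}

SUBGROUP_LABELS = {0: "C9-super-low", 1: "C9-low", 2: "C9-medium", 3: "C9-high"}

#: candidate genes for the loss-of-function expression screen
DEFAULT_CANDIDATE_GENES = ("NEK1", "OPTN", "TBK1", "SETX", "SPG11", "ATP13A2")


@dataclass(frozen=True)
class GenotypeTriple:
    """Unphased allele pairs at the three modifier SNPs for one individual.

    Each field is a sorted 2-tuple of allele strings, or ``None`` when the
    genotype is missing at that SNP.  Phase is never represented.
    """

    rs2492816: Optional[tuple[str, str]]
    rs13691: Optional[tuple[str, str]]
    rs113860022: Optional[tuple[str, str]]

    def __post_init__(self):
        for snp in SNP_IDS:
            pair = getattr(self, snp)
            if pair is None:
                continue
            allowed = set(SNP_ALLELES[snp])
            if len(pair) != 2 or not set(pair) <= allowed:
                raise ValueError(f"alleles {pair!r} not in {allowed} for {snp}")
            if tuple(sorted(pair)) != tuple(pair):
                object.__setattr__(self, snp, tuple(sorted(pair)))

    @property
    def complete(self) -> bool:
        return all(getattr(self, snp) is not None for snp in SNP_IDS)

    def pairs(self) -> tuple:
        return (self.rs2492816, self.rs13691, self.rs113860022)

    @classmethod
    def from_strings(cls, g1: str, g2: str, g3: str) -> "GenotypeTriple":
        """Build from two-letter genotype strings, e.g. ``("GA", "AG", "GC")``."""

        def parse(s):
            if s is None or s in ("..", "NN"):
                return None
            return tuple(sorted(s))

        return cls(parse(g1), parse(g2), parse(g3))


@dataclass
class PipelineConfig:
    """End-to-end analysis settings with the study's published defaults."""

    snp_ids: tuple = SNP_IDS
    snp_alleles: dict = field(default_factory=lambda: dict(SNP_ALLELES))
    hre_haplotype: tuple = HRE_HAPLOTYPE
    #: fraction removed from each survival/time tail before regression
    trim_fraction: float = 0.05
    #: ALSFRS-R total anchored at onset and at death
    alsfrs_onset_anchor: float = 48.0
    alsfrs_death_anchor: float = 0.0
    #: primary time-to-threshold score (half of the 48-point maximum)
    alsfrs_threshold: int = 24
    alsfrs_scan_range: tuple = (3, 45)
    #: onset sites retained for survival analysis
    onset_sites: tuple = ("limb", "bulbar")
    #: covariates used in the per-base footprint dose test
    footprint_covariates: tuple = ("sex", "frip")
    #: IQR multiplier for the low-expression outlier screen
    outlier_iqr_k: float = 3.0
    candidate_genes: tuple = DEFAULT_CANDIDATE_GENES
    missing_haplotype_eps: float = 0.005
    em_tol: float = 1e-8
    em_max_iter: int = 10_000
    junction_min_count: int = 5
    junction_noise_count: int = 2
    junction_window: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if not 0 <= self.alsfrs_threshold <= 48:
            raise ValueError("alsfrs_threshold must lie in [0, 48]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("snp_ids", "hre_haplotype", "onset_sites", "candidate_genes",
                    "footprint_covariates", "alsfrs_scan_range"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass
class EffectEstimate:
    """A slope or mean-difference with its uncertainty."""

    estimate: float
    se: float
    p: float
    n: int
    transform: Optional[str] = None

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if not 0 <= self.p <= 1:
            raise ValueError("p-value must lie in [0, 1]")
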