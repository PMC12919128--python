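"""Founder-haplotype inference and WTA subgroup assignment.

Frequencies of the founder haplotypes are estimated from unphased genotypes
with the classic two/three-locus EM algorithm: phase-ambiguous
multi-heterozygotes are fractionally assigned to the compatible haplotype
pairs in proportion to the current frequency products (E-step), and expected
haplotype counts are renormalised (M-step).  Under Hardy–Weinberg random
pairing the log-likelihood is non-decreasing across iterations, which the
implementation asserts on every run.

For repeat-expansion carriers the wild-type allele (WTA) is obtained by
subtracting the invariant HRE haplotype from the unphased genotype triple;
the residual must be one of the four founder haplotypes and maps to the
ordinal subgroup code 0–3.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    EffectEstimate,
    FOUNDER_CODES,
    GenotypeTriple,
    HRE_HAPLOTYPE,
    SNP_ALLELES,
    SNP_IDS,
    SUBGROUP_LABELS,
)

logger = logging.getLogger(__name__)


class HREIncompatibleGenotypeError(ValueError):
    """Genotype lacks an allele required by the repeat-expansion haplotype."""


class NonFounderWTAError(ValueError):
    """Residual wild-type haplotype is not one of the four founders."""


@dataclass
class HaplotypeFrequencies:
    """EM-estimated haplotype frequency vector with convergence metadata."""

    freqs: dict  # haplotype tuple -> frequency
    log_likelihood: float
    iterations: int
    converged: bool
    n_samples: int
    loglik_trace: list = field(default_factory=list, repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"/".join(h): f for h, f in self.freqs.items()}, name="frequency"
        )


@dataclass
class SubgroupCode:
    """Ordinal WTA subgroup for an HRE carrier (0 super-low … 3 high)."""

    code: int
    wta_haplotype: tuple
    label: str


# ---------------------------------------------------------------------------
# EM frequency estimation
# ---------------------------------------------------------------------------

def _select_pairs(triple: GenotypeTriple, idx: Sequence[int]):
    pairs = [triple.pairs()[i] for i in idx]
    if any(p is None for p in pairs):
        return None
    return tuple(pairs)


def _haplotype_space(idx: Sequence[int]):
    allele_sets = [SNP_ALLELES[SNP_IDS[i]] for i in idx]
    return [tuple(h) for h in itertools.product(*allele_sets)]


def _compatible_pairs(genotype, haplotypes):
    """Ordered haplotype pairs whose per-site allele multisets match."""
    out = []
    for h1, h2 in itertools.product(haplotypes, repeat=2):
        if all(tuple(sorted((a, b))) == g for a, b, g in zip(h1, h2, genotype)):
            out.append((h1, h2))
    return out


def em_haplotype_frequencies(
    genotypes: Iterable[GenotypeTriple],
    snps: Sequence[int] = (0, 1),
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HaplotypeFrequencies:
    """Estimate haplotype frequencies over the selected SNPs.

    Parameters
    ----------
    genotypes
        Unphased genotype triples; samples missing any selected SNP are
        excluded.
    snps
        Indices into ``(rs2492816, rs13691, rs113860022)`` — ``(0, 1)`` for
        the two common variants, ``(0, 1, 2)`` for the 3-SNP extension.
    tol
        Convergence threshold on the maximum frequency change.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    obs = []
    for g in genotypes:
        sel = _select_pairs(g, snps)
        if sel is not None:
            obs.append(sel)
    if not obs:
        raise ValueError("no complete genotypes at the selected SNPs")

    haps = _haplotype_space(snps)
    hap_index = {h: i for i, h in enumerate(haps)}
    counts = pd.Series(obs).value_counts()
    categories = list(counts.index)
    weights = counts.to_numpy(dtype=float)
    n = weights.sum()

    # pre-compute compatible ordered pairs per observed genotype category
    pair_lists = [
        [(hap_index[a], hap_index[b]) for a, b in _compatible_pairs(g, haps)]
        for g in categories
    ]

    # initialise at the product of marginal allele frequencies
    freqs = np.ones(len(haps))
    for site, i in enumerate(snps):
        _, alt = SNP_ALLELES[SNP_IDS[i]]
        alt_count = sum(w * g[site].count(alt) for g, w in zip(categories, weights))
        p_alt = alt_count / (2 * n)
        for h, j in hap_index.items():
            freqs[j] *= p_alt if h[site] == alt else 1 - p_alt
    if freqs.sum() == 0:  # degenerate marginals; fall back to flat
        freqs = np.ones(len(haps))
    freqs /= freqs.sum()

    def loglik(f):
        ll = 0.0
        for pl, w in zip(pair_lists, weights):
            p = sum(f[i] * f[j] for i, j in pl)
            ll += w * (math.log(p) if p > 0 else -math.inf)
        return ll

    trace = [loglik(freqs)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(len(haps))
        for pl, w in zip(pair_lists, weights):
            probs = np.array([freqs[i] * freqs[j] for i, j in pl])
            tot = probs.sum()
            if tot == 0:
                continue
            probs /= tot
            for (i, j), pr in zip(pl, probs):
                expected[i] += w * pr
                expected[j] += w * pr
        new = expected / (2 * n)
        delta = np.abs(new - freqs).max()
        freqs = new
        ll = loglik(freqs)
        if ll < trace[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        trace.append(ll)
        if delta < tol:
            converged = True
            break

    return HaplotypeFrequencies(
        freqs={h: float(freqs[hap_index[h]]) for h in haps},
        log_likelihood=float(trace[-1]),
        iterations=it,
        converged=converged,
        n_samples=int(n),
        loglik_trace=trace,
    )


def detect_missing_haplotype(
    freqs: HaplotypeFrequencies, eps: float = 0.005
) -> list:
    """Haplotypes with estimated frequency below ``eps`` (exact zeros always)."""
    return [h for h, f in freqs.freqs.items() if f < eps or f == 0.0]


# ---------------------------------------------------------------------------
# Rare-allele nesting
# ---------------------------------------------------------------------------

def test_rare_allele_nesting(genotypes: Iterable[GenotypeTriple]) -> dict:
    """Check that every rs113860022-G copy can sit on a rs2492816-G/rs13691-A
    background, as required if the rare allele is nested inside the C9-low
    haplotype.

    Returns a report dict with carrier counts; a carrier is *compatible* when
    some phase assignment places all of its G copies on (G, A, ·) haplotypes.
    """
    all_haps = _haplotype_space((0, 1, 2))
    n_carriers = 0
    compatible = 0
    incompatible_samples = []
    for k, g in enumerate(genotypes):
        if g.rs113860022 is None or "G" not in g.rs113860022:
            continue
        if g.rs2492816 is None or g.rs13691 is None:
            continue
        n_carriers += 1
        ok = False
        for h1, h2 in _compatible_pairs(g.pairs(), all_haps):
            if all(
                h[:2] == ("G", "A") for h in (h1, h2) if h[2] == "G"
            ):
                ok = True
                break
        if ok:
            compatible += 1
        else:
            incompatible_samples.append(k)
    return {
        "n_carriers": n_carriers,
        "compatible": compatible,
        "incompatible": n_carriers - compatible,
        "incompatible_indices": incompatible_samples,
        "note": "no carriers" if n_carriers == 0 else "",
    }


# ---------------------------------------------------------------------------
# WTA subgroup assignment
# ---------------------------------------------------------------------------

def assign_wta_subgroup(triple: GenotypeTriple, hre_carrier: bool = True) -> SubgroupCode:
    """Subtract the HRE haplotype from an expansion carrier's unphased triple
    and code the residual wild-type haplotype.

    Raises
    ------
    HREIncompatibleGenotypeError
        if the triple lacks an A at rs2492816, a G at rs13691 or a C at
        rs113860022 (all demanded by the co-inheritance of the expansion
        with the A/G/C background).
    NonFounderWTAError
        if the residual is not one of the four founder haplotypes.
    """
    if not hre_carrier:
        raise ValueError("WTA subgroups are defined only for HRE carriers")
    if not triple.complete:
        raise ValueError("genotype triple must be complete")
    residual = []
    for pair, hre_allele, snp in zip(triple.pairs(), HRE_HAPLOTYPE, SNP_IDS):
        if hre_allele not in pair:
            raise HREIncompatibleGenotypeError(
                f"HRE-incompatible genotype: no {hre_allele} at {snp}"
            )
        rest = list(pair)
        rest.remove(hre_allele)
        residual.append(rest[0])
    wta = tuple(residual)
    if wta not in FOUNDER_CODES:
        raise NonFounderWTAError(f"non-founder WTA haplotype {wta}")
    code = FOUNDER_CODES[wta]
    return SubgroupCode(code=code, wta_haplotype=wta, label=SUBGROUP_LABELS[code])


def diplotype_label(triple: GenotypeTriple) -> Optional[str]:
    """Founder-diplotype label for a non-carrier, or None if ambiguous or
    inconsistent with the founder set.

    Enumerates phase-consistent founder haplotype pairs; a unique unordered
    pair yields a label like ``"GAC|GGC"``.
    """
    if not triple.complete:
        return None
    founders = list(FOUNDER_CODES)
    pairs = {
        tuple(sorted(("".join(h1), "".join(h2))))
        for h1, h2 in _compatible_pairs(triple.pairs(), founders)
    }
    if len(pairs) != 1:
        return None
    return "|".join(next(iter(pairs)))


# ---------------------------------------------------------------------------
# Marginal dosage effects
# ---------------------------------------------------------------------------

def dosage_effect(
    y: Sequence[float],
    dose: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
) -> EffectEstimate:
    """OLS slope of a phenotype on alt-allele dosage (0/1/2), optionally
    adjusted for covariates.
    """
    y = np.asarray(y, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if y.shape != dose.shape:
        raise ValueError("y and dose must have equal length")
    if len(np.unique(dose)) < 2:
        raise ValueError("dose is constant; no effect is estimable")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    X = pd.DataFrame({"dose": dose})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()
    return EffectEstimate(
        estimate=float(fit.params["dose"]),
        se=float(fit.bse["dose"]),
        p=float(min(max(fit.pvalues["dose"], 0.0), 1.0)) if np.isfinite(fit.pvalues["dose"]) else 1.0,
        n=int(y.size),
    )


def alt_dose(triple: GenotypeTriple, snp: str) -> Optional[int]:
    """Alt-allele count (0/1/2) at one SNP, or None when missing."""
    pair = getattr(triple, snp)
    if pair is None:
        return None
    return sum(a == SNP_ALLELES[snp][1] for a in pair)
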