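"""Site-level hybrid-swarm diagnostics.

A sampled site is called a hybrid swarm when three conditions hold
jointly: no parental fish of any taxon was sampled, species-diagnostic
alleles are randomly distributed among individuals (binomial test), and
genotypes are in Hardy-Weinberg proportions.  The binomial test follows
the sample-level plug-in construction: each fish's nonnative-allele
count is compared with a Binomial(2L_i, p-hat) draw, via a chi-square
style statistic whose null distribution is obtained by parametric
bootstrap (the named references describe the comparison but not a
statistic, so the statistic choice is documented here and seeded for
reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .admixture import classify_individual, estimate_admixture, taxa_present
from .model import (
    MISSING,
    TAXA,
    TAXON_INDEX,
    GenotypeRecord,
    HybridClass,
    MarkerPanel,
)

CONSISTENT_Y = "consistent_Y"
REJECTED_N = "rejected_N"
NOT_APPLICABLE = "not_applicable_NA"


@dataclass
class SwarmTestResult:
    p_hat: Optional[float]
    statistic: Optional[float]
    p_value: Optional[float]
    n_bootstrap: int
    seed: int
    decision: str

    @property
    def flag(self) -> str:
        """Printed-table style flag: Y, N, or NA."""
        return {CONSISTENT_Y: "Y", REJECTED_N: "N", NOT_APPLICABLE: "NA"}[self.decision]


@dataclass
class HWEResult:
    loci_examined: int
    n_deficit_significant: int
    n_excess_significant: int
    fis_multilocus: Optional[float]
    out_of_hwp: bool


@dataclass
class SiteSummary:
    site_id: str
    n: int
    parental_counts: Dict[str, int]
    allele_percentages: Dict[str, float]
    swarm_test: Optional[SwarmTestResult]
    hwe: Optional[HWEResult]
    is_swarm: bool
    classes: List[HybridClass] = field(default_factory=list)


def site_allele_percentages(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
) -> Dict[str, float]:
    """Per-taxon allele percentages for one site.

    With alleles of at most two taxa present, percentages are pooled
    allele counts over the pair panel.  When all three taxa contribute,
    the site value is the mean of per-fish maximum-likelihood estimates
    weighted by each fish's typed-allele count (mirroring how three-way
    fish are handled individually).
    """
    if not records:
        raise ValueError("no records at site")
    union: set = set()
    for r in records:
        union.update(taxa_present(r, panel))
    if len(union) <= 2:
        pair = _pad_pair(union)
        ia = TAXON_INDEX[pair[0]]
        idx = panel.indices_for_taxa(pair)
        is_a = panel.taxon_of[idx] == ia
        a_alleles = 0
        total = 0
        for r in records:
            calls = r.calls[idx]
            typed = calls != MISSING
            d = calls[typed].astype(int)
            a_alleles += int(d[is_a[typed]].sum() + (2 - d[~is_a[typed]]).sum())
            total += 2 * int(typed.sum())
        if total == 0:
            raise ValueError("no successful calls at site")
        out = {t: 0.0 for t in TAXA}
        out[pair[0]] = 100.0 * a_alleles / total
        out[pair[1]] = 100.0 - out[pair[0]]
        return out
    weights = []
    qs = []
    for r in records:
        est = estimate_admixture(r, panel)
        qs.append(est.q)
        weights.append(est.alleles_counted)
    w = np.asarray(weights, dtype=float)
    q_bar = (np.vstack(qs) * w[:, None]).sum(axis=0) / w.sum()
    return {t: 100.0 * float(q_bar[i]) for i, t in enumerate(TAXA)}


def _pad_pair(union: set) -> Tuple[str, str]:
    taxa = sorted(union, key=TAXA.index)
    if len(taxa) == 2:
        return taxa[0], taxa[1]
    t = taxa[0] if taxa else "WCT"
    other = "RT" if t != "RT" else "WCT"
    return t, other


def classify_site(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    **classify_kwargs,
) -> List[HybridClass]:
    return [
        classify_individual(r, estimate_admixture(r, panel), panel, **classify_kwargs)
        for r in records
    ]


def loci_examined_for_site(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    classes: Optional[Sequence[HybridClass]] = None,
) -> Optional[int]:
    """Number of loci for HWE testing: the union of pair panels for the
    taxa whose alleles occur in admixed individuals.

    Returns None when the site has no admixed fish (no test applies).
    """
    if classes is None:
        classes = classify_site(records, panel)
    union: set = set()
    for r, c in zip(records, classes):
        if not c.is_parental:
            union.update(taxa_present(r, panel))
    if not union:
        return None
    if len(union) == 1:
        union = set(_pad_pair(union))
    counts = panel.counts_by_taxon
    return sum(counts[t] for t in union)


def _examined_taxa(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    classes: Sequence[HybridClass],
    majority: str,
) -> Tuple[str, ...]:
    union: set = {majority}
    for r, c in zip(records, classes):
        if not c.is_parental:
            union.update(taxa_present(r, panel))
    if len(union) == 1:
        union = set(_pad_pair(union))
    return tuple(sorted(union, key=TAXA.index))


def binomial_randomness_test(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    B: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    min_n: int = 10,
    classes: Optional[Sequence[HybridClass]] = None,
    nonnative_reference: Optional[str] = None,
) -> SwarmTestResult:
    """Test whether diagnostic alleles are randomly distributed among fish.

    Fish i carries k_i nonnative alleles among 2 L_i typed pair-panel
    alleles; under random mating k_i ~ Binomial(2 L_i, p) with a shared
    p.  The statistic is X = sum_i (k_i - 2 L_i p_hat)^2 /
    (2 L_i p_hat (1 - p_hat)); its null distribution comes from B
    parametric-bootstrap replicates in which p_hat is re-estimated, so
    the plug-in estimation is accounted for.  Sites with fewer than
    ``min_n`` fish or without admixed fish are not analyzed (NA), as are
    degenerate sites with p_hat of exactly 0 or 1.

    ``nonnative_reference`` fixes which taxon counts as "native"; by
    default it is the site's majority taxon by pooled allele share.
    """
    if classes is None:
        classes = classify_site(records, panel)
    n_admixed = sum(1 for c in classes if not c.is_parental)
    if len(records) < min_n or n_admixed == 0:
        return SwarmTestResult(None, None, None, B, seed, NOT_APPLICABLE)

    pcts = site_allele_percentages(records, panel)
    majority = nonnative_reference or max(pcts, key=lambda t: pcts[t])
    examined = _examined_taxa(records, panel, classes, majority)
    idx = panel.indices_for_taxa(examined)
    is_native = panel.taxon_of[idx] == TAXON_INDEX[majority]

    k = []
    two_L = []
    for r in records:
        calls = r.calls[idx]
        typed = calls != MISSING
        d = calls[typed].astype(int)
        nonnative = int((2 - d[is_native[typed]]).sum() + d[~is_native[typed]].sum())
        k.append(nonnative)
        two_L.append(2 * int(typed.sum()))
    k = np.asarray(k, dtype=float)
    two_L = np.asarray(two_L, dtype=float)
    if np.any(two_L == 0):
        keep = two_L > 0
        k, two_L = k[keep], two_L[keep]
    p_hat = k.sum() / two_L.sum()
    if p_hat <= 0.0 or p_hat >= 1.0:
        return SwarmTestResult(float(p_hat), None, None, B, seed, NOT_APPLICABLE)

    def statistic(kv: np.ndarray, p: float) -> np.ndarray:
        expected = two_L * p
        var = two_L * p * (1.0 - p)
        return np.sum((kv - expected) ** 2 / var, axis=-1)

    X = float(statistic(k, p_hat))
    rng = np.random.default_rng(seed)
    k_star = rng.binomial(two_L.astype(int), p_hat, size=(B, len(k))).astype(float)
    p_star = k_star.sum(axis=1) / two_L.sum()
    # degenerate replicates (all-0 or all-1) have X* = 0 under their own
    # p-hat; they cannot exceed an observed X > 0
    ok = (p_star > 0) & (p_star < 1)
    X_star = np.zeros(B)
    if ok.any():
        expected = two_L[None, :] * p_star[ok, None]
        var = two_L[None, :] * (p_star[ok, None] * (1 - p_star[ok, None]))
        X_star[ok] = np.sum((k_star[ok] - expected) ** 2 / var, axis=1)
    p_value = float(np.mean(X_star >= X))
    decision = REJECTED_N if p_value < alpha else CONSISTENT_Y
    return SwarmTestResult(float(p_hat), X, p_value, B, seed, decision)


def hwe_exact_locus(n_AA: int, n_Aa: int, n_aa: int) -> Tuple[float, float]:
    """Exact conditional Hardy-Weinberg test for a biallelic locus.

    Conditions on the observed allele counts and enumerates every
    compatible heterozygote count h (same parity as the minor-allele
    count); P(h) follows the standard conditional distribution
    proportional to  2^h * n! / (n_AA! h! n_aa!)  with the allele-count
    factorials fixed.  Returns one-sided tail probabilities
    (P(het <= observed), P(het >= observed)).  A monomorphic locus
    returns (1.0, 1.0).
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    if nA == 0 or na == 0:
        return 1.0, 1.0
    h_min = nA % 2
    h_max = min(nA, na)
    hs = np.arange(h_min, h_max + 1, 2)
    # log P(h) up to a shared constant
    n_AA_h = (nA - hs) // 2
    n_aa_h = (na - hs) // 2
    logp = hs * np.log(2.0) - (gammaln(n_AA_h + 1) + gammaln(hs + 1) + gammaln(n_aa_h + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = n_Aa
    p_deficit = float(p[hs <= obs].sum())
    p_excess = float(p[hs >= obs].sum())
    return p_deficit, p_excess


def fis_weir_cockerham_locus(n_AA: int, n_Aa: int, n_aa: int) -> Tuple[Optional[float], float, float]:
    """Weir & Cockerham small-sample f (F_IS) for one locus.

    Returns (f, b_component, c_component); the multilocus estimate is
    1 - sum(c) / sum(b + c) over polymorphic loci.  Positive f is a
    heterozygote deficit.  Monomorphic loci are undefined (None, 0, 0).
    """
    n = n_AA + n_Aa + n_aa
    if n < 2:
        raise ValueError("need at least two genotyped fish")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p == 0.0 or p == 1.0:
        return None, 0.0, 0.0
    h_obs = n_Aa / n
    b = (n / (n - 1.0)) * (p * (1 - p) - h_obs * (2 * n - 1) / (4 * n))
    c = h_obs / 2.0
    denom = b + c
    f = 1.0 - c / denom if denom != 0 else None
    return f, b, c


def _locus_genotype_counts(
    records: Sequence[GenotypeRecord],
    locus_index: int,
) -> Tuple[int, int, int]:
    col = np.array([r.calls[locus_index] for r in records])
    typed = col != MISSING
    d = col[typed]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def site_hwe(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    alpha: float = 0.05,
    classes: Optional[Sequence[HybridClass]] = None,
) -> Optional[HWEResult]:
    """Per-locus exact HWE tests and multilocus F_IS for one site.

    ``loci_examined`` is the full union pair-panel size; monomorphic
    loci count toward it but can never be significant.  A site is out
    of Hardy-Weinberg proportions when either significant-deficit or
    significant-excess counts exceed 5% of the loci examined.
    """
    if classes is None:
        classes = classify_site(records, panel)
    loci_examined = loci_examined_for_site(records, panel, classes)
    if loci_examined is None:
        return None
    union: set = set()
    for r, c in zip(records, classes):
        if not c.is_parental:
            union.update(taxa_present(r, panel))
    if len(union) == 1:
        union = set(_pad_pair(union))
    idx = panel.indices_for_taxa(sorted(union, key=TAXA.index))
    n_def = n_exc = 0
    b_sum = c_sum = 0.0
    any_poly = False
    for j in idx:
        n_AA, n_Aa, n_aa = _locus_genotype_counts(records, j)
        if n_AA + n_Aa + n_aa < 2:
            continue
        p_def, p_exc = hwe_exact_locus(n_AA, n_Aa, n_aa)
        if p_def < alpha:
            n_def += 1
        if p_exc < alpha:
            n_exc += 1
        f, b, c = fis_weir_cockerham_locus(n_AA, n_Aa, n_aa)
        if f is not None:
            any_poly = True
            b_sum += b
            c_sum += c
    fis = 1.0 - c_sum / (b_sum + c_sum) if any_poly and (b_sum + c_sum) != 0 else None
    return hwp_site_criterion(n_def, n_exc, loci_examined, alpha=alpha, fis_multilocus=fis)


def hwp_site_criterion(
    n_deficit_significant: int,
    n_excess_significant: int,
    loci_examined: int,
    alpha: float = 0.05,
    fis_multilocus: Optional[float] = None,
) -> HWEResult:
    """Apply the site-level 5%-of-loci rule (strict inequality)."""
    out = max(n_deficit_significant, n_excess_significant) > alpha * loci_examined
    return HWEResult(
        loci_examined=loci_examined,
        n_deficit_significant=n_deficit_significant,
        n_excess_significant=n_excess_significant,
        fis_multilocus=fis_multilocus,
        out_of_hwp=out,
    )


def swarm_classification(
    parental_counts: Mapping[str, int],
    swarm_test: Optional[SwarmTestResult],
    hwe: Optional[HWEResult],
) -> bool:
    """Hybrid swarm: no parental fish, random allele distribution, and
    Hardy-Weinberg proportions.  A site whose binomial test was not
    applicable cannot be classified as a swarm."""
    if sum(parental_counts.values()) > 0:
        return False
    if swarm_test is None or swarm_test.decision != CONSISTENT_Y:
        return False
    if hwe is None or hwe.out_of_hwp:
        return False
    return True


def summarize_site(
    site_id: str,
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    B: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    **classify_kwargs,
) -> SiteSummary:
    """Run the full site-level battery and compose the swarm decision."""
    classes = classify_site(records, panel, **classify_kwargs)
    parental_counts = {t: 0 for t in TAXA}
    for c in classes:
        if c.is_parental:
            parental_counts[c.taxa_involved[0]] += 1
    pcts = site_allele_percentages(records, panel)
    swarm_test = binomial_randomness_test(
        records, panel, B=B, alpha=alpha, seed=seed, classes=classes
    )
    hwe = site_hwe(records, panel, alpha=alpha, classes=classes)
    return SiteSummary(
        site_id=site_id,
        n=len(records),
        parental_counts=parental_counts,
        allele_percentages=pcts,
        swarm_test=swarm_test,
        hwe=hwe,
        is_swarm=swarm_classification(parental_counts, swarm_test, hwe),
        classes=list(classes),
    )
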