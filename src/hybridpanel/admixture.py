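"""Per-individual admixture estimation and hybrid classification.

For a fish carrying alleles of at most two taxa, the ancestry
proportion is a closed-form allele count over the pair panel (the loci
diagnostic for either member of the pair).  For a fish carrying alleles
of all three taxa the proportions are estimated by maximum likelihood:
at a locus diagnostic for taxon T the diagnostic allele has probability
q_T and the alternative allele probability 1 - q_T, which is shared by
the other two taxa.  The alternative alleles are therefore latently
attributed, and an EM iteration splits each one between the two
non-diagnostic taxa in proportion to their current q.  Missing calls
drop out of both numerator and denominator, so proportions are always
"of alleles actually genotyped".
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .model import (
    ADMIXED,
    F1,
    MISSING,
    PARENTAL,
    TAXA,
    TAXON_INDEX,
    AdmixtureEstimate,
    GenotypeRecord,
    HybridClass,
    MarkerPanel,
)


def taxa_present(record: GenotypeRecord, panel: MarkerPanel) -> Tuple[str, ...]:
    """Taxa with at least one observed diagnostic allele in this fish."""
    typed = record.typed_mask
    if not typed.any():
        raise ValueError(f"record {record.individual_id!r} has no successful calls")
    present = []
    for i, t in enumerate(TAXA):
        mask = typed & (panel.taxon_of == i)
        if record.calls[mask].sum() >= 1:
            present.append(t)
    return tuple(present)


def _diag_alt_counts(record: GenotypeRecord, panel: MarkerPanel) -> Tuple[np.ndarray, np.ndarray, int]:
    """Per-taxon (diagnostic, alternative) allele counts over typed loci."""
    typed = record.typed_mask
    diag = np.zeros(3)
    alt = np.zeros(3)
    for i in range(3):
        mask = typed & (panel.taxon_of == i)
        d = record.calls[mask].astype(int)
        diag[i] = d.sum()
        alt[i] = (2 - d).sum()
    loci_used = int(typed.sum())
    return diag, alt, loci_used


def _log_likelihood(q: np.ndarray, diag: np.ndarray, alt: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        lq = np.where(diag > 0, np.log(np.maximum(q, 1e-300)), 0.0)
        l1q = np.where(alt > 0, np.log(np.maximum(1.0 - q, 1e-300)), 0.0)
    return float(np.sum(diag * lq + alt * l1q))


def two_taxon_proportion(
    record: GenotypeRecord,
    panel: MarkerPanel,
    pair: Tuple[str, str],
) -> AdmixtureEstimate:
    """Closed-form ancestry for a fish with alleles of at most two taxa.

    Over the pair panel (loci diagnostic for either member), each
    diagnostic allele at an A-locus and each alternative allele at a
    B-locus counts toward A; the denominator is twice the number of
    successfully typed pair-panel loci.
    """
    a, b = pair
    ia, ib = TAXON_INDEX[a], TAXON_INDEX[b]
    idx = panel.indices_for_taxa(pair)
    calls = record.calls[idx]
    typed = calls != MISSING
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise ValueError(f"record {record.individual_id!r}: no typed loci in pair panel {pair}")
    is_a = panel.taxon_of[idx] == ia
    d = calls[typed].astype(int)
    a_alleles = int(d[is_a[typed]].sum() + (2 - d[~is_a[typed]]).sum())
    total = 2 * n_typed
    q = np.zeros(3)
    q[ia] = a_alleles / total
    q[ib] = 1.0 - q[ia]
    diag, alt, _ = _diag_alt_counts(record, panel)
    return AdmixtureEstimate(
        q=q,
        loci_used=n_typed,
        alleles_counted=total,
        log_likelihood=_log_likelihood(q, diag, alt),
        method="two_taxon_count",
    )


def threeway_em_admixture(
    record: GenotypeRecord,
    panel: MarkerPanel,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> AdmixtureEstimate:
    """Maximum-likelihood three-way ancestry by EM.

    E-step: each alternative allele at a locus diagnostic for T is
    fractionally attributed to the other taxa U in proportion
    q_U / (1 - q_T).  M-step: q becomes attributed totals over total
    typed alleles.  Initialized at the simplex barycenter (the
    boundary is absorbing), stops when the log-likelihood gain drops
    below ``tol``.  The log-likelihood is non-decreasing by
    construction; an iteration limit is reported via ``converged``.
    """
    diag, alt, loci_used = _diag_alt_counts(record, panel)
    total = float(diag.sum() + alt.sum())
    if total == 0:
        raise ValueError(f"record {record.individual_id!r} has no successful calls")
    q = np.full(3, 1.0 / 3.0)
    ll = _log_likelihood(q, diag, alt)
    converged = False
    for _ in range(max_iter):
        attributed = diag.copy()
        for t in range(3):
            if alt[t] == 0:
                continue
            others = [u for u in range(3) if u != t]
            denom = q[others].sum()
            if denom <= 0:
                # all alternative mass already collapsed onto taxon t's
                # complement boundary; split evenly to stay defined
                share = np.full(2, 0.5)
            else:
                share = q[others] / denom
            for u, s in zip(others, share):
                attributed[u] += alt[t] * s
        q_new = attributed / total
        ll_new = _log_likelihood(q_new, diag, alt)
        if ll_new < ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        gain = ll_new - ll
        q, ll = q_new, ll_new
        if gain < tol:
            converged = True
            break
    return AdmixtureEstimate(
        q=q,
        loci_used=loci_used,
        alleles_counted=int(total),
        log_likelihood=ll,
        method="threeway_em",
        converged=converged,
    )


def estimate_admixture(record: GenotypeRecord, panel: MarkerPanel) -> AdmixtureEstimate:
    """Dispatch: closed-form count for <=2 observed taxa, EM for three.

    A fish showing alleles of a single taxon is scored against the pair
    of that taxon and the most plausible alternative (RT, or WCT for a
    pure RT fish); its q for the unobserved taxa is 0 either way.
    """
    present = taxa_present(record, panel)
    if len(present) == 3:
        return threeway_em_admixture(record, panel)
    if len(present) == 2:
        return two_taxon_proportion(record, panel, (present[0], present[1]))
    t = present[0]
    other = "RT" if t != "RT" else "WCT"
    return two_taxon_proportion(record, panel, (t, other))


def heterozygous_fraction(
    record: GenotypeRecord,
    panel: MarkerPanel,
    pair: Tuple[str, str],
) -> Optional[float]:
    """Fraction of typed pair-panel loci called heterozygous (dosage 1)."""
    idx = panel.indices_for_taxa(pair)
    calls = record.calls[idx]
    typed = calls != MISSING
    if not typed.any():
        return None
    return float((calls[typed] == 1).mean())


def classify_individual(
    record: GenotypeRecord,
    estimate: AdmixtureEstimate,
    panel: MarkerPanel,
    parental_threshold: float = 0.99,
    f1_window: Tuple[float, float] = (0.49, 0.51),
    het_threshold: float = 0.90,
) -> HybridClass:
    """Parental / F1 / admixed classification.

    A fish is a nonintrogressed parental form when at least 99% of its
    alleles come from a single taxon.  A first-generation hybrid has
    49-51% of alleles from each of two parents and nearly all
    informative loci heterozygous ("nearly all" operationalized as the
    ``het_threshold`` fraction, default 90%).
    """
    q = estimate.q
    top = int(np.argmax(q))
    if q[top] >= parental_threshold:
        return HybridClass(label=PARENTAL[TAXA[top]], taxa_involved=(TAXA[top],))
    involved = taxa_present(record, panel)
    order = np.argsort(q)[::-1]
    first, second = int(order[0]), int(order[1])
    lo, hi = f1_window
    if lo <= q[first] <= hi and lo <= q[second] <= hi:
        pair = (TAXA[first], TAXA[second])
        het = heterozygous_fraction(record, panel, pair)
        if het is not None and het >= het_threshold:
            return HybridClass(label=F1, taxa_involved=tuple(sorted(pair, key=TAXA.index)))
    return HybridClass(label=ADMIXED, taxa_involved=involved)
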