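"""Marker and individual quality control.

Implements the rescreening rules used to arrive at the final diagnostic
panel: removal of loci whose apparent admixture frequency is an outlier
(such loci are more parsimoniously explained as non-diagnostic through
ascertainment bias than as targets of selection), removal of loci with
high assay failure rates, exclusion of poorly genotyped individuals,
detection of perfectly linked locus pairs, and quantification of
between-run genotyping discordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import (
    MISSING,
    TAXA,
    TAXON_INDEX,
    GenotypeRecord,
    MarkerPanel,
    records_to_dosage_matrix,
)

#: Tie-break preference for majority-taxon assignment.  The study region
#: is the native range of WCT, so ties default toward calling a fish WCT.
DEFAULT_TIE_ORDER: Tuple[str, ...] = ("WCT", "RT", "YCT")


@dataclass
class LocusQCReport:
    locus_id: str
    admixture_frequency: Optional[float]
    failure_rate: float
    flagged_outlier: bool
    flagged_failure: bool
    linked_partner: Optional[str] = None


@dataclass
class ReplicateDiscordance:
    n_pairs: int
    mean_pct: float
    min_pct: float
    max_pct: float
    per_pair: Dict[str, float] = field(default_factory=dict)


def majority_taxon(
    record: GenotypeRecord,
    panel: MarkerPanel,
    tie_order: Sequence[str] = DEFAULT_TIE_ORDER,
) -> str:
    """Plurality taxon by diagnostic-allele count, ties broken by ``tie_order``."""
    typed = record.typed_mask
    counts = np.zeros(len(TAXA))
    for i in range(len(TAXA)):
        mask = typed & (panel.taxon_of == i)
        counts[i] = record.calls[mask].sum()
    best = counts.max()
    for t in tie_order:
        if counts[TAXON_INDEX[t]] == best:
            return t
    raise AssertionError("unreachable")


def locus_admixture_frequency(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    tie_order: Sequence[str] = DEFAULT_TIE_ORDER,
) -> Dict[str, Optional[float]]:
    """Per-locus fraction of genotyped fish whose call conflicts with
    their panel-wide majority taxon.

    At a locus diagnostic for taxon T, a fish whose majority taxon is T
    conflicts when it carries at least one alternative allele (dosage
    <= 1); a fish of any other majority taxon conflicts when it carries
    at least one diagnostic allele (dosage >= 1).  Loci with zero
    successful calls get ``None``.
    """
    dosage = records_to_dosage_matrix(records)
    majors = np.array([TAXON_INDEX[majority_taxon(r, panel, tie_order)] for r in records])
    out: Dict[str, Optional[float]] = {}
    for j, lid in enumerate(panel.nuclear_ids):
        col = dosage[:, j]
        typed = col != MISSING
        n_typed = int(typed.sum())
        if n_typed == 0:
            out[lid] = None
            continue
        own = majors == panel.taxon_of[j]
        conflict = np.where(own, col <= 1, col >= 1)
        out[lid] = float((conflict & typed).sum() / n_typed)
    return out


def flag_outlier_loci(
    frequencies: Mapping[str, Optional[float]],
    k: float = 2.0,
) -> Tuple[set, float, float]:
    """Flag loci whose admixture frequency exceeds mean + k*SD.

    The cutoff is one-sided high (the concern is loci over-reporting
    introgression) and computed in a single pass over all defined
    frequencies before any removal.  Returns (flagged ids, mean, SD);
    SD is the sample standard deviation.
    """
    items = [(lid, f) for lid, f in frequencies.items() if f is not None]
    if len(items) < 2:
        raise ValueError("need at least two loci with defined frequencies")
    values = np.array([f for _, f in items])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cutoff = mean + k * sd
    flagged = {lid for lid, f in items if f > cutoff}
    return flagged, mean, sd


def locus_failure_rates(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    threshold: float = 0.15,
) -> Dict[str, Tuple[float, bool]]:
    """Per-locus missing-call rate; flagged when strictly above threshold."""
    dosage = records_to_dosage_matrix(records)
    n = len(records)
    out = {}
    for j, lid in enumerate(panel.nuclear_ids):
        rate = float((dosage[:, j] == MISSING).sum() / n)
        out[lid] = (rate, rate > threshold)
    return out


def individual_call_rates(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    threshold: float = 0.85,
) -> Tuple[List[GenotypeRecord], List[GenotypeRecord]]:
    """Split records into (kept, excluded) by genotyping success rate.

    A fish is excluded when its fraction of successful calls across the
    nuclear panel is strictly below ``threshold``.
    """
    kept, excluded = [], []
    for r in records:
        rate = r.n_typed / panel.n_nuclear
        (excluded if rate < threshold else kept).append(r)
    return kept, excluded


def detect_perfect_linkage(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
) -> List[Tuple[str, str]]:
    """Pairs of loci with identical dosages wherever both are called.

    A pair is reported only if at least one fish has both loci called;
    the second locus of each pair (later in panel order) is the
    droppable one.
    """
    dosage = records_to_dosage_matrix(records)
    pairs = []
    L = panel.n_nuclear
    for i in range(L):
        for j in range(i + 1, L):
            both = (dosage[:, i] != MISSING) & (dosage[:, j] != MISSING)
            if not both.any():
                continue
            if np.array_equal(dosage[both, i], dosage[both, j]):
                pairs.append((panel.nuclear_ids[i], panel.nuclear_ids[j]))
    return pairs


def replicate_discordance(
    run1: Sequence[GenotypeRecord],
    run2: Sequence[GenotypeRecord],
) -> ReplicateDiscordance:
    """Between-run allele discordance for re-genotyped individuals.

    For each individual present in both runs, the discordance is the
    number of differing allele copies (|d1 - d2| per locus) among loci
    called in both runs, divided by the number of alleles compared
    (2 x loci), as a percentage.
    """
    by_id1 = {r.individual_id: r for r in run1}
    by_id2 = {r.individual_id: r for r in run2}
    shared = sorted(set(by_id1) & set(by_id2))
    if not shared:
        raise ValueError("no shared individuals between runs")
    per_pair = {}
    for ind in shared:
        c1, c2 = by_id1[ind].calls, by_id2[ind].calls
        both = (c1 != MISSING) & (c2 != MISSING)
        n_alleles = 2 * int(both.sum())
        if n_alleles == 0:
            per_pair[ind] = 0.0
            continue
        mismatches = int(np.abs(c1[both].astype(int) - c2[both].astype(int)).sum())
        per_pair[ind] = 100.0 * mismatches / n_alleles
    values = np.array(list(per_pair.values()))
    return ReplicateDiscordance(
        n_pairs=len(shared),
        mean_pct=float(values.mean()),
        min_pct=float(values.min()),
        max_pct=float(values.max()),
        per_pair=per_pair,
    )
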