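"""Core data model for diagnostic-SNP hybridization analysis.

Three taxa are tracked throughout: westslope cutthroat trout (WCT),
rainbow trout (RT), and Yellowstone cutthroat trout (YCT).  Nuclear
genotypes are stored as the per-locus dosage of the locus's diagnostic
allele (0, 1, 2, or missing), because every downstream statistic
consumes dosages only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

TAXA: Tuple[str, str, str] = ("WCT", "RT", "YCT")
TAXON_INDEX: Mapping[str, int] = {t: i for i, t in enumerate(TAXA)}

SITE_CLASSES: Tuple[str, ...] = ("Low", "PIBO", "Middle", "Headwater")
#: Longitudinal position of each site class, downstream-most first.
SITE_CLASS_ORDER: Mapping[str, int] = {c: i for i, c in enumerate(SITE_CLASSES)}

MISSING: int = -1  # dosage sentinel for a failed genotype call
MISSING_SYMBOL: str = "."


class PanelError(ValueError):
    """Raised for malformed marker panels or genotype tables."""


@dataclass(frozen=True)
class Locus:
    """A single diagnostic SNP.

    The diagnostic allele is fixed (or treated as fixed) in
    ``diagnostic_taxon`` and absent in the other two taxa, so its dosage
    in a fish counts alleles inherited from that taxon.
    """

    locus_id: str
    diagnostic_taxon: str
    marker_class: str = "nuclear"

    def __post_init__(self) -> None:
        if self.diagnostic_taxon not in TAXA:
            raise PanelError(f"unknown taxon {self.diagnostic_taxon!r} for locus {self.locus_id}")
        if self.marker_class not in ("nuclear", "mito"):
            raise PanelError(f"unknown marker class {self.marker_class!r} for locus {self.locus_id}")


class MarkerPanel:
    """An ordered collection of diagnostic loci.

    Parameters
    ----------
    loci :
        Loci in panel order (nuclear and mitochondrial).  Locus ids must
        be unique.
    """

    def __init__(self, loci: Iterable[Locus]):
        loci = list(loci)
        if not loci:
            raise PanelError("empty panel")
        seen = set()
        for loc in loci:
            if loc.locus_id in seen:
                raise PanelError(f"duplicate locus_id {loc.locus_id!r}")
            seen.add(loc.locus_id)
        self.loci: Tuple[Locus, ...] = tuple(loci)
        self.nuclear_loci: Tuple[Locus, ...] = tuple(l for l in loci if l.marker_class == "nuclear")
        self.mito_loci: Tuple[Locus, ...] = tuple(l for l in loci if l.marker_class == "mito")
        self.nuclear_ids: Tuple[str, ...] = tuple(l.locus_id for l in self.nuclear_loci)
        #: per nuclear locus, index into TAXA of the diagnostic taxon
        self.taxon_of: np.ndarray = np.array(
            [TAXON_INDEX[l.diagnostic_taxon] for l in self.nuclear_loci], dtype=np.int8
        )

    @property
    def n_nuclear(self) -> int:
        return len(self.nuclear_loci)

    @property
    def counts_by_taxon(self) -> Mapping[str, int]:
        return {t: int(np.sum(self.taxon_of == i)) for i, t in enumerate(TAXA)}

    def pair_panel_size(self, a: str, b: str) -> int:
        """Number of nuclear loci diagnostic for either member of a pair."""
        c = self.counts_by_taxon
        return c[a] + c[b]

    @property
    def pair_panel_sizes(self) -> Mapping[Tuple[str, str], int]:
        out = {}
        for i, a in enumerate(TAXA):
            for b in TAXA[i + 1:]:
                out[(a, b)] = self.pair_panel_size(a, b)
        return out

    def indices_for_taxa(self, taxa: Sequence[str]) -> np.ndarray:
        """Indices of nuclear loci diagnostic for any of ``taxa``."""
        wanted = {TAXON_INDEX[t] for t in taxa}
        return np.flatnonzero(np.isin(self.taxon_of, list(wanted)))

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class GenotypeRecord:
    """One fish: metadata plus diagnostic-allele dosages.

    ``calls`` is aligned to the panel's nuclear loci; entries are 0, 1,
    2 or :data:`MISSING`.  ``mitotype`` is the taxon label of the
    maternally inherited haplotype ("missing" when unresolved).
    """

    individual_id: str
    stream_id: str
    site_id: str
    site_class: str
    rt_native: bool
    mitotype: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.site_class not in SITE_CLASSES:
            raise PanelError(f"unknown site class {self.site_class!r}")
        if self.mitotype not in TAXA and self.mitotype != "missing":
            raise PanelError(f"unknown mitotype {self.mitotype!r}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError(f"illegal dosage values in record {self.individual_id!r}")

    @property
    def typed_mask(self) -> np.ndarray:
        return self.calls != MISSING

    @property
    def n_typed(self) -> int:
        return int(self.typed_mask.sum())


@dataclass(frozen=True)
class SiteMeta:
    site_id: str
    stream_id: str
    site_class: str
    rt_native: bool
    sample_size: int

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise PanelError("sample_size must be >= 1")


@dataclass
class AdmixtureEstimate:
    """Per-fish ancestry proportions on the 3-simplex (WCT, RT, YCT)."""

    q: np.ndarray
    loci_used: int
    alleles_counted: int
    log_likelihood: float
    method: str  # "two_taxon_count" | "threeway_em"
    converged: bool = True

    def __post_init__(self) -> None:
        self.q = np.clip(np.asarray(self.q, dtype=float), 0.0, 1.0)
        s = self.q.sum()
        if s > 0:
            self.q = self.q / s

    def q_for(self, taxon: str) -> float:
        return float(self.q[TAXON_INDEX[taxon]])


# Hybrid classification labels
PARENTAL = {t: f"PARENTAL_{t}" for t in TAXA}
F1 = "F1"
ADMIXED = "ADMIXED"


@dataclass(frozen=True)
class HybridClass:
    label: str
    taxa_involved: Tuple[str, ...]

    @property
    def is_parental(self) -> bool:
        return self.label.startswith("PARENTAL_")


def records_to_dosage_matrix(records: Sequence[GenotypeRecord]) -> np.ndarray:
    """Stack records into an (n_fish, n_loci) int8 dosage matrix."""
    if not records:
        raise PanelError("no records")
    return np.vstack([r.calls for r in records])


def group_by_site(records: Sequence[GenotypeRecord]) -> Mapping[str, list]:
    out: dict = {}
    for r in records:
        out.setdefault(r.site_id, []).append(r)
    return out
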