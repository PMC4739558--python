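"""Readers and writers for panel, genotype, and GENEPOP text formats.

Formats
-------
panel.tsv
    Columns ``locus_id``, ``diagnostic_taxon``, ``marker_class``.
genotypes.tsv
    Columns ``individual_id``, ``stream_id``, ``site_id``,
    ``site_class``, ``rt_native``, ``mitotype``, then one column per
    nuclear locus with values ``0|1|2|.``.
GENEPOP export
    Title line, one locus name per line, one ``pop`` block per site,
    4-digit diploid coding (diagnostic allele ``01``, alternative
    ``02``, missing ``0000``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    MISSING_SYMBOL,
    TAXA,
    GenotypeRecord,
    Locus,
    MarkerPanel,
    PanelError,
)

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("individual_id", "stream_id", "site_id", "site_class", "rt_native", "mitotype")


def read_panel(path) -> MarkerPanel:
    """Read a marker panel from a tab-separated table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "diagnostic_taxon", "marker_class"}
    if not required.issubset(df.columns):
        raise PanelError(f"panel file missing columns: {sorted(required - set(df.columns))}")
    loci = [
        Locus(row.locus_id, row.diagnostic_taxon, row.marker_class)
        for row in df.itertuples(index=False)
    ]
    return MarkerPanel(loci)


def write_panel(panel: MarkerPanel, path) -> None:
    df = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in panel.loci],
            "diagnostic_taxon": [l.diagnostic_taxon for l in panel.loci],
            "marker_class": [l.marker_class for l in panel.loci],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def default_panel() -> MarkerPanel:
    """The default 86-locus nuclear panel plus two mitochondrial SNPs.

    Locus identifiers are synthetic placeholders; the panel reproduces
    the published composition (35 WCT / 18 YCT / 33 RT nuclear loci and
    two mito markers), which is all any statistic here consumes.
    """
    loci: List[Locus] = []
    for taxon, n in (("WCT", 35), ("YCT", 18), ("RT", 33)):
        for i in range(1, n + 1):
            loci.append(Locus(f"{taxon}_{i:03d}", taxon, "nuclear"))
    loci.append(Locus("MT_WCT", "WCT", "mito"))
    loci.append(Locus("MT_RT", "RT", "mito"))
    return MarkerPanel(loci)


def _parse_call(symbol: str, where: str) -> int:
    if symbol == MISSING_SYMBOL:
        return MISSING
    if symbol in ("0", "1", "2"):
        return int(symbol)
    raise PanelError(f"illegal call symbol {symbol!r} at {where}")


def read_genotypes(path, panel: MarkerPanel) -> List[GenotypeRecord]:
    """Read a genotype table, validating loci against ``panel``.

    Missing calls (``.``) are preserved.  The file's locus columns must
    be exactly the panel's nuclear loci (any order is rejected to guard
    against silent column drift).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_meta:
        raise PanelError(f"genotype file missing metadata columns: {missing_meta}")
    locus_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    unknown = sorted(set(locus_cols) - set(panel.nuclear_ids))
    if unknown:
        raise PanelError(f"unknown locus columns: {unknown}")
    absent = sorted(set(panel.nuclear_ids) - set(locus_cols))
    if absent:
        raise PanelError(f"panel loci absent from genotype file: {absent}")

    records = []
    for idx, row in df.iterrows():
        calls = np.array(
            [_parse_call(str(row[lid]), f"row {idx}, locus {lid}") for lid in panel.nuclear_ids],
            dtype=np.int8,
        )
        records.append(
            GenotypeRecord(
                individual_id=str(row.individual_id),
                stream_id=str(row.stream_id),
                site_id=str(row.site_id),
                site_class=str(row.site_class),
                rt_native=str(row.rt_native) in ("1", "True", "true"),
                mitotype=str(row.mitotype),
                calls=calls,
            )
        )
    return records


def write_genotypes(records: Sequence[GenotypeRecord], panel: MarkerPanel, path) -> None:
    rows = []
    for r in records:
        row: Dict[str, object] = {
            "individual_id": r.individual_id,
            "stream_id": r.stream_id,
            "site_id": r.site_id,
            "site_class": r.site_class,
            "rt_native": int(r.rt_native),
            "mitotype": r.mitotype,
        }
        for lid, call in zip(panel.nuclear_ids, r.calls):
            row[lid] = MISSING_SYMBOL if call == MISSING else str(int(call))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


#: Default joint decision table for the two mitochondrial SNPs.
#:
#: The mito markers report presence/absence of the WCT-diagnostic and
#: RT-diagnostic haplotype variants respectively.  A haplotype carrying
#: the WCT variant only is a WCT mitotype, the RT variant only an RT
#: mitotype, and neither variant the YCT mitotype.  Both variants at
#: once is physically inconsistent for a haploid genome and maps to
#: "missing".  The joint coding of real assays varies, so the table is
#: an argument with this documented default.
DEFAULT_MITO_TABLE: Mapping[Tuple[bool, bool], str] = {
    (True, False): "WCT",
    (False, True): "RT",
    (False, False): "YCT",
}


def mitotype_from_mito_snps(
    call_a: int,
    call_b: int,
    decision_table: Mapping[Tuple[bool, bool], str] = DEFAULT_MITO_TABLE,
) -> str:
    """Resolve a mitotype from two haploid mito SNP calls.

    Calls use the diploid dosage scale of the assay: 2 = variant
    present, 0 = absent.  A heterozygous call (1) on a haploid marker is
    inconsistent, and any missing call leaves the mitotype unresolved;
    both return ``"missing"``.
    """
    for call in (call_a, call_b):
        if call not in (0, 1, 2, MISSING):
            raise PanelError(f"illegal mito call {call!r}")
    if call_a in (MISSING, 1) or call_b in (MISSING, 1):
        if 1 in (call_a, call_b):
            logger.warning("heteroplasmic mito call (%s, %s); mitotype set to missing", call_a, call_b)
        return "missing"
    key = (call_a == 2, call_b == 2)
    taxon = decision_table.get(key)
    if taxon is None:
        logger.warning("conflicting mito pattern %s; mitotype set to missing", key)
        return "missing"
    return taxon


def export_genepop(
    records: Sequence[GenotypeRecord],
    panel: MarkerPanel,
    path,
    title: str = "hybridpanel export",
) -> None:
    """Write records as a GENEPOP text file, one ``pop`` block per site."""
    if not records:
        raise PanelError("no records to export")
    by_site: Dict[str, List[GenotypeRecord]] = {}
    site_order: List[str] = []
    for r in records:
        if r.site_id not in by_site:
            site_order.append(r.site_id)
        by_site.setdefault(r.site_id, []).append(r)

    def code(call: int) -> str:
        if call == MISSING:
            return "0000"
        # diagnostic allele = 01, alternative = 02
        return {2: "0101", 1: "0102", 0: "0202"}[int(call)]

    lines = [title]
    lines.extend(panel.nuclear_ids)
    for site in site_order:
        lines.append("pop")
        for r in by_site[site]:
            genos = " ".join(code(c) for c in r.calls)
            lines.append(f"{r.individual_id} ,  {genos}")
    Path(path).write_text("\n".join(lines) + "\n")
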