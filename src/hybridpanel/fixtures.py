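"""Packaged transcriptions of the published literature-review and
site-survey tables.

``table1`` is the literature review: 29 studies of cutthroat x rainbow
trout introgression, with counts of sampled locations where admixture
was present, where no parental forms remained, and where admixture was
absent.

``table2`` is the survey itself: 188 site records (one per sampled
location) with sample size, parental counts, allele percentages per
taxon, the binomial allele-distribution flag, and the
heterozygote-deficit/excess locus counts.

Percentages printed as ``<0.1`` are parsed to 0.05 and flagged in a
companion ``*_below_detection`` column so reproduction checks can apply
the printed rounding rule.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

TABLE1_SHA256 = "d2b4a72f3b3bef7f3ac16eb13dfe5325182778a0a8489857d97ad0c99183f7ba"
TABLE2_SHA256 = "b0b6392256ed12813d89532373c5f5c02ca50b501a1f50c936229cd21260a6f9"

BELOW_DETECTION_VALUE = 0.05  # stand-in for percentages printed "<0.1"


class FixtureIntegrityError(RuntimeError):
    """The shipped fixture does not match its recorded checksum."""


def _read(name: str, expected_sha: str) -> bytes:
    data = resources.files("hybridpanel.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha:
        raise FixtureIntegrityError(f"{name}: checksum {digest} != expected {expected_sha}")
    return data


def load_table1() -> pd.DataFrame:
    """Literature-review table (29 rows)."""
    import io as _io

    raw = _read("table1.tsv", TABLE1_SHA256)
    df = pd.read_csv(_io.BytesIO(raw), sep="\t", dtype={"introduced": str})
    df["introduced"] = df["introduced"].fillna("")
    for col in ("markers", "n_present", "n_no_parentals", "n_absent"):
        df[col] = df[col].astype(int)
    return df


def _parse_pct(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    below = series.astype(str).str.strip() == "<0.1"
    values = series.where(~below, BELOW_DETECTION_VALUE).astype(float)
    return values, below


def load_table2() -> pd.DataFrame:
    """Site-survey table (188 rows), numeric fields parsed.

    Column notes: ``binomial`` is Y/N/NA as printed; ``loci``,
    ``fis_plus`` and ``fis_minus`` are nullable integers (absent for
    sites that were not tested); ``pct_*`` are floats with companion
    ``pct_*_below_detection`` flags for entries printed ``<0.1``.
    """
    import io as _io

    raw = _read("table2.tsv", TABLE2_SHA256)
    df = pd.read_csv(
        _io.BytesIO(raw),
        sep="\t",
        dtype={"stream_disambig": str, "site_disambig": str, "binomial": str},
    )
    df["stream_disambig"] = df["stream_disambig"].fillna("")
    df["site_disambig"] = df["site_disambig"].fillna("")
    df["rt_native"] = df["rt_native"].astype(bool)
    for col in ("n", "parentals_wct", "parentals_rt"):
        df[col] = df[col].astype(int)
    for col in ("pct_wct", "pct_rt", "pct_yct"):
        values, below = _parse_pct(df[col])
        df[col] = values
        df[f"{col}_below_detection"] = below
    for col in ("loci", "fis_plus", "fis_minus"):
        df[col] = df[col].astype("Int64")
    df["stream_key"] = np.where(
        df["stream_disambig"] != "",
        df["stream"] + " (" + df["stream_disambig"] + ")",
        df["stream"],
    )
    df["site_id"] = (
        df["stream_key"]
        + " "
        + df["site_class"]
        + np.where(df["site_disambig"] != "", " (" + df["site_disambig"] + ")", "")
    )
    # same stream name can occur both inside and outside the historical
    # RT range (distinct streams); qualify the colliding ids
    dup = df["site_id"].duplicated(keep=False)
    df.loc[dup & df["rt_native"], "site_id"] += " [RT-native]"
    return df
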