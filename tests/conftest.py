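import numpy as np
import pytest

from hybridpanel import default_panel
from hybridpanel.model import GenotypeRecord, Locus, MarkerPanel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def tiny_panel():
    """2 WCT + 2 RT + 1 YCT nuclear loci."""
    return MarkerPanel(
        [
            Locus("W1", "WCT"),
            Locus("W2", "WCT"),
            Locus("R1", "RT"),
            Locus("R2", "RT"),
            Locus("Y1", "YCT"),
        ]
    )


def make_record(calls, panel, individual_id="fish", site_id="site", mitotype="WCT",
                stream_id="stream", site_class="PIBO", rt_native=False):
    calls = np.asarray(calls, dtype=np.int8)
    assert calls.shape == (panel.n_nuclear,)
    return GenotypeRecord(
        individual_id=individual_id,
        stream_id=stream_id,
        site_id=site_id,
        site_class=site_class,
        rt_native=rt_native,
        mitotype=mitotype,
        calls=calls,
    )


def parental_calls(panel, taxon):
    """Dosage vector of a pure parental fish: 2 at own-taxon loci, 0 elsewhere."""
    from hybridpanel.model import TAXON_INDEX

    return np.where(panel.taxon_of == TAXON_INDEX[taxon], 2, 0).astype(np.int8)


def f1_calls(panel, a, b):
    """F1 between a and b: dosage 1 at loci diagnostic for either, 0 elsewhere."""
    from hybridpanel.model import TAXON_INDEX

    out = np.zeros(panel.n_nuclear, dtype=np.int8)
    mask = np.isin(panel.taxon_of, [TAXON_INDEX[a], TAXON_INDEX[b]])
    out[mask] = 1
    return out
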