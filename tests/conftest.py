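import numpy as np
import pytest
from hypothesis import settings

from hylquant.peptide_core import ProteinChain
from hylquant.quant import EvidenceRecord, LocusQuant

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def hotspot_chain() -> ProteinChain:
    """Chain fragment whose LTVLSSASTK lysine reports as K350."""
    return ProteinChain(
        chain_id="HC-K",
        sequence="DSTYSLSSTLTLSKLTVLSSASTKGPSVFPLAPSSKADYEK",
        numbering_offset=326,
    )


def locus_from_areas(k0, k1, kox0, kox1, chain_id="HC-K", site=350) -> LocusQuant:
    return LocusQuant(
        chain_id=chain_id, site=site,
        area_K_0mc=k0, area_K_1mc=k1, area_Kox_0mc=kox0, area_Kox_1mc=kox1,
    )


def evidence_for_locus(k0, k1, kox0, kox1, chain_id="HC-K", site=350):
    """Four-species evidence block for one locus with the given areas."""
    short = dict(chain_id=chain_id, sequence="LTVLSSASTK", start=341, end=350)
    long_ = dict(chain_id=chain_id, sequence="LTVLSSASTKGPSVFPLAPSSK",
                 start=341, end=362)
    records = []
    for area, mc, modified, coords in [
        (k0, 0, False, short), (k1, 1, False, long_),
        (kox0, 0, True, short), (kox1, 1, True, long_),
    ]:
        if area > 0:
            records.append(EvidenceRecord(
                missed_cleavages=mc, modified=modified,
                mod_site=site if modified else None, area=area, **coords,
            ))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
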