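import pytest
from hypothesis import settings

from phylohgt.taxa import TaxonGroup, TaxonInfo, TaxonMap

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_map() -> TaxonMap:
    """A pocket panel: 3 vascular plants, bryophyte, alga, SAR, Amorphea,
    archaeon, 8 PA and 4 NPA bacteria."""
    entries = {}
    for name, group in [
        ("P1", TaxonGroup.VASCULAR_PLANT),
        ("P2", TaxonGroup.VASCULAR_PLANT),
        ("P3", TaxonGroup.VASCULAR_PLANT),
        ("Bryo1", TaxonGroup.BRYOPHYTE),
        ("Alga1", TaxonGroup.ALGA),
        ("Sar1", TaxonGroup.SAR),
        ("A1", TaxonGroup.AMORPHEA),
        ("Arch1", TaxonGroup.ARCHAEA),
    ]:
        entries[name] = TaxonInfo(group=group)
    for i in range(1, 9):
        entries[f"B{i}"] = TaxonInfo(group=TaxonGroup.PA_BACTERIA)
    for i in range(1, 5):
        entries[f"N{i}"] = TaxonInfo(group=TaxonGroup.NPA_BACTERIA)
    return TaxonMap(entries)
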