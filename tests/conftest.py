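import io

import pytest

from ale.metadata_model import SampleMetadata
from ale.tissue_ontology import load_obo

# Hand-written 8-term fixture ontology.  Depth structure (root = 0):
#   tissues(0) -> brain(1) -> hippocampus(2) -> hippocampal pyramidal layer(3)
#   tissues(0) -> pancreas(1), ovary(1)
#   islet is_a pancreas AND is_a hippocampal pyramidal layer  (diamond:
#     parents at depths 1 and 3, so its depth is 2)
#   spleen is obsolete and must never be matched.
FIXTURE_OBO = """format-version: 1.2
ontology: fixture-tissue

[Term]
id: BTO:0000000
name: tissues

[Term]
id: BTO:0000001
name: brain
is_a: BTO:0000000

[Term]
id: BTO:0000002
name: hippocampus
is_a: BTO:0000001

[Term]
id: BTO:0000003
name: hippocampal pyramidal layer
synonym: "cap" EXACT []
is_a: BTO:0000002

[Term]
id: BTO:0000004
name: pancreas
is_a: BTO:0000000

[Term]
id: BTO:0000005
name: ovary
is_a: BTO:0000000

[Term]
id: BTO:0000006
name: islet
is_a: BTO:0000004
is_a: BTO:0000003

[Term]
id: BTO:0000007
name: spleen
is_obsolete: true
is_a: BTO:0000000
"""

#: the published characteristics block of sample GSM17122
GSM17122_CHARACTERISTICS = (
    "Genetic Background: NOD; Transgene: BDC2.5 T cell receptor genes; "
    "Age: 25 days; Tissue: Pancreas; "
    "Isolation: FACS on CD45+ Hoechst- (viable) cells"
)


@pytest.fixture(scope="session")
def fixture_graph():
    return load_obo(io.StringIO(FIXTURE_OBO))


@pytest.fixture()
def gsm17122():
    return SampleMetadata(
        sample_id="GSM17122",
        series_id="GSE1064",
        organism="Mus musculus",
        characteristics_raw={1: GSM17122_CHARACTERISTICS},
    )
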