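import textwrap

import numpy as np
import pytest
from hypothesis import settings

from plastmark.alignment import Alignment

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_alignment():
    return Alignment(["t1", "t2", "t3", "t4"],
                     ["AAAA", "AAAT", "AATT", "ATTT"])


GENBANK_FIXTURE = textwrap.dedent("""\
    LOCUS       TESTPLAST                 60 bp    DNA     circular PLN 01-JAN-2020
    DEFINITION  Synthetic test plastid fragment.
    ACCESSION   TEST0001
    VERSION     TEST0001.1
    SOURCE      Testus syntheticus
      ORGANISM  Testus syntheticus
                Eukaryota; Rhodophyta.
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="Testus syntheticus"
         CDS             1..12
                         /gene="rbcL"
         CDS             complement(20..23)
                         /gene="psbA"
         CDS             join(1..6,10..15)
                         /gene="gltB"
         CDS             30..35
                         /product="hypothetical protein"
         CDS             40..45
    ORIGIN
            1 atgaaacccg ggtttaaagt ttcccatgaa atttggcaat gcatgcatgc atgcatgcat
    //
    """)


@pytest.fixture
def genbank_file(tmp_path):
    path = tmp_path / "test.gb"
    path.write_text(GENBANK_FIXTURE)
    return path
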