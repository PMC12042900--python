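import numpy as np
import pytest

from chkit.variant_filtering import AnnotatedVariant, GenePanel


@pytest.fixture
def chip_panel():
    return GenePanel(
        name="chip",
        genes=frozenset({"DNMT3A", "TET2", "ASXL1", "JAK2", "SF3B1", "SRSF2", "TP53", "PPM1D"}),
        hotspot_exemptions=frozenset({("JAK2", "V617F"), ("DNMT3A", "882")}),
    )


@pytest.fixture
def lymphoid_panel():
    return GenePanel(
        name="lymphoid",
        genes=frozenset({"KMT2D", "KMT2A", "ADGRV1", "STAT3"}),
    )


@pytest.fixture
def make_variant():
    """Factory for an all-rules-passing variant; override fields per test."""

    def _make(**overrides):
        defaults = dict(
            sample_id="S1",
            chrom="chr4",
            pos=105_233_100,
            ref="C",
            alt="T",
            gene="TET2",
            consequence="missense",
            caller_label="PASS",
            somatic_quality=30.0,
            germline_quality=1.0,
            total_depth=50,
            alt_depth=6,
            ref_fwd=22,
            ref_rev=22,
            alt_fwd=3,
            alt_rev=3,
            gnomad_max_pop_af=0.0,
            cosmic_count=5,
            reported_lchip=False,
            reported_all=False,
            splice_distance_bp=None,
            protein_change=None,
        )
        defaults.update(overrides)
        return AnnotatedVariant(**defaults)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
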