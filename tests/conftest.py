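import numpy as np
import pytest

from splitlr.layout import BarcodeLayout, BarcodeRound, Priming
from splitlr.simulate import make_synthetic_layout


@pytest.fixture(scope="session")
def layout() -> BarcodeLayout:
    """Default synthetic layout: 16-bp barcodes, pairwise distance >= 7."""
    return make_synthetic_layout(seed=7)


@pytest.fixture(scope="session")
def tiny_layout() -> BarcodeLayout:
    """Hand-written 2-barcode-per-round layout for exact-construction tests."""
    r1 = {"w01_dT": "AAAAAAAA", "w01_hex": "CCCCCCCC", "w02_dT": "GGGGGGGG", "w02_hex": "TTTTTTTT"}
    r2 = {"a": "ACACACAC", "b": "GTGTGTGT"}
    r3 = {"a": "AACCGGTT", "b": "TTGGCCAA"}
    return BarcodeLayout(
        rounds=[
            BarcodeRound(whitelist=r1, barcode_length=8),
            BarcodeRound(whitelist=r2, barcode_length=8),
            BarcodeRound(whitelist=r3, barcode_length=8),
        ],
        linkers=["ATCCACGTGCTTGAGA", "GTGGCCGATGTTTCGC"],
        umi_length=10,
        priming_map={
            "AAAAAAAA": Priming.OLIGO_DT,
            "CCCCCCCC": Priming.RANDOM_HEXAMER,
            "GGGGGGGG": Priming.OLIGO_DT,
            "TTTTTTTT": Priming.RANDOM_HEXAMER,
        },
        well_pair_map={
            "AAAAAAAA": "w01",
            "CCCCCCCC": "w01",
            "GGGGGGGG": "w02",
            "TTTTTTTT": "w02",
        },
    )


def build_read(layout: BarcodeLayout, bc1: str, bc2: str, bc3: str, umi: str, cdna: str) -> str:
    """Forward-orientation read exactly matching the layout geometry."""
    l1, l2 = layout.linkers
    return cdna + umi + bc3 + l1 + bc2 + l2 + bc1
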