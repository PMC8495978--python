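"""Barcode layout description for split-pool combinatorial barcoding.

A Split-seq library carries three rounds of well barcodes separated by fixed
linker ("spacer") sequences, followed by a UMI, all appended to the cDNA.
Round-1 wells are loaded with two primers (oligo-dT and random hexamer), so
two distinct round-1 barcodes map to one physical well; the round-1 barcode
therefore encodes both the well and the priming strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List

import yaml


class Priming(str, Enum):
    OLIGO_DT = "OLIGO_DT"
    RANDOM_HEXAMER = "RANDOM_HEXAMER"
    NA = "NA"


@dataclass
class BarcodeRound:
    """One round of split-pool barcoding: well id -> fixed-length barcode."""

    whitelist: Dict[str, str]
    barcode_length: int = 8

    def __post_init__(self) -> None:
        if not self.whitelist:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in self.whitelist.values()}
        if lengths != {self.barcode_length}:
            raise ValueError(
                f"barcodes must all have length {self.barcode_length}, got lengths {sorted(lengths)}"
            )

    @property
    def barcodes(self) -> List[str]:
        return sorted(self.whitelist.values())


@dataclass
class BarcodeLayout:
    """Geometry and whitelists of the barcode block at the 3' end of a read.

    Oriented read structure (5'->3'):
        cDNA | UMI | bc3 | linker1 | bc2 | linker2 | bc1

    ``rounds`` is ordered round 1..3 (round 1 is the priming-encoding round,
    read out last on the oriented strand).
    """

    rounds: List[BarcodeRound]
    linkers: List[str]
    umi_length: int = 10
    priming_map: Dict[str, Priming] = field(default_factory=dict)
    well_pair_map: Dict[str, str] = field(default_factory=dict)
    max_edit_distance: int = 3
    max_linker_errors: int = 2

    def __post_init__(self) -> None:
        if len(self.rounds) != 3:
            raise ValueError("layout requires exactly 3 barcode rounds")
        if len(self.linkers) != 2:
            raise ValueError("layout requires exactly 2 linkers")
        self.priming_map = {
            k: Priming(v) for k, v in self.priming_map.items()
        }
        r1 = set(self.rounds[0].whitelist.values())
        missing = r1 - set(self.priming_map)
        if missing:
            raise ValueError(f"priming_map missing round-1 barcodes: {sorted(missing)[:3]}...")
        missing = r1 - set(self.well_pair_map)
        if missing:
            raise ValueError(f"well_pair_map missing round-1 barcodes: {sorted(missing)[:3]}...")
        wells: Dict[str, List[str]] = {}
        for bc, well in self.well_pair_map.items():
            wells.setdefault(well, []).append(bc)
        bad = {w: bcs for w, bcs in wells.items() if len(bcs) != 2}
        if bad:
            raise ValueError(f"each well must receive exactly two round-1 barcodes; bad wells: {sorted(bad)[:3]}")

    @property
    def block_length(self) -> int:
        """Total length of the UMI + barcode + linker block."""
        return (
            self.umi_length
            + sum(r.barcode_length for r in self.rounds)
            + sum(len(l) for l in self.linkers)
        )

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {"whitelist": r.whitelist, "barcode_length": r.barcode_length}
                for r in self.rounds
            ],
            "linkers": list(self.linkers),
            "umi_length": self.umi_length,
            "priming_map": {k: v.value for k, v in self.priming_map.items()},
            "well_pair_map": dict(self.well_pair_map),
            "max_edit_distance": self.max_edit_distance,
            "max_linker_errors": self.max_linker_errors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BarcodeLayout":
        return cls(
            rounds=[BarcodeRound(**r) for r in d["rounds"]],
            linkers=list(d["linkers"]),
            umi_length=int(d.get("umi_length", 10)),
            priming_map=d.get("priming_map", {}),
            well_pair_map=d.get("well_pair_map", {}),
            max_edit_distance=int(d.get("max_edit_distance", 3)),
            max_linker_errors=int(d.get("max_linker_errors", 2)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "BarcodeLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
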