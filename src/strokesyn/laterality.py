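"""Channel-to-region mapping and interhemispheric laterality indices.

After lesion-orientation normalization (every patient's lesioned hemisphere
mapped to the right), the laterality index per region of interest is

    LI = (mean beta contralateral - mean beta ipsilateral)
         / (mean beta contralateral + mean beta ipsilateral)

with contralateral/ipsilateral resolved relative to the moving arm.  In the
normalized orientation the affected arm is the left arm, so affected-arm
movement makes the (lesioned) right hemisphere contralateral.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .fnirs import BetaMap, N_CHANNELS

REGIONS = ("PMC", "M1", "S1")


@dataclass
class LateralityResult:
    li_pmc: Optional[float]
    li_m1: Optional[float]
    li_s1: Optional[float]
    moving_arm: str
    out_of_range: bool = False   # mixed-sign betas can push LI outside [-1, 1]

    def as_dict(self) -> dict:
        return {"PMC": self.li_pmc, "M1": self.li_m1, "S1": self.li_s1}


class RegionMap:
    """Maps each of the 24 channels to a (region, hemisphere) cell.

    The default layout (4 channels per region x hemisphere, channel i
    mirroring channel i+12) is a documented stand-in: real montages should
    supply their own YAML (``channel: {region, hemisphere, mirror}``).
    """

    def __init__(self, mapping: dict[int, dict]):
        if set(mapping) != set(range(1, N_CHANNELS + 1)):
            raise ValueError(f"region map must cover channels 1..{N_CHANNELS}")
        for ch, info in mapping.items():
            if info["region"] not in REGIONS:
                raise ValueError(f"channel {ch}: unknown region {info['region']}")
            if info["hemisphere"] not in ("left", "right"):
                raise ValueError(f"channel {ch}: bad hemisphere {info['hemisphere']}")
        for region in REGIONS:
            for hemi in ("left", "right"):
                if not any(i["region"] == region and i["hemisphere"] == hemi
                           for i in mapping.values()):
                    raise ValueError(f"empty cell: {region}/{hemi}")
        self.mapping = mapping

    @classmethod
    def default(cls) -> "RegionMap":
        with resources.files("strokesyn.data").joinpath("region_map.yaml").open() as fh:
            return cls.from_yaml_stream(fh)

    @classmethod
    def from_yaml_stream(cls, stream) -> "RegionMap":
        raw = yaml.safe_load(stream)
        return cls({int(k): dict(v) for k, v in raw.items()})

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path) as fh:
            return cls.from_yaml_stream(fh)

    def channels(self, region: str, hemisphere: str) -> list[int]:
        return sorted(
            ch for ch, i in self.mapping.items()
            if i["region"] == region and i["hemisphere"] == hemisphere
        )

    def mirror_pairs(self) -> list[tuple[int, int]]:
        """Symmetric (left, right) channel pairs; errors if any channel lacks one."""
        pairs = []
        for ch, info in self.mapping.items():
            if info["hemisphere"] != "left":
                continue
            m = info.get("mirror")
            if m is None or m not in self.mapping:
                raise ValueError(f"channel {ch} has no mirror channel")
            mi = self.mapping[m]
            if mi["hemisphere"] != "right" or mi["region"] != info["region"]:
                raise ValueError(f"channel {ch}: mirror {m} is not its right-side twin")
            pairs.append((ch, m))
        if 2 * len(pairs) != N_CHANNELS:
            raise ValueError("asymmetric region map: mirror pairs do not cover all channels")
        return pairs


def normalize_lesion_orientation(
    betamap: BetaMap, lesion_side: str, region_map: RegionMap
) -> BetaMap:
    """Map every lesion to the right hemisphere by swapping mirror channels.

    Left-lesion subjects get each channel's beta exchanged with its mirror;
    right-lesion and lesion-free subjects pass through unchanged.  Applying
    the swap twice is the identity.
    """
    if lesion_side not in ("left", "right", "none"):
        raise ValueError(f"unknown lesion side {lesion_side!r}")
    if lesion_side != "left":
        return betamap
    beta = betamap.beta.copy()
    for left_ch, right_ch in region_map.mirror_pairs():
        beta[left_ch - 1], beta[right_ch - 1] = beta[right_ch - 1], beta[left_ch - 1]
    return BetaMap(beta=beta, design_info=dict(betamap.design_info))


def laterality_index(
    betamap: BetaMap,
    region_map: RegionMap,
    moving_arm: str,
    denom_tol: float = 1e-12,
) -> LateralityResult:
    """Per-region LI for one block, relative to the moving arm.

    moving_arm 'affected' (left arm in normalized orientation) makes the
    right hemisphere contralateral; 'unaffected' the left.  A vanishing
    denominator marks that region's LI missing rather than infinite.
    """
    if moving_arm not in ("affected", "unaffected"):
        raise ValueError(f"unknown arm {moving_arm!r}")
    contra_hemi = "right" if moving_arm == "affected" else "left"
    ipsi_hemi = "left" if contra_hemi == "right" else "right"
    beta = np.asarray(betamap.beta, dtype=float)
    values = {}
    out_of_range = False
    for region in REGIONS:
        bc = beta[[c - 1 for c in region_map.channels(region, contra_hemi)]].mean()
        bi = beta[[c - 1 for c in region_map.channels(region, ipsi_hemi)]].mean()
        denom = bc + bi
        if abs(denom) < denom_tol:
            values[region] = None
        else:
            li = float((bc - bi) / denom)
            values[region] = li
            if abs(li) > 1.0:
                out_of_range = True
    return LateralityResult(
        li_pmc=values["PMC"], li_m1=values["M1"], li_s1=values["S1"],
        moving_arm=moving_arm, out_of_range=out_of_range,
    )
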