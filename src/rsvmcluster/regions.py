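"""AAL-90 cerebral parcellation region labels.

The Automated Anatomical Labeling atlas divides the cerebrum into 45
bilateral regions (90 nodes).  Odd atlas indices are left-hemisphere,
even are right, so the canonical ordering alternates ``.L`` / ``.R``
within each region pair.  Abbreviations follow the conventional short
codes (PreCG, SFGdor, ...) used throughout the connectomics literature.
"""

from __future__ import annotations

_AAL_STEMS = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]

#: The 90 AAL region abbreviations in atlas order (left before right).
AAL90: list[str] = [f"{stem}.{side}" for stem in _AAL_STEMS for side in ("L", "R")]


def default_region_ids(n_regions: int) -> list[str]:
    """Region labels for an ``n_regions``-node network.

    Returns the AAL-90 abbreviations when ``n_regions`` is 90, otherwise
    generic ``R001 ...`` placeholders so that synthetic networks of any
    size carry usable labels.
    """
    if n_regions == len(AAL90):
        return list(AAL90)
    return [f"R{i + 1:03d}" for i in range(n_regions)]
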