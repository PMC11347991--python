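"""Published photophysical reference values for the supported reporters.

These constants are inputs to worked examples and consistency checks, not
quantities the package estimates: intensity-weighted average lifetimes
(T_i, ns) and pairwise lifetime differences of the FAST lifetime-modulating
tags (shortT/midT/longT) with the fluorogens HBR-2,5DM and HBR-3,5DM, the
EGFP lifetime, and quantum-yield/lifetime pairs used to illustrate the
radiative/non-radiative rate decomposition.
"""

#: Pairwise lifetime differences |delta T_i| (ns) measured in HeLa cells,
#: keyed by fluorogen and reporter pair.
HELA_PAIRWISE_DELTA_TI_NS: dict[str, dict[tuple[str, str], float]] = {
    "HBR-2,5DM": {
        ("shortT", "midT"): 0.39,
        ("midT", "longT"): 0.22,
        ("shortT", "longT"): 0.61,
    },
    "HBR-3,5DM": {
        ("shortT", "midT"): 0.80,
        ("midT", "longT"): 0.22,
        ("shortT", "longT"): 1.0,
    },
}

#: T_i histogram peak positions (ns) in the three-population co-culture of
#: nuclei-labeled cells (HBR-2,5DM).
COCULTURE_PEAKS_NS: dict[str, float] = {
    "shortT550": 1.45,
    "midT550": 1.89,
    "longT550": 2.10,
}

#: EGFP intensity-weighted lifetime and its reported margin over longT550.
EGFP_TI_NS = 2.6
EGFP_LONGT550_DELTA_NS = 0.5

#: Four-population green-channel peaks (shortT550/midT550/longT550/EGFP).
FOURPLEX_PEAKS_NS = (1.26, 1.64, 1.82, 2.08)

#: (quantum yield, T_i ns) of two assemblies with near-identical brightness
#: but distinguishable lifetimes — the canonical rate-decomposition example.
QY_LIFETIME_EXAMPLES: dict[str, tuple[float, float]] = {
    "greenFAST:HMBR": (0.23, 1.25),
    "iFAST:HMBR": (0.22, 1.73),
}

#: Single-population lifetimes measured in zebrafish larvae (ns).
ZEBRAFISH_TI_NS: dict[str, float] = {
    "shortT550": 1.45,
    "midT550": 1.70,
    "longT550": 1.93,
}
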