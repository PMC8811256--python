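"""Bundled reference data.

The two-tier screen reference is the published breakpoint survey for the
"Jackson" x "KS4895" soybean cross: 26 genotypes (24 recombinant inbred
lines plus both parents) with their parent-relative transpiration-decrease
indices from the AgNO3 screen (RDTR_K, RNDTR_K — decrease relative to the
"KS4895" parent) and their fitted VPD breakpoints at 32 and 37 degC, where
"Linear" marks a genotype whose transpiration response kept a single
constant slope (no limited-transpiration expression).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["two_tier_screen_reference", "two_tier_screen_long"]

# genotype, rdtr_k, rndtr_k, bp at 32C, bp at 37C ("Linear" = no breakpoint)
_SCREEN_ROWS = [
    ("#16", 0.14, 0.13, 1.7, 2.10),
    ("#91", 0.24, 0.22, 2.7, "Linear"),
    ("#23", 0.29, 0.27, 1.4, 3.34),
    ("#73", 0.30, 0.27, 2.9, 1.96),
    ("#22", 0.35, 0.26, 1.3, "Linear"),
    ("#79", 0.43, 0.40, 2.8, "Linear"),
    ("#151", 0.49, 0.38, "Linear", "Linear"),
    ("#87", 0.71, 0.67, 3.0, 2.39),
    ("#102", 0.72, 0.68, "Linear", "Linear"),
    ("#24", 0.75, 0.66, 2.2, "Linear"),
    ("#168", 0.78, 0.78, "Linear", "Linear"),
    ("#55", 0.79, 0.76, "Linear", "Linear"),
    ("#93", 0.79, 0.71, 2.1, "Linear"),
    ("#14", 0.86, 0.84, "Linear", "Linear"),
    ("#56", 0.92, 0.91, "Linear", "Linear"),
    ("#147", 0.93, 0.90, 2.9, "Linear"),
    ("KS4895", 1.00, 1.00, 2.0, "Linear"),
    ("#35", 1.07, 1.08, 2.8, "Linear"),
    ("#152", 1.08, 1.12, "Linear", "Linear"),
    ("#51", 1.42, 1.52, "Linear", "Linear"),
    ("#108", 1.51, 1.64, "Linear", "Linear"),
    ("#3", 1.81, 2.02, "Linear", "Linear"),
    ("Jackson", 3.05, 3.61, "Linear", "Linear"),
    ("#134", 3.28, 3.49, "Linear", "Linear"),
    ("#142", 6.24, 7.25, "Linear", "Linear"),
    ("#139", 9.77, 12.73, "Linear", "Linear"),
]


def two_tier_screen_reference() -> pd.DataFrame:
    """The 26-genotype reference screen, one row per genotype.

    Columns: genotype, rdtr_k, rndtr_k, bp_32c, bp_37c (float kPa or the
    literal "Linear").
    """
    return pd.DataFrame(
        _SCREEN_ROWS, columns=["genotype", "rdtr_k", "rndtr_k", "bp_32c", "bp_37c"]
    )


def two_tier_screen_long() -> pd.DataFrame:
    """Long form of the reference screen: one row per genotype x temperature.

    Columns: genotype, rdtr_k, rndtr_k, temperature_c, bp.
    """
    wide = two_tier_screen_reference()
    longs = []
    for temp, col in [(32.0, "bp_32c"), (37.0, "bp_37c")]:
        longs.append(
            wide[["genotype", "rdtr_k", "rndtr_k"]].assign(
                temperature_c=temp, bp=wide[col]
            )
        )
    return pd.concat(longs, ignore_index=True)
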