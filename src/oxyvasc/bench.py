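"""Bench-side characterization formulas for oxygen-generating particles.

Pure calculators: encapsulation efficiency and loading capacity of the
peroxide payload, degree of methacrylation of the hydrogel precursor,
and hydrogel swelling ratio.  Out-of-range results (e.g. a swelling ratio
above any physical bound) are returned as computed, with a warning —
measurement anomalies should surface, not vanish.
"""

from __future__ import annotations

import warnings


def _warn_if_outside(value: float, lo: float, hi: float, name: str) -> float:
    if not (lo <= value <= hi):
        warnings.warn(
            f"{name} = {value:.4g} falls outside [{lo}, {hi}]; "
            "check the input measurements", stacklevel=3,
        )
    return value


def encapsulation_efficiency(total: float, lost: float) -> float:
    """Percent of added peroxide retained after washing:
    100 * (total - lost) / total."""
    if total <= 0:
        raise ValueError("total mass must be > 0")
    if lost < 0 or lost > total:
        raise ValueError("lost mass must lie in [0, total]")
    return _warn_if_outside(100.0 * (total - lost) / total, 0.0, 100.0,
                            "encapsulation efficiency")


def loading_capacity(encapsulated: float, final_mass: float) -> float:
    """Percent peroxide content of the finished microparticles:
    100 * encapsulated / final_mass."""
    if final_mass <= 0:
        raise ValueError("final particle mass must be > 0")
    if encapsulated < 0:
        raise ValueError("encapsulated mass must be >= 0")
    return _warn_if_outside(100.0 * encapsulated / final_mass, 0.0, 100.0,
                            "loading capacity")


def degree_of_methacrylation(i_sample: float, i_blank: float,
                             i_standard: float) -> float:
    """Fraction of substituted amines from a fluorescence assay:
    1 - (I_sample - I_blank) / (I_standard - I_blank)."""
    if i_standard == i_blank:
        raise ValueError("standard and blank intensities must differ")
    return _warn_if_outside(
        1.0 - (i_sample - i_blank) / (i_standard - i_blank), 0.0, 1.0,
        "degree of methacrylation",
    )


def swelling_ratio(w0: float, wt: float) -> float:
    """Percent mass gain of a swollen hydrogel: 100 * (Wt - W0) / W0."""
    if w0 <= 0:
        raise ValueError("initial weight must be > 0")
    if wt < 0:
        raise ValueError("swollen weight must be >= 0")
    value = 100.0 * (wt - w0) / w0
    if value < 0:
        warnings.warn(
            f"swelling ratio = {value:.4g} is negative (mass loss); "
            "check the input measurements", stacklevel=2,
        )
    return value
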