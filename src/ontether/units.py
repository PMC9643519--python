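"""Unit system: millimetre - MPa - Newton.

All lengths are mm, stresses/moduli MPa, forces N. Pressures given in mmHg
(clinical convention for IOP/ICP) convert with 1 mmHg = 133.322 Pa.
Post-processing reports stresses in kPa and strains in percent.
"""

MMHG_TO_MPA = 133.322e-6
"""1 mmHg in MPa."""

MPA_TO_KPA = 1000.0
MM_TO_UM = 1000.0
FRACTION_TO_PERCENT = 100.0


def mmhg_to_mpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to MPa."""
    return p_mmhg * MMHG_TO_MPA
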