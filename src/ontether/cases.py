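"""Tissue-stiffness case definitions for the sensitivity analysis.

The sensitivity matrix varies the posterior sclera, peripapillary sclera,
and ON sheath between their published stiff (95th percentile) and
compliant (5th percentile) levels; every other region keeps its average
card.  Cases A-D have a stiff posterior sclera and E-H a compliant one,
each sub-grid walking (peripapillary, sheath) through (stiff, stiff),
(stiff, compliant), (compliant, stiff), (compliant, compliant).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .constitutive import (
    MaterialLibrary,
    homogenize_on_interior,
)
from .errors import MaterialLookupError

__all__ = ["CaseSpec", "SENSITIVITY_CASES", "make_case_materials",
           "STIFFNESS_LEVELS"]

STIFFNESS_LEVELS = ("average", "stiff", "compliant")

#: label -> (posterior sclera, peripapillary sclera, ON sheath)
SENSITIVITY_CASES = {
    "A": ("stiff", "stiff", "stiff"),
    "B": ("stiff", "stiff", "compliant"),
    "C": ("stiff", "compliant", "stiff"),
    "D": ("stiff", "compliant", "compliant"),
    "E": ("compliant", "stiff", "stiff"),
    "F": ("compliant", "stiff", "compliant"),
    "G": ("compliant", "compliant", "stiff"),
    "H": ("compliant", "compliant", "compliant"),
}


@dataclass(frozen=True)
class CaseSpec:
    """Per-region stiffness levels of one simulation case."""

    label: str = "average"
    posterior_sclera: str = "average"
    peripapillary_sclera: str = "average"
    on_sheath: str = "average"
    on_connective: str = "average"

    def __post_init__(self):
        for region in ("posterior_sclera", "peripapillary_sclera",
                       "on_sheath", "on_connective"):
            level = getattr(self, region)
            if level not in STIFFNESS_LEVELS:
                raise MaterialLookupError(
                    f"case {self.label!r}: unknown stiffness level "
                    f"{level!r} for {region}")

    @classmethod
    def from_label(cls, label: str) -> "CaseSpec":
        """'average' or one of the sensitivity labels A..H."""
        if label == "average":
            return cls()
        try:
            post, peri, sheath = SENSITIVITY_CASES[label]
        except KeyError:
            raise MaterialLookupError(
                f"unknown case label {label!r}; valid: average, "
                f"{', '.join(SENSITIVITY_CASES)}") from None
        return cls(label=label, posterior_sclera=post,
                   peripapillary_sclera=peri, on_sheath=sheath)

    def with_on(self, level: str) -> "CaseSpec":
        """Same case with a different ON connective-tissue stiffness."""
        return replace(self, label=f"{self.label}-on_{level}",
                       on_connective=level)


#: Hardening floor applied to every card in scenario runs (fraction of
#: C10).  Inside the fitted strain range the polynomial hardening exceeds
#: this and the response is the published card exactly; beyond it, the
#: floor prevents the unphysical non-monotone extrapolation of percentile
#: fits (notably the 5th-percentile peripapillary sclera, whose uniaxial
#: stress would otherwise fall beyond ~12% strain).
SCENARIO_HARDENING_FLOOR = 0.2


def make_case_materials(case: CaseSpec, library: MaterialLibrary,
                        mode: str = "2d",
                        connective_fraction: float = None,
                        hardening_floor: float = SCENARIO_HARDENING_FLOOR,
                        ) -> dict:
    """Full region -> material-card map for one case.

    In 2-D mode the ON interior appears as the single homogenized region
    ``on_homogenized`` (area-fraction blend of the case's connective card
    with the neural card); in 3-D the honeycomb regions ``on_connective``
    and ``on_neural`` carry their own cards.  All reduced-polynomial cards
    receive the monotone-extrapolation safeguard (see
    ``SCENARIO_HARDENING_FLOOR``; pass 0 to disable).
    """
    mats = {
        "anterior_sclera": library.get("anterior_sclera", "average"),
        "equatorial_sclera": library.get("equatorial_sclera", "average"),
        "posterior_sclera": library.get("posterior_sclera",
                                        case.posterior_sclera),
        "peripapillary_sclera": library.get("peripapillary_sclera",
                                            case.peripapillary_sclera),
        "on_sheath": library.get("on_sheath", case.on_sheath),
        "lamina_cribrosa": library.get("lamina_cribrosa", "average"),
    }
    conn = library.get("on_connective", case.on_connective)
    neural = library.get("on_neural", "average")
    if mode == "2d":
        kwargs = ({} if connective_fraction is None
                  else {"connective_fraction": connective_fraction})
        mats["on_homogenized"] = homogenize_on_interior(conn, neural, **kwargs)
    else:
        mats["on_connective"] = conn
        mats["on_neural"] = neural
    if hardening_floor:
        mats = {k: (v.with_hardening_floor(hardening_floor)
                    if hasattr(v, "with_hardening_floor") else v)
                for k, v in mats.items()}
    return mats
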