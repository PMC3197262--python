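"""Magnetic and RF properties of stent materials.

Two scalar parameters per material drive the image-artifact model:

``delta_chi``
    Volume magnetic susceptibility difference between the stent alloy and
    soft tissue (dimensionless, SI volume convention).  Literature values at
    1.5 T: tantalum ~190e-6, nitinol ~255e-6, platinum ~290e-6; austenitic
    stainless steel (316L) is far larger, on the order of 1e-3 to 1e-2.
    Tissue-to-tissue differences (<10e-6) are negligible by comparison.

``shielding_factor``
    Multiplicative factor on the nominal excitation flip angle inside the
    stented lumen, standing in for the RF (B1) shielding produced by eddy
    currents induced in the conductive strut cage.  The true B1 response
    depends on the wire configuration and is not predictable from material
    alone; the values below are calibration constants chosen so that the
    simulated signal regimes order by material the way phantom measurements
    do (steel worst, nitinol/tantalum intermediate-to-good, braided
    cobalt-superalloy above unity).  A factor above 1 models the regime in
    which the effective in-lumen excitation lands nearer the Ernst angle
    than the nominal flip does, raising in-stent signal above the unstented
    reference.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MaterialProps", "MATERIALS", "get_material"]


@dataclass(frozen=True)
class MaterialProps:
    """Artifact-relevant properties of one stent material."""

    name: str
    delta_chi: float
    shielding_factor: float

    def __post_init__(self) -> None:
        if not (self.delta_chi >= 0.0):
            raise ValueError(f"delta_chi must be finite and >= 0, got {self.delta_chi}")
        if not (0.0 < self.shielding_factor <= 1.5):
            raise ValueError(
                f"shielding_factor must be in (0, 1.5], got {self.shielding_factor}"
            )


#: Default material registry.  delta_chi for tantalum/nitinol/platinum are
#: literature susceptibility differences vs. tissue; the steel and
#: cobalt-superalloy entries and every shielding_factor are simulator
#: calibration constants (see module docstring), not measured quantities.
MATERIALS: dict[str, MaterialProps] = {
    "tantalum": MaterialProps("tantalum", delta_chi=190e-6, shielding_factor=0.95),
    "nitinol": MaterialProps("nitinol", delta_chi=255e-6, shielding_factor=0.80),
    "platinum-iridium": MaterialProps(
        "platinum-iridium", delta_chi=290e-6, shielding_factor=0.25
    ),
    "316L": MaterialProps("316L", delta_chi=5e-3, shielding_factor=0.45),
    "cobalt-superalloy": MaterialProps(
        "cobalt-superalloy", delta_chi=220e-6, shielding_factor=1.45
    ),
    "PET+cobalt-superalloy": MaterialProps(
        "PET+cobalt-superalloy", delta_chi=220e-6, shielding_factor=1.10
    ),
    # convenience entry for artifact-free control phantoms
    "none": MaterialProps("none", delta_chi=0.0, shielding_factor=1.0),
}


def get_material(name: str) -> MaterialProps:
    """Look up a material by registry name (case-sensitive)."""
    try:
        return MATERIALS[name]
    except KeyError:
        known = ", ".join(sorted(MATERIALS))
        raise KeyError(f"unknown material {name!r}; known materials: {known}") from None
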