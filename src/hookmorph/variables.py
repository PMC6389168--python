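"""Canonical vocabulary of the 14 hook and handle measurements.

Eleven lengths are reported in micrometres, three angles in degrees.
`VARIABLE_NAMES` fixes the column order used by every table in the package.
"""

from __future__ import annotations

#: Canonical column order for measurement tables.
VARIABLE_NAMES: tuple[str, ...] = (
    "HL",   # hook length: extent of the hook along the shaft axis
    "HNL",  # handle length: tip to base of the handle
    "AD",   # aperture distance: point tip to centre of the articulation base
    "PSW",  # proximal shaft width: articulation base to the heel zenith
    "PL",   # point length: perpendicular distance from the AD vector to the outer zenith
    "DSW",  # distal shaft width: hook width where the PL vector crosses the structure
    "ICL",  # inner curve length: inner-blade zenith to the tip/outer-zenith chord
    "OCL",  # outer curve length: outer-blade zenith to the same chord
    "PCA",  # point curve angle: between the PL vector and the chord (degrees)
    "ISL",  # inner shaft length: PL/inner-edge intercept to the articulation base
    "IAA",  # inner aperture angle at the PL/inner-edge intercept (degrees)
    "OSL",  # outer shaft length: PL/outer-edge intercept to the heel zenith
    "OAA",  # outer aperture angle at the PL/outer-edge intercept (degrees)
    "DPL",  # distal point length: point tip to the outer zenith
)

#: Variables measured in degrees; everything else is in micrometres.
ANGLE_VARIABLES: frozenset[str] = frozenset({"PCA", "IAA", "OAA"})

#: Variables measured on the hook proper (HNL needs the handle landmarks).
HOOK_VARIABLES: tuple[str, ...] = tuple(v for v in VARIABLE_NAMES if v != "HNL")

#: Units keyed by variable name.
UNITS: dict[str, str] = {
    name: ("deg" if name in ANGLE_VARIABLES else "um") for name in VARIABLE_NAMES
}
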