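"""Unit conversions.

Amounts inside the simulator are expressed in fmol per lattice voxel.  The
scaling anchor is 5 mM == 0.32 fmol/voxel, which fixes the linear conversion
used for every species.
"""

MM_ANCHOR = 5.0  # mM
FMOL_ANCHOR = 0.32  # fmol/voxel

#: fmol/voxel per mM
FMOL_PER_MM = FMOL_ANCHOR / MM_ANCHOR


def mm_to_fmol_per_voxel(c_mm: float) -> float:
    """Convert a concentration in mM to fmol/voxel (linear through zero)."""
    if c_mm < 0:
        raise ValueError(f"concentration must be non-negative, got {c_mm}")
    return c_mm * FMOL_PER_MM


def fmol_per_voxel_to_mm(c_fmol: float) -> float:
    """Inverse of :func:`mm_to_fmol_per_voxel`."""
    if c_fmol < 0:
        raise ValueError(f"concentration must be non-negative, got {c_fmol}")
    return c_fmol / FMOL_PER_MM
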