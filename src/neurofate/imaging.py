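"""Imaging geometry constants.

The two-photon fields are 509 x 509 um sampled at 1024 x 1024 pixels with
z-planes every 2 um, so the native voxel pitch is ~0.497 um in XY and 2 um
in Z.  These constants are the single source of truth for converting
between micrometres and voxel units throughout the package.
"""

#: XY pixel pitch in micrometres (509 um field / 1024 pixels).
XY_PITCH_UM: float = 509.0 / 1024.0

#: Z step between planes in micrometres.
Z_PITCH_UM: float = 2.0

#: Default (dx, dy, dz) voxel size in micrometres.
DEFAULT_VOXEL_SIZE_UM: tuple[float, float, float] = (XY_PITCH_UM, XY_PITCH_UM, Z_PITCH_UM)


def voxel_volume_um3(voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM) -> float:
    """Volume of a single voxel in cubic micrometres."""
    dx, dy, dz = voxel_size
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel dimensions must be positive")
    return dx * dy * dz
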