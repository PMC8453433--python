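"""Shared label and channel conventions.

Tissue label maps are single-label uint8 volumes. The left-right axis is
always axis 0 and must have even extent so that the midline falls between
two voxel columns and reflection is an exact permutation.
"""

BACKGROUND = 0
CSF = 1
GM = 2
WM = 3
LESION = 4

TISSUE_NAMES = {
    BACKGROUND: "background",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
    LESION: "lesion",
}

#: Image channels carried by every timepoint.
CHANNELS = ("mtr", "t1w", "t2w")

#: Axis across which left and right hemispheres mirror.
LR_AXIS = 0
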