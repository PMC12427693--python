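"""The 19-channel 10-20 montage used throughout the package.

Channel order is the canonical clinical ordering (frontal-polar to midline
parietal) that all recordings are normalized to on load.
"""

CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

N_CHANNELS = len(CHANNELS_1020)


def channel_index(label: str) -> int:
    """Index of *label* in the canonical montage order."""
    try:
        return CHANNELS_1020.index(label)
    except ValueError:
        raise KeyError(f"unknown 10-20 channel label: {label!r}") from None
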