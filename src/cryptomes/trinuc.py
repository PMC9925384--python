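"""96-channel single-base-substitution context machinery.

Single-base substitutions are represented on the pyrimidine strand: a
mutation whose reference base is a purine is reverse-complemented so that
the reference is always C or T.  The 96 channels are the six pyrimidine
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 4 x 4
possible 5' and 3' flanking bases, in the conventional catalog ordering
(substitution-major, then 5' base, then 3' base).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def _make_channels() -> list[str]:
    channels = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                channels.append(f"{five}[{sub}]{three}")
    return channels


#: The 96 channel labels, e.g. ``"T[C>T]A"``, in catalog order.
CHANNELS: tuple[str, ...] = tuple(_make_channels())
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Pyrimidine-strand channel label for a substitution with its flanks.

    ``five`` and ``three`` are the bases immediately 5' and 3' of the
    mutated base on the same strand as ``ref``/``alt``.  Purine-reference
    mutations are reverse-complemented onto the pyrimidine strand.
    """
    ref, alt = ref.upper(), alt.upper()
    five, three = five.upper(), three.upper()
    if ref == alt or ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in CHANNEL_INDEX:
        raise ValueError(f"unrecognized channel {label}")
    return label


def channel_context(channel: str) -> str:
    """Pyrimidine-strand trinucleotide (e.g. ``"TCA"`` for ``"T[C>A]A"``)."""
    return channel[0] + channel[2] + channel[6]


def channel_alt(channel: str) -> str:
    """Alternate base of a channel on the pyrimidine strand."""
    return channel[4]


def trinuc_at(seq: str, pos: int) -> str:
    """Trinucleotide centred on 1-based position ``pos`` of ``seq``."""
    if pos < 2 or pos > len(seq) - 1:
        raise ValueError(f"position {pos} has no complete trinucleotide context")
    return seq[pos - 2 : pos + 1].upper()


def context_positions(seq: str) -> dict[str, np.ndarray]:
    """Map each pyrimidine-strand trinucleotide to the 1-based positions
    of ``seq`` whose centre base mutates in that context.

    A position with centre C or T matches its forward trinucleotide; a
    position with centre A or G matches the reverse complement.  Positions
    1 and len(seq) are excluded (incomplete context).
    """
    seq = seq.upper()
    index: dict[str, list[int]] = {}
    for pos in range(2, len(seq)):
        tri = seq[pos - 2 : pos + 1]
        if any(b not in BASES for b in tri):
            continue
        if tri[1] in "AG":
            tri = revcomp(tri)
        index.setdefault(tri, []).append(pos)
    return {k: np.asarray(v, dtype=np.int64) for k, v in index.items()}
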