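"""The 96-channel single-base-substitution (SBS) convention.

Substitutions are expressed on the pyrimidine strand (reference base C or T),
giving six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each in 16
trinucleotide contexts (4 x 5' flank, 4 x 3' flank).  Channel order follows
the conventional alphabetical catalogue layout: classes in the order above,
contexts sorted by 5' then 3' flank, e.g. ``A[C>A]A, A[C>A]C, ... T[T>G]T``.
"""

from __future__ import annotations

import re

BASES = ("A", "C", "G", "T")
CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CLASSES6 = CLASSES  # alias used when collapsing spectra

#: the 96 channel labels in canonical order
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{cls}]{three}"
    for cls in CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CHANNEL_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(context: str, ref: str, alt: str) -> str | None:
    """Map a substitution with trinucleotide ``context`` to its channel label.

    ``context`` is the 3-mer centred on the variant on the reference strand;
    purine-reference substitutions are folded onto the pyrimidine strand by
    reverse complement.  Returns ``None`` for ambiguous input (N bases or a
    context whose middle base disagrees with ``ref``).
    """
    if len(context) != 3 or context[1] != ref or ref == alt:
        return None
    if any(b not in "ACGT" for b in context) or alt not in "ACGT":
        return None
    if ref in "AG":  # fold to pyrimidine strand
        context = revcomp(context)
        ref = complement(ref)
        alt = complement(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def parse_channel(label: str) -> tuple[str, str, str, str]:
    """Split a channel label into (5' flank, ref, alt, 3' flank)."""
    m = _CHANNEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a valid 96-channel label: {label!r}")
    return m.group(1), m.group(2), m.group(3), m.group(4)


def class_of(label: str) -> str:
    """Six-class substitution type (e.g. 'C>T') of a channel label."""
    five, ref, alt, three = parse_channel(label)
    return f"{ref}>{alt}"


CHANNEL_CLASS = tuple(class_of(c) for c in CHANNELS)
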