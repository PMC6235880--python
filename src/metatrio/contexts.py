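"""Trinucleotide substitution contexts and genome constants.

Somatic SNVs are conventionally collapsed onto the pyrimidine strand: a
substitution is described by its pyrimidine reference base (C or T), the
alternate base, and the two flanking bases, giving 6 substitution classes
x 16 flank combinations = 96 context labels of the form ``A[C>A]A``.
Purine-reference SNVs (G or A) are reverse-complemented before binning.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

BASES = ("A", "C", "G", "T")

#: substitution classes in canonical (COSMIC) order
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _build_context_labels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: the 96 canonical pyrimidine-centered context labels, in COSMIC order
CONTEXT_LABELS: tuple[str, ...] = _build_context_labels()

CONTEXT_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def context_label(ref: str, alt: str, context: str) -> str:
    """Canonical 96-bin label for an SNV with trinucleotide ``context``.

    ``context`` is the 5' base, the reference base and the 3' base as read
    on the reference strand; purine references are strand-collapsed.

    Raises ``ValueError`` for non-SNVs, contexts containing N, or a context
    whose middle base disagrees with ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3:
        raise ValueError(f"context must be 3 bases, got {context!r}")
    if "N" in context or "N" in ref or "N" in alt:
        raise ValueError(f"context contains N: {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref in ("G", "A"):
        ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in CONTEXT_INDEX:
        raise ValueError(f"invalid context label {label!r}")
    return label


def parse_context_label(label: str) -> tuple[str, str, str]:
    """Split ``"A[C>T]G"`` into (ref, alt, trinucleotide context)."""
    if label not in CONTEXT_INDEX:
        raise ValueError(f"unknown context label {label!r}")
    five, rest = label.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return ref, alt, five + ref + three


#: hs37d5 autosome lengths (GRCh37), chromosome names without "chr" prefix
HS37D5_AUTOSOMES: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (hs37d5 naming)."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom
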