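"""Antisense oligonucleotide (ASO) definitions and base-pairing vocabulary.

An ASO is a short synthetic nucleic acid, written 5'->3', carrying a sugar
modification at every position (2'-O-methoxyethyl [MOE], 2'-O-methyl [OMe],
morpholino [PMO] or unmodified DNA) and a backbone type (phosphorothioate or
the neutral morpholino backbone).  Duplexes with target pre-mRNA are always
antiparallel, so the 3' end of the ASO covers the 5' end of its target
footprint.

Alphabet conventions
--------------------
Targets are pre-mRNA but may arrive as DNA-alphabet FASTA; OMe ASOs are
written with U, MOE/DNA ASOs with T.  Internally both are normalised to a
T-alphabet: the pairing rules treat T and U as the same base, matching the
interchangeable "G-U/G-T" wobble usage in the splicing literature.
5-methylcytosine (written ``mC`` or lowercase ``m`` prefix) pairs exactly as
C and is retained only for display.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "SugarMod",
    "Backbone",
    "PairClass",
    "Anchor",
    "AsoDefinition",
    "pair_class",
    "complement_base",
    "antisense_of",
    "derive_short_series",
    "mixed_chemistry_variant",
]


class SugarMod(str, enum.Enum):
    """Per-position sugar chemistry of an ASO residue."""

    MOE = "MOE"
    OME = "OME"
    PMO = "PMO"
    DNA = "DNA"


class Backbone(str, enum.Enum):
    PS = "PS"
    PMO_NEUTRAL = "PMO_NEUTRAL"


class PairClass(str, enum.Enum):
    """Classification of one duplex column.

    CANONICAL - Watson-Crick pair; WOBBLE - G:T/U or T/U:G; MISMATCH - any
    other base opposition; ASO_BULGE / TARGET_BULGE - an unpaired nucleotide
    on the respective strand.
    """

    CANONICAL = "canonical"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"
    ASO_BULGE = "aso_bulge"
    TARGET_BULGE = "target_bulge"


class Anchor(str, enum.Enum):
    """Which part of the parent's target footprint a truncated ASO covers."""

    FIRST = "first"
    MIDDLE = "middle"
    LAST = "last"


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_VALID = set("ACGTUN")

# token per residue: optional 5-methyl prefix "m" then a base letter
_SEQ_TOKEN = re.compile(r"m?[ACGTUNacgtun]")


def normalize_base(base: str) -> str:
    """Map one residue token to the internal T-alphabet (mC->C, U->T)."""
    b = base.lstrip("m").upper()
    b = "T" if b == "U" else b
    if b not in _VALID:
        raise ValueError(f"invalid nucleotide symbol: {base!r}")
    return b


def tokenize_sequence(sequence: str) -> list[str]:
    """Split an ASO/target string into residue tokens, keeping mC markers."""
    tokens = _SEQ_TOKEN.findall(sequence)
    if "".join(tokens) != sequence:
        bad = re.sub(_SEQ_TOKEN, "", sequence)
        raise ValueError(f"invalid nucleotide symbol: {bad[0]!r}")
    return tokens


def pair_class(aso_base: str, target_base: str) -> PairClass:
    """Classify the pairing of an ASO base against a target base.

    Antiparallel opposition is assumed.  T and U are interchangeable; mC
    pairs as C; degenerate bases (N) mismatch everything.
    """
    a = normalize_base(aso_base)
    t = normalize_base(target_base)
    if "N" in (a, t):
        return PairClass.MISMATCH
    if _COMPLEMENT[a] == t:
        return PairClass.CANONICAL
    if {a, t} == {"G", "T"}:
        return PairClass.WOBBLE
    return PairClass.MISMATCH


def complement_base(base: str) -> str:
    b = normalize_base(base)
    if b == "N":
        return "N"
    return _COMPLEMENT[b]


def antisense_of(target_segment: str) -> str:
    """Reverse complement of a target segment, written 5'->3'.

    This is the perfectly complementary ASO for that segment under
    antiparallel pairing; ``antisense_of`` is an involution.
    """
    return "".join(complement_base(b) for b in reversed(target_segment))


@dataclass(frozen=True)
class AsoDefinition:
    """An oligonucleotide with per-position chemistry.

    ``sequence`` is stored 5'->3' and may contain U (OMe chemistry) or mC
    tokens; ``sugar_mods`` has one tag per residue.  Position numbering for
    reporting is 1-based from the ASO 3' end (the convention used when
    describing mixed-chemistry blocks); :meth:`position_from_5prime`
    provides the alternative 5'-based view.
    """

    name: str
    sequence: str
    sugar_mods: tuple[SugarMod, ...]
    backbone: Backbone = Backbone.PS
    tokens: tuple[str, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        tokens = tuple(tokenize_sequence(self.sequence))
        object.__setattr__(self, "tokens", tokens)
        if len(tokens) != len(self.sugar_mods):
            raise ValueError(
                f"{self.name}: sequence has {len(tokens)} residues but "
                f"{len(self.sugar_mods)} sugar tags"
            )
        if len(tokens) < 8:
            raise ValueError(f"{self.name}: ASOs shorter than 8 nt are not supported")
        for tok in tokens:
            normalize_base(tok)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def bases(self) -> str:
        """Normalised T-alphabet bases, 5'->3' (mC -> C, U -> T)."""
        return "".join(normalize_base(t) for t in self.tokens)

    def base_at(self, pos_5prime: int) -> str:
        """Normalised base at 1-based position counted from the 5' end."""
        return normalize_base(self.tokens[pos_5prime - 1])

    def mod_at_3prime(self, pos_3prime: int) -> SugarMod:
        """Sugar tag at 1-based position counted from the 3' end."""
        return self.sugar_mods[len(self) - pos_3prime]

    def position_from_5prime(self, pos_3prime: int) -> int:
        return len(self) - pos_3prime + 1

    def perfect_target(self) -> str:
        """The target footprint (sense strand, 5'->3') this ASO fully pairs."""
        return antisense_of(self.bases)


def uniform(name: str, sequence: str, mod: SugarMod, backbone: Backbone = Backbone.PS) -> AsoDefinition:
    """Convenience constructor for a single-chemistry ASO."""
    n = len(tokenize_sequence(sequence))
    return AsoDefinition(name, sequence, (mod,) * n, backbone)


def derive_short_series(aso: AsoDefinition, k: int, anchor: Anchor) -> AsoDefinition:
    """Truncate an ASO so its footprint covers part of the parent's target.

    ``anchor`` selects which k residues of the parent's target footprint the
    child covers: FIRST means the 5'-most k target residues (covered by the
    3' end of the ASO, because pairing is antiparallel), LAST the 3'-most k,
    MIDDLE a centred window.  Chemistry tags are sliced with the sequence.
    """
    m = len(aso)
    if not 8 <= k <= m:
        raise ValueError(f"k={k} out of range [8, {m}]")
    if anchor is Anchor.FIRST:
        start = m - k  # 5'-based slice start on the ASO
    elif anchor is Anchor.LAST:
        start = 0
    else:
        start = (m - k) - (m - k) // 2  # centre the footprint on the target
    tokens = aso.tokens[start : start + k]
    mods = aso.sugar_mods[start : start + k]
    prefix = {Anchor.FIRST: "F", Anchor.MIDDLE: "M", Anchor.LAST: "L"}[anchor]
    name = aso.name if k == m else f"{prefix}{k}:{aso.name}"
    return AsoDefinition(name, "".join(tokens), mods, aso.backbone)


def footprint_offset(parent_len: int, k: int, anchor: Anchor) -> int:
    """0-based offset of the truncated footprint within the parent footprint."""
    if anchor is Anchor.FIRST:
        return 0
    if anchor is Anchor.LAST:
        return parent_len - k
    return (parent_len - k) // 2


def mixed_chemistry_variant(
    parent: AsoDefinition,
    name: str,
    ome_blocks_3prime: list[tuple[int, int]],
) -> AsoDefinition:
    """Replace MOE with OMe in 1-based inclusive blocks counted from the 3' end.

    Mixed-chemistry series are conventionally numbered from the ASO 3' end;
    e.g. blocks ``[(1, 12), (16, 18)]`` leave MOE only at 3'-positions 13-15.
    """
    mods = list(parent.sugar_mods)
    n = len(parent)
    for lo, hi in ome_blocks_3prime:
        if not 1 <= lo <= hi <= n:
            raise ValueError(f"block {(lo, hi)} outside 1..{n}")
        for p3 in range(lo, hi + 1):
            mods[n - p3] = SugarMod.OME
    return replace(parent, name=name, sugar_mods=tuple(mods))
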