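"""Packaged ASO and target fixtures.

Two provenance classes, recorded per fixture:

* ``literature`` — the ISS-N1-targeting ASO sequences and the first 32 nt
  of SMN2 intron 7.  These are established, publicly documented sequences
  (the 18-mer MOE ASO is the nusinersen sequence; the intron-7 start
  contains ISS-N1 at positions 10-24 and the 18-mer footprint at 10-27).
* ``synthetic`` — reconstructions of the validated off-target annealing
  sites.  The genomic site sequences themselves are not reproduced here;
  each synthetic site is built from the perfect 18-mer footprint by
  applying exactly the reported duplex degradations (e.g. the POLR2H exon 2
  site: mismatches opposing the ASO 3' end at exon positions 8 and 10,
  G-T wobbles at exon positions 16 and 20, 14 canonical pairs), so duplex
  feature counts — not base identities — match the validated sites.
  Scrambled-control sequences are likewise deterministic same-composition
  shuffles, not the published controls.

Use :func:`fixture_catalogue` for the full set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .oligo import (
    Anchor,
    AsoDefinition,
    Backbone,
    SugarMod,
    antisense_of,
    derive_short_series,
    mixed_chemistry_variant,
    uniform,
)
from .simulate import Edit, EditKind, apply_edits

__all__ = ["TargetFixture", "fixture_catalogue", "ISS_N1_REGION", "F18MOE_FOOTPRINT"]

# First 32 nt of SMN2 intron 7; ISS-N1 occupies positions 10-24, the 18-mer
# MOE ASO footprint positions 10-27, the 20-mer PMO footprint 10-29.
ISS_N1_REGION = "GTAAGTCTGCCAGCATTATGAAAGTGAATCTT"

# Perfect (fully complementary) target footprint of the 18-mer ASOs.
F18MOE_FOOTPRINT = "CCAGCATTATGAAAGTGA"


@dataclass(frozen=True)
class TargetFixture:
    """A target record with its annealing-site truth and exon annotation."""

    target_id: str
    sequence: str
    site_span: tuple[int, int]  # 1-based inclusive on the record
    site_seq: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open intervals
    provenance: str
    expected: dict | None = None  # expected duplex feature counts vs the 18-mer MOE ASO


def _f18moe() -> AsoDefinition:
    # methylcytosine (mC) at every C position, as in the marketed 18-mer
    return AsoDefinition(
        "F18MOE",
        "TmCAmCTTTmCATAATGmCTGG",
        (SugarMod.MOE,) * 18,
        Backbone.PS,
    )


def _scramble(name: str, parent: AsoDefinition, seed: int) -> AsoDefinition:
    """Deterministic same-composition shuffle (synthetic stand-in for the
    published scrambled controls, whose base order is not reproduced here)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(parent))
    tokens = [parent.tokens[i] for i in order]
    return AsoDefinition(name, "".join(tokens), parent.sugar_mods, parent.backbone)


# Edits defining each synthetic off-target site, as 1-based positions within
# the 18-mer footprint (footprint position i opposes ASO 5'-position 19-i).
# Mismatch replacement bases are pinned for reproducibility.
_SITE_EDITS: dict[str, list[tuple[int, EditKind, str | None]]] = {
    # 14 canonical, 2 mismatches (opposing the ASO 3' end), 2 mid wobbles
    "POLR2H": [(1, EditKind.MISMATCH, "A"), (3, EditKind.MISMATCH, "T"),
               (9, EditKind.WOBBLE_SWAP, None), (13, EditKind.WOBBLE_SWAP, None)],
    # 15 canonical
    "PITHD1": [(6, EditKind.WOBBLE_SWAP, None), (11, EditKind.MISMATCH, "A"),
               (14, EditKind.WOBBLE_SWAP, None)],
    # 13 canonical (weakest validated site)
    "SERPINB7": [(3, EditKind.MISMATCH, "C"), (6, EditKind.WOBBLE_SWAP, None),
                 (9, EditKind.WOBBLE_SWAP, None), (12, EditKind.WOBBLE_SWAP, None),
                 (18, EditKind.MISMATCH, "C")],
    # 15 canonical + one bulged target nucleotide
    "RTTN": [(2, EditKind.MISMATCH, "A"), (6, EditKind.WOBBLE_SWAP, None),
             (13, EditKind.WOBBLE_SWAP, None), (9, EditKind.INSERT, "C")],
    # 15 canonical
    "REV3L": [(4, EditKind.MISMATCH, "A"), (9, EditKind.WOBBLE_SWAP, None),
              (18, EditKind.WOBBLE_SWAP, None)],
    # 15 canonical
    "PRKRA": [(2, EditKind.WOBBLE_SWAP, None), (6, EditKind.WOBBLE_SWAP, None),
              (10, EditKind.MISMATCH, "C")],
    # 14 canonical
    "GOLGA4": [(1, EditKind.MISMATCH, "A"), (5, EditKind.WOBBLE_SWAP, None),
               (12, EditKind.WOBBLE_SWAP, None), (16, EditKind.MISMATCH, "G")],
    # 14 canonical
    "PAK1": [(2, EditKind.WOBBLE_SWAP, None), (5, EditKind.MISMATCH, "A"),
             (9, EditKind.WOBBLE_SWAP, None), (18, EditKind.MISMATCH, "C")],
}

_SITE_EXONS = {"POLR2H": ("exon2", 8), "PITHD1": ("exon2", 21), "SERPINB7": ("exon4", 21),
               "RTTN": ("exon4", 21), "REV3L": ("exon9", 21), "PRKRA": ("exon2", 21),
               "GOLGA4": ("exon4", 21), "PAK1": ("exon2", 21)}

# Mutant POLR2H sites: M1 restores the two mismatches, M2 the two wobbles,
# M3 all four (perfect complementarity).
_POLR2H_MUTANTS = {
    "POLR2H_M1": [(9, EditKind.WOBBLE_SWAP, None), (13, EditKind.WOBBLE_SWAP, None)],
    "POLR2H_M2": [(1, EditKind.MISMATCH, "A"), (3, EditKind.MISMATCH, "T")],
    "POLR2H_M3": [],
}


def site_sequence(gene: str) -> str:
    """The 18-mer (19-mer for the bulged site) degraded footprint."""
    edits_raw = dict(_SITE_EDITS, **_POLR2H_MUTANTS)[gene]
    edits = [Edit(p, k, b) for p, k, b in edits_raw]
    return apply_edits(F18MOE_FOOTPRINT, _f18moe(), edits)


def _site_record(gene: str, site_exon_offset: int, exon_name: str, seed: int) -> TargetFixture:
    """Embed a site in synthetic intron/exon context.

    Layout: 60 nt intron - exon - 60 nt intron, with the site starting at
    the given 1-based position within the exon (POLR2H uses exon position 8,
    matching the reported site location of exon-2 positions 8-25).
    """
    rng = np.random.default_rng(seed)
    site = site_sequence(gene)
    pre_exon = site_exon_offset - 1  # exonic bases before the site
    post_exon = 20
    bases = np.array(list("ACGT"))
    intron5 = "".join(rng.choice(bases, size=60))
    intron3 = "".join(rng.choice(bases, size=60))
    pre = list(rng.choice(bases, size=pre_exon))
    post = list(rng.choice(bases, size=post_exon))
    # pin the bases adjacent to the site so the planted duplex cannot extend
    # into the synthetic context (the ASO terminal base mismatches itself)
    aso_bases = _f18moe().bases
    if pre:
        pre[-1] = aso_bases[-1]  # 5' neighbour opposes the ASO 3' terminus
    if post:
        post[0] = aso_bases[0]
    exon = "".join(pre) + site + "".join(post)
    seq = intron5 + exon + intron3
    start = len(intron5) + pre_exon  # 0-based site start
    edits = dict(_SITE_EDITS, **_POLR2H_MUTANTS)[gene]
    kinds = [k for _, k, _ in edits]
    return TargetFixture(
        target_id=f"{gene}_{exon_name}",
        sequence=seq,
        site_span=(start + 1, start + len(site)),
        site_seq=site,
        exons=((len(intron5), len(intron5) + len(exon)),),
        provenance="synthetic reconstruction (feature counts match the validated site)",
        expected={
            "n_mismatch": kinds.count(EditKind.MISMATCH),
            "n_wobble": kinds.count(EditKind.WOBBLE_SWAP),
            "n_bulge": kinds.count(EditKind.INSERT) + kinds.count(EditKind.DELETE),
        },
    )


def fixture_catalogue() -> dict:
    """All packaged ASO and target fixtures.

    Returns a dict with keys ``asos`` (name -> AsoDefinition), ``targets``
    (gene -> TargetFixture for the eight validated off-target sites plus the
    POLR2H M1/M2/M3 mutants) and ``iss_n1_region`` (the intron-7 start as a
    TargetFixture with no exon annotation).
    """
    f18moe = _f18moe()
    f18ome = uniform("F18OMe", "UCACUUUCAUAAUGCUGG", SugarMod.OME, Backbone.PS)
    f20pmo = uniform("F20PMO", "ATTCACTTTCATAATGCTGG", SugarMod.PMO, Backbone.PMO_NEUTRAL)

    asos: dict[str, AsoDefinition] = {
        "F18MOE": f18moe,
        "F18OMe": f18ome,
        "F20PMO": f20pmo,
        "ScrMOE": _scramble("ScrMOE", f18moe, 181),
        "ScrOMe": _scramble("ScrOMe", f18ome, 182),
        "ScrPMO": _scramble("ScrPMO", f20pmo, 183),
    }
    # truncation series: F/M/L cover the first/middle/last k target residues
    for k in (14, 10):
        for anchor, prefix in ((Anchor.FIRST, "F"), (Anchor.MIDDLE, "M"), (Anchor.LAST, "L")):
            short = derive_short_series(f18moe, k, anchor)
            asos[f"{prefix}{k}MOE"] = replace(short, name=f"{prefix}{k}MOE")
    # mixed-chemistry series; blocks numbered 1-based from the ASO 3' end
    mixed_blocks = {
        "OMe1-6": [(1, 6)],
        "OMe4-9": [(4, 9)],
        "OMe7-13": [(7, 13)],
        "OMe10-15": [(10, 15)],
        "OMe13-18": [(13, 18)],
        "OMe1-9": [(1, 9)],
        "OMe1-12": [(1, 12)],
        "OMe1-12/16-18": [(1, 12), (16, 18)],
    }
    for name, blocks in mixed_blocks.items():
        asos[name] = mixed_chemistry_variant(f18moe, name, blocks)

    targets = {}
    for i, (gene, (exon_name, offset)) in enumerate(_SITE_EXONS.items()):
        targets[gene] = _site_record(gene, offset, exon_name, seed=97 + i)
    for gene in _POLR2H_MUTANTS:
        targets[gene] = _site_record(gene, 8, "exon2", seed=97)  # same context as WT

    iss = TargetFixture(
        target_id="SMN2_intron7_start",
        sequence=ISS_N1_REGION,
        site_span=(10, 27),
        site_seq=ISS_N1_REGION[9:27],
        exons=(),
        provenance="literature",
        expected={"n_mismatch": 0, "n_wobble": 0, "n_bulge": 0},
    )
    return {"asos": asos, "targets": targets, "iss_n1_region": iss}
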