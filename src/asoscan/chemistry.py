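"""Chemistry-specific off-target competence rules for ASO:target duplexes.

Whether an imperfect duplex actually perturbs splicing depends on the ASO's
sugar chemistry: fully MOE-modified ASOs tolerate several mismatch/wobble
pairings with exonic targets, OMe-modified ASOs have poor or no tolerance,
and PMOs behave like OMe in this respect; full complementarity rescues every
chemistry.  The rules below encode those observations as a small threshold
policy over duplex features:

* hard constraints common to all chemistries — a minimum number of canonical
  pairs, a contiguous canonical "seed" (duplexes nucleate from 3-7
  contiguous pairs), and no non-canonical block longer than the zippering
  process can bridge;
* per-chemistry budgets for the number of non-canonical columns compatible
  with a STRONG or WEAK effect, with each non-canonical column charged to
  the sugar modification of the ASO base at that column;
* a requirement for a minimum uninterrupted run of MOE residues (at least
  six) before an imperfect duplex can be called STRONG.

This is a deliberate simplification of position-dependent effects seen with
mixed-chemistry ASOs: a single per-column attribution rule cannot capture
every exon's positional profile, and every threshold is configurable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .duplex import (
    DuplexAlignment,
    DuplexFeatures,
    ScanParams,
    align_duplex,
    feature_summary,
)
from .oligo import AsoDefinition, PairClass, SugarMod

__all__ = [
    "SitePolicy",
    "Grade",
    "CompetenceVerdict",
    "longest_modification_run",
    "hard_constraints",
    "classify_competence",
    "competence_series",
]


class Grade(enum.IntEnum):
    """Ordered off-target competence grades (NONE < WEAK < STRONG)."""

    NONE = 0
    WEAK = 1
    STRONG = 2


def _default_strong() -> dict[SugarMod, int]:
    return {SugarMod.MOE: 5, SugarMod.OME: 0, SugarMod.PMO: 0, SugarMod.DNA: 0}


def _default_weak() -> dict[SugarMod, int]:
    return {SugarMod.MOE: 6, SugarMod.OME: 2, SugarMod.PMO: 2, SugarMod.DNA: 2}


@dataclass(frozen=True)
class SitePolicy:
    """Thresholds governing site competence.

    ``min_canonical`` anchors at the weakest validated off-target duplex (13
    canonical pairs); ``max_noncanonical_strong[MOE]`` = 5 is its complement
    for an 18-mer.  ``min_seed`` sits inside the 3-7 nt seeding range.
    ``min_moe_run``: at least six uninterrupted MOE residues are required
    for a robust off-target effect.
    """

    min_canonical: int = 13
    max_contig_noncanonical: int = 3
    min_seed: int = 5
    max_noncanonical_strong: Mapping[SugarMod, int] = field(default_factory=_default_strong)
    max_noncanonical_weak: Mapping[SugarMod, int] = field(default_factory=_default_weak)
    min_moe_run: int = 6

    def __post_init__(self) -> None:
        if not 3 <= self.min_seed <= 7:
            raise ValueError("min_seed must lie in 3..7")
        for chem in self.max_noncanonical_strong:
            if self.max_noncanonical_weak[chem] < self.max_noncanonical_strong[chem]:
                raise ValueError(f"weak budget below strong budget for {chem}")
        if min(self.min_canonical, self.max_contig_noncanonical, self.min_moe_run) < 0:
            raise ValueError("thresholds must be >= 0")

    @classmethod
    def from_json(cls, path) -> "SitePolicy":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("max_noncanonical_strong", "max_noncanonical_weak"):
            if key in raw:
                raw[key] = {SugarMod(k): int(v) for k, v in raw[key].items()}
        return cls(**raw)

    def to_json(self, path) -> None:
        out = {
            "min_canonical": self.min_canonical,
            "max_contig_noncanonical": self.max_contig_noncanonical,
            "min_seed": self.min_seed,
            "max_noncanonical_strong": {k.value: v for k, v in self.max_noncanonical_strong.items()},
            "max_noncanonical_weak": {k.value: v for k, v in self.max_noncanonical_weak.items()},
            "min_moe_run": self.min_moe_run,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


@dataclass(frozen=True)
class CompetenceVerdict:
    grade: Grade
    reasons: tuple[str, ...]


def longest_modification_run(aso: AsoDefinition, mod: SugarMod) -> int:
    """Length of the longest contiguous block of positions carrying ``mod``."""
    best = cur = 0
    for m in aso.sugar_mods:
        cur = cur + 1 if m is mod else 0
        best = max(best, cur)
    return best


def hard_constraints(features: DuplexFeatures, policy: SitePolicy) -> tuple[bool, list[str]]:
    """Chemistry-independent annealing constraints.

    Pass iff no non-canonical block exceeds the zippering barrier, a seed-
    length canonical run exists, and enough canonical pairs form overall.
    """
    reasons = []
    if features.max_noncanonical_run > policy.max_contig_noncanonical:
        reasons.append("contiguous-noncanonical")
    if features.max_canonical_run < policy.min_seed:
        reasons.append("min-seed")
    if features.n_canonical < policy.min_canonical:
        reasons.append("min-canonical")
    return (not reasons), reasons


def _noncanonical_chemistries(aso: AsoDefinition, alignment: DuplexAlignment) -> list[SugarMod]:
    """Sugar modification charged for each non-canonical column.

    A mismatch or wobble is charged to the ASO base in that column; a bulge
    (either strand) to the nearest ASO base along the column sequence.
    """
    mods: list[SugarMod] = []
    cols = alignment.columns
    for idx, col in enumerate(cols):
        if col.pair is PairClass.CANONICAL:
            continue
        pos = col.aso_pos
        if pos is None:  # target bulge: nearest flanking ASO base
            for other in list(cols[idx + 1 :]) + list(reversed(cols[:idx])):
                if other.aso_pos is not None:
                    pos = other.aso_pos
                    break
        mods.append(aso.sugar_mods[pos - 1])
    return mods


def classify_competence(
    aso: AsoDefinition, alignment: DuplexAlignment, policy: SitePolicy = SitePolicy()
) -> CompetenceVerdict:
    """Grade a candidate site's off-target competence under the ASO chemistry.

    Rule order: a perfect all-canonical duplex is STRONG for every chemistry
    (full complementarity rescues OMe and PMO); otherwise the hard
    constraints gate everything; then STRONG requires all non-canonical
    columns to be MOE-modified within the MOE strong budget and a >= 6 nt
    uninterrupted MOE run on the ASO; otherwise WEAK within the weak budget
    of the dominant chemistry at the non-canonical columns; else NONE.
    """
    if alignment.aso_name != aso.name:
        raise ValueError(
            f"alignment was produced for {alignment.aso_name!r}, not {aso.name!r}"
        )
    feats = alignment.features
    if feats.n_noncanonical == 0:
        return CompetenceVerdict(Grade.STRONG, ("perfect-duplex",))

    ok, failed = hard_constraints(feats, policy)
    if not ok:
        return CompetenceVerdict(Grade.NONE, tuple(failed))

    nc_mods = _noncanonical_chemistries(aso, alignment)
    reasons = ["hard-constraints"]
    if (
        all(m is SugarMod.MOE for m in nc_mods)
        and feats.n_noncanonical <= policy.max_noncanonical_strong[SugarMod.MOE]
        and longest_modification_run(aso, SugarMod.MOE) >= policy.min_moe_run
    ):
        reasons.append("moe-tolerance")
        return CompetenceVerdict(Grade.STRONG, tuple(reasons))

    # dominant chemistry at the non-canonical columns; ties resolve to the
    # least permissive (smallest weak budget) of the tied chemistries
    counts: dict[SugarMod, int] = {}
    for m in nc_mods:
        counts[m] = counts.get(m, 0) + 1
    top = max(counts.values())
    dominant = min(
        (m for m, c in counts.items() if c == top),
        key=lambda m: policy.max_noncanonical_weak[m],
    )
    if feats.n_noncanonical <= policy.max_noncanonical_weak[dominant]:
        reasons.append(f"weak-budget-{dominant.value.lower()}")
        return CompetenceVerdict(Grade.WEAK, tuple(reasons))
    return CompetenceVerdict(Grade.NONE, (f"budget-exhausted-{dominant.value.lower()}",))


def competence_series(
    aso_variants: Sequence[AsoDefinition],
    target_site: str,
    policy: SitePolicy = SitePolicy(),
    params: Optional[ScanParams] = None,
) -> list[dict]:
    """Best alignment features + verdict for each variant on one target site.

    Reproduces truncation / mixed-chemistry panels qualitatively: one row per
    variant, aligned against the same target sequence.
    """
    params = params or ScanParams()
    rows = []
    for aso in aso_variants:
        aln = align_duplex(aso, target_site, params, target_id="site")
        f = aln.features
        verdict = classify_competence(aso, aln, policy)
        rows.append(
            {
                "aso": aso.name,
                "length": len(aso),
                "score": aln.score,
                "n_canonical": f.n_canonical,
                "n_wobble": f.n_wobble,
                "n_mismatch": f.n_mismatch,
                "n_bulge": f.n_bulge,
                "n_noncanonical": f.n_noncanonical,
                "grade": verdict.grade.name,
                "reasons": ";".join(verdict.reasons),
            }
        )
    return rows
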