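"""Synthetic inputs with known ground truth.

Three generators feed the pipeline with data whose truth is known by
construction: target sequences with planted (and controllably degraded)
ASO annealing sites, cassette-exon event tables with planted delta-PSI
effects and binomial replicate noise, and qPCR Ct tables with planted fold
changes.  Every generator takes a mandatory seed and documents its
distributional assumptions; none attempts to model real-data features such
as sequence composition bias, overdispersion beyond the optional
beta-binomial, or correlated replicates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .oligo import AsoDefinition, antisense_of, complement_base, normalize_base

__all__ = [
    "EditKind",
    "Edit",
    "PlantSpec",
    "PlantedSite",
    "plant_target_site",
    "EventSimSpec",
    "simulate_event_table",
    "simulate_qpcr_table",
]

_BASES = np.array(list("ACGT"))


class EditKind(str, enum.Enum):
    MISMATCH = "mismatch"
    WOBBLE_SWAP = "wobble_swap"
    INSERT = "insert"
    DELETE = "delete"


@dataclass(frozen=True)
class Edit:
    """One controlled degradation of a perfect target footprint.

    ``position`` is 1-based within the footprint.  MISMATCH substitutes the
    target base for one that neither pairs canonically nor wobbles with the
    opposing ASO base; WOBBLE_SWAP substitutes so the ASO base pairs as
    G:T/U or T/U:G instead of canonically; INSERT adds a base after the
    position (target bulge); DELETE removes the base (ASO bulge).
    """

    position: int
    kind: EditKind
    base: Optional[str] = None  # for INSERT; random when omitted


@dataclass(frozen=True)
class PlantSpec:
    aso: AsoDefinition
    edits: tuple[Edit, ...] = ()
    flank5: int = 100
    flank3: int = 100
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.aso)
        for e in self.edits:
            if not 1 <= e.position <= n:
                raise ValueError(f"edit position {e.position} outside footprint 1..{n}")
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")


@dataclass(frozen=True)
class PlantedSite:
    """A generated target record plus its ground-truth annotation."""

    target_id: str
    sequence: str
    site_span: tuple[int, int]  # 1-based inclusive
    site_seq: str
    n_mismatch: int
    n_wobble: int
    n_bulge: int


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p)) if n else ""


def apply_edits(footprint: str, aso: AsoDefinition, edits: Sequence[Edit],
                rng: Optional[np.random.Generator] = None) -> str:
    """Apply edits to a perfect footprint; returns the degraded site sequence."""
    rng = rng or np.random.default_rng(0)
    bases = list(footprint)
    m = len(aso)
    inserts: dict[int, str] = {}
    deletes: set[int] = set()
    for e in edits:
        aso_base = aso.base_at(m - e.position + 1)  # antiparallel opposition
        if e.kind is EditKind.MISMATCH:
            forbidden = {bases[e.position - 1], complement_base(aso_base)}
            if aso_base == "G":
                forbidden.add("T")
            if aso_base == "T":
                forbidden.add("G")
            if e.base is not None:
                b = normalize_base(e.base)
                if b in forbidden - {bases[e.position - 1]}:
                    raise ValueError(
                        f"base {e.base!r} at footprint position {e.position} is not a mismatch"
                    )
                bases[e.position - 1] = b
            else:
                choices = [b for b in "ACGT" if b not in forbidden]
                bases[e.position - 1] = str(rng.choice(choices))
        elif e.kind is EditKind.WOBBLE_SWAP:
            if aso_base == "G":
                bases[e.position - 1] = "T"
            elif aso_base == "T":
                bases[e.position - 1] = "G"
            else:
                raise ValueError(
                    f"ASO base {aso_base} at footprint position {e.position} cannot wobble"
                )
        elif e.kind is EditKind.INSERT:
            ins = e.base or str(rng.choice(_BASES))
            if normalize_base(ins) not in "ACGT":
                raise ValueError(f"insert base {e.base!r} outside alphabet")
            inserts[e.position] = ins
        else:
            deletes.add(e.position)
    out = []
    for i, b in enumerate(bases, start=1):
        if i not in deletes:
            out.append(b)
        if i in inserts:
            out.append(inserts[i])
    return "".join(out)


def plant_target_site(spec: PlantSpec, target_id: str = "planted") -> PlantedSite:
    """Embed an edited ASO footprint in random background sequence.

    Background is i.i.d. at the configured GC fraction (no higher-order
    structure).  The truth annotation records the embedded interval and the
    feature counts the edits imply.  The two background bases immediately
    flanking the site are pinned to mismatch the ASO termini (each is set to
    the terminal ASO base itself), so the recorded interval is the unique
    optimal alignment rather than tying with a one-base bulged extension.
    """
    rng = np.random.default_rng(spec.seed)
    site = apply_edits(spec.aso.perfect_target(), spec.aso, spec.edits, rng)
    left = _random_background(rng, spec.flank5, spec.gc)
    right = _random_background(rng, spec.flank3, spec.gc)
    aso_bases = spec.aso.bases
    if left:
        left = left[:-1] + aso_bases[-1]  # 5' neighbour opposes the ASO 3' end
    if right:
        right = aso_bases[0] + right[1:]
    seq = left + site + right
    kinds = [e.kind for e in spec.edits]
    return PlantedSite(
        target_id=target_id,
        sequence=seq,
        site_span=(len(left) + 1, len(left) + len(site)),
        site_seq=site,
        n_mismatch=kinds.count(EditKind.MISMATCH),
        n_wobble=kinds.count(EditKind.WOBBLE_SWAP),
        n_bulge=kinds.count(EditKind.INSERT) + kinds.count(EditKind.DELETE),
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventSimSpec:
    """Design of a synthetic cassette-exon event table.

    Null events share one PSI between groups; true events differ by exactly
    ``delta_psi_true`` (random direction).  Per-sample inclusion counts are
    binomial at ``depth`` total junction reads (optionally beta-binomial
    with intra-class correlation ``rho``); effective lengths are fixed at 1
    (plain-count PSI).  PSI draws: null U(0.15, 0.85); true events' lower
    group U(0.15, 0.45) so that at depth >= 100 both isoforms stay above
    the 10-read support rule.
    """

    n_events: int = 200
    n_true: int = 20
    delta_psi_true: float = 0.4
    depth: int = 100
    samples_per_group: int = 3
    seed: int = 0
    rho: float = 0.0  # beta-binomial overdispersion; 0 = pure binomial
    control_group: str = "control"
    treated_group: str = "treated"

    def __post_init__(self) -> None:
        if self.n_true > self.n_events:
            raise ValueError("n_true must be <= n_events")
        if not 0 < self.delta_psi_true <= 1:
            raise ValueError("delta_psi_true must lie in (0, 1]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")


def _draw_counts(rng: np.random.Generator, psi: float, depth: int, n: int, rho: float) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(depth, psi, size=n)
    nu = (1 - rho) / rho
    ps = rng.beta(psi * nu, (1 - psi) * nu, size=n)
    return rng.binomial(depth, ps)


def simulate_event_table(spec: EventSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format event table plus its truth labels.

    Returns ``(table, truth)``: the table has the standard event columns;
    truth carries event_id, is_true, psi_control, psi_treated.
    """
    rng = np.random.default_rng(spec.seed)
    rows, truth_rows = [], []
    true_ids = set(range(spec.n_true))  # first n_true events carry effects
    for k in range(spec.n_events):
        if k in true_ids:
            lo = rng.uniform(0.15, 0.45)
            hi = min(0.98, lo + spec.delta_psi_true)
            psis = (lo, hi) if rng.random() < 0.5 else (hi, lo)
        else:
            p0 = rng.uniform(0.15, 0.85)
            psis = (p0, p0)
        eid = f"ev{k:04d}"
        for group, psi in zip((spec.control_group, spec.treated_group), psis):
            ijc = _draw_counts(rng, psi, spec.depth, spec.samples_per_group, spec.rho)
            for r, i in enumerate(ijc):
                rows.append(
                    {
                        "event_id": eid,
                        "gene": f"GENE{k:04d}",
                        "group": group,
                        "sample": f"{group}_{r + 1}",
                        "ijc": int(i),
                        "sjc": int(spec.depth - i),
                        "len_inc": 1,
                        "len_skip": 1,
                    }
                )
        truth_rows.append(
            {
                "event_id": eid,
                "is_true": k in true_ids,
                "psi_control": psis[0],
                "psi_treated": psis[1],
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


def simulate_qpcr_table(
    log2_fold_changes: dict[str, float],
    control_condition: str = "control",
    n_replicates: int = 3,
    seed: int = 0,
    noise_sd: float = 0.1,
    base_target_ct: float = 24.0,
    base_normalizer_ct: float = 18.0,
) -> pd.DataFrame:
    """Ct table with planted log2 fold changes relative to a control.

    A condition with planted log2 fold change f has mean dCt shifted by -f
    relative to control (so its recovered RQ is 2^f); Gaussian noise of sd
    ``noise_sd`` cycles is added independently to each Ct measurement.
    """
    rng = np.random.default_rng(seed)
    conditions = {control_condition: 0.0, **log2_fold_changes}
    rows = []
    for cond, f in conditions.items():
        for r in range(n_replicates):
            rows.append(
                {
                    "sample": f"{cond}_{r + 1}",
                    "condition": cond,
                    "target_ct": base_target_ct - f + rng.normal(0, noise_sd),
                    "normalizer_ct": base_normalizer_ct + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
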