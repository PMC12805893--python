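"""File formats, site-context annotation, and the end-to-end pipeline.

Formats: FASTA for targets (wrapped or unwrapped, case-insensitive, U
accepted and normalised), BED for exon annotations (0-based half-open, as
always in BED), TSV for hits/events/qPCR/gel/DE tables, JSON for policy and
machine-readable reports.  All coordinates in reports are 1-based inclusive;
BED I/O stays 0-based half-open.
"""

from __future__ import annotations

import enum
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

import pandas as pd
from Bio import SeqIO

from .chemistry import SitePolicy, classify_competence, competence_series
from .duplex import DuplexAlignment, ScanParams, flatten_diagram, scan_sequence
from .fixtures import fixture_catalogue
from .oligo import AsoDefinition, Backbone, SugarMod
from .quant import EventFilterThresholds, analyze_event_table, filter_events

__all__ = [
    "SiteContext",
    "ExonAnnotation",
    "read_fasta",
    "read_bed",
    "write_bed",
    "read_aso_table",
    "annotate_site_context",
    "hits_to_frame",
    "run_pipeline",
]


class SiteContext(str, enum.Enum):
    EXONIC = "EXONIC"
    INTRONIC = "INTRONIC"
    EXON_BOUNDARY = "EXON_BOUNDARY"


@dataclass(frozen=True)
class ExonAnnotation:
    """Sorted, non-overlapping exon intervals on one target (0-based
    half-open, BED convention)."""

    target_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.target_id}: empty exon interval {(start, end)}")
            if start < prev_end:
                raise ValueError(f"{self.target_id}: exon intervals overlap or are unsorted")
            prev_end = end


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA into (id, sequence) pairs."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_bed(path) -> list[ExonAnnotation]:
    """Read a BED3+ file into per-target exon annotations."""
    per_target: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            strand = parts[5] if len(parts) >= 6 else "+"
            per_target.setdefault(parts[0], []).append((start, end, strand))
    out = []
    for tid, ivals in per_target.items():
        ivals.sort()
        out.append(ExonAnnotation(tid, tuple((s, e) for s, e, _ in ivals), ivals[0][2]))
    return out


def write_bed(annotations: Iterable[ExonAnnotation], path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for start, end in ann.exons:
                fh.write(f"{ann.target_id}\t{start}\t{end}\n")


def read_aso_table(path) -> list[AsoDefinition]:
    """Read ASO definitions from TSV: name, sequence, chemistry, backbone.

    ``chemistry`` is either one tag applied to every position (``MOE``) or a
    comma-separated per-position list; ``MOEx18`` style repeats also parse.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    req = {"name", "sequence", "chemistry", "backbone"}
    if not req <= set(df.columns):
        raise ValueError(f"ASO table must have columns {sorted(req)}")
    out = []
    for _, row in df.iterrows():
        tags = _parse_chemistry(row["chemistry"])
        seq = row["sequence"]
        mods = tuple(tags) if len(tags) > 1 else (tags[0],) * _token_count(seq)
        out.append(AsoDefinition(row["name"], seq, mods, Backbone(row["backbone"])))
    return out


def _token_count(seq: str) -> int:
    from .oligo import tokenize_sequence

    return len(tokenize_sequence(seq))


def _parse_chemistry(spec: str) -> list[SugarMod]:
    tags = []
    for part in str(spec).split(","):
        part = part.strip()
        if "x" in part:
            tag, _, count = part.partition("x")
            tags.extend([SugarMod(tag.strip().upper())] * int(count))
        else:
            tags.append(SugarMod(part.upper()))
    return tags


def annotate_site_context(
    site_span: tuple[int, int], annotation: ExonAnnotation, target_len: Optional[int] = None
) -> SiteContext:
    """Classify a 1-based inclusive site span against exon intervals.

    EXONIC iff the full span lies within one exon; INTRONIC iff fully
    outside all exons; EXON_BOUNDARY otherwise.
    """
    s0, e0 = site_span[0] - 1, site_span[1]  # to 0-based half-open
    if s0 < 0 or (target_len is not None and e0 > target_len):
        raise ValueError(f"site {site_span} outside target bounds")
    for start, end in annotation.exons:
        if start <= s0 and e0 <= end:
            return SiteContext.EXONIC
        if s0 < end and start < e0:
            return SiteContext.EXON_BOUNDARY
    return SiteContext.INTRONIC


def hits_to_frame(
    hits: Sequence[DuplexAlignment],
    aso: AsoDefinition,
    policy: Optional[SitePolicy] = None,
    annotations: Optional[dict[str, ExonAnnotation]] = None,
) -> pd.DataFrame:
    """Tabulate scan hits (one row per site), with verdicts when a policy is
    given and exon context when annotations are given."""
    rows = []
    for h in hits:
        f = h.features
        row = {
            "aso": h.aso_name,
            "target_id": h.target_id,
            "start": h.target_span[0],
            "end": h.target_span[1],
            "strand": h.strand,
            "score": h.score,
            "n_canonical": f.n_canonical,
            "n_wobble": f.n_wobble,
            "n_mismatch": f.n_mismatch,
            "n_bulge": f.n_bulge,
            "max_noncanonical_run": f.max_noncanonical_run,
            "max_canonical_run": f.max_canonical_run,
            "duplex_string": flatten_diagram(h),
        }
        if policy is not None:
            v = classify_competence(aso, h, policy)
            row["grade"] = v.grade.name
            row["reasons"] = ";".join(v.reasons)
        if annotations is not None and h.target_id in annotations:
            row["context"] = annotate_site_context(h.target_span, annotations[h.target_id]).value
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["target_id", "start"], kind="stable").reset_index(drop=True)
    return df


def run_pipeline(config: dict, log: Optional[TextIO] = None) -> dict:
    """Execute scan -> classify -> (optional) splice filter from a config.

    Config keys: ``targets`` (FASTA path) or ``use_fixtures`` (bool);
    ``asos`` (TSV path) or ``fixture_asos`` (list of fixture names);
    optional ``bed`` (exon BED path), ``policy`` (JSON path), ``scan``
    (ScanParams overrides), ``events`` (event TSV path) with
    ``control_group``; ``both_strands``.  Returns a JSON-ready report with
    per-site verdicts, duplex diagrams, and per-stage record counts.
    """
    def say(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    cat = fixture_catalogue() if (config.get("use_fixtures") or config.get("fixture_asos")) else None

    if config.get("targets"):
        targets = read_fasta(config["targets"])
        annotations = {}
    elif cat is not None:
        targets = [(t.target_id, t.sequence) for t in cat["targets"].values()]
        targets.append((cat["iss_n1_region"].target_id, cat["iss_n1_region"].sequence))
        annotations = {
            t.target_id: ExonAnnotation(t.target_id, t.exons)
            for t in cat["targets"].values()
            if t.exons
        }
    else:
        raise ValueError("config must name 'targets' or set 'use_fixtures'")
    if config.get("bed"):
        annotations = {a.target_id: a for a in read_bed(config["bed"])}

    if config.get("asos"):
        asos = read_aso_table(config["asos"])
    elif cat is not None:
        names = config.get("fixture_asos") or list(cat["asos"])
        asos = [cat["asos"][n] for n in names]
    else:
        raise ValueError("config must name 'asos' or set 'use_fixtures'")

    policy = SitePolicy.from_json(config["policy"]) if config.get("policy") else SitePolicy()
    params = ScanParams(**config.get("scan", {}))

    say(f"scanning {len(targets)} target(s) with {len(asos)} ASO(s)")
    all_hits = []
    frames = []
    for aso in asos:
        hits = []
        for tid, seq in targets:
            hits.extend(
                scan_sequence(aso, tid, seq, params, both_strands=bool(config.get("both_strands")))
            )
        frames.append(hits_to_frame(hits, aso, policy, annotations or None))
        all_hits.extend((aso, h) for h in hits)
    hit_table = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["aso", "target_id", "start"], kind="stable")
        .reset_index(drop=True)
        if any(len(f) for f in frames)
        else pd.DataFrame()
    )

    report: dict = {
        "n_targets": len(targets),
        "n_asos": len(asos),
        "n_sites": int(len(hit_table)),
        "sites": hit_table.to_dict(orient="records"),
    }

    if config.get("events"):
        thresholds = EventFilterThresholds(**config.get("event_thresholds", {}))
        table = pd.read_csv(config["events"], sep="\t")
        events = analyze_event_table(table, control_group=config.get("control_group", "control"))
        dropped: list[str] = []
        survivors = filter_events(events, thresholds, log=dropped)
        say(f"splice filter: {len(survivors)}/{len(events)} events survive")
        report["splice_filter"] = {
            "n_events": len(events),
            "n_survivors": len(survivors),
            "n_inclusion": sum(1 for e in survivors if e.delta_psi > 0),
            "n_skipping": sum(1 for e in survivors if e.delta_psi < 0),
            "dropped": dropped,
            "survivors": [
                {
                    "event_id": e.event_id,
                    "gene": e.gene,
                    "delta_psi": e.delta_psi,
                    "p_value": e.p_value,
                    "fdr": e.fdr,
                    "direction": e.direction,
                }
                for e in survivors
            ],
        }

    if not report["n_sites"]:
        say("warning: scan produced no sites")
    return report
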