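"""Downstream splicing and expression quantification.

Covers the quantification stages that sit downstream of a splice-switching
ASO experiment:

* percent-spliced-in (PSI) from inclusion/skipping junction counts with
  effective-length normalisation,
* a pooled-binomial likelihood-ratio test for group PSI differences (an
  explicit stand-in for event-model software such as rMATS, whose internal
  paired likelihood model is out of scope here — the three published
  post-filters are what this module reproduces faithfully),
* Benjamini-Hochberg FDR adjustment,
* the event filter: FDR < 0.05, |dPSI| >= 0.1, and >= 10 average junction
  reads supporting each isoform in at least one sample group,
* gel densitometry percent inclusion, ddCt relative expression, and
  differential-expression table threshold summaries.

Event tables are long-format DataFrames with columns
``event_id, gene, group, sample, ijc, sjc, len_inc, len_skip``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EventFilterThresholds",
    "SpliceEvent",
    "psi_from_junctions",
    "bh_adjust",
    "delta_psi_test",
    "events_from_table",
    "analyze_event_table",
    "filter_events",
    "gel_percent_inclusion",
    "ddct_relative_expression",
    "summarize_de_table",
]

EVENT_COLUMNS = ["event_id", "gene", "group", "sample", "ijc", "sjc", "len_inc", "len_skip"]


@dataclass(frozen=True)
class EventFilterThresholds:
    """Published post-filters for differential splicing events."""

    fdr_max: float = 0.05
    min_avg_junction_reads: float = 10.0
    min_abs_delta_psi: float = 0.1

    def __post_init__(self) -> None:
        if min(self.fdr_max, self.min_avg_junction_reads, self.min_abs_delta_psi) <= 0:
            raise ValueError("all thresholds must be positive")


def psi_from_junctions(ijc: float, sjc: float, len_inc: float = 1.0, len_skip: float = 1.0) -> float:
    """Length-normalised percent spliced in.

    PSI = (ijc/lI) / (ijc/lI + sjc/lS); NaN when no junction reads at all.
    """
    if ijc < 0 or sjc < 0:
        raise ValueError("junction counts must be non-negative")
    if len_inc <= 0 or len_skip <= 0:
        raise ValueError("effective lengths must be positive")
    if ijc + sjc == 0:
        return math.nan
    ni = ijc / len_inc
    ns = sjc / len_skip
    return ni / (ni + ns)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SpliceEvent:
    """One cassette-exon event with per-sample junction counts.

    ``groups``/``ijc``/``sjc`` are parallel per-sample arrays; effective
    lengths are shared across samples.  Derived statistics are filled by
    :func:`analyze_event_table`.
    """

    event_id: str
    gene: str
    groups: tuple[str, ...]
    samples: tuple[str, ...]
    ijc: np.ndarray
    sjc: np.ndarray
    len_inc: float = 1.0
    len_skip: float = 1.0
    psi: np.ndarray = field(default=None, repr=False)
    delta_psi: float = math.nan
    p_value: float = math.nan
    fdr: float = math.nan

    def __post_init__(self) -> None:
        self.ijc = np.asarray(self.ijc, dtype=float)
        self.sjc = np.asarray(self.sjc, dtype=float)
        if np.any(self.ijc < 0) or np.any(self.sjc < 0):
            raise ValueError(f"{self.event_id}: negative junction counts")
        self.psi = np.array(
            [psi_from_junctions(i, s, self.len_inc, self.len_skip) for i, s in zip(self.ijc, self.sjc)]
        )

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups])

    def group_mean_psi(self, group: str) -> float:
        return float(np.mean(self.psi[self.group_mask(group)]))

    def group_isoform_support(self, group: str) -> float:
        """min over isoforms of the group's mean raw junction count."""
        m = self.group_mask(group)
        return float(min(self.ijc[m].mean(), self.sjc[m].mean()))

    def best_group_support(self) -> float:
        """max over groups of the per-group isoform support."""
        return max(self.group_isoform_support(g) for g in self.group_labels())


def _binom_ll(k: float, n: float) -> float:
    """Binomial log-likelihood at the MLE p=k/n (weights may be fractional)."""
    if n == 0:
        return 0.0
    ll = 0.0
    if k > 0:
        ll += k * math.log(k / n)
    if n - k > 0:
        ll += (n - k) * math.log((n - k) / n)
    return ll


def delta_psi_test(event: SpliceEvent) -> float:
    """Two-sided test that pooled length-normalised inclusion proportions
    differ between the two groups.

    Likelihood-ratio test of two binomials versus one, with length-
    normalised counts as (possibly fractional) weights; the statistic is
    referred to chi-square with 1 df.  Returns NaN when a group has no
    junction reads.
    """
    labels = event.group_labels()
    if len(labels) != 2:
        raise ValueError(f"{event.event_id}: need exactly two groups, got {labels}")
    ks, ns = [], []
    for g in labels:
        m = event.group_mask(g)
        if m.sum() < 2:
            raise ValueError(f"{event.event_id}: need >= 2 samples per group")
        ki = event.ijc[m].sum() / event.len_inc
        si = event.sjc[m].sum() / event.len_skip
        if ki + si == 0:
            return math.nan
        ks.append(ki)
        ns.append(ki + si)
    ll_alt = _binom_ll(ks[0], ns[0]) + _binom_ll(ks[1], ns[1])
    ll_null = _binom_ll(ks[0] + ks[1], ns[0] + ns[1])
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    return float(stats.chi2.sf(lr, df=1))


def events_from_table(table: pd.DataFrame) -> list[SpliceEvent]:
    """Build :class:`SpliceEvent` objects from a long-format event table."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    events = []
    for event_id, sub in table.groupby("event_id", sort=False):
        events.append(
            SpliceEvent(
                event_id=str(event_id),
                gene=str(sub["gene"].iloc[0]),
                groups=tuple(sub["group"].astype(str)),
                samples=tuple(sub["sample"].astype(str)),
                ijc=sub["ijc"].to_numpy(),
                sjc=sub["sjc"].to_numpy(),
                len_inc=float(sub["len_inc"].iloc[0]),
                len_skip=float(sub["len_skip"].iloc[0]),
            )
        )
    return events


def analyze_event_table(
    table: pd.DataFrame, control_group: str, treated_group: Optional[str] = None
) -> list[SpliceEvent]:
    """Compute per-event PSI, dPSI (treated - control), p-values and FDR."""
    events = events_from_table(table)
    for ev in events:
        labels = ev.group_labels()
        if control_group not in labels:
            raise ValueError(f"{ev.event_id}: control group {control_group!r} absent")
        treated = treated_group or next(g for g in labels if g != control_group)
        ev.delta_psi = ev.group_mean_psi(treated) - ev.group_mean_psi(control_group)
        ev.p_value = delta_psi_test(ev)
    ps = np.array([ev.p_value for ev in events])
    finite = ~np.isnan(ps)
    fdrs = np.full(ps.shape, math.nan)
    if finite.any():
        fdrs[finite] = bh_adjust(ps[finite])
    for ev, fdr in zip(events, fdrs):
        ev.fdr = float(fdr)
    return events


def filter_events(
    events: Iterable[SpliceEvent],
    thresholds: EventFilterThresholds = EventFilterThresholds(),
    log: Optional[list[str]] = None,
) -> list[SpliceEvent]:
    """Apply the published post-filters to analysed events.

    Keep iff FDR < fdr_max AND |dPSI| >= min_abs_delta_psi AND, for each
    isoform, the mean raw junction count across the samples of a group is
    >= min_avg_junction_reads for both isoforms within at least one group.
    Events with undefined PSI or p-value are dropped with a logged reason.
    Survivors carry ``direction``: "inclusion" (dPSI > 0) or "skipping".
    """
    survivors = []
    for ev in events:
        if np.isnan(ev.psi).any() or math.isnan(ev.p_value) or math.isnan(ev.fdr):
            if log is not None:
                log.append(f"{ev.event_id}: dropped (undefined PSI or p-value)")
            continue
        if math.isnan(ev.delta_psi):
            if log is not None:
                log.append(f"{ev.event_id}: dropped (undefined delta PSI)")
            continue
        if ev.fdr >= thresholds.fdr_max:
            continue
        if abs(ev.delta_psi) < thresholds.min_abs_delta_psi:
            continue
        if ev.best_group_support() < thresholds.min_avg_junction_reads:
            continue
        ev.direction = "inclusion" if ev.delta_psi > 0 else "skipping"
        survivors.append(ev)
    return survivors


def gel_percent_inclusion(band_intensities: dict[str, float]) -> dict[str, float]:
    """Percent of lane signal per isoform band (complements sum to 100)."""
    if any(v < 0 for v in band_intensities.values()):
        raise ValueError("band intensities must be non-negative")
    total = sum(band_intensities.values())
    if total <= 0:
        raise ValueError("cannot quantify a lane with zero total signal")
    return {iso: 100.0 * v / total for iso, v in band_intensities.items()}


def ddct_relative_expression(
    records: pd.DataFrame, control_condition: str, log: Optional[list[str]] = None
) -> pd.DataFrame:
    """ddCt relative quantification against a normalizer assay.

    ``records`` columns: sample, condition, target_ct, normalizer_ct.
    dCt = Ct_target - Ct_normalizer per sample; ddCt = mean dCt(condition) -
    mean dCt(control); RQ = 2^(-ddCt), so the control condition has RQ 1.
    Samples missing either Ct are excluded with a logged reason.
    """
    req = {"sample", "condition", "target_ct", "normalizer_ct"}
    if not req <= set(records.columns):
        raise ValueError(f"qPCR table must have columns {sorted(req)}")
    df = records.copy()
    bad = df["target_ct"].isna() | df["normalizer_ct"].isna()
    if bad.any() and log is not None:
        for s in df.loc[bad, "sample"]:
            log.append(f"{s}: excluded (missing Ct)")
    df = df.loc[~bad]
    if control_condition not in set(df["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent")
    df["dct"] = df["target_ct"] - df["normalizer_ct"]
    grouped = df.groupby("condition", sort=False)["dct"].agg(["mean", "count", "std"])
    ddct = grouped["mean"] - grouped.loc[control_condition, "mean"]
    out = pd.DataFrame(
        {
            "condition": grouped.index,
            "n": grouped["count"].to_numpy(),
            "mean_dct": grouped["mean"].to_numpy(),
            "ddct": ddct.to_numpy(),
            "rq": np.power(2.0, -ddct.to_numpy()),
            "sd_dct": grouped["std"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def summarize_de_table(records: pd.DataFrame) -> dict[str, int]:
    """Threshold summary of a differential-expression table.

    ``records`` columns: gene, log2fc, padj.  significant = padj < 0.05;
    fc_gt2 = significant AND |log2FC| > 1; up/down split significant genes
    by the sign of log2FC.
    """
    if len(records) == 0:
        return {"significant": 0, "fc_gt2": 0, "up": 0, "down": 0}
    req = {"gene", "log2fc", "padj"}
    if not req <= set(records.columns):
        raise ValueError(f"DE table must have columns {sorted(req)}")
    if ((records["padj"] < 0) | (records["padj"] > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    sig = records["padj"] < 0.05
    return {
        "significant": int(sig.sum()),
        "fc_gt2": int((sig & (records["log2fc"].abs() > 1)).sum()),
        "up": int((sig & (records["log2fc"] > 0)).sum()),
        "down": int((sig & (records["log2fc"] < 0)).sum()),
    }
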