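"""Donor-vs-indigenous source classification and transfer detection.

This is the accounting at the heart of the package.  For one donor–recipient
pair, every ASV is first labelled by where it was seen before transplant:

* ``DONOR_ONLY``       — in the pooled donor sample, absent from every
  recipient baseline (pre-antibiotic, D-1) sample;
* ``INDIGENOUS_ONLY``  — the converse;
* ``SHARED``           — in both;
* ``NOVEL``            — in neither (appears only post-transplant, if ever).

An ASV then counts as *transferred* at a post-FMT timepoint when it is
present in at least 50% of the recipient animals at that timepoint (the
fraction is configurable; the whole-animal threshold is the ceiling of
``prevalence * n_recipients``) and its origin label is ``DONOR_ONLY`` or
``SHARED``.  ``INDIGENOUS_ONLY`` ASVs passing the same prevalence rule are
"remaining" indigenous taxa; prevalent ``NOVEL`` ASVs are reported
separately and never enter the three origin classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping

import pandas as pd

from .tables import CountTable, Taxonomy

__all__ = [
    "SourceLabel",
    "PresenceRule",
    "TransferConfig",
    "SourceClassification",
    "TransferSummary",
    "classify_sources",
    "detect_transfers",
    "transfer_rate",
    "family_transfer_rates",
    "venn_decomposition",
    "washout_profile",
]


class SourceLabel(str, Enum):
    DONOR_ONLY = "DONOR_ONLY"
    INDIGENOUS_ONLY = "INDIGENOUS_ONLY"
    SHARED = "SHARED"
    NOVEL = "NOVEL"


@dataclass(frozen=True)
class PresenceRule:
    """An ASV is present in a sample iff its count >= ``min_count``."""

    min_count: int = 1

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True)
class TransferConfig:
    """Prevalence rule for calling a taxon transferred at a timepoint."""

    recipient_prevalence: float = 0.5
    presence: PresenceRule = field(default_factory=PresenceRule)

    def __post_init__(self) -> None:
        if not (0 < self.recipient_prevalence <= 1):
            raise ValueError("recipient_prevalence must be in (0, 1]")


@dataclass(frozen=True)
class SourceClassification:
    """Per-ASV origin labels for one donor–recipient pair."""

    labels: Mapping[str, SourceLabel]

    def asvs(self, label: SourceLabel) -> frozenset[str]:
        return frozenset(a for a, l in self.labels.items() if l is label)

    @property
    def donor_only(self) -> frozenset[str]:
        return self.asvs(SourceLabel.DONOR_ONLY)

    @property
    def indigenous_only(self) -> frozenset[str]:
        return self.asvs(SourceLabel.INDIGENOUS_ONLY)

    @property
    def shared(self) -> frozenset[str]:
        return self.asvs(SourceLabel.SHARED)

    @property
    def novel(self) -> frozenset[str]:
        return self.asvs(SourceLabel.NOVEL)

    @property
    def donor_present(self) -> frozenset[str]:
        """All ASVs seen in the donor sample (donor-only plus shared)."""
        return self.donor_only | self.shared

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TransferSummary:
    """Per-timepoint transferred / remaining ASV sets for one pair.

    ``timepoints`` preserves the analysis order (chronological).  The three
    class sets are pairwise disjoint at every timepoint because the origin
    labels partition the ASV universe.
    """

    timepoints: tuple[str, ...]
    donor_only_transferred: Mapping[str, frozenset[str]]
    indigenous_only_remaining: Mapping[str, frozenset[str]]
    shared_transferred: Mapping[str, frozenset[str]]
    novel_prevalent: Mapping[str, frozenset[str]]
    n_recipients: Mapping[str, int]

    def transferred(self, timepoint: str) -> frozenset[str]:
        """Donor-origin ASVs (donor-only or shared) transferred at a timepoint."""
        if timepoint not in self.timepoints:
            raise KeyError(f"unknown timepoint {timepoint!r}; have {self.timepoints}")
        return self.donor_only_transferred[timepoint] | self.shared_transferred[timepoint]

    def to_frame(self) -> pd.DataFrame:
        """Counts per timepoint in the shape of the study's transfer table."""
        rows = {
            tp: {
                "donor_only_transferred": len(self.donor_only_transferred[tp]),
                "indigenous_only_remaining": len(self.indigenous_only_remaining[tp]),
                "shared_transferred": len(self.shared_transferred[tp]),
            }
            for tp in self.timepoints
        }
        df = pd.DataFrame.from_dict(rows, orient="index").loc[list(self.timepoints)]
        df.index.name = "timepoint"
        return df


def classify_sources(
    donor_sample: CountTable,
    baseline_samples: CountTable,
    presence: PresenceRule = PresenceRule(),
) -> SourceClassification:
    """Label every ASV of the pair's universe by pre-transplant occurrence.

    The universe is the union of the two slices' ASV sets.  Baseline
    ("indigenous") presence is the union over recipient baseline samples:
    one baseline animal carrying the ASV suffices.
    """
    if donor_sample.shape[0] != 1:
        raise ValueError(f"donor slice must hold exactly one sample, got {donor_sample.shape[0]}")
    if baseline_samples.shape[0] < 1:
        raise ValueError("baseline slice must hold at least one recipient sample")
    donor_present = {
        a for a in donor_sample.asv_ids if donor_sample.data.iloc[0][a] >= presence.min_count
    }
    base = baseline_samples.data >= presence.min_count
    baseline_present = set(base.columns[base.any(axis=0)])
    labels: dict[str, SourceLabel] = {}
    for asv in dict.fromkeys(donor_sample.asv_ids + baseline_samples.asv_ids):
        in_donor = asv in donor_present
        in_base = asv in baseline_present
        if in_donor and in_base:
            labels[asv] = SourceLabel.SHARED
        elif in_donor:
            labels[asv] = SourceLabel.DONOR_ONLY
        elif in_base:
            labels[asv] = SourceLabel.INDIGENOUS_ONLY
        else:
            labels[asv] = SourceLabel.NOVEL
    return SourceClassification(labels)


def prevalence_threshold(prevalence: float, n_recipients: int) -> int:
    """Whole-animal threshold for '>= prevalence of the recipients'.

    Ceiling, so that e.g. 50% of 5 rats means 3 rats.
    """
    return max(1, math.ceil(prevalence * n_recipients))


def detect_transfers(
    classification: SourceClassification,
    timepoint_samples: Mapping[str, CountTable],
    cfg: TransferConfig = TransferConfig(),
) -> TransferSummary:
    """Apply the recipient-prevalence rule at every post-FMT timepoint.

    ``timepoint_samples`` maps each timepoint label to the slice of that
    timepoint's recipient samples (one group only).  Iteration order of the
    mapping defines the report order.
    """
    donor_only_t: dict[str, frozenset[str]] = {}
    indig_t: dict[str, frozenset[str]] = {}
    shared_t: dict[str, frozenset[str]] = {}
    novel_t: dict[str, frozenset[str]] = {}
    n_rec: dict[str, int] = {}
    for tp, slice_ in timepoint_samples.items():
        n = slice_.shape[0]
        if n < 1:
            raise ValueError(f"timepoint {tp!r} has no recipient samples")
        need = prevalence_threshold(cfg.recipient_prevalence, n)
        present = slice_.data >= cfg.presence.min_count
        prevalent = set(present.columns[present.sum(axis=0) >= need])
        donor_only_t[tp] = frozenset(prevalent & classification.donor_only)
        indig_t[tp] = frozenset(prevalent & classification.indigenous_only)
        shared_t[tp] = frozenset(prevalent & classification.shared)
        novel_t[tp] = frozenset(prevalent & classification.novel)
        n_rec[tp] = n
    return TransferSummary(
        timepoints=tuple(timepoint_samples),
        donor_only_transferred=donor_only_t,
        indigenous_only_remaining=indig_t,
        shared_transferred=shared_t,
        novel_prevalent=novel_t,
        n_recipients=n_rec,
    )


def transfer_rate(transferred: int, donor_total: int) -> float:
    """Percentage of donor ASVs transferred, to one decimal (half-up).

    ``transfer_rate(132, 415)`` is 31.8 — about a third of the donor
    community establishing in the recipients.
    """
    if donor_total <= 0:
        raise ValueError("donor_total must be positive")
    if not (0 <= transferred <= donor_total):
        raise ValueError("transferred must be between 0 and donor_total")
    pct = Decimal(100 * transferred) / Decimal(donor_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def family_transfer_rates(
    classification: SourceClassification,
    summary: TransferSummary,
    tax: Taxonomy,
    timepoint: str,
) -> pd.DataFrame:
    """Per-family transfer fractions at one timepoint.

    ``donor_total`` counts the donor-present ASVs of the family (donor-only
    plus shared); ``transferred`` those of them in the timepoint's
    transferred set.  Families absent from the donor are excluded.
    """
    transferred_set = summary.transferred(timepoint)
    donor_asvs = sorted(classification.donor_present)
    families = tax.rank_labels(donor_asvs, "family")
    rows = []
    for family, members in families.groupby(families):
        total = len(members)
        moved = sum(1 for a in members.index if a in transferred_set)
        rows.append(
            {
                "family": family,
                "donor_total": total,
                "transferred": moved,
                "fraction": moved / total,
                "percent": transfer_rate(moved, total),
            }
        )
    df = pd.DataFrame(rows).sort_values("family").set_index("family")
    return df


def venn_decomposition(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    set_c: frozenset[str] | set[str],
) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
    }
    assert sum(regions.values()) == len(a | b | c)
    return regions


def washout_profile(
    classification: SourceClassification,
    summary: TransferSummary,
    tax: Taxonomy,
    family: str,
) -> pd.Series:
    """Transferred-ASV count of one family across the timepoints, in order.

    A washout (transient colonisation, e.g. the donor's Enterobacteriaceae
    disappearing after the first days) shows as non-zero early entries
    followed by zeros.
    """
    donor_asvs = sorted(classification.donor_present)
    families = tax.rank_labels(donor_asvs, "family")
    members = set(families.index[families == family])
    if not members:
        raise ValueError(f"family {family!r} has no donor-present ASVs")
    counts = {
        tp: len(summary.transferred(tp) & members) for tp in summary.timepoints
    }
    out = pd.Series(counts, name=family).loc[list(summary.timepoints)]
    out.index.name = "timepoint"
    return out
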