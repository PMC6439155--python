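"""Grading candidate diagnostic markers against germplasm panels.

A marker intended to select for a QTL is only as good as its agreement
with the *known* QTL status of validated donor and recipient lines.  A
marker that calls a known QTL-negative line positive produces false
positives (wasted selection, or worse, a spurious "donor"); one that
calls a known QTL-positive line negative produces false negatives
(real donors discarded, MAS silently failing in their crosses).

This module evaluates per-marker false-positive rate, false-negative
rate and call rate on a :class:`GenotypePanel`, ranks candidate markers
(FPR first — false positives are the costlier error in a breeding
program), predicts per-cross MAS success, and derives per-line QTL
profiles (fingerprints).

Calls are coded ``A`` (the allele designated favourable), ``B``
(alternative), ``H`` (heterozygous) or missing.  Heterozygous calls
default to counting as positive — codominant markers detect the
favourable allele and enrichment strategies keep heterozygotes — and
the policy is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Role",
    "QtlStatus",
    "HetPolicy",
    "GenotypePanel",
    "MarkerAccuracy",
    "CrossPrediction",
    "evaluate_marker",
    "rank_markers",
    "mas_success_matrix",
    "qtl_profile",
]

CALLS = ("A", "B", "H")


class Role(str, Enum):
    DONOR = "donor"
    RECIPIENT = "recipient"
    OTHER = "other"


class QtlStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class HetPolicy(str, Enum):
    HET_AS_POSITIVE = "het_as_positive"
    HET_AS_NEGATIVE = "het_as_negative"


@dataclass(frozen=True)
class GenotypePanel:
    """Lines with known QTL status plus their per-marker calls.

    ``lines``: DataFrame indexed by unique line_id with columns ``role``
    and ``qtl_status``.  ``calls``: DataFrame with the same index, one
    column per marker, values in {"A", "B", "H"} or missing (pd.NA).
    """

    lines: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        lines = self.lines.copy()
        if not lines.index.is_unique:
            dupes = lines.index[lines.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate line ids: {dupes}")
        for col in ("role", "qtl_status"):
            if col not in lines.columns:
                raise ValueError(f"lines table is missing the {col!r} column")
        lines["role"] = lines["role"].map(lambda v: Role(v).value)
        lines["qtl_status"] = lines["qtl_status"].map(lambda v: QtlStatus(v).value)
        calls = self.calls.astype("string")
        if not calls.columns.is_unique:
            dupes = calls.columns[calls.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate marker ids: {dupes}")
        if not calls.index.equals(lines.index):
            raise ValueError("calls matrix index must match the lines table")
        bad = calls.stack().loc[lambda s: ~s.isin(CALLS)]
        if len(bad):
            raise ValueError(
                f"invalid genotype calls (expected A/B/H/NA): {bad.to_dict()}"
            )
        object.__setattr__(self, "lines", lines)
        object.__setattr__(self, "calls", calls)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def line_ids(self) -> list[str]:
        return list(self.lines.index)

    def called_positive(self, marker_id: str, het_policy: HetPolicy) -> pd.Series:
        """Boolean series: does the call designate each line QTL-positive?
        Missing calls are left as pd.NA."""
        calls = self.calls[marker_id]
        het_pos = HetPolicy(het_policy) is HetPolicy.HET_AS_POSITIVE
        return calls.map(
            lambda c: pd.NA if pd.isna(c) else (c == "A" or (c == "H" and het_pos))
        )


@dataclass(frozen=True)
class MarkerAccuracy:
    """FPR/FNR/call-rate summary for one marker on one panel.

    Rates use only lines of known status with non-missing calls; the
    call rate is the non-missing fraction over *all* panel lines.
    """

    marker_id: str
    fpr: float
    fnr: float
    call_rate: float
    n_pos_scored: int
    n_neg_scored: int


def evaluate_marker(
    panel: GenotypePanel,
    marker_id: str,
    het_policy: HetPolicy = HetPolicy.HET_AS_POSITIVE,
) -> MarkerAccuracy:
    """Grade one marker against the known QTL statuses of the panel.

    FPR = fraction of scored status-negative lines the marker calls
    positive; FNR = fraction of scored status-positive lines it calls
    negative.  Lines of unknown status are excluded from both
    denominators; missing calls are excluded and reported through the
    call rate instead.  Raises if either scored class is empty — a rate
    with a zero denominator would be meaningless, not zero.
    """
    if marker_id not in panel.calls.columns:
        raise KeyError(f"marker {marker_id!r} not in panel")
    called_pos = panel.called_positive(marker_id, het_policy)
    scored = called_pos.notna()
    status = panel.lines["qtl_status"]
    pos_scored = scored & (status == QtlStatus.POSITIVE.value)
    neg_scored = scored & (status == QtlStatus.NEGATIVE.value)
    n_pos, n_neg = int(pos_scored.sum()), int(neg_scored.sum())
    if n_pos == 0 or n_neg == 0:
        empty = []
        if n_pos == 0:
            empty.append("QTL-positive")
        if n_neg == 0:
            empty.append("QTL-negative")
        raise ValueError(
            f"marker {marker_id!r}: no scored {' or '.join(empty)} lines; "
            "accuracy rates are undefined"
        )
    fpr = float(called_pos[neg_scored].astype(bool).mean())
    fnr = float((~called_pos[pos_scored].astype(bool)).mean())
    call_rate = float(scored.mean())
    return MarkerAccuracy(marker_id, fpr, fnr, call_rate, n_pos, n_neg)


def rank_markers(
    panel: GenotypePanel,
    het_policy: HetPolicy = HetPolicy.HET_AS_POSITIVE,
) -> list[MarkerAccuracy]:
    """All markers graded and sorted best first.

    Sort key: (FPR, FNR, 1 - call_rate), ties broken by marker id, so
    the ordering is deterministic and false positives — the costlier
    error in a breeding program — dominate.
    """
    accs = [evaluate_marker(panel, m, het_policy) for m in panel.marker_ids]
    return sorted(
        accs, key=lambda a: (a.fpr, a.fnr, 1.0 - a.call_rate, a.marker_id)
    )


@dataclass(frozen=True)
class CrossPrediction:
    """Predicted MAS success per (donor, recipient) cross for one marker."""

    marker_id: str
    matrix: pd.DataFrame  # bool, donors (rows) x recipients (columns)
    n_success: int
    n_crosses: int

    @property
    def success_fraction(self) -> float:
        return self.n_success / self.n_crosses if self.n_crosses else float("nan")


def mas_success_matrix(
    panel: GenotypePanel,
    marker_id: str,
    het_policy: HetPolicy = HetPolicy.HET_AS_POSITIVE,
) -> CrossPrediction:
    """Predict in which donor x recipient crosses MAS would work.

    A cross succeeds iff the marker calls the donor QTL-positive *and*
    the recipient QTL-negative — only then does the marker segregate
    with the introgression.  A missing call on either parent counts as
    failure (no selectable signal).
    """
    roles = panel.lines["role"]
    donors = list(panel.lines.index[roles == Role.DONOR.value])
    recipients = list(panel.lines.index[roles == Role.RECIPIENT.value])
    if not donors or not recipients:
        raise ValueError("panel needs at least one donor and one recipient line")
    called_pos = panel.called_positive(marker_id, het_policy)
    informative_donor = called_pos.loc[donors].fillna(False).astype(bool)
    informative_recip = (~called_pos.loc[recipients].astype("boolean")).fillna(
        False
    ).astype(bool)
    matrix = pd.DataFrame(
        informative_donor.to_numpy()[:, None]
        & informative_recip.to_numpy()[None, :],
        index=pd.Index(donors, name="donor"),
        columns=pd.Index(recipients, name="recipient"),
    )
    return CrossPrediction(
        marker_id, matrix, int(matrix.to_numpy().sum()), matrix.size
    )


def qtl_profile(
    panel: GenotypePanel,
    marker_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-line QTL fingerprint derived from designated markers.

    ``marker_map`` maps marker_id -> QTL name.  Each cell is
    ``positive`` (call A), ``negative`` (B), ``heterozygous`` (H) or
    ``missing``.  Panel markers absent from the map are ignored with a
    warning; when several mapped markers report on the same QTL, the
    first non-missing call in panel column order is used.  All lines are
    profiled, including those of unknown QTL status.
    """
    missing_markers = [m for m in marker_map if m not in panel.calls.columns]
    if missing_markers:
        raise KeyError(f"mapped markers not in panel: {missing_markers}")
    unmapped = [m for m in panel.marker_ids if m not in marker_map]
    if unmapped:
        warnings.warn(
            f"markers without a QTL assignment ignored: {unmapped}", stacklevel=2
        )
    verdict = {"A": "positive", "B": "negative", "H": "heterozygous"}
    qtls: dict[str, list[str]] = {}
    for marker in panel.marker_ids:  # panel order fixes precedence
        if marker in marker_map:
            qtls.setdefault(marker_map[marker], []).append(marker)
    profile = pd.DataFrame(index=panel.lines.index, columns=list(qtls), dtype=object)
    for qtl, markers in qtls.items():
        combined = pd.Series(pd.NA, index=panel.lines.index, dtype="string")
        for marker in markers:
            combined = combined.fillna(panel.calls[marker])
        profile[qtl] = combined.map(
            lambda c: "missing" if pd.isna(c) else verdict[c]
        )
    return profile
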