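"""Panel I/O and the synthetic panel generator.

The canonical panel format is a CSV with header
``line_id,role,qtl_status,<marker_id>,...`` and calls coded ``A``
(favourable-designated allele), ``B`` (alternative), ``H``
(heterozygous) or ``NA`` (missing).  A minimal read-only VCF path is
provided for convenience: genotypes (GT) only, with a sidecar table
designating the favourable allele per site.

The generator builds panels whose *measured* per-marker FPR, FNR and
call rate equal the requested values exactly (miscalled and missing
lines are chosen by seeded shuffle), which makes every grading routine
testable without external data.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .markers import GenotypePanel, QtlStatus, Role

__all__ = [
    "MarkerSpec",
    "generate_panel",
    "write_panel_csv",
    "read_panel_csv",
    "read_favourable_alleles",
    "read_minimal_vcf",
    "PanelFormatError",
]

FIXED_COLUMNS = ("line_id", "role", "qtl_status")
MISSING_CODE = "NA"


class PanelFormatError(ValueError):
    """A panel file does not conform to the documented schema."""


@dataclass(frozen=True)
class MarkerSpec:
    """Requested accuracy for one synthetic marker.

    Rates must be exactly achievable with the panel's line counts:
    ``fnr x (scored positives)``, ``fpr x (scored negatives)`` and the
    per-class missing counts implied by ``call_rate`` must all be whole
    numbers, otherwise the generator refuses and lists what is
    achievable.
    """

    fpr: float = 0.0
    fnr: float = 0.0
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("fpr", self.fpr), ("fnr", self.fnr),
                        ("call_rate", self.call_rate)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _exact_count(rate: float, total: int, what: str, marker: str) -> int:
    k = rate * total
    if abs(k - round(k)) > 1e-9:
        achievable = ", ".join(f"{i}/{total}={i / total:.4g}" for i in range(total + 1))
        raise ValueError(
            f"marker {marker!r}: {what}={rate} is not achievable with "
            f"{total} lines; achievable values: {achievable}"
        )
    return int(round(k))


def generate_panel(
    n_donors: int,
    n_recipients: int,
    markers: "int | Mapping[str, MarkerSpec]",
    seed: int = 0,
) -> GenotypePanel:
    """Build a synthetic panel of donors (QTL-positive) and recipients
    (QTL-negative) with markers of exactly specified accuracy.

    ``markers`` is either a count (that many perfect markers, named
    ``m1``, ``m2``, ...) or a mapping of marker id to
    :class:`MarkerSpec`.  Missing calls are allocated per status class
    so the requested call rate leaves whole-number scored denominators;
    miscalls are then drawn among the scored lines.  Deterministic for a
    fixed seed.
    """
    if n_donors < 1 or n_recipients < 1:
        raise ValueError("need at least one donor and one recipient")
    if isinstance(markers, int):
        markers = {f"m{i + 1}": MarkerSpec() for i in range(markers)}
    width = max(2, len(str(max(n_donors, n_recipients))))
    donor_ids = [f"donor_{i + 1:0{width}d}" for i in range(n_donors)]
    recip_ids = [f"recipient_{i + 1:0{width}d}" for i in range(n_recipients)]
    lines = pd.DataFrame(
        {
            "role": [Role.DONOR.value] * n_donors
            + [Role.RECIPIENT.value] * n_recipients,
            "qtl_status": [QtlStatus.POSITIVE.value] * n_donors
            + [QtlStatus.NEGATIVE.value] * n_recipients,
        },
        index=pd.Index(donor_ids + recip_ids, name="line_id"),
    )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    calls = pd.DataFrame(index=lines.index, columns=list(markers), dtype="string")
    for marker_id, spec in markers.items():
        col = pd.Series(
            ["A"] * n_donors + ["B"] * n_recipients,
            index=lines.index,
            dtype="string",
        )
        for ids in (donor_ids, recip_ids):
            n_miss = _exact_count(
                1.0 - spec.call_rate, len(ids), "1 - call_rate", marker_id
            )
            missing = rng.permutation(ids)[:n_miss]
            col.loc[missing] = pd.NA
        scored_donors = [i for i in donor_ids if not pd.isna(col.loc[i])]
        scored_recips = [i for i in recip_ids if not pd.isna(col.loc[i])]
        n_fn = _exact_count(spec.fnr, len(scored_donors), "fnr", marker_id)
        n_fp = _exact_count(spec.fpr, len(scored_recips), "fpr", marker_id)
        col.loc[rng.permutation(scored_donors)[:n_fn]] = "B"
        col.loc[rng.permutation(scored_recips)[:n_fp]] = "A"
        calls[marker_id] = col
    return GenotypePanel(lines, calls)


def write_panel_csv(panel: GenotypePanel, path_or_buf) -> None:
    """Write the documented CSV schema (LF newlines, NA for missing) to
    a path or an open text buffer."""

    def _write(fh) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(FIXED_COLUMNS) + panel.marker_ids)
        for line_id, meta in panel.lines.iterrows():
            row = [line_id, meta["role"], meta["qtl_status"]]
            for marker in panel.marker_ids:
                call = panel.calls.at[line_id, marker]
                row.append(MISSING_CODE if pd.isna(call) else str(call))
            writer.writerow(row)

    if hasattr(path_or_buf, "write"):
        _write(path_or_buf)
    else:
        with open(path_or_buf, "w", newline="") as fh:
            _write(fh)


def read_panel_csv(path: "str | Path") -> GenotypePanel:
    """Read the documented CSV schema; CRLF input is accepted.

    Malformed headers or rows raise :class:`PanelFormatError` with the
    offending line number.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelFormatError(f"{path}: empty file") from None
        if tuple(header[: len(FIXED_COLUMNS)]) != FIXED_COLUMNS:
            raise PanelFormatError(
                f"{path}, line 1: header must start with "
                f"{','.join(FIXED_COLUMNS)}; got {','.join(header[:3])}"
            )
        marker_ids = header[len(FIXED_COLUMNS):]
        records, call_rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise PanelFormatError(
                    f"{path}, line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            records.append(row[: len(FIXED_COLUMNS)])
            call_rows.append(
                [pd.NA if c == MISSING_CODE or c == "" else c
                 for c in row[len(FIXED_COLUMNS):]]
            )
    lines = pd.DataFrame(
        records, columns=list(FIXED_COLUMNS)
    ).set_index("line_id")
    calls = pd.DataFrame(
        call_rows,
        index=lines.index,
        columns=pd.Index(marker_ids),
        dtype="string",
    )
    try:
        return GenotypePanel(lines, calls)
    except ValueError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


def read_favourable_alleles(path: "str | Path") -> dict[str, str]:
    """Read the sidecar TSV mapping marker id -> favourable allele.

    Two tab-separated columns with header ``marker_id`` and
    ``favourable_allele``; marker ids are VCF ID fields, or
    ``CHROM:POS`` (1-based) for records without an ID.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"marker_id", "favourable_allele"}
    if not expected.issubset(table.columns):
        raise PanelFormatError(
            f"{path}: sidecar needs columns {sorted(expected)}; "
            f"got {list(table.columns)}"
        )
    return dict(zip(table["marker_id"], table["favourable_allele"]))


def read_minimal_vcf(
    vcf_path: "str | Path", favourable: "Mapping[str, str] | str | Path"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read GT fields from a VCF into an A/B/H call matrix.

    ``favourable`` maps each marker (VCF ID, or ``CHROM:POS``) to the
    allele sequence designated favourable at that site.  Sample
    genotypes homozygous for the favourable allele become ``A``,
    homozygous for any other allele ``B``, mixed ``H``; ``./.`` is
    missing.  Markers without a sidecar entry are skipped with a
    warning.  Returns ``(calls, meta)`` where ``meta`` records the
    1-based chrom/pos/alleles per retained marker.  Only GT is
    consumed; all other fields are ignored.
    """
    import pysam  # localized: only needed on the VCF path

    if not isinstance(favourable, Mapping):
        favourable = read_favourable_alleles(favourable)
    calls_cols: dict[str, list] = {}
    meta_rows = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            marker_id = rec.id or f"{rec.chrom}:{rec.pos}"
            fav = favourable.get(marker_id)
            if fav is None:
                warnings.warn(
                    f"marker {marker_id!r} has no favourable-allele entry; skipped",
                    stacklevel=2,
                )
                continue
            if fav not in rec.alleles:
                raise PanelFormatError(
                    f"{vcf_path}: favourable allele {fav!r} for {marker_id!r} "
                    f"is not among the site alleles {rec.alleles}"
                )
            column = []
            for sample in samples:
                alleles = rec.samples[sample].alleles
                if alleles is None or any(a is None for a in alleles):
                    column.append(pd.NA)
                elif all(a == fav for a in alleles):
                    column.append("A")
                elif any(a == fav for a in alleles):
                    column.append("H")
                else:
                    column.append("B")
            calls_cols[marker_id] = column
            meta_rows.append(
                {
                    "marker_id": marker_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,  # 1-based as in the VCF
                    "favourable_allele": fav,
                }
            )
    calls = pd.DataFrame(
        calls_cols, index=pd.Index(samples, name="line_id"), dtype="string"
    )
    meta = pd.DataFrame(
        meta_rows, columns=["marker_id", "chrom", "pos", "favourable_allele"]
    ).set_index("marker_id")
    return calls, meta
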