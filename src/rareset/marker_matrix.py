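"""Data model and I/O for bulk-level binary SSR scoring.

A landrace collection is genotyped as pooled DNA "bulks": each accession
contributes ``B`` bulks (default 3) of several plants, and each bulk is
scored 1/0 for presence/absence of every marker/allele combination — one
column per specific allele at a specific SSR locus, labelled
``"MARKER_allele"`` (e.g. ``"PHI015_80"``). Collapsing the bulks of one
accession by summation yields the accession-level *z*-score in ``0..B``:
the number of bulks in which the combination was detected.

Null alleles are ordinary columns (allele part ``"null"``), never missing
data; a missing bulk is a validation error, not something to impute.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

LABEL_SEP = "_"
BULK_ID_SEP = "·"  # "accession·bulk" ids used at bulk level

_B_COMMENT = re.compile(r"^#\s*bulks_per_accession\s*=\s*(\d+)\s*$")


def make_label(marker: str, allele: str) -> str:
    """Compose the ``MARKER_allele`` column label."""
    return f"{marker}{LABEL_SEP}{allele}"


def split_label(label: str) -> tuple[str, str]:
    """Split a column label into its (marker, allele) parts.

    The allele part is whatever follows the *last* underscore, so marker
    names may themselves contain underscores; allele parts are kept as
    strings so null alleles can be labelled ``"null"``.
    """
    marker, sep, allele = label.rpartition(LABEL_SEP)
    if not sep or not marker or not allele:
        raise ValueError(f"column label {label!r} does not parse as MARKER_allele")
    return marker, allele


@dataclass
class Violation:
    """One validation finding: a machine code, the entity concerned, a message."""

    code: str
    entity: str
    message: str


@dataclass
class BulkMatrix:
    """Binary presence matrix with one row per (accession, bulk).

    ``data`` is indexed by a two-level MultiIndex (accession, bulk) with
    bulk numbers 1..B, and holds one integer 0/1 column per marker/allele
    combination.
    """

    data: pd.DataFrame
    bulks_per_accession: int = 3

    def __post_init__(self) -> None:
        if self.data.index.nlevels != 2:
            raise ValueError("BulkMatrix.data must be indexed by (accession, bulk)")
        self.data.index = self.data.index.set_names(["accession", "bulk"])

    @property
    def accession_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values(0)))

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BulkMatrix):
            return NotImplemented
        return (
            self.bulks_per_accession == other.bulks_per_accession
            and self.data.shape == other.data.shape
            and list(self.data.columns) == list(other.data.columns)
            and list(self.data.index) == list(other.data.index)
            and np.array_equal(self.data.to_numpy(), other.data.to_numpy())
        )


@dataclass
class AccessionMatrix:
    """Accession-level z-score matrix: integer counts in 0..B per column."""

    data: pd.DataFrame
    bulks_per_accession: int = 3

    @property
    def accession_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_accessions(self) -> int:
        return len(self.data.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AccessionMatrix):
            return NotImplemented
        return (
            self.bulks_per_accession == other.bulks_per_accession
            and self.data.shape == other.data.shape
            and list(self.data.columns) == list(other.data.columns)
            and list(self.data.index) == list(other.data.index)
            and np.array_equal(self.data.to_numpy(), other.data.to_numpy())
        )


Matrix = Union[BulkMatrix, AccessionMatrix]


def read_bulk_calls(
    path: str | Path,
    bulks_per_accession: int = 3,
    accessions: Sequence[str] | None = None,
) -> BulkMatrix:
    """Read a long-format allele-call CSV into a :class:`BulkMatrix`.

    The file has header columns ``accession,bulk,marker,allele`` with one
    row per detected allele per bulk; a bulk with no detected alleles is
    simply absent and scores all-zero. Columns of the result are the union
    of observed (marker, allele) pairs sorted by (marker, allele); duplicate
    rows collapse to a single 1.

    Parameters
    ----------
    accessions
        Optional declared accession list; accessions with no calls at all
        are then included as all-zero rows (and flagged by ``validate``).
    """
    B = int(bulks_per_accession)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["accession", "bulk", "marker", "allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"calls file missing required column(s): {missing}")

    records: list[tuple[str, int, str]] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        acc, bulk, marker, allele = (
            row.accession.strip(),
            row.bulk.strip(),
            row.marker.strip(),
            row.allele.strip(),
        )
        if not acc or not marker or not allele:
            raise ValueError(f"malformed row at line {line_no}: empty field")
        try:
            bulk_i = int(bulk)
        except ValueError:
            raise ValueError(
                f"malformed row at line {line_no}: bulk {bulk!r} is not an integer"
            ) from None
        records.append((acc, bulk_i, make_label(marker, allele)))

    seen_accessions = list(dict.fromkeys(r[0] for r in records))
    all_accessions = list(accessions) if accessions is not None else seen_accessions
    unknown = [a for a in seen_accessions if a not in set(all_accessions)]
    if unknown:
        raise ValueError(f"calls reference undeclared accession(s): {unknown}")

    offenders = sorted(
        {(acc, b) for acc, b, _ in records if not 1 <= b <= B},
        key=lambda t: (t[0], t[1]),
    )
    if offenders:
        raise ValueError(
            f"bulk identifiers outside 1..{B} (accession, bulk): {offenders}"
        )

    labels = sorted({lab for _, _, lab in records}, key=split_label)
    index = pd.MultiIndex.from_tuples(
        [(a, b) for a in all_accessions for b in range(1, B + 1)],
        names=["accession", "bulk"],
    )
    data = pd.DataFrame(0, index=index, columns=labels, dtype=np.int64)
    for acc, b, lab in records:
        data.loc[(acc, b), lab] = 1
    return BulkMatrix(data=data, bulks_per_accession=B)


def collapse_bulks(m: BulkMatrix) -> AccessionMatrix:
    """Sum bulk presences per accession into z-scores in ``0..B``."""
    z = m.data.groupby(level="accession", sort=False).sum()
    return AccessionMatrix(data=z, bulks_per_accession=m.bulks_per_accession)


def validate(m: Matrix, allow_empty_accessions: bool = False) -> list[Violation]:
    """Check all structural invariants; return a list of violations (empty if valid)."""
    out: list[Violation] = []
    cols = list(m.data.columns)
    dup = pd.Index(cols)[pd.Index(cols).duplicated()].unique().tolist()
    for c in dup:
        out.append(Violation("duplicate-column", str(c), "column label repeated"))
    for c in cols:
        try:
            split_label(str(c))
        except ValueError:
            out.append(
                Violation("bad-label", str(c), "does not parse as MARKER_allele")
            )

    values = m.data.to_numpy()
    if isinstance(m, BulkMatrix):
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            for r, c in zip(*np.nonzero(bad)):
                out.append(
                    Violation(
                        "non-binary value",
                        f"{m.data.index[r]}/{cols[c]}",
                        f"bulk score {values[r, c]} is not 0 or 1",
                    )
                )
        counts = m.data.groupby(level="accession", sort=False).size()
        B = m.bulks_per_accession
        for acc, n in counts.items():
            if n != B:
                out.append(
                    Violation(
                        "bulk count mismatch", str(acc), f"has {n} bulks, expected {B}"
                    )
                )
            bulks = sorted(m.data.loc[acc].index) if n else []
            if n == B and bulks != list(range(1, B + 1)):
                out.append(
                    Violation(
                        "bulk-ids", str(acc), f"bulk ids {bulks} are not 1..{B}"
                    )
                )
        if not allow_empty_accessions and len(m.data):
            sums = m.data.groupby(level="accession", sort=False).sum().sum(axis=1)
            for acc, s in sums.items():
                if s == 0:
                    out.append(
                        Violation(
                            "empty-accession", str(acc), "no presence in any bulk"
                        )
                    )
    else:
        B = m.bulks_per_accession
        bad = (values < 0) | (values > B) | (values != np.floor(values))
        if bad.any():
            for r, c in zip(*np.nonzero(bad)):
                out.append(
                    Violation(
                        "z-range",
                        f"{m.data.index[r]}/{cols[c]}",
                        f"z={values[r, c]} outside 0..{B}",
                    )
                )
        if not allow_empty_accessions and len(m.data):
            for acc, s in m.data.sum(axis=1).items():
                if s == 0:
                    out.append(
                        Violation("empty-accession", str(acc), "all-zero z profile")
                    )
    return out


def write_matrix(m: Matrix, path: str | Path) -> None:
    """Write a matrix as wide CSV (round-trips bit-exactly with :func:`read_matrix`).

    Bulk matrices get identifier columns ``accession,bulk``; accession
    matrices get ``accession`` plus a leading ``# bulks_per_accession=B``
    comment line carrying B.
    """
    path = Path(path)
    if isinstance(m, BulkMatrix):
        m.data.reset_index().to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# bulks_per_accession={m.bulks_per_accession}\n")
            m.data.reset_index().to_csv(fh, index=False)


def read_matrix(path: str | Path, bulks_per_accession: int | None = None) -> Matrix:
    """Read a wide CSV written by :func:`write_matrix`, detecting the dialect.

    A ``bulk`` identifier column marks a bulk-level matrix; otherwise the
    file is an accession-level z matrix (B taken from the comment header,
    the ``bulks_per_accession`` argument, or the maximum observed z).
    """
    path = Path(path)
    header_B: int | None = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        match = _B_COMMENT.match(first.strip())
        if match:
            header_B = int(match.group(1))
    df = pd.read_csv(path, comment="#")
    if "accession" not in df.columns:
        raise ValueError("matrix file has no 'accession' column")
    df["accession"] = df["accession"].astype(str)
    if "bulk" in df.columns:
        df = df.set_index(["accession", "bulk"])
        B = bulks_per_accession
        if B is None:
            B = int(df.groupby(level="accession", sort=False).size().max())
        return BulkMatrix(data=df.astype(np.int64), bulks_per_accession=B)
    df = df.set_index("accession")
    B = bulks_per_accession or header_B
    if B is None:
        B = max(3, int(df.to_numpy().max(initial=0)))
    return AccessionMatrix(data=df.astype(np.int64), bulks_per_accession=int(B))


METADATA_COLUMNS = ["race1", "race2", "kernel_color", "lat", "lon", "masl"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read accession metadata (race, kernel color, coordinates, altitude).

    Expected columns: ``accession,race1,race2,kernel_color,lat,lon,masl``.
    Returns a DataFrame indexed by accession; range violations raise.
    """
    df = pd.read_csv(path, dtype={"accession": str})
    missing = [c for c in ["accession", *METADATA_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file missing column(s): {missing}")
    df = df.set_index("accession")
    problems = []
    lat, lon, masl = df["lat"], df["lon"], df["masl"]
    problems += list(df.index[(lat.notna()) & ((lat < -90) | (lat > 90))])
    problems += list(df.index[(lon.notna()) & ((lon < -180) | (lon > 180))])
    problems += list(df.index[(masl.notna()) & (masl < 0)])
    if problems:
        raise ValueError(f"metadata out of range for accession(s): {sorted(set(problems))}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().to_csv(path, index=False)
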