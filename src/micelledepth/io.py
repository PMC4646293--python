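"""Readers and writers for the tabular exchange formats the pipeline touches.

Peak tables and shift tables travel as TSV with a fixed header; restraints are
exported either as CYANA-style upper/lower limit files (``.upl``/``.lol``) or
as a single TSV.  All writers are byte-stable: identical input produces
identical files (no timestamps in data lines).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .types import (
    AtomRef,
    DecaySeries,
    DepthRestraint,
    FormatError,
    ParseError,
    RestraintKind,
    ShiftRecord,
)

PEAK_COLUMNS = ["residue", "resname", "atom", "condition", "delay_s", "intensity"]
SHIFT_COLUMNS = ["residue", "resname", "atom", "shift_ppm"]

#: Pseudo-residue used to give the micelle center a concrete atom for
#: structure-calculation restraint formats: atom Q1 of residue CEN, numbered
#: one past the last peptide residue.
CENTER_RESIDUE_NAME = "CEN"
CENTER_ATOM_NAME = "Q1"


def _read_tsv(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() | ~out.map(math.isfinite)
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ParseError(
            f"{path}: non-numeric {column} value {raw[bad.idxmax()]!r} at line {line}"
        )
    return out


def read_peak_table(path: Union[str, Path], dialect: str = "tsv") -> list[DecaySeries]:
    """Read a peak-intensity table into per-(atom, condition) decay series.

    The file must be TSV with header columns ``residue``, ``resname``,
    ``atom``, ``condition``, ``delay_s``, ``intensity``.  Rows are grouped by
    (atom, condition) and sorted by delay; duplicate (atom, condition, delay)
    rows are rejected.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    df = _read_tsv(path, PEAK_COLUMNS)
    if df.empty:
        return []
    df = df.assign(
        residue=_numeric(df, "residue", path).astype(int),
        delay_s=_numeric(df, "delay_s", path),
        intensity=_numeric(df, "intensity", path),
    )

    series: list[DecaySeries] = []
    for (res, resname, atom, cond), grp in df.groupby(
        ["residue", "resname", "atom", "condition"], sort=True
    ):
        ref = AtomRef(int(res), str(resname), str(atom))
        if grp["delay_s"].duplicated().any():
            dup = grp.loc[grp["delay_s"].duplicated(), "delay_s"].iloc[0]
            raise ParseError(
                f"{path}: duplicate delay {dup} s for {ref} condition {cond!r}"
            )
        grp = grp.sort_values("delay_s")
        series.append(
            DecaySeries(
                atom=ref,
                condition_label=str(cond),
                delays=grp["delay_s"].tolist(),
                intensities=grp["intensity"].tolist(),
            )
        )
    return series


def write_peak_table(series: Iterable[DecaySeries], path: Union[str, Path]) -> None:
    """Write decay series back to the TSV dialect ``read_peak_table`` accepts."""
    rows = []
    for s in series:
        for t, v in zip(s.delays, s.intensities):
            rows.append(
                {
                    "residue": s.atom.residue_number,
                    "resname": s.atom.residue_name,
                    "atom": s.atom.atom_name,
                    "condition": s.condition_label,
                    "delay_s": repr(t),
                    "intensity": repr(v),
                }
            )
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_shift_table(path: Union[str, Path]) -> list[ShiftRecord]:
    """Read a chemical-shift TSV (residue, resname, atom, shift_ppm)."""
    path = Path(path)
    df = _read_tsv(path, SHIFT_COLUMNS)
    if df.empty:
        return []
    df = df.assign(
        residue=_numeric(df, "residue", path).astype(int),
        shift_ppm=_numeric(df, "shift_ppm", path),
    )
    return [
        ShiftRecord(AtomRef(int(r.residue), r.resname, r.atom), float(r.shift_ppm))
        for r in df.itertuples()
    ]


def write_shift_table(records: Iterable[ShiftRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "residue": rec.atom.residue_number,
            "resname": rec.atom.residue_name,
            "atom": rec.atom.atom_name,
            "shift_ppm": repr(rec.shift),
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=SHIFT_COLUMNS).to_csv(path, sep="\t", index=False)


def _center_residue_number(restraints: Sequence[DepthRestraint]) -> int:
    if not restraints:
        return 1
    return max(r.atom.residue_number for r in restraints) + 1


def _limit_line(r: DepthRestraint, cen: int, limit: float) -> str:
    return (
        f"{r.atom.residue_number:4d} {r.atom.residue_name:>4s} {r.atom.atom_name:>5s}"
        f" {cen:4d} {CENTER_RESIDUE_NAME:>4s} {CENTER_ATOM_NAME:>5s}"
        f" {limit:8.2f} {r.weight:6.2f}\n"
    )


_HEADER = (
    "# micelle-center distance restraints\n"
    f"# micelle center = atom {CENTER_ATOM_NAME} of pseudo-residue "
    f"{CENTER_RESIDUE_NAME} (number = last peptide residue + 1)\n"
    "# columns: residue resname atom  cen_residue cen_resname cen_atom  limit_A weight\n"
)


def write_center_restraints(
    restraints: Sequence[DepthRestraint],
    path: Union[str, Path],
    format: str = "cyana_upl_lol",
) -> list[Path]:
    """Write center-referenced distance restraints.

    ``cyana_upl_lol`` writes ``<path>.upl`` (upper limits; bounded restraints
    only) and ``<path>.lol`` (lower limits; all restraints).  ``tsv`` writes a
    single file with one row per restraint.  An empty restraint list produces
    files containing only the header comment.  Returns the paths written.
    """
    path = Path(path)
    if format == "tsv":
        rows = [
            {
                "residue": r.atom.residue_number,
                "resname": r.atom.residue_name,
                "atom": r.atom.atom_name,
                "target_distance": repr(r.target_distance),
                "lower": "" if r.lower is None else repr(r.lower),
                "upper": "" if r.upper is None else repr(r.upper),
                "weight": repr(r.weight),
                "kind": r.kind.value,
            }
            for r in restraints
        ]
        cols = ["residue", "resname", "atom", "target_distance", "lower", "upper", "weight", "kind"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        return [path]

    if format != "cyana_upl_lol":
        raise ValueError(f"unsupported restraint format {format!r}")

    cen = _center_residue_number(restraints)
    upl = path.with_suffix(".upl")
    lol = path.with_suffix(".lol")
    with open(upl, "w") as fh:
        fh.write(_HEADER)
        for r in restraints:
            if r.kind is RestraintKind.BOUNDED:
                fh.write(_limit_line(r, cen, r.upper))
    with open(lol, "w") as fh:
        fh.write(_HEADER)
        for r in restraints:
            fh.write(_limit_line(r, cen, r.lower))
    return [upl, lol]
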