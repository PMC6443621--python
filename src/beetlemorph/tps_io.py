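"""Readers and writers for the tpsDig file dialect, taxa tables and trees.

The TPS format stores one block per specimen.  A block starts with
``LM=<n>`` followed by ``n`` coordinate lines, optionally followed by
``CURVES=<c>`` and, for each curve, ``POINTS=<p>`` with ``p`` coordinate
lines.  Trailing ``IMAGE=``, ``ID=`` and ``SCALE=`` records carry
metadata.  Coordinates are written with 17 significant digits so that a
write–read cycle reproduces every IEEE double bit-exactly.

Semilandmark curves are converted to fixed landmarks by concatenating all
curve points, in curve order then point order, onto the landmark list —
the file-level equivalent of deleting the curve/point count lines and
replacing the landmark count with the total point count.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from beetlemorph.errors import (
    EmptyInputError,
    ReconciliationError,
    TpsIntegrityError,
    TpsParseError,
)

__all__ = [
    "SpecimenRecord",
    "TaxaTable",
    "read_tps",
    "write_tps",
    "curves_to_landmarks",
    "read_taxa_table",
    "read_newick",
    "reconcile_tree_and_table",
]


@dataclass
class SpecimenRecord:
    """One digitized specimen: raw landmarks and/or semilandmark curves.

    Coordinates are kept in image units as digitized; ``scale`` (units per
    pixel), when present, is applied only on explicit request, never
    silently.
    """

    specimen_id: str = ""
    image_ref: str | None = None
    scale: float | None = None
    landmarks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    curves: list[np.ndarray] = field(default_factory=list)
    structure_tag: str | None = None  # "pronotum" or "elytron"

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float).reshape(-1, 2)
        self.curves = [np.asarray(c, dtype=float).reshape(-1, 2) for c in self.curves]
        for c in self.curves:
            if len(c) < 2:
                raise TpsIntegrityError("every curve needs at least 2 points")
        if not np.all(np.isfinite(self.landmarks)) or any(
            not np.all(np.isfinite(c)) for c in self.curves
        ):
            raise TpsIntegrityError("non-finite coordinates")
        if self.scale is not None and not self.scale > 0:
            raise TpsIntegrityError(f"SCALE must be positive, got {self.scale}")

    @property
    def n_points(self) -> int:
        return len(self.landmarks) + sum(len(c) for c in self.curves)

    def scaled(self) -> "SpecimenRecord":
        """Return a copy with SCALE applied to all coordinates (explicit opt-in)."""
        s = 1.0 if self.scale is None else self.scale
        return replace(
            self,
            landmarks=self.landmarks * s,
            curves=[c * s for c in self.curves],
            scale=None,
        )


def curves_to_landmarks(record: SpecimenRecord) -> SpecimenRecord:
    """Convert semilandmark curves to fixed landmarks.

    All curve points are appended, in curve order then point order, to the
    landmark list; the curves list becomes empty, so on write the LM= count
    equals the total point count.  A record that is already landmark-only
    is returned unchanged (idempotent).
    """
    if not record.curves:
        if len(record.landmarks) == 0:
            raise EmptyInputError(
                f"record {record.specimen_id!r} has no curves and no landmarks"
            )
        return record
    merged = np.vstack([record.landmarks] + list(record.curves))
    return replace(record, landmarks=merged, curves=[])


def _parse_count(line: str, key: str, lineno: int) -> int:
    body = line.split("=", 1)[1].strip()
    try:
        n = int(body)
    except ValueError:
        raise TpsParseError(f"line {lineno}: cannot parse {key}= count from {line!r}")
    if n < 0:
        raise TpsParseError(f"line {lineno}: negative {key}= count")
    return n


def _parse_coords(lines: list[str], start: int, n: int, path: str) -> tuple[np.ndarray, int]:
    pts = np.empty((n, 2))
    i = start
    for j in range(n):
        if i >= len(lines):
            raise TpsIntegrityError(
                f"{path}: expected {n} coordinate lines, file ended after {j}"
            )
        lineno, raw = lines[i]
        parts = raw.split()
        if len(parts) != 2:
            raise TpsParseError(
                f"line {lineno}: expected 'x y' coordinate pair, got {raw!r}"
            )
        try:
            pts[j, 0] = float(parts[0])
            pts[j, 1] = float(parts[1])
        except ValueError:
            raise TpsParseError(f"line {lineno}: non-numeric coordinate in {raw!r}")
        i += 1
    if not np.all(np.isfinite(pts)):
        raise TpsIntegrityError(f"{path}: non-finite coordinate near line {lines[start][0]}")
    return pts, i


def read_tps(path, structure_tag: str | None = None) -> list[SpecimenRecord]:
    """Parse a tpsDig-dialect file into a list of :class:`SpecimenRecord`.

    Accepts LF or CRLF line endings; blank lines between blocks are
    ignored.  Point counts are checked against the declared LM= and
    POINTS= values and a mismatch raises :class:`TpsIntegrityError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read()
    lines = [
        (i + 1, ln.strip())
        for i, ln in enumerate(raw.splitlines())
        if ln.strip()
    ]
    records: list[SpecimenRecord] = []
    i = 0
    while i < len(lines):
        lineno, ln = lines[i]
        if not ln.upper().startswith("LM="):
            raise TpsParseError(f"line {lineno}: expected LM= to start a specimen block, got {ln!r}")
        n_lm = _parse_count(ln, "LM", lineno)
        landmarks, i = _parse_coords(lines, i + 1, n_lm, str(path))
        curves: list[np.ndarray] = []
        image_ref = None
        spec_id = ""
        scale = None
        while i < len(lines):
            lineno, ln = lines[i]
            up = ln.upper()
            if up.startswith("LM="):
                break
            if up.startswith("CURVES="):
                n_curves = _parse_count(ln, "CURVES", lineno)
                i += 1
                for _ in range(n_curves):
                    if i >= len(lines) or not lines[i][1].upper().startswith("POINTS="):
                        raise TpsIntegrityError(
                            f"{path}: CURVES={n_curves} declared but POINTS= block missing"
                            f" near line {lineno}"
                        )
                    p_lineno, p_ln = lines[i]
                    n_pts = _parse_count(p_ln, "POINTS", p_lineno)
                    pts, i = _parse_coords(lines, i + 1, n_pts, str(path))
                    curves.append(pts)
            elif up.startswith("IMAGE="):
                image_ref = ln.split("=", 1)[1].strip()
                i += 1
            elif up.startswith("ID="):
                spec_id = ln.split("=", 1)[1].strip()
                i += 1
            elif up.startswith("SCALE="):
                body = ln.split("=", 1)[1].strip()
                try:
                    scale = float(body)
                except ValueError:
                    raise TpsParseError(f"line {lineno}: non-numeric SCALE {body!r}")
                i += 1
            else:
                raise TpsParseError(f"line {lineno}: unrecognized record {ln!r}")
        records.append(
            SpecimenRecord(
                specimen_id=spec_id,
                image_ref=image_ref,
                scale=scale,
                landmarks=landmarks,
                curves=curves,
                structure_tag=structure_tag,
            )
        )
    return records


def _fmt(x: float) -> str:
    # 17 significant digits round-trips any IEEE-754 double exactly
    return f"{x:.17g}"


def write_tps(records: list[SpecimenRecord], path) -> None:
    """Write records in the tpsDig dialect (LF endings, full precision)."""
    buf = io.StringIO()
    for rec in records:
        buf.write(f"LM={len(rec.landmarks)}\n")
        for x, y in rec.landmarks:
            buf.write(f"{_fmt(x)} {_fmt(y)}\n")
        if rec.curves:
            buf.write(f"CURVES={len(rec.curves)}\n")
            for c in rec.curves:
                buf.write(f"POINTS={len(c)}\n")
                for x, y in c:
                    buf.write(f"{_fmt(x)} {_fmt(y)}\n")
        if rec.image_ref is not None:
            buf.write(f"IMAGE={rec.image_ref}\n")
        if rec.specimen_id != "":
            buf.write(f"ID={rec.specimen_id}\n")
        if rec.scale is not None:
            buf.write(f"SCALE={_fmt(rec.scale)}\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


class TaxaTable:
    """Species-to-group mapping with derived richness counts.

    Wraps a DataFrame with columns ``species_id, genus, tribe, subfamily,
    family, ingroup`` and exposes per-genus / per-subfamily species
    tallies.  Counts are invariant to row order.
    """

    REQUIRED = ["species_id", "genus", "tribe", "subfamily", "family", "ingroup"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ReconciliationError(f"taxa table missing columns: {missing}")
        if df["species_id"].duplicated().any():
            dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
            raise ReconciliationError(f"duplicate species_id values: {dups[:5]}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def counts(self, level: str) -> dict[str, int]:
        """Species tally per group at ``level`` (genus/tribe/subfamily/family)."""
        if level not in self.REQUIRED[1:5]:
            raise ReconciliationError(f"unknown grouping level {level!r}")
        return self.df.groupby(level, sort=True)["species_id"].count().to_dict()

    def group_of(self, level: str) -> dict[str, str]:
        """Map species_id -> group label at ``level``."""
        return dict(zip(self.df["species_id"], self.df[level]))

    @property
    def ingroup_species(self) -> list[str]:
        mask = self.df["ingroup"].astype(bool)
        return self.df.loc[mask, "species_id"].tolist()


def read_taxa_table(path) -> TaxaTable:
    """Read the CSV taxa table (header row required)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return TaxaTable(df)


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree with uniquely labeled tips."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dups = []
        for l in labels:
            if l in seen:
                dups.append(l)
            seen.add(l)
        raise ReconciliationError(f"duplicate tip labels: {sorted(set(dups))}")
    return tree


def reconcile_tree_and_table(tree: dendropy.Tree, table: TaxaTable, level: str) -> dict[str, int]:
    """Check every tip label names a group at ``level``; return group counts.

    Raises :class:`ReconciliationError` listing every offending tip.
    """
    counts = table.counts(level)
    # outgroup tips may be labeled at family level even when level is finer
    known = set(counts) | set(table.df["family"]) | set(table.df["species_id"])
    offenders = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label not in known
    ]
    if offenders:
        raise ReconciliationError(
            f"tree tips not present in taxa table at level {level!r}: {offenders}"
        )
    return counts
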