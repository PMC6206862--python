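"""Readers and writers for every on-disk artifact.

All files are UTF-8, tab-separated text; lines starting with ``#`` are
comments. Band-presence matrices exist in two dialects differing only in
their missing-value token: the STRUCTURE dialect writes ``-9``, the TASSEL
dialect writes ``?``. Internally missing is always ``NaN``.

Multi-band SSRs are stored band-per-column with a marker-id prefix
(``NAU2631-1``, ``NAU2631-2``, ...), mirroring how dominant PAGE fragments
are named in the field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .traits import TRAITS

MISSING_TOKEN: dict[str, str] = {"structure": "-9", "tassel": "?"}

MAX_CHROMOSOME = 26


def _check_dialect(dialect: str) -> str:
    if dialect not in MISSING_TOKEN:
        raise SchemaError(f"unknown band-matrix dialect {dialect!r}; use 'structure' or 'tassel'")
    return dialect


# ---------------------------------------------------------------------------
# Marker map


class MarkerMap:
    """SSR marker map: name, chromosome (1-26), bp position, ordered band ids.

    Parameters
    ----------
    table
        DataFrame with columns ``marker``, ``chrom``, ``pos_bp``, ``bands``
        where ``bands`` is a sequence of band-column ids.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chrom", "pos_bp", "bands"}
        missing = required - set(table.columns)
        if missing:
            raise SchemaError(f"marker map: missing column(s) {sorted(missing)}")
        tab = table.copy()
        tab["bands"] = tab["bands"].apply(tuple)
        if tab["marker"].duplicated().any():
            dup = tab.loc[tab["marker"].duplicated(), "marker"].iloc[0]
            raise SchemaError(f"marker map: duplicate marker name {dup!r}")
        chrom = tab["chrom"].astype(int)
        if ((chrom < 1) | (chrom > MAX_CHROMOSOME)).any():
            bad = tab.loc[(chrom < 1) | (chrom > MAX_CHROMOSOME), "marker"].iloc[0]
            raise SchemaError(f"marker map: chromosome out of [1,{MAX_CHROMOSOME}] for {bad!r}")
        if (tab["pos_bp"].astype(float) < 0).any():
            raise SchemaError("marker map: negative position")
        all_bands = [b for bs in tab["bands"] for b in bs]
        if len(all_bands) != len(set(all_bands)):
            seen, dup = set(), None
            for b in all_bands:
                if b in seen:
                    dup = b
                    break
                seen.add(b)
            raise SchemaError(f"marker map: band id {dup!r} not globally unique")
        tab["chrom"] = chrom
        tab["pos_bp"] = tab["pos_bp"].astype(int)
        self.table = tab.set_index("marker", drop=False)
        self.band_to_marker: dict[str, str] = {
            b: m for m, bs in zip(tab["marker"], tab["bands"]) for b in bs
        }

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    @property
    def band_order(self) -> list[str]:
        return [b for bs in self.table["bands"] for b in bs]

    def chrom_of(self, marker: str) -> int:
        return int(self.table.at[marker, "chrom"])

    def pos_of(self, marker: str) -> int:
        return int(self.table.at[marker, "pos_bp"])

    def distance_bp(self, m1: str, m2: str) -> float:
        """Physical distance in bp, NaN for inter-chromosomal pairs."""
        if self.chrom_of(m1) != self.chrom_of(m2):
            return float("nan")
        return float(abs(self.pos_of(m1) - self.pos_of(m2)))

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.table.equals(other.table)


# ---------------------------------------------------------------------------
# Band matrix


class BandMatrix:
    """Individuals x band-presence matrix; entries 1.0 / 0.0 / NaN."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise SchemaError(f"band matrix: duplicate individual id {dup!r}")
        arr = data.astype(float)
        vals = arr.to_numpy()
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"band matrix: entry {vals[i, j]!r} at individual {data.index[i]!r}, "
                f"band {data.columns[j]!r} is not 0/1/missing"
            )
        self.data = arr

    @property
    def individuals(self) -> list[str]:
        return list(self.data.index)

    @property
    def bands(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, individuals: Sequence[str]) -> "BandMatrix":
        missing = [i for i in individuals if i not in self.data.index]
        if missing:
            raise SchemaError(f"band matrix: unknown individual(s) {missing[:5]}")
        return BandMatrix(self.data.loc[list(individuals)])

    def validate_against(self, marker_map: MarkerMap) -> None:
        unknown = [c for c in self.data.columns if c not in marker_map.band_to_marker]
        if unknown:
            raise SchemaError(f"band matrix: column(s) not in marker map: {unknown[:5]}")

    def concat(self, other: "BandMatrix") -> "BandMatrix":
        if list(other.data.columns) != list(self.data.columns):
            raise SchemaError("band matrix concat: band columns differ")
        return BandMatrix(pd.concat([self.data, other.data]))

    def equals(self, other: "BandMatrix") -> bool:
        a, b = self.data, other.data
        if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
            return False
        return np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# L x T design


@dataclasses.dataclass
class LxTDesign:
    """Line × Tester mating design: which F1 came from which (line, tester).

    ``checks`` maps check labels (``K3``, ``K4``) to individual ids of the
    commercial check cultivars grown alongside the trial.
    """

    lines: list[str]
    testers: list[str]
    crosses: pd.DataFrame  # columns: line, tester, f1
    checks: dict[str, str]

    def __post_init__(self):
        need = {"line", "tester", "f1"}
        if need - set(self.crosses.columns):
            raise SchemaError("design: crosses table needs columns line, tester, f1")
        if self.crosses["f1"].duplicated().any():
            raise SchemaError("design: duplicate F1 id in cross map")
        if self.crosses.duplicated(subset=["line", "tester"]).any():
            raise SchemaError("design: duplicate (line, tester) pair")
        parents = set(self.lines) | set(self.testers)
        overlap = parents & set(self.crosses["f1"])
        if overlap:
            raise SchemaError(f"design: F1 ids overlap parent ids: {sorted(overlap)[:5]}")
        self._f1_of = {
            (r.line, r.tester): r.f1 for r in self.crosses.itertuples(index=False)
        }
        self._parents_of = {
            r.f1: (r.line, r.tester) for r in self.crosses.itertuples(index=False)
        }

    def f1_of(self, line: str, tester: str) -> str:
        return self._f1_of[(line, tester)]

    def parents_of(self, f1: str) -> tuple[str, str]:
        return self._parents_of[f1]

    def f1s_of_tester(self, tester: str) -> list[str]:
        sub = self.crosses[self.crosses["tester"] == tester]
        return list(sub["f1"])

    @property
    def f1s(self) -> list[str]:
        return list(self.crosses["f1"])


# ---------------------------------------------------------------------------
# Phenotype table

PHENO_COLUMNS = ("individual", "trait", "location", "year", "replicate", "value")


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(PHENO_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"phenotype table: missing column(s) {sorted(missing)}")
    tab = table.loc[:, list(PHENO_COLUMNS)].copy()
    bad_traits = set(tab["trait"]) - set(TRAITS)
    if bad_traits:
        raise SchemaError(f"phenotype table: unknown trait code(s) {sorted(bad_traits)}")
    vals = pd.to_numeric(tab["value"], errors="coerce")
    if vals.isna().any() or not np.isfinite(vals).all():
        row = tab.index[~np.isfinite(vals.fillna(np.inf))][0]
        raise ParseError(f"phenotype table: non-numeric or non-finite value at row {row}")
    tab["value"] = vals.astype(float)
    key = ["individual", "trait", "location", "year", "replicate"]
    if tab.duplicated(subset=key).any():
        dup = tab.loc[tab.duplicated(subset=key), key].iloc[0].tolist()
        raise SchemaError(f"phenotype table: duplicate record key {dup}")
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# File I/O


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc


def read_band_matrix(path, dialect: str) -> BandMatrix:
    """Read a band matrix; ``dialect`` fixes the missing token (-9 or ?)."""
    _check_dialect(dialect)
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: band matrix needs an id column plus band columns")
    raw = raw.set_index(raw.columns[0])
    tok = MISSING_TOKEN[dialect]
    mapping = {"0": 0.0, "1": 1.0, tok: np.nan}
    out = np.empty(raw.shape, dtype=float)
    vals = raw.to_numpy()
    for (i, j), v in np.ndenumerate(vals):
        v = str(v).strip()
        if v not in mapping:
            raise ParseError(
                f"{path}: unknown token {v!r} at individual {raw.index[i]!r}, "
                f"band {raw.columns[j]!r} (dialect {dialect!r})"
            )
        out[i, j] = mapping[v]
    return BandMatrix(pd.DataFrame(out, index=raw.index.astype(str), columns=raw.columns))


def write_band_matrix(matrix: BandMatrix, path, dialect: str,
                      marker_map: MarkerMap | None = None) -> None:
    """Write a band matrix with bit-exact dialect tokens.

    If a marker map is given, columns are emitted in map order.
    """
    _check_dialect(dialect)
    tok = MISSING_TOKEN[dialect]
    data = matrix.data
    if marker_map is not None:
        order = [b for b in marker_map.band_order if b in data.columns]
        data = data.loc[:, order]
    txt = data.copy().astype(object)
    arr = data.to_numpy()
    txt[:] = np.where(np.isnan(arr), tok, np.where(arr == 1.0, "1", "0"))
    txt.index.name = "individual"
    txt.to_csv(path, sep="\t")


def convert_band_matrix(src, dst, from_dialect: str, to_dialect: str) -> None:
    """Dialect conversion: changes only the missing token."""
    write_band_matrix(read_band_matrix(src, from_dialect), dst, to_dialect)


def read_marker_map(path) -> MarkerMap:
    raw = _read_tsv(path)
    need = {"marker", "chrom", "pos_bp", "bands"}
    if need - set(raw.columns):
        raise SchemaError(f"{path}: marker map needs columns {sorted(need)}")
    raw = raw.copy()
    raw["bands"] = raw["bands"].apply(lambda s: tuple(str(s).split(",")))
    try:
        raw["chrom"] = raw["chrom"].astype(int)
        raw["pos_bp"] = raw["pos_bp"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer chrom/pos_bp ({exc})") from exc
    return MarkerMap(raw)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    tab = marker_map.table.reset_index(drop=True).copy()
    tab["bands"] = tab["bands"].apply(",".join)
    tab.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    raw = _read_tsv(path)
    return validate_phenotypes(raw)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    validate_phenotypes(table).to_csv(path, sep="\t", index=False)


def read_design(path) -> LxTDesign:
    """Read a design table: rows of kind ``cross`` (line, tester, f1) and
    kind ``check`` (check label in the ``line`` column, id in ``f1``)."""
    raw = _read_tsv(path)
    need = {"kind", "line", "tester", "f1"}
    if need - set(raw.columns):
        raise SchemaError(f"{path}: design table needs columns {sorted(need)}")
    crosses = raw[raw["kind"] == "cross"][["line", "tester", "f1"]].reset_index(drop=True)
    checks = {r.line: r.f1 for r in raw[raw["kind"] == "check"].itertuples(index=False)}
    unknown = set(raw["kind"]) - {"cross", "check"}
    if unknown:
        raise SchemaError(f"{path}: unknown design row kind(s) {sorted(unknown)}")
    lines = list(dict.fromkeys(crosses["line"]))
    testers = list(dict.fromkeys(crosses["tester"]))
    return LxTDesign(lines=lines, testers=testers, crosses=crosses, checks=checks)


def write_design(design: LxTDesign, path) -> None:
    rows = [("cross", r.line, r.tester, r.f1) for r in design.crosses.itertuples(index=False)]
    rows += [("check", label, "", ind) for label, ind in design.checks.items()]
    pd.DataFrame(rows, columns=["kind", "line", "tester", "f1"]).to_csv(
        path, sep="\t", index=False
    )
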