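"""Family-file ingestion, count tabulation and Table-style reporting.

The family file is tab-delimited with a header line ``family_id  father
mother  child``.  Genotypes are written ``AA``, ``Aa``/``aA``, ``aa`` (``A``
is the risk allele) or as risk-allele dosages ``2``, ``1``, ``0``; a missing
parent is ``NA``, ``.`` or an empty field.  The child genotype is never
missing — families enter the study because the child is affected and
genotyped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import json

import pandas as pd

from .assoc import lrt, tdt, zcom
from .counts import DyadCounts, FamilyDataset, MonadCounts, TriadCounts
from .estimate import RiskModel

__all__ = [
    "FamilyRecord",
    "TabulationReport",
    "FamilyFileError",
    "read_families",
    "tabulate",
    "expand_records",
    "read_counts",
    "analyze",
]

_GENO_CODES = {"AA": 2, "Aa": 1, "aA": 1, "aa": 0, "2": 2, "1": 1, "0": 0}
_MISSING = {"", "NA", "na", "Na", "nA", ".", "NaN", "nan"}
_DOSAGE_TO_STR = {2: "AA", 1: "Aa", 0: "aa", None: "NA"}


class FamilyFileError(ValueError):
    """Malformed family file; the message lists offending line numbers."""


@dataclass(frozen=True)
class FamilyRecord:
    """One ascertained family: genotypes as risk-allele dosages (None = missing)."""

    family_id: str
    father: "int | None"
    mother: "int | None"
    child: "int | None"

    @property
    def kind(self) -> str:
        n_parents = (self.father is not None) + (self.mother is not None)
        return {2: "triad", 1: "dyad", 0: "monad"}[n_parents]


@dataclass(frozen=True)
class TabulationReport:
    """Tabulated counts plus an exact accounting of excluded records."""

    counts: FamilyDataset
    n_excluded_mendelian: int
    n_excluded_uninformative: int
    exclusions: list = field(default_factory=list)  # (family_id, reason)

    @property
    def n_included(self) -> int:
        return self.counts.n_families


def _parse_genotype(token: str):
    token = token.strip()
    if token in _MISSING:
        return None, True
    if token in _GENO_CODES:
        return _GENO_CODES[token], True
    return None, False


def read_families(path) -> list:
    """Parse a tab-delimited family file into :class:`FamilyRecord` s.

    Raises :class:`FamilyFileError` listing every malformed line (bad
    genotype token, wrong column count, or missing child genotype).
    """
    path = Path(path)
    records: list[FamilyRecord] = []
    problems: list[str] = []
    with path.open() as handle:
        header = handle.readline()
        if not header.strip():
            raise FamilyFileError(f"{path}: empty file")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                problems.append(f"line {lineno}: expected 4 tab-separated fields, got {len(parts)}")
                continue
            fam, *geno_tokens = parts
            genos = []
            ok = True
            for col, token in zip(("father", "mother", "child"), geno_tokens):
                value, parsed = _parse_genotype(token)
                if not parsed:
                    problems.append(f"line {lineno}: unrecognised {col} genotype {token!r}")
                    ok = False
                genos.append(value)
            if ok and genos[2] is None:
                problems.append(f"line {lineno}: child genotype is missing (family {fam!r})")
                ok = False
            if ok:
                records.append(FamilyRecord(fam, father=genos[0], mother=genos[1], child=genos[2]))
    if problems:
        raise FamilyFileError(f"{path}: " + "; ".join(problems))
    return records


# (sorted parental dosage pair, child dosage) -> triad cell index 0..9
_TRIAD_CELL = {
    ((2, 2), 2): 0,
    ((1, 2), 2): 1,
    ((1, 2), 1): 2,
    ((0, 2), 1): 3,
    ((1, 1), 2): 4,
    ((1, 1), 1): 5,
    ((1, 1), 0): 6,
    ((0, 1), 1): 7,
    ((0, 1), 0): 8,
    ((0, 0), 0): 9,
}

# (observed parent dosage, child dosage) -> dyad cell index 0..6
_DYAD_CELL = {
    (2, 2): 0,
    (2, 1): 1,
    (1, 2): 2,
    (1, 1): 3,
    (1, 0): 4,
    (0, 1): 5,
    (0, 0): 6,
}


def tabulate(records: Iterable[FamilyRecord]) -> TabulationReport:
    """Map family records onto the fixed triad/dyad/monad cells.

    Mating types are unordered (swapping the parent columns of a triad never
    changes its cell) and the dyad cell ignores which parent was genotyped.
    Mendelian-inconsistent families — a child genotype impossible given the
    observed parent(s) — are excluded and counted, not raised.
    """
    triads = [0] * 10
    dyads = [0] * 7
    monads = [0, 0, 0]  # s2, s1, s0
    exclusions = []
    n_mendel = 0
    n_uninf = 0
    for rec in records:
        if rec.child is None:
            n_uninf += 1
            exclusions.append((rec.family_id, "child genotype missing"))
            continue
        if rec.kind == "triad":
            key = (tuple(sorted((rec.father, rec.mother))), rec.child)
            cell = _TRIAD_CELL.get(key)
            if cell is None:
                n_mendel += 1
                exclusions.append((rec.family_id, "Mendelian-inconsistent triad"))
            else:
                triads[cell] += 1
        elif rec.kind == "dyad":
            parent = rec.father if rec.father is not None else rec.mother
            cell = _DYAD_CELL.get((parent, rec.child))
            if cell is None:
                n_mendel += 1
                exclusions.append((rec.family_id, "Mendelian-inconsistent dyad"))
            else:
                dyads[cell] += 1
        else:
            monads[2 - rec.child] += 1
    return TabulationReport(
        counts=FamilyDataset(
            triads=TriadCounts(triads),
            dyads=DyadCounts(dyads),
            monads=MonadCounts(*monads),
        ),
        n_excluded_mendelian=n_mendel,
        n_excluded_uninformative=n_uninf,
        exclusions=exclusions,
    )


_TRIAD_GENOS = [  # (father, mother, child) dosage per cell
    (2, 2, 2), (2, 1, 2), (2, 1, 1), (2, 0, 1), (1, 1, 2),
    (1, 1, 1), (1, 1, 0), (1, 0, 1), (1, 0, 0), (0, 0, 0),
]
_DYAD_GENOS = [(2, 2), (2, 1), (1, 2), (1, 1), (1, 0), (0, 1), (0, 0)]


def expand_records(data: FamilyDataset, prefix: str = "F") -> list:
    """Synthesise one FamilyRecord per counted family (inverse of tabulate).

    Dyads are emitted with the mother genotyped; the likelihood is
    parent-sex-agnostic so the choice is arbitrary.
    """
    out = []
    idx = 0
    for cell, (f, m, c) in enumerate(_TRIAD_GENOS):
        for _ in range(int(data.triads.cells[cell])):
            idx += 1
            out.append(FamilyRecord(f"{prefix}{idx}", father=f, mother=m, child=c))
    for cell, (g, c) in enumerate(_DYAD_GENOS):
        for _ in range(int(data.dyads.cells[cell])):
            idx += 1
            out.append(FamilyRecord(f"{prefix}{idx}", father=None, mother=g, child=c))
    for dosage, count in ((2, data.monads.s2), (1, data.monads.s1), (0, data.monads.s0)):
        for _ in range(int(count)):
            idx += 1
            out.append(FamilyRecord(f"{prefix}{idx}", father=None, mother=None, child=dosage))
    return out


def write_families(records: Sequence[FamilyRecord], path) -> None:
    """Write records in the family-file format (genotype strings, NA for missing)."""
    with Path(path).open("w") as handle:
        handle.write("family_id\tfather\tmother\tchild\n")
        for rec in records:
            handle.write(
                f"{rec.family_id}\t{_DOSAGE_TO_STR[rec.father]}"
                f"\t{_DOSAGE_TO_STR[rec.mother]}\t{_DOSAGE_TO_STR[rec.child]}\n"
            )


_COUNT_KEYS = [f"n{i}" for i in range(1, 11)] + [f"m{i}" for i in range(1, 8)] + ["s2", "s1", "s0"]


def read_counts(path) -> FamilyDataset:
    """Read a pre-tabulated counts file (JSON object or two-column TSV).

    Keys are ``n1..n10``, ``m1..m7``, ``s2``, ``s1``, ``s0``; absent keys
    default to zero.
    """
    path = Path(path)
    text = path.read_text()
    values: dict[str, int] = {}
    if text.lstrip().startswith("{"):
        raw = json.loads(text)
        values = {str(k): int(v) for k, v in raw.items()}
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.lower().startswith(("key", "cell")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FamilyFileError(f"{path}: line {lineno}: expected 'key<TAB>value'")
            values[parts[0].strip()] = int(parts[1])
    unknown = set(values) - set(_COUNT_KEYS)
    if unknown:
        raise FamilyFileError(f"{path}: unknown count keys {sorted(unknown)}")
    return FamilyDataset(
        triads=TriadCounts([values.get(f"n{i}", 0) for i in range(1, 11)]),
        dyads=DyadCounts([values.get(f"m{i}", 0) for i in range(1, 8)]),
        monads=MonadCounts(
            s2=values.get("s2", 0), s1=values.get("s1", 0), s0=values.get("s0", 0)
        ),
    )


_LRT_MODELS = tuple(m.value for m in RiskModel)


def analyze(
    data,
    models: Sequence[str] = _LRT_MODELS + ("TDT", "zcom"),
    data_used: "str | Sequence[str]" = "FT+PD+AM",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run the requested tests and report MLEs and p-values in a tidy table.

    ``data`` may be a FamilyDataset, a family-file path, or a counts-file
    path (detected by content).  ``data_used`` restricts the likelihood to
    full triads (``FT``), triads plus dyads (``FT+PD``) or everything
    (``FT+PD+AM``); several subsets may be requested at once.  The optional
    Bonferroni column divides the nominal level by the number of tests run;
    the per-test p-values themselves are never adjusted.
    """
    if isinstance(data, (str, Path)):
        path = Path(data)
        with path.open() as handle:
            head = handle.read(1024).lstrip()
        if head.startswith("{") or head.split("\t")[0].strip() in _COUNT_KEYS:
            data = read_counts(path)
        else:
            data = tabulate(read_families(path)).counts
    if isinstance(data_used, str):
        data_used = [data_used]

    rows = []
    n_tests = len(models) * len(data_used)
    for subset_name in data_used:
        subset = data.subset(subset_name)
        for name in models:
            key = name.strip().lower()
            if key == "tdt":
                res = tdt(subset.triads)
                fit_cols = {}
            elif key == "zcom":
                res = zcom(subset.triads, subset.dyads)
                fit_cols = {}
            else:
                res = lrt(subset, name)
                fit_cols = {
                    "p_null": res.null_fit.p_hat,
                    "p_alt": res.alt_fit.p_hat,
                    "psi1": res.alt_fit.psi1_hat,
                    "psi2": res.alt_fit.psi2_hat,
                }
            row = {
                "model": res.test,
                "data_used": subset_name.upper(),
                **fit_cols,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
            if bonferroni:
                row["bonferroni_p"] = min(1.0, res.p_value * n_tests)
            rows.append(row)
    columns = ["model", "data_used", "p_null", "p_alt", "psi1", "psi2", "statistic", "df", "p_value"]
    if bonferroni:
        columns.append("bonferroni_p")
    return pd.DataFrame(rows).reindex(columns=columns)
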