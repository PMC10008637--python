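"""Core containers and file I/O for codominant genotype and trait tables.

The genotype container holds diploid calls at multi-allelic codominant loci
(SSR / InDel fragment sizes): for each (accession, locus) an unordered pair of
positive integer allele codes, or missing.  Two text dialects are supported:

* ``delimited`` — CSV/TSV with one header row of locus names and one ``a/b``
  pair cell per locus (a two-column-per-locus layout is also accepted on read);
* ``structure`` — the classic STRUCTURE input layout with two rows per
  individual, an optional population column, and ``-9`` for missing.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal missing-genotype sentinel (also the STRUCTURE file convention).
MISSING = -9

#: Tokens accepted as "missing" in delimited files.
_MISSING_TOKENS = {"", "na", "nan", "-9", "-9/-9", "./.", "?"}


class FormatError(ValueError):
    """A genotype/trait file does not follow the declared dialect."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant (e.g. duplicate ids)."""


@dataclass(frozen=True)
class Accession:
    """One germplasm entry: a landrace or breeding line."""

    id: str
    population: str = "NA"
    origin: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("accession id must be non-empty")
        if not self.population:
            raise ValidationError(f"accession {self.id!r}: empty population label")


class GenotypeMatrix:
    """Diploid codominant genotype calls, accession x locus.

    Parameters
    ----------
    accessions:
        Ordered accessions; ids must be unique.
    loci:
        Ordered unique locus names.
    calls:
        Integer array of shape ``(n_accessions, n_loci, 2)``.  Allele codes are
        positive integers; a missing call has both entries equal to
        :data:`MISSING`.  Pairs are stored order-normalised (smaller first), so
        genotype equality is insensitive to input allele order.
    """

    def __init__(self, accessions, loci, calls):
        accessions = list(accessions)
        loci = list(loci)
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(accessions), len(loci), 2):
            raise ValidationError(
                f"calls shape {calls.shape} != ({len(accessions)}, {len(loci)}, 2)"
            )
        ids = [a.id for a in accessions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate accession id(s): {dup}")
        if len(set(loci)) != len(loci):
            raise ValidationError("duplicate locus names")
        half_missing = (calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise ValidationError(
                f"half-missing call at accession {ids[i]!r}, locus {loci[l]!r}"
            )
        bad = (calls <= 0) & (calls != MISSING)
        if bad.any():
            i, l, _ = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive allele code at accession {ids[i]!r}, locus {loci[l]!r}"
            )
        self.accessions = accessions
        self.loci = loci
        self.calls = np.sort(calls, axis=2)  # MISSING < any code, so (m, m) is stable

    # -- basic protocol ----------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.accessions]

    @property
    def populations(self) -> pd.Series:
        return pd.Series([a.population for a in self.accessions], index=self.ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def subset(self, population: str | None = None, ids=None) -> "GenotypeMatrix":
        """Rows restricted to a population label and/or an id collection."""
        keep = np.ones(self.n_accessions, dtype=bool)
        if population is not None:
            keep &= np.array([a.population == population for a in self.accessions])
        if ids is not None:
            wanted = set(ids)
            keep &= np.array([a.id in wanted for a in self.accessions])
        acc = [a for a, k in zip(self.accessions, keep) if k]
        return GenotypeMatrix(acc, self.loci, self.calls[keep])

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeMatrix)
            and self.accessions == other.accessions
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self):
        return f"GenotypeMatrix({self.n_accessions} accessions x {self.n_loci} loci)"


@dataclass
class TraitTable:
    """Phenotypes: qualitative (integer category codes) and quantitative traits.

    Both frames are indexed by accession id; qualitative values are small
    integer codes (pandas ``Int64`` with NA for missing), quantitative values
    floats (NaN for missing).  ``populations`` carries the metadata label.
    """

    qualitative: pd.DataFrame
    quantitative: pd.DataFrame
    populations: pd.Series = field(default=None)

    def __post_init__(self):
        if not self.qualitative.index.equals(self.quantitative.index):
            raise ValidationError("qualitative/quantitative indexes differ")
        if self.qualitative.index.has_duplicates:
            raise ValidationError("duplicate accession ids in trait table")
        self.qualitative = self.qualitative.astype("Int64")
        self.quantitative = self.quantitative.astype(float)
        if self.populations is None:
            self.populations = pd.Series("NA", index=self.qualitative.index)
        self.populations = self.populations.reindex(self.qualitative.index)
        finite = self.quantitative.to_numpy(dtype=float)
        if np.isinf(finite).any():
            raise ValidationError("non-finite quantitative trait value")

    @property
    def ids(self) -> list[str]:
        return list(self.qualitative.index)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _parse_pair_cell(tok: str, where: str):
    tok = tok.strip()
    if tok.lower() in _MISSING_TOKENS:
        return (MISSING, MISSING)
    m = re.fullmatch(r"(-?\d+)\s*/\s*(-?\d+)", tok)
    if not m:
        raise FormatError(f"{where}: cannot parse genotype cell {tok!r}")
    a, b = int(m.group(1)), int(m.group(2))
    if a == MISSING or b == MISSING:
        return (MISSING, MISSING)
    return (a, b)


def read_genotypes(path, dialect: str = "delimited") -> GenotypeMatrix:
    """Read a :class:`GenotypeMatrix` from ``delimited`` or ``structure`` text."""
    if dialect == "delimited":
        return _read_delimited(path)
    if dialect == "structure":
        return _read_structure(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_delimited(path) -> GenotypeMatrix:
    sep = _sep_for(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=sep) if r]
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if not header or header[0].lower() not in {"id", "accession"}:
        raise FormatError(f"{path}: first header column must be 'id' or 'accession'")
    meta_cols = {"population", "origin"}
    ncol_meta = 1
    while ncol_meta < len(header) and header[ncol_meta].lower() in meta_cols:
        ncol_meta += 1
    locus_cols = header[ncol_meta:]
    # two-column layout: every locus name appears exactly twice consecutively
    two_col = (
        len(locus_cols) >= 2
        and len(locus_cols) % 2 == 0
        and all(locus_cols[i] == locus_cols[i + 1] for i in range(0, len(locus_cols), 2))
    )
    loci = locus_cols[::2] if two_col else locus_cols
    accessions, calls = [], []
    for ln, row in enumerate(rows[1:], start=2):
        row = [c.strip() for c in row]
        if len(row) != len(header):
            raise FormatError(f"{path}:{ln}: expected {len(header)} fields, got {len(row)}")
        meta = dict(zip((h.lower() for h in header[:ncol_meta]), row[:ncol_meta]))
        acc = Accession(
            id=meta.get("id") or meta.get("accession"),
            population=meta.get("population", "NA") or "NA",
            origin=meta.get("origin", ""),
        )
        body = row[ncol_meta:]
        pairs = []
        if two_col:
            for j in range(0, len(body), 2):
                a, b = body[j], body[j + 1]
                if a.lower() in _MISSING_TOKENS or b.lower() in _MISSING_TOKENS:
                    pairs.append((MISSING, MISSING))
                else:
                    try:
                        ai, bi = int(a), int(b)
                    except ValueError as exc:
                        raise FormatError(f"{path}:{ln}: bad allele {a!r}/{b!r}") from exc
                    if ai == MISSING or bi == MISSING:
                        pairs.append((MISSING, MISSING))
                    else:
                        pairs.append((ai, bi))
        else:
            for j, tok in enumerate(body):
                pairs.append(_parse_pair_cell(tok, f"{path}:{ln} locus {loci[j]!r}"))
        accessions.append(acc)
        calls.append(pairs)
    calls = (
        np.array(calls, dtype=np.int64)
        if calls
        else np.empty((0, len(loci), 2), dtype=np.int64)
    )
    return GenotypeMatrix(accessions, loci, calls)


def _read_structure(path) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    # optional first line of locus names (detected: an odd line count, since
    # genotype rows come in pairs)
    header = None
    if len(lines) % 2 == 1:
        header, lines = lines[0], lines[1:]
    widths = {len(ln) for ln in lines}
    if len(widths) > 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    width = widths.pop() if widths else 0
    if header is not None:
        extra = width - 1 - len(header)
        if extra not in (0, 1):
            raise FormatError(
                f"{path}: header lists {len(header)} loci but rows carry {width - 1} fields"
            )
        has_pop = extra == 1
        loci = header
    else:
        # without a header the optional pop column is undetectable; assume absent
        has_pop = False
        loci = [f"L{j + 1}" for j in range(width - 1)]
    off = 2 if has_pop else 1
    n_loci = width - off
    accessions, calls = [], []
    for i in range(0, len(lines), 2):
        r1, r2 = lines[i], lines[i + 1]
        if r1[0] != r2[0]:
            raise FormatError(f"{path}: row pair mismatch {r1[0]!r} vs {r2[0]!r}")
        pop = r1[off - 1] if has_pop else "NA"
        pairs = []
        for j in range(n_loci):
            try:
                a, b = int(r1[off + j]), int(r2[off + j])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: individual {r1[0]!r}, locus {loci[j]!r}: bad token"
                ) from exc
            if a == MISSING or b == MISSING:
                a = b = MISSING
            elif a <= 0 or b <= 0:
                raise FormatError(
                    f"{path}: individual {r1[0]!r}, locus {loci[j]!r}: "
                    f"unknown missing token {a}/{b} (expected -9)"
                )
            pairs.append((a, b))
        accessions.append(Accession(id=r1[0], population=pop))
        calls.append(pairs)
    return GenotypeMatrix(accessions, loci, np.array(calls, dtype=np.int64))


def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "delimited") -> None:
    """Write a genotype matrix; output is bit-stable for a fixed input."""
    if dialect == "delimited":
        sep = _sep_for(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter=sep, lineterminator="\n")
            w.writerow(["id", "population", "origin", *gm.loci])
            for acc, row in zip(gm.accessions, gm.calls):
                cells = [
                    "NA" if a == MISSING else f"{a}/{b}" for a, b in row
                ]
                w.writerow([acc.id, acc.population, acc.origin, *cells])
    elif dialect == "structure":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(" ".join(gm.loci) + "\n")
            pops = {p: i + 1 for i, p in enumerate(dict.fromkeys(a.population for a in gm.accessions))}
            for acc, row in zip(gm.accessions, gm.calls):
                for c in (0, 1):
                    toks = [acc.id, str(pops[acc.population])]
                    toks += [str(int(x)) for x in row[:, c]]
                    fh.write(" ".join(toks) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# trait I/O
# ---------------------------------------------------------------------------

_QUAL_PREFIX, _QUANT_PREFIX = "qual:", "quant:"


def write_traits(tt: TraitTable, path) -> None:
    """Single CSV with 'qual:'/'quant:' column prefixes to keep trait kinds."""
    out = pd.DataFrame(index=tt.qualitative.index)
    out["population"] = tt.populations
    for c in tt.qualitative.columns:
        out[_QUAL_PREFIX + c] = tt.qualitative[c]
    for c in tt.quantitative.columns:
        out[_QUANT_PREFIX + c] = tt.quantitative[c]
    out.to_csv(path, index_label="id")


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, index_col="id")
    qual = df[[c for c in df.columns if c.startswith(_QUAL_PREFIX)]].copy()
    quant = df[[c for c in df.columns if c.startswith(_QUANT_PREFIX)]].copy()
    qual.columns = [c[len(_QUAL_PREFIX):] for c in qual.columns]
    quant.columns = [c[len(_QUANT_PREFIX):] for c in quant.columns]
    pops = df["population"] if "population" in df else None
    return TraitTable(qualitative=qual, quantitative=quant, populations=pops)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationIssue:
    kind: str
    detail: str


def validate_dataset(gm: GenotypeMatrix | None, tt: TraitTable | None) -> list[ValidationIssue]:
    """Report-only consistency check; never mutates or raises on content."""
    issues: list[ValidationIssue] = []
    if gm is not None and tt is not None:
        gids, tids = set(gm.ids), set(tt.ids)
        for i in sorted(gids - tids):
            issues.append(ValidationIssue("unmatched accession", f"{i} only in genotypes"))
        for i in sorted(tids - gids):
            issues.append(ValidationIssue("unmatched accession", f"{i} only in traits"))
    if gm is not None:
        miss = gm.missing_mask()
        for j, locus in enumerate(gm.loci):
            col = gm.calls[~miss[:, j], j, :]
            if col.size == 0:
                issues.append(ValidationIssue("all-missing locus", locus))
            elif np.unique(col).size == 1:
                issues.append(ValidationIssue("monomorphic locus", locus))
    if tt is not None:
        for c in tt.qualitative.columns:
            if tt.qualitative[c].isna().all():
                issues.append(ValidationIssue("all-missing trait", c))
        for c in tt.quantitative.columns:
            if tt.quantitative[c].isna().all():
                issues.append(ValidationIssue("all-missing trait", c))
    return issues
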