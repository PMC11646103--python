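"""Genotype tables, allele-frequency tables, and colony-level QC.

Colonies are supplied as one table each: an optional queen plus her workers,
genotyped at L codominant microsatellite loci. Entries are unordered diploid
allele pairs; missing data are tolerated and preserved. Before inference a
colony passes through :func:`qc_filter`, which applies the standard rules for
sibship studies: drop workers typed at fewer than half the loci, drop loci
typed in fewer than half the individuals, drop loci that are monomorphic
within the colony, and declare the colony evaluable only if enough
polymorphic loci remain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = None

#: role flags
QUEEN = "queen"
WORKER = "worker"

_MISSING_TOKENS = {"", "0", "00", "000", "na", "nan", "none", "-"}


def _normalize_allele(label) -> str:
    """Canonical string form of an allele label.

    Numeric labels are compared after stripping leading zeros, so the
    fragment sizes ``98`` and ``098`` (2- vs 3-digit Genepop coding) are the
    same allele.
    """
    s = str(label).strip()
    if re.fullmatch(r"\d+", s):
        return str(int(s))
    return s


def _canonical_pair(a, b):
    a, b = _normalize_allele(a), _normalize_allele(b)
    return (a, b) if a <= b else (b, a)


class GenotypeTable:
    """Individuals x loci matrix of unordered diploid allele pairs.

    Parameters
    ----------
    individual_ids : sequence of str
    locus_names : sequence of str
    entries : nested sequence, shape (n_individuals, n_loci)
        Each entry an ``(allele, allele)`` pair or ``None`` for missing.
        Pairs are canonicalized (sorted, zero-padding-normalized) on ingest.
    roles : sequence of {"queen", "worker"}
        At most one individual may be flagged queen.
    """

    def __init__(self, individual_ids, locus_names, entries, roles):
        self.individual_ids = [str(i) for i in individual_ids]
        self.locus_names = [str(l) for l in locus_names]
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = [i for i in self.individual_ids
                     if self.individual_ids.count(i) > 1]
            raise ValueError(f"duplicated individual id(s): {sorted(set(dupes))}")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicated locus names")
        self.roles = list(roles)
        if len(self.roles) != len(self.individual_ids):
            raise ValueError("roles and individual_ids length mismatch")
        bad = set(self.roles) - {QUEEN, WORKER}
        if bad:
            raise ValueError(f"unknown role(s): {bad}")
        if self.roles.count(QUEEN) > 1:
            raise ValueError("at most one individual may be flagged queen")
        self.entries = []
        for row in entries:
            if len(row) != len(self.locus_names):
                raise ValueError("entry row length does not match locus count")
            self.entries.append(
                [None if e is None else _canonical_pair(*e) for e in row]
            )
        if len(self.entries) != len(self.individual_ids):
            raise ValueError("entries and individual_ids length mismatch")

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def queen_index(self):
        """Row index of the queen, or None when no queen is present."""
        try:
            return self.roles.index(QUEEN)
        except ValueError:
            return None

    @property
    def worker_indices(self):
        return [i for i, r in enumerate(self.roles) if r == WORKER]

    def genotype(self, individual: int, locus: int):
        return self.entries[individual][locus]

    def missing_fraction(self, individual: int) -> float:
        row = self.entries[individual]
        return sum(e is None for e in row) / len(row)

    def locus_missing_fraction(self, locus: int) -> float:
        col = [row[locus] for row in self.entries]
        return sum(e is None for e in col) / len(col)

    def alleles_at(self, locus: int) -> set:
        """Distinct allele labels observed at a locus."""
        out = set()
        for row in self.entries:
            e = row[locus]
            if e is not None:
                out.update(e)
        return out

    def subset(self, individuals=None, loci=None) -> "GenotypeTable":
        ind = list(range(self.n_individuals)) if individuals is None else list(individuals)
        loc = list(range(self.n_loci)) if loci is None else list(loci)
        return GenotypeTable(
            [self.individual_ids[i] for i in ind],
            [self.locus_names[l] for l in loc],
            [[self.entries[i][l] for l in loc] for i in ind],
            [self.roles[i] for i in ind],
        )

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeTable)
            and self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and self.roles == other.roles
            and self.entries == other.entries
        )

    def __repr__(self):
        q = "queen + " if self.queen_index is not None else ""
        return (f"<GenotypeTable {q}{len(self.worker_indices)} workers x "
                f"{self.n_loci} loci>")


@dataclass
class AlleleFrequencies:
    """Per-locus allele labels and population frequencies.

    ``loci`` maps locus name -> (list of allele labels, frequency array).
    Frequencies are strictly positive and sum to one per locus.
    """

    loci: dict

    def __post_init__(self):
        for name, (labels, p) in self.loci.items():
            p = np.asarray(p, dtype=float)
            if len(labels) != len(p):
                raise ValueError(f"{name}: labels/frequency length mismatch")
            if len(labels) != len(set(labels)):
                raise ValueError(f"{name}: duplicated allele labels")
            if np.any(p <= 0):
                raise ValueError(f"{name}: frequencies must be strictly positive")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name}: frequencies must sum to 1 (got {p.sum()})")
            self.loci[name] = ([_normalize_allele(a) for a in labels], p)

    @classmethod
    def uniform(cls, locus_names, n_alleles) -> "AlleleFrequencies":
        """Equal frequencies over ``n_alleles`` labels "1".."k" at each locus."""
        labels = [str(a + 1) for a in range(n_alleles)]
        p = np.full(n_alleles, 1.0 / n_alleles)
        return cls({name: (list(labels), p.copy()) for name in locus_names})

    def labels(self, locus):
        return self.loci[locus][0]

    def p(self, locus):
        return self.loci[locus][1]

    def n_alleles(self, locus):
        return len(self.loci[locus][0])

    def covers(self, table: GenotypeTable) -> bool:
        """True if every allele observed in ``table`` has nonzero frequency."""
        for l, name in enumerate(table.locus_names):
            if name not in self.loci:
                return False
            if not table.alleles_at(l) <= set(self.labels(name)):
                return False
        return True


@dataclass
class QCReport:
    """Outcome of colony-level quality filtering."""

    removed_individuals: list = field(default_factory=list)  # (id, reason)
    removed_loci: list = field(default_factory=list)         # (name, reason)
    n_polymorphic_loci: int = 0
    min_polymorphic_loci: int = 6
    colony_evaluable: bool = False

    def __str__(self):
        lines = [f"QC report: {len(self.removed_individuals)} individuals and "
                 f"{len(self.removed_loci)} loci removed;"]
        for i, r in self.removed_individuals:
            lines.append(f"  - individual {i}: {r}")
        for l, r in self.removed_loci:
            lines.append(f"  - locus {l}: {r}")
        lines.append(
            f"{self.n_polymorphic_loci} polymorphic loci retained "
            f"(minimum {self.min_polymorphic_loci}); colony "
            f"{'evaluable' if self.colony_evaluable else 'NOT evaluable'}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(path, format: str = "csv") -> GenotypeTable:
    """Read a colony genotype table.

    CSV dialect: header ``id,role,<locus>_a1,<locus>_a2,...`` with
    role in {queen, worker}; missing alleles coded 0 or left empty.

    Genepop dialect: title line (ignored), locus names (one per line or
    comma-separated on one line), ``Pop``, then ``id , 0102 0000`` records
    with 2- or 3-digit allele codes, 00/000 = missing. One population per
    colony. An individual whose id equals "queen" (case-insensitive) is
    flagged as the queen; all others are workers.
    """
    if format == "csv":
        return _read_csv(path)
    if format == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown format: {format!r}")


def _pair_from_tokens(a, b, where):
    a = str(a).strip().lower()
    b = str(b).strip().lower()
    a_missing = a in _MISSING_TOKENS
    b_missing = b in _MISSING_TOKENS
    if a_missing != b_missing:
        raise ValueError(f"half-missing genotype at {where}")
    if a_missing:
        return None
    return (a, b)


def _read_csv(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 4 or cols[0] != "id" or cols[1] != "role":
        raise ValueError("CSV header must start with 'id,role' followed by "
                         "<locus>_a1,<locus>_a2 column pairs")
    allele_cols = cols[2:]
    if len(allele_cols) % 2 != 0:
        raise ValueError("odd number of allele columns")
    loci = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith("_a1") and c2.endswith("_a2") and c1[:-3] == c2[:-3]):
            raise ValueError(f"allele columns must pair as <locus>_a1,<locus>_a2 "
                             f"(got {c1!r},{c2!r})")
        loci.append(c1[:-3])
    ids, roles, entries = [], [], []
    for ridx, row in df.iterrows():
        ids.append(row["id"])
        role = str(row["role"]).strip().lower()
        if role not in (QUEEN, WORKER):
            raise ValueError(f"line {ridx + 2}: unknown role {row['role']!r}")
        roles.append(role)
        ent = []
        for i, loc in enumerate(loci):
            a = row[allele_cols[2 * i]]
            b = row[allele_cols[2 * i + 1]]
            ent.append(_pair_from_tokens(a, b, f"line {ridx + 2}, locus {loc}"))
        entries.append(ent)
    return GenotypeTable(ids, loci, entries, roles)


def _read_genepop(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise ValueError("truncated Genepop file")
    body = lines[1:]  # title line ignored
    loci = []
    pop_at = None
    for i, ln in enumerate(body):
        if ln.strip().lower() == "pop":
            pop_at = i
            break
        loci.extend(t.strip() for t in ln.split(",") if t.strip())
    if pop_at is None:
        raise ValueError("no 'Pop' line found")
    records = body[pop_at + 1:]
    if any(ln.strip().lower() == "pop" for ln in records):
        raise ValueError("expected a single population (one colony) per file")
    ids, roles, entries = [], [], []
    for ln in records:
        if "," not in ln:
            raise ValueError(f"malformed Genepop record (no comma): {ln!r}")
        ident, geno = ln.split(",", 1)
        ident = ident.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"individual {ident!r}: {len(tokens)} genotypes for {len(loci)} loci")
        ent = []
        for tok, loc in zip(tokens, loci):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(
                    f"individual {ident!r}, locus {loc}: bad genotype code {tok!r}")
            half = len(tok) // 2
            ent.append(_pair_from_tokens(tok[:half], tok[half:],
                                         f"individual {ident}, locus {loc}"))
        ids.append(ident)
        roles.append(QUEEN if ident.lower() == QUEEN else WORKER)
        entries.append(ent)
    return GenotypeTable(ids, loci, entries, roles)


def write_genotypes(table: GenotypeTable, path, format: str = "csv") -> None:
    """Write a genotype table; inverse of :func:`read_genotypes`."""
    if format == "csv":
        cols = {"id": table.individual_ids, "role": table.roles}
        for l, name in enumerate(table.locus_names):
            a1, a2 = [], []
            for i in range(table.n_individuals):
                e = table.entries[i][l]
                a1.append("0" if e is None else e[0])
                a2.append("0" if e is None else e[1])
            cols[f"{name}_a1"] = a1
            cols[f"{name}_a2"] = a2
        pd.DataFrame(cols).to_csv(path, index=False)
    elif format == "genepop":
        width = 2
        for l in range(table.n_loci):
            for row in table.entries:
                e = row[l]
                if e is not None and any(len(a) > 2 for a in e):
                    width = 3
        with open(path, "w") as fh:
            fh.write("colony genotypes\n")
            for name in table.locus_names:
                fh.write(name + "\n")
            fh.write("Pop\n")
            for i, ident in enumerate(table.individual_ids):
                codes = []
                for e in table.entries[i]:
                    if e is None:
                        codes.append("0" * (2 * width))
                    else:
                        codes.append(e[0].zfill(width) + e[1].zfill(width))
                fh.write(f"{ident} , " + " ".join(codes) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# QC and in-colony frequency estimation


def qc_filter(table: GenotypeTable, max_missing_frac: float = 0.5,
              min_polymorphic_loci: int = 6):
    """Apply colony-level quality filters.

    Order: (1) workers missing at more than ``max_missing_frac`` of loci are
    discarded (the queen, if present, is always kept — her genotype is
    optional data, not a sampled offspring); (2) loci missing in more than
    ``max_missing_frac`` of the remaining individuals are removed; (3) loci
    monomorphic across the remaining individuals are removed. The report
    counts the polymorphic loci that survive and flags the colony evaluable
    only when at least ``min_polymorphic_loci`` remain.

    Returns ``(filtered_table, QCReport)``. Idempotent.
    """
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("empty genotype table")
    report = QCReport(min_polymorphic_loci=min_polymorphic_loci)

    keep_ind = []
    for i in range(table.n_individuals):
        if table.roles[i] == WORKER and table.missing_fraction(i) > max_missing_frac:
            report.removed_individuals.append(
                (table.individual_ids[i],
                 f"missing at {table.missing_fraction(i):.1%} of loci "
                 f"(> {max_missing_frac:.0%})"))
        else:
            keep_ind.append(i)
    t = table.subset(individuals=keep_ind)

    keep_loc = []
    for l in range(t.n_loci):
        frac = t.locus_missing_fraction(l)
        if frac > max_missing_frac:
            report.removed_loci.append(
                (t.locus_names[l],
                 f"missing in {frac:.1%} of individuals (> {max_missing_frac:.0%})"))
        else:
            keep_loc.append(l)
    t = t.subset(loci=keep_loc)

    keep_loc = []
    for l in range(t.n_loci):
        n_alleles = len(t.alleles_at(l))
        if n_alleles < 2:
            report.removed_loci.append((t.locus_names[l], "monomorphic"))
        else:
            keep_loc.append(l)
    t = t.subset(loci=keep_loc)

    report.n_polymorphic_loci = sum(
        len(t.alleles_at(l)) >= 2 for l in range(t.n_loci))
    report.colony_evaluable = report.n_polymorphic_loci >= min_polymorphic_loci
    return t, report


def estimate_allele_frequencies(tables, pseudocount: float = 1.0) -> AlleleFrequencies:
    """Allele frequencies by counting allele copies, with add-``pseudocount``
    smoothing over each locus's observed allele universe.

    This is the fallback when no external reference population is available;
    within-colony counts violate Hardy-Weinberg assumptions (families are not
    random samples) but remain serviceable as a prior for parental alleles.
    """
    if isinstance(tables, GenotypeTable):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    counts: dict[str, dict[str, float]] = {}
    for t in tables:
        for l, name in enumerate(t.locus_names):
            c = counts.setdefault(name, {})
            for row in t.entries:
                e = row[l]
                if e is not None:
                    for a in e:
                        c[a] = c.get(a, 0.0) + 1.0
    loci = {}
    for name, c in counts.items():
        if not c:
            raise ValueError(f"locus {name}: no observed alleles")
        labels = sorted(c, key=lambda a: (len(a), a))
        tot = sum(c.values()) + pseudocount * len(labels)
        p = np.array([(c[a] + pseudocount) / tot for a in labels])
        loci[name] = (labels, p)
    missing = [n for t in tables for n in t.locus_names if not counts.get(n)]
    if missing:
        raise ValueError(f"loci with no observed alleles: {sorted(set(missing))}")
    return AlleleFrequencies(loci)


def read_allele_frequencies(path) -> AlleleFrequencies:
    """Read a ``locus,allele,frequency`` CSV."""
    df = pd.read_csv(path, dtype={"locus": str, "allele": str,
                                  "frequency": float})
    need = {"locus", "allele", "frequency"}
    if not need <= set(df.columns):
        raise ValueError("frequency table needs columns locus,allele,frequency")
    loci = {}
    for name, grp in df.groupby("locus", sort=False):
        loci[str(name)] = (list(grp["allele"]), grp["frequency"].to_numpy())
    return AlleleFrequencies(loci)


def write_allele_frequencies(freqs: AlleleFrequencies, path) -> None:
    rows = []
    for name, (labels, p) in freqs.loci.items():
        for a, f in zip(labels, p):
            rows.append((name, a, f))
    pd.DataFrame(rows, columns=["locus", "allele", "frequency"]).to_csv(
        path, index=False)
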