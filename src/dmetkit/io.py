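"""Reading, writing and canonicalization of DMET-style genotype tables.

The tabular layout mirrors what DMET Console exports: the first row holds
sample identifiers, the first column probe identifiers, and each cell a
diploid call such as ``C/T`` or the literal ``NoCall``.  A second header row
named ``Class`` assigns each sample to a phenotype class; alternatively a
two-column sidecar file (``sample_id<TAB>class``) can provide the labels.

Genotype calls are unordered allele pairs over the alphabet ``{-, A, C, G, T}``
(``-`` is a legitimate allele denoting a deletion/absent allele, not a missing
measurement) and are stored canonically sorted, so ``G/C`` and ``C/G`` are the
same call.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, UnknownProbeError, ValidationError

#: Allele alphabet in canonical order ("-" sorts before the bases).
ALLELES = ("-", "A", "C", "G", "T")

#: Tokens (lower-cased) accepted as a missing genotype measurement.
NOCALL_TOKENS = frozenset({"nocall", "---", "./."})

_CALL_RE = re.compile(r"^([ACGT-])/([ACGT-])$")


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """A canonicalized diploid genotype call, or a NoCall.

    ``allele1 <= allele2`` under the fixed ordering ``- < A < C < G < T``;
    a NoCall carries no alleles.
    """

    allele1: str | None
    allele2: str | None
    is_nocall: bool = False

    def __post_init__(self) -> None:
        if self.is_nocall:
            if self.allele1 is not None or self.allele2 is not None:
                raise ValueError("NoCall carries no alleles")
        else:
            if self.allele1 not in ALLELES or self.allele2 not in ALLELES:
                raise ValueError(f"alleles must be in {ALLELES}")
            if self.allele1 > self.allele2:  # type: ignore[operator]
                raise ValueError("alleles must be canonically ordered")

    def __str__(self) -> str:
        if self.is_nocall:
            return "NoCall"
        return f"{self.allele1}/{self.allele2}"


#: The unique NoCall instance.
NOCALL = GenotypeCall(None, None, True)


@lru_cache(maxsize=4096)
def canonicalize_genotype(raw: str) -> GenotypeCall:
    """Parse a raw cell into a canonical :class:`GenotypeCall`.

    ``"X/Y"`` with alleles in ``{A,C,G,T,-}`` (any case, any order) maps to
    the sorted pair; ``NoCall``/``---``/``./.`` (case-insensitive) map to
    :data:`NOCALL`.  Canonicalization is idempotent: feeding back ``str(call)``
    returns an equal call.

    Raises :class:`ParseError` for anything else.
    """
    if not isinstance(raw, str):
        raise ParseError(f"genotype cell must be a string, got {type(raw).__name__}")
    token = raw.strip()
    if token.lower() in NOCALL_TOKENS:
        return NOCALL
    m = _CALL_RE.match(token.upper())
    if m is None:
        raise ParseError(f"unrecognized genotype call {raw!r}")
    a, b = sorted((m.group(1), m.group(2)))
    return GenotypeCall(a, b)


@dataclass
class DmetDataset:
    """A probes × samples matrix of genotype calls with per-sample class labels."""

    probe_ids: list[str]
    sample_ids: list[str]
    calls: list[list[GenotypeCall]]
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = _duplicates(self.probe_ids)
            raise ValidationError(f"duplicate probe id(s): {', '.join(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample id(s): {', '.join(dupes)}")
        if len(self.calls) != len(self.probe_ids):
            raise ValidationError(
                f"call matrix has {len(self.calls)} rows for {len(self.probe_ids)} probes"
            )
        for pid, row in zip(self.probe_ids, self.calls):
            if len(row) != len(self.sample_ids):
                raise ValidationError(
                    f"probe {pid!r}: {len(row)} cells for {len(self.sample_ids)} samples"
                )
        missing = [s for s in self.sample_ids if s not in self.class_labels]
        if missing:
            raise ValidationError(
                f"sample(s) without class label: {', '.join(missing)}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[str]:
        """Distinct class names present, lexicographically sorted."""
        return sorted({self.class_labels[s] for s in self.sample_ids})

    def samples_of(self, class_name: str) -> list[str]:
        return [s for s in self.sample_ids if self.class_labels[s] == class_name]

    def probe_row(self, probe_id: str) -> list[GenotypeCall]:
        try:
            idx = self.probe_ids.index(probe_id)
        except ValueError:
            raise UnknownProbeError([probe_id]) from None
        return self.calls[idx]


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in items:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# reading


def _delimiter(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")


def load_class_file(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>class`` sidecar file."""
    labels: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            sample, label = row[0].strip(), row[1].strip()
            if sample.lower() in {"sample_id", "sample"}:  # optional header
                continue
            if sample in labels:
                raise ValidationError(f"{path}: duplicate sample id {sample!r}")
            labels[sample] = label
    return labels


def _read_rows(path: str | Path, dialect: str) -> list[list[str]]:
    p = Path(path)
    if p.suffix.lower() in {".xlsx", ".xls"}:
        try:
            import pandas as pd

            frame = pd.read_excel(p, header=None, dtype=str)
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ParseError(
                "reading Excel files requires the 'excel' extra (openpyxl); "
                "export the sheet as TSV instead"
            ) from exc
        return [
            ["" if pd.isna(c) else str(c) for c in row]
            for row in frame.itertuples(index=False)
        ]
    with open(p, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh, delimiter=_delimiter(dialect))]


def read_dmet_table(
    path: str | Path,
    dialect: str = "tsv",
    class_file: str | Path | None = None,
) -> DmetDataset:
    """Read a DMET-layout genotype table into a :class:`DmetDataset`.

    Class labels come from a second header row whose first cell is ``Class``,
    or — when that row is absent — from *class_file*.  Row and column order
    are preserved; every cell is canonicalized.
    """
    rows = [r for r in _read_rows(path, dialect)]
    # drop trailing fully-blank lines (editors often add one)
    while rows and all(not c.strip() for c in rows[-1]):
        rows.pop()
    if not rows:
        raise ParseError(f"{path}: empty file")

    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    n = len(sample_ids)

    body = rows[1:]
    labels: dict[str, str]
    if body and body[0] and body[0][0].strip().lower() == "class":
        class_row = body.pop(0)
        if len(class_row) != n + 1:
            raise ParseError(
                f"{path}: line 2: Class row has {len(class_row) - 1} labels "
                f"for {n} samples"
            )
        labels = {s: c.strip() for s, c in zip(sample_ids, class_row[1:])}
    elif class_file is not None:
        labels = load_class_file(class_file)
    else:
        raise ValidationError(
            f"{path}: no 'Class' header row and no class file given"
        )

    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValidationError(
            f"{path}: sample(s) without class label: {', '.join(missing)}"
        )

    probe_ids: list[str] = []
    calls: list[list[GenotypeCall]] = []
    offset = 3 if class_file is None else 2  # first data line number
    for lineno, row in enumerate(body, start=offset):
        if all(not c.strip() for c in row):
            continue
        if len(row) != n + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {n + 1} fields, got {len(row)}"
            )
        pid = row[0].strip()
        parsed: list[GenotypeCall] = []
        for sid, cell in zip(sample_ids, row[1:]):
            try:
                parsed.append(canonicalize_genotype(cell))
            except ParseError as exc:
                raise ParseError(
                    f"{path}: line {lineno}, probe {pid!r}, sample {sid!r}: {exc}"
                ) from None
        probe_ids.append(pid)
        calls.append(parsed)

    return DmetDataset(probe_ids, sample_ids, calls, {s: labels[s] for s in sample_ids})


# ---------------------------------------------------------------------------
# writing


def write_dmet_table(
    dataset: DmetDataset, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write *dataset* in the DMET layout (sample row, Class row, probe rows).

    ``read_dmet_table(write_dmet_table(d)) == d``.
    """
    delim = _delimiter(dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["ProbeID", *dataset.sample_ids])
        writer.writerow(
            ["Class", *(dataset.class_labels[s] for s in dataset.sample_ids)]
        )
        for pid, row in zip(dataset.probe_ids, dataset.calls):
            writer.writerow([pid, *(str(c) for c in row)])


def select_probes(dataset: DmetDataset, probe_subset: Iterable[str]) -> DmetDataset:
    """Restrict *dataset* to *probe_subset*, in the requested order."""
    wanted = list(probe_subset)
    index = {pid: i for i, pid in enumerate(dataset.probe_ids)}
    missing = [pid for pid in wanted if pid not in index]
    if missing:
        raise UnknownProbeError(missing)
    return DmetDataset(
        probe_ids=wanted,
        sample_ids=list(dataset.sample_ids),
        calls=[dataset.calls[index[pid]] for pid in wanted],
        class_labels=dict(dataset.class_labels),
    )
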